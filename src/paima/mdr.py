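"""Exhaustive Multifactor Dimensionality Reduction (MDR).

MDR pools the 3^k multilocus genotype cells of a k-locus combination into
two risk classes: a cell is *high risk* when its case:control ratio meets
a threshold T (by default the dataset's overall case:control ratio), and
*low risk* otherwise.  The k loci thereby collapse to one binary
attribute whose classification performance — balanced accuracy,
sensitivity, specificity, precision, Cohen's kappa, F-measure and the
Pearson chi-square of the 2x2 confusion table — measures the joint
(possibly purely epistatic) effect of the combination.

Conventions, fixed here and documented because implementations differ:

* a cell whose ratio equals T exactly is labeled high;
* a cell with cases but no controls is high, one with neither is *empty*;
* empty cells predict low risk by default (``empty_cell`` policy);
* individuals missing a genotype at any model locus are excluded from
  cell counting and from metric computation for that model.

The exhaustive search evaluates every C(p, k) combination for each k
under stratified 10-fold cross-validation.  Within a k-class the winner
has the highest mean training balanced accuracy (the lowest training
classification error); the overall best model has the highest mean
testing balanced accuracy, ties broken by cross-validation consistency
and then by smaller k.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortDataset
from .variants import MISSING

log = logging.getLogger(__name__)

HIGH, LOW, EMPTY = 1, 0, -1

DEFAULT_FOLD_SEED = 42


# ---------------------------------------------------------------------
# metric primitives

def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Mean of the per-class recalls."""
    return (sensitivity + specificity) / 2.0


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class MetricsRecord:
    """Confusion counts and the derived classification metrics.

    Undefined ratios on degenerate margins are reported as NaN.
    ``chi2`` is the uncorrected Pearson statistic (1 df);
    ``chi2_corrected`` applies the Yates continuity correction.
    """

    tp: float
    fn: float
    fp: float
    tn: float
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    balanced_accuracy: float
    kappa: float
    f_measure: float
    chi2: float
    chi2_corrected: float
    p_value: float

    @classmethod
    def from_counts(cls, tp: float, fn: float, fp: float, tn: float) -> "MetricsRecord":
        n = tp + fn + fp + tn
        if n == 0:
            raise ValueError("empty confusion table")
        sens = tp / (tp + fn) if tp + fn > 0 else float("nan")
        spec = tn / (tn + fp) if tn + fp > 0 else float("nan")
        prec = tp / (tp + fp) if tp + fp > 0 else float("nan")
        acc = (tp + tn) / n
        ba = balanced_accuracy(sens, spec)
        # Cohen's kappa from the marginals
        pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
        kappa = (acc - pe) / (1 - pe) if pe < 1 else float("nan")
        fm = f_measure(prec, sens)
        det = tp * tn - fn * fp
        denom = (tp + fn) * (fp + tn) * (tp + fp) * (fn + tn)
        if denom > 0:
            chi2 = n * det**2 / denom
            chi2_c = n * max(abs(det) - n / 2.0, 0.0) ** 2 / denom
        else:
            chi2 = chi2_c = float("nan")
        pval = float(stats.chi2.sf(chi2, df=1)) if not np.isnan(chi2) else float("nan")
        return cls(tp, fn, fp, tn, sens, spec, prec, acc, ba, kappa, fm, chi2, chi2_c, pval)


# ---------------------------------------------------------------------
# risk-model construction

@dataclass
class RiskModel:
    """High/low/empty labels for every multilocus genotype cell."""

    loci: tuple[int, ...]
    cell_labels: np.ndarray  # length 3^k, values HIGH / LOW / EMPTY
    threshold: float

    def __post_init__(self) -> None:
        self.loci = tuple(int(i) for i in self.loci)
        self.cell_labels = np.asarray(self.cell_labels, dtype=np.int8)
        if len(self.cell_labels) != 3 ** len(self.loci):
            raise ValueError("cell label table must cover all 3^k cells")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    @property
    def k(self) -> int:
        return len(self.loci)

    def cell_label(self, cell: Sequence[int]) -> int:
        return int(self.cell_labels[int(np.ravel_multi_index(tuple(cell), (3,) * self.k))])


def _cell_index(genotypes: np.ndarray, loci: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Flat 3^k cell index per individual and the non-missing validity mask."""
    cells = np.zeros(len(genotypes), dtype=np.int64)
    valid = np.ones(len(genotypes), dtype=bool)
    for locus in loci:
        col = genotypes[:, locus]
        valid &= col != MISSING
        cells = cells * 3 + np.where(col == MISSING, 0, col)
    return cells, valid


def _labels_from_counts(case_counts: np.ndarray, ctrl_counts: np.ndarray, threshold: float) -> np.ndarray:
    labels = np.full(len(case_counts), EMPTY, dtype=np.int8)
    occupied = (case_counts + ctrl_counts) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        high = case_counts >= threshold * ctrl_counts
    labels[occupied & high] = HIGH
    labels[occupied & ~high] = LOW
    return labels


def label_cells(loci: Sequence[int], data: CohortDataset, threshold: float | None = None) -> RiskModel:
    """Label every genotype cell of ``loci`` high or low risk.

    A cell is high when cases/controls >= T (ties high; controls == 0
    with cases present is high); cells with no individuals are empty.
    T defaults to the dataset's case:control ratio.
    """
    loci = tuple(int(i) for i in loci)
    if len(loci) == 0:
        raise ValueError("need at least one locus")
    if len(set(loci)) != len(loci):
        raise ValueError("loci must be distinct")
    if data.n_individuals == 0:
        raise ValueError("empty dataset")
    if threshold is None:
        if data.n_controls == 0:
            raise ValueError("cannot derive a default threshold without controls")
        threshold = data.n_cases / data.n_controls
    cells, valid = _cell_index(data.genotypes, loci)
    ncell = 3 ** len(loci)
    case = data.phenotype == 1
    case_counts = np.bincount(cells[valid & case], minlength=ncell)
    ctrl_counts = np.bincount(cells[valid & ~case], minlength=ncell)
    return RiskModel(loci, _labels_from_counts(case_counts, ctrl_counts, threshold), threshold)


def classify(model: RiskModel, data: CohortDataset, empty_cell: str = "low") -> np.ndarray:
    """Predict case status from cell labels.

    Returns a vector with 1 (predicted case), 0 (predicted control) or
    -1 for individuals excluded by the missing-genotype policy (or by
    ``empty_cell="exclude"``).
    """
    if empty_cell not in ("low", "high", "exclude"):
        raise ValueError("empty_cell must be 'low', 'high' or 'exclude'")
    cells, valid = _cell_index(data.genotypes, model.loci)
    labels = model.cell_labels[cells]
    pred = np.where(labels == HIGH, 1, 0).astype(np.int8)
    if empty_cell == "high":
        pred[labels == EMPTY] = 1
    elif empty_cell == "exclude":
        pred[labels == EMPTY] = -1
    pred[~valid] = -1
    return pred


def evaluate(predictions: np.ndarray, phenotype: np.ndarray) -> MetricsRecord:
    """Score predictions against the phenotype (excluded entries dropped)."""
    predictions = np.asarray(predictions)
    phenotype = np.asarray(phenotype)
    if len(predictions) != len(phenotype):
        raise ValueError("length mismatch")
    keep = predictions >= 0
    pred, truth = predictions[keep], phenotype[keep]
    if len(pred) == 0 or truth.min() == truth.max():
        raise ValueError("need at least one case and one control after exclusions")
    tp = int(((pred == 1) & (truth == 1)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    return MetricsRecord.from_counts(tp, fn, fp, tn)


def fit_and_evaluate(loci: Sequence[int], data: CohortDataset, threshold: float | None = None) -> tuple[RiskModel, MetricsRecord]:
    """Label cells on the full dataset and score the refit (resubstitution)."""
    model = label_cells(loci, data, threshold)
    return model, evaluate(classify(model, data), data.phenotype)


# ---------------------------------------------------------------------
# cross-validation

def stratified_folds(phenotype: np.ndarray, n_folds: int, seed: int, max_redraw: int = 5) -> np.ndarray:
    """Phenotype-stratified fold assignment (0..n_folds-1 per individual).

    Folds are redrawn (bounded) if any fold ends up single-class, then an
    error is raised — only possible when a class has fewer members than
    folds.
    """
    from sklearn.model_selection import StratifiedKFold

    phenotype = np.asarray(phenotype)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    for attempt in range(max_redraw):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        assignment = np.empty(len(phenotype), dtype=np.int32)
        try:
            for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(phenotype)), phenotype)):
                assignment[test_idx] = f
        except ValueError as exc:
            raise ValueError(f"cannot stratify {n_folds} folds: {exc}") from exc
        ok = all(
            len(np.unique(phenotype[assignment == f])) == 2 for f in range(n_folds)
        )
        if ok:
            return assignment
    raise ValueError("could not draw folds with both classes present in every fold")


@dataclass
class CVSummary:
    """Cross-validated performance of one locus combination.

    ``training_metrics`` / ``testing_metrics`` average the per-fold metric
    values (their count fields hold the pooled counts across folds);
    ``testing_metrics_pooled`` recomputes every metric from the pooled
    confusion counts.  ``cv_consistency`` counts the folds in which this
    combination had the best training balanced accuracy within its
    k-class — meaningful when produced by :func:`search`; a standalone
    :func:`cross_validate` reports ``n_folds`` by convention.
    """

    loci: tuple[int, ...]
    rsids: tuple[str, ...]
    training_metrics: MetricsRecord
    testing_metrics: MetricsRecord
    testing_metrics_pooled: MetricsRecord
    cv_consistency: int
    n_folds: int
    fold_seed: int
    model: RiskModel | None = None

    @property
    def k(self) -> int:
        return len(self.loci)


_METRIC_FIELDS = (
    "sensitivity", "specificity", "precision", "accuracy",
    "balanced_accuracy", "kappa", "f_measure", "chi2", "chi2_corrected", "p_value",
)


def _mean_metrics(per_fold_counts: np.ndarray) -> MetricsRecord:
    """Fold-averaged metrics; count fields pooled across folds.

    ``per_fold_counts`` has shape (n_folds, 4) ordered (tp, fn, fp, tn).
    """
    records = [MetricsRecord.from_counts(*row) for row in per_fold_counts]
    pooled = per_fold_counts.sum(axis=0)
    means = {f: float(np.nanmean([getattr(r, f) for r in records])) for f in _METRIC_FIELDS}
    return MetricsRecord(tp=pooled[0], fn=pooled[1], fp=pooled[2], tn=pooled[3], **means)


def _fold_counts(
    cells: np.ndarray,
    valid: np.ndarray,
    case: np.ndarray,
    folds: np.ndarray,
    n_folds: int,
    ncell: int,
    threshold: float | None,
    empty_cell: str = "low",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-fold confusion counts (train, test), each (n_folds, 4)."""
    train_counts = np.zeros((n_folds, 4))
    test_counts = np.zeros((n_folds, 4))
    for f in range(n_folds):
        te = folds == f
        tr = ~te
        ca_tr = np.bincount(cells[valid & tr & case], minlength=ncell)
        co_tr = np.bincount(cells[valid & tr & ~case], minlength=ncell)
        t = threshold if threshold is not None else (
            ca_tr.sum() / co_tr.sum() if co_tr.sum() else 1.0
        )
        labels = _labels_from_counts(ca_tr, co_tr, t)
        pred_high = labels == HIGH
        if empty_cell == "high":
            pred_high = pred_high | (labels == EMPTY)
        ca_te = np.bincount(cells[valid & te & case], minlength=ncell)
        co_te = np.bincount(cells[valid & te & ~case], minlength=ncell)
        train_counts[f] = (
            ca_tr[pred_high].sum(), ca_tr[~pred_high].sum(),
            co_tr[pred_high].sum(), co_tr[~pred_high].sum(),
        )
        test_counts[f] = (
            ca_te[pred_high].sum(), ca_te[~pred_high].sum(),
            co_te[pred_high].sum(), co_te[~pred_high].sum(),
        )
    return train_counts, test_counts


def cross_validate(
    loci: Sequence[int],
    data: CohortDataset,
    n_folds: int = 10,
    fold_seed: int = DEFAULT_FOLD_SEED,
    threshold: float | None = None,
    cv_consistency: int | None = None,
) -> CVSummary:
    """Stratified k-fold cross-validation of one locus combination.

    Cells are labeled on each training 9/10 and scored on both partitions;
    metrics are averaged over folds (and pooled, for the testing side).
    """
    loci = tuple(int(i) for i in loci)
    folds = stratified_folds(data.phenotype, n_folds, fold_seed)
    cells, valid = _cell_index(data.genotypes, loci)
    case = data.phenotype == 1
    ncell = 3 ** len(loci)
    tr_counts, te_counts = _fold_counts(cells, valid, case, folds, n_folds, ncell, threshold)
    rsids = tuple(np.array(data.column_labels())[list(loci)])
    model = label_cells(loci, data, threshold)
    return CVSummary(
        loci=loci,
        rsids=rsids,
        training_metrics=_mean_metrics(tr_counts),
        testing_metrics=_mean_metrics(te_counts),
        testing_metrics_pooled=MetricsRecord.from_counts(*te_counts.sum(axis=0)),
        cv_consistency=n_folds if cv_consistency is None else cv_consistency,
        n_folds=n_folds,
        fold_seed=fold_seed,
        model=model,
    )


# ---------------------------------------------------------------------
# exhaustive search

@dataclass
class SearchResult:
    """Outcome of the exhaustive k-way search.

    ``table`` holds one row per evaluated combination; ``per_k`` the
    training winner of each k-class (with full CV detail and refit
    model); ``ranked`` the per-k winners ordered by the overall
    criterion (testing balanced accuracy, consistency, smaller k), so
    ``ranked[0]`` is the best model.
    """

    table: pd.DataFrame
    per_k: dict[int, CVSummary]
    ranked: list[CVSummary]

    @property
    def best(self) -> CVSummary:
        return self.ranked[0]


def search(
    data: CohortDataset,
    k_min: int = 1,
    k_max: int = 3,
    n_folds: int = 10,
    fold_seed: int = DEFAULT_FOLD_SEED,
    threshold: float | None = None,
) -> SearchResult:
    """Evaluate every C(p, k) locus combination for k in [k_min, k_max].

    Per fold, cells are labeled on the training part and scored on the
    held-out part.  Within each k-class, cross-validation consistency is
    the number of folds in which a combination attains the fold's best
    training balanced accuracy (ties -> the lexicographically first
    combination).
    """
    p = data.n_variants
    if not 1 <= k_min <= k_max <= p:
        raise ValueError("need 1 <= k_min <= k_max <= number of variants")
    folds = stratified_folds(data.phenotype, n_folds, fold_seed)
    case = data.phenotype == 1
    labels = np.array(data.column_labels())

    rows = []
    per_k: dict[int, CVSummary] = {}
    for k in range(k_min, k_max + 1):
        combos = list(itertools.combinations(range(p), k))
        ncell = 3**k
        n_combo = len(combos)
        tr_ba = np.empty((n_combo, n_folds))
        all_tr = np.empty((n_combo, n_folds, 4))
        all_te = np.empty((n_combo, n_folds, 4))
        for ci, combo in enumerate(combos):
            cells, valid = _cell_index(data.genotypes, combo)
            tr_counts, te_counts = _fold_counts(cells, valid, case, folds, n_folds, ncell, threshold)
            all_tr[ci] = tr_counts
            all_te[ci] = te_counts
            with np.errstate(invalid="ignore", divide="ignore"):
                sens = tr_counts[:, 0] / (tr_counts[:, 0] + tr_counts[:, 1])
                spec = tr_counts[:, 3] / (tr_counts[:, 2] + tr_counts[:, 3])
            tr_ba[ci] = (sens + spec) / 2.0
        # fold winners within the k-class -> consistency counts
        winners = np.argmax(np.nan_to_num(tr_ba, nan=-1.0), axis=0)
        consistency = np.bincount(winners, minlength=n_combo)
        with np.errstate(invalid="ignore", divide="ignore"):
            te_sens = all_te[..., 0] / (all_te[..., 0] + all_te[..., 1])
            te_spec = all_te[..., 3] / (all_te[..., 2] + all_te[..., 3])
        te_ba = (te_sens + te_spec) / 2.0
        mean_tr_ba = np.nanmean(tr_ba, axis=1)
        mean_te_ba = np.nanmean(te_ba, axis=1)
        for ci, combo in enumerate(combos):
            rows.append(
                {
                    "k": k,
                    "loci": combo,
                    "rsids": ",".join(labels[list(combo)]),
                    "training_balanced_accuracy": mean_tr_ba[ci],
                    "testing_balanced_accuracy": mean_te_ba[ci],
                    "cv_consistency": int(consistency[ci]),
                }
            )
        best_ci = int(np.argmax(mean_tr_ba))
        combo = combos[best_ci]
        cells, valid = _cell_index(data.genotypes, combo)
        tr_counts, te_counts = _fold_counts(cells, valid, case, folds, n_folds, ncell, threshold)
        per_k[k] = CVSummary(
            loci=combo,
            rsids=tuple(labels[list(combo)]),
            training_metrics=_mean_metrics(tr_counts),
            testing_metrics=_mean_metrics(te_counts),
            testing_metrics_pooled=MetricsRecord.from_counts(*te_counts.sum(axis=0)),
            cv_consistency=int(consistency[best_ci]),
            n_folds=n_folds,
            fold_seed=fold_seed,
            model=label_cells(combo, data, threshold),
        )
    ranked = sorted(
        per_k.values(),
        key=lambda s: (-s.testing_metrics.balanced_accuracy, -s.cv_consistency, s.k),
    )
    table = pd.DataFrame(rows).sort_values(
        ["testing_balanced_accuracy", "cv_consistency"], ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    return SearchResult(table=table, per_k=per_k, ranked=ranked)


def best_model_report(summary: CVSummary) -> dict:
    """JSON-serializable report of a cross-validated model."""
    def metrics_dict(m: MetricsRecord) -> dict:
        out = {f: (None if np.isnan(getattr(m, f)) else float(getattr(m, f))) for f in _METRIC_FIELDS}
        out.update({c: float(getattr(m, c)) for c in ("tp", "fn", "fp", "tn")})
        return out

    cell_table = None
    if summary.model is not None:
        k = summary.model.k
        cell_table = {
            "/".join(map(str, cell)): {HIGH: "high", LOW: "low", EMPTY: "empty"}[
                summary.model.cell_label(cell)
            ]
            for cell in itertools.product((0, 1, 2), repeat=k)
        }
    return {
        "loci": list(summary.loci),
        "rsids": list(summary.rsids),
        "k": summary.k,
        "cv_consistency": summary.cv_consistency,
        "n_folds": summary.n_folds,
        "fold_seed": summary.fold_seed,
        "training": metrics_dict(summary.training_metrics),
        "testing": metrics_dict(summary.testing_metrics),
        "testing_pooled": metrics_dict(summary.testing_metrics_pooled),
        "threshold": None if summary.model is None else summary.model.threshold,
        "cell_labels": cell_table,
    }
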