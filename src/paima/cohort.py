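"""Synthetic case cohorts, frequency-derived pseudo-controls, and planted
epistatic penetrance structure.

The study design this module emulates is a 1:1 case/"pseudo-control"
comparison: cases are real (here: simulated) individuals, while controls
are *constructed* from population allele frequencies by expanding each
frequency into Hardy-Weinberg genotype counts for a fixed number of
individuals.  The pseudo-control expansion is deterministic (expected
counts, largest-remainder rounding) so the control table for a given
frequency vector is always the same; a seeded stochastic mode is
available as an option.

For method validation the module can also plant known 2- or 3-locus
penetrance structure (e.g. XOR / parity models with no marginal effects)
into a genotype pool and sample a balanced case-control dataset from it.

Loci are independent by default (no linkage disequilibrium); an optional
Gaussian-copula mode induces block correlation between latent allele
dosages, emulating the LD that shows up as negative (redundant)
interaction information in real panels.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import MISSING, NA_TOKEN, FuncClass, VariantRecord

log = logging.getLogger(__name__)

PROVENANCES = ("observed", "synthetic", "pseudo_control", "merged")


@dataclass
class CohortDataset:
    """Genotype matrix with phenotype and per-column variant metadata.

    ``genotypes`` is ``n_individuals x n_variants`` int8 with entries
    0/1/2 (minor-allele counts) or ``-1`` for missing; ``phenotype`` is
    1 = case, 0 = control.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    variants: list[VariantRecord]
    provenance: str = "observed"
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        n, p = self.genotypes.shape
        if len(self.phenotype) != n:
            raise ValueError(f"phenotype length {len(self.phenotype)} != {n} rows")
        if len(self.variants) != p:
            raise ValueError(f"{len(self.variants)} variant records != {p} columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype entries must be 0, 1, 2 or -1 (missing)")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValueError("phenotype must be binary")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")
        if self.sample_ids is None:
            self.sample_ids = [f"S{i + 1}" for i in range(n)]
        elif len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")

    # -- conveniences -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    def column_labels(self) -> list[str]:
        """Unique per-column labels (rsid, disambiguated when duplicated)."""
        seen: dict[str, int] = {}
        labels = []
        for rsid in self.rsids:
            seen[rsid] = seen.get(rsid, 0) + 1
            labels.append(rsid if seen[rsid] == 1 else f"{rsid}.{seen[rsid]}")
        return labels

    # -- I/O ----------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write ``sample_id  phenotype  <rsid...>`` with ``NA`` missing."""
        df = pd.DataFrame(self.genotypes.astype(object), columns=self.column_labels())
        df = df.mask(df == MISSING, NA_TOKEN)
        df.insert(0, "phenotype", self.phenotype)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        variants: Sequence[VariantRecord] | None = None,
        provenance: str = "observed",
    ) -> "CohortDataset":
        df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN])
        sample_ids = df["sample_id"].astype(str).tolist()
        phenotype = df["phenotype"].to_numpy()
        gcols = [c for c in df.columns if c not in ("sample_id", "phenotype")]
        geno = df[gcols].to_numpy(dtype=float)
        geno = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
        if variants is None:
            variants = synthetic_records(len(gcols), rsids=[c.split(".")[0] for c in gcols])
        return cls(geno, phenotype, list(variants), provenance, sample_ids)


def synthetic_records(
    p: int,
    mafs: Sequence[float] | None = None,
    rsids: Sequence[str] | None = None,
) -> list[VariantRecord]:
    """Placeholder variant metadata for simulated loci."""
    recs = []
    for i in range(p):
        recs.append(
            VariantRecord(
                rsid=rsids[i] if rsids is not None else f"rs{9000001 + i}",
                genes=frozenset({f"LOCUS{i + 1}"}),
                func_class=FuncClass.NSSNV,
                pop_maf=None if mafs is None else float(mafs[i]),
                cohort_maf=None if mafs is None else float(mafs[i]),
            )
        )
    return recs


def _as_freqs(mafs: Sequence[float]) -> np.ndarray:
    f = np.asarray(mafs, dtype=float)
    if f.ndim != 1 or len(f) == 0:
        raise ValueError("need a non-empty 1-D frequency vector")
    if ((f < 0) | (f > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    return f


def sample_cases(
    mafs: Sequence[float],
    n: int,
    seed: int,
    variants: Sequence[VariantRecord] | None = None,
) -> CohortDataset:
    """Draw ``n`` case individuals under Hardy-Weinberg equilibrium.

    Each genotype is an independent Binomial(2, maf) draw, i.e.
    P(2) = maf^2, P(1) = 2 maf (1 - maf), P(0) = (1 - maf)^2.
    Bit-reproducible for a given ``seed``.
    """
    f = _as_freqs(mafs)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    geno = rng.binomial(2, f[None, :], size=(n, len(f))).astype(np.int8)
    recs = list(variants) if variants is not None else synthetic_records(len(f), f)
    return CohortDataset(geno, np.ones(n, dtype=np.int8), recs, "synthetic")


def hwe_genotype_counts(maf: float, n: int) -> tuple[int, int, int]:
    """Expected HWE genotype counts ``(n2, n1, n0)`` for ``n`` individuals.

    Largest-remainder rounding so the counts sum exactly to ``n``; ties in
    the remainders are broken toward the heterozygote class, then toward
    the minor homozygote (fixed, arbitrary order).
    """
    expected = np.array([n * maf**2, n * 2 * maf * (1 - maf), n * (1 - maf) ** 2])
    base = np.floor(expected).astype(int)
    deficit = n - int(base.sum())
    remainders = expected - base
    # priority: remainder desc, heterozygote first on ties, then class 2
    order = sorted(range(3), key=lambda i: (-remainders[i], i != 1, i))
    for i in order[:deficit]:
        base[i] += 1
    return int(base[0]), int(base[1]), int(base[2])


def build_pseudo_controls(
    pop_mafs: Sequence[float],
    n: int,
    variants: Sequence[VariantRecord] | None = None,
    mode: str = "expected",
    seed: int | None = None,
) -> CohortDataset:
    """Expand population allele frequencies into ``n`` control genotypes.

    ``mode="expected"`` (default) lays out, per variant, the deterministic
    expected HWE genotype counts (all 2s first, then 1s, then 0s).
    ``mode="sampled"`` draws seeded HWE genotypes instead.
    """
    f = _as_freqs(pop_mafs)
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode == "sampled":
        if seed is None:
            raise ValueError("sampled mode requires a seed")
        ds = sample_cases(f, n, seed, variants)
        return CohortDataset(ds.genotypes, np.zeros(n, dtype=np.int8), ds.variants, "pseudo_control")
    if mode != "expected":
        raise ValueError("mode must be 'expected' or 'sampled'")
    cols = []
    for maf in f:
        n2, n1, n0 = hwe_genotype_counts(float(maf), n)
        cols.append(np.repeat([2, 1, 0], [n2, n1, n0]).astype(np.int8))
    geno = np.column_stack(cols)
    recs = list(variants) if variants is not None else synthetic_records(len(f), f)
    return CohortDataset(geno, np.zeros(n, dtype=np.int8), recs, "pseudo_control")


@dataclass(frozen=True)
class PenetranceModel:
    """Disease probability as a function of a k-locus genotype cell.

    ``table`` maps each of the 3^k genotype tuples of ``loci`` to a
    penetrance; cells absent from the supplied mapping are filled with
    ``baseline`` at construction.
    """

    loci: tuple[int, ...]
    table: Mapping[tuple[int, ...], float]
    baseline: float = 0.0

    def __post_init__(self) -> None:
        k = len(self.loci)
        if k not in (2, 3):
            raise ValueError("penetrance models support 2 or 3 loci")
        if not 0.0 <= self.baseline <= 1.0:
            raise ValueError("baseline must be a probability")
        full = {}
        for cell in itertools.product((0, 1, 2), repeat=k):
            p = float(self.table.get(cell, self.baseline))
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"penetrance {p} for cell {cell} outside [0, 1]")
            full[cell] = p
        object.__setattr__(self, "table", full)

    def penetrance(self, genotype_row: Sequence[int]) -> float:
        cell = tuple(int(genotype_row[i]) for i in self.loci)
        return self.table[cell]

    def penetrance_vector(self, genotypes: np.ndarray) -> np.ndarray:
        """Vectorized penetrance lookup over the rows of a genotype matrix."""
        k = len(self.loci)
        idx = np.zeros(len(genotypes), dtype=int)
        for j, locus in enumerate(self.loci):
            idx = idx * 3 + genotypes[:, locus]
        flat = np.empty(3**k)
        for cell, p in self.table.items():
            flat[int(np.ravel_multi_index(cell, (3,) * k))] = p
        return flat[idx]

    # -- canonical epistatic testbeds ---------------------------------
    @classmethod
    def parity(cls, loci: Sequence[int], high: float = 0.9, low: float = 0.1) -> "PenetranceModel":
        """XOR/parity model: penetrance ``high`` where the summed genotype
        codes are odd, ``low`` where even.  Under allele frequency 0.5 the
        single-locus marginals vanish, so all signal is interaction.
        """
        loci = tuple(loci)
        table = {
            cell: (high if sum(cell) % 2 == 1 else low)
            for cell in itertools.product((0, 1, 2), repeat=len(loci))
        }
        return cls(loci=loci, table=table, baseline=low)


def plant_epistasis(
    pool: CohortDataset,
    model: PenetranceModel,
    n_cases: int,
    n_controls: int,
    seed: int,
    max_attempts_factor: int = 200,
) -> CohortDataset:
    """Sample a balanced case-control dataset with planted epistasis.

    Individuals are drawn from ``pool`` rows with replacement and assigned
    case status with the probability given by the penetrance model at
    their multilocus genotype, until both quotas are met.  Raises after
    ``max_attempts_factor * (n_cases + n_controls)`` draws when a quota is
    unreachable (e.g. all penetrances 0 or 1).
    """
    if max(model.loci) >= pool.n_variants:
        raise ValueError("model loci outside the pool's variant range")
    rng = np.random.default_rng(seed)
    quota = n_cases + n_controls
    cap = max_attempts_factor * quota
    case_rows: list[np.ndarray] = []
    ctrl_rows: list[np.ndarray] = []
    attempts = 0
    batch = max(256, quota)
    while (len(case_rows) < n_cases or len(ctrl_rows) < n_controls) and attempts < cap:
        idx = rng.integers(0, pool.n_individuals, size=batch)
        rows = pool.genotypes[idx]
        pen = model.penetrance_vector(rows)
        status = rng.random(batch) < pen
        attempts += batch
        for row, is_case in zip(rows, status):
            if is_case and len(case_rows) < n_cases:
                case_rows.append(row)
            elif not is_case and len(ctrl_rows) < n_controls:
                ctrl_rows.append(row)
    if len(case_rows) < n_cases or len(ctrl_rows) < n_controls:
        raise RuntimeError(
            f"could not reach quotas ({len(case_rows)}/{n_cases} cases, "
            f"{len(ctrl_rows)}/{n_controls} controls) within {cap} draws"
        )
    geno = np.vstack([np.array(case_rows), np.array(ctrl_rows)]).astype(np.int8)
    pheno = np.concatenate([np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)])
    return CohortDataset(geno, pheno, list(pool.variants), "merged")


def correlated_dosage_pool(
    mafs: Sequence[float],
    n: int,
    seed: int,
    rho: float = 0.0,
    block_size: int = 2,
) -> CohortDataset:
    """HWE-marginal genotype pool with optional block LD.

    A Gaussian copula correlates latent allele dosages within consecutive
    blocks of ``block_size`` loci at correlation ``rho``; marginals stay
    Hardy-Weinberg.  ``rho=0`` reduces to independent loci.
    """
    f = _as_freqs(mafs)
    p = len(f)
    rng = np.random.default_rng(seed)
    geno = np.empty((n, p), dtype=np.int8)
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        width = stop - start
        cov = np.full((width, width), rho)
        np.fill_diagonal(cov, 1.0)
        for allele in range(2):  # two independent haplotype draws per locus
            z = rng.multivariate_normal(np.zeros(width), cov, size=n, method="cholesky")
            carriers = stats.norm.cdf(z) < f[start:stop][None, :]
            if allele == 0:
                acc = carriers.astype(np.int8)
            else:
                acc += carriers.astype(np.int8)
        geno[:, start:stop] = acc
    recs = synthetic_records(p, f)
    return CohortDataset(geno, np.zeros(n, dtype=np.int8), recs, "synthetic")


def merge(cases: CohortDataset, controls: CohortDataset) -> CohortDataset:
    """Row-concatenate two datasets sharing an identical variant list."""
    if controls.n_individuals == 0 or cases.n_individuals == 0:
        raise ValueError("cannot merge an empty dataset")
    if cases.n_variants != controls.n_variants:
        raise ValueError(
            f"variant count mismatch: {cases.n_variants} vs {controls.n_variants}"
        )
    for a, b in zip(cases.variants, controls.variants):
        if a.rsid != b.rsid:
            raise ValueError(f"variant mismatch at {a.rsid!r} vs {b.rsid!r}")
    geno = np.vstack([cases.genotypes, controls.genotypes])
    pheno = np.concatenate([cases.phenotype, controls.phenotype])
    ids = [f"CA_{s}" for s in cases.sample_ids] + [f"CO_{s}" for s in controls.sample_ids]
    return CohortDataset(geno, pheno, list(cases.variants), "merged", ids)
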