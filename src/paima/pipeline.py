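"""End-to-end orchestration: refine -> synthesize/load -> merge -> MDR ->
entropy network -> power note -> Markdown report.

Every stage writes its outputs to the run directory and logs its counts,
so the analysis funnel (input variants -> retained variants -> pairs ->
triples -> best model) can be reconstructed from the logs or from the
report alone.  All seeds are recorded in the report; rerunning a config
reproduces the numeric outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from math import comb
from pathlib import Path

import numpy as np
import yaml

from . import cohort as ch
from . import entropy as en
from . import fixtures as fx
from . import mdr
from . import power as pw
from . import variants as vr

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (paths resolved at run time).

    With the default ``None`` inputs the shipped fixtures are used: cases
    are synthesized from the cohort allele-frequency column and
    pseudo-controls expanded from the population column.
    """

    out_dir: str = "results/run"
    annotated_path: str | None = None  # TSV/VCF; None -> shipped variant table
    panel_path: str | None = None  # None -> shipped 128-gene panel
    n_cases: int = 100
    n_controls: int = 100
    case_seed: int = 42
    k_min: int = 1
    k_max: int = 3
    n_folds: int = 10
    fold_seed: int = 42
    threshold: float | None = None  # None -> case:control ratio
    node_threshold: float = en.DEFAULT_NODE_THRESHOLD
    include_triangles: bool = True
    power_alpha: float = 0.05
    power_psi: float = 2.5

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text)
        return cls(**payload)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineReport:
    config: RunConfig
    funnel: dict
    outputs: dict


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                out = fn(*args, **kwargs)
                log.info("stage %s: done", name)
                return out
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - funnel into StageError
                raise StageError(name, exc) from exc

        return wrapper

    return deco


@_stage("refine")
def refine_stage(config: RunConfig, out: Path):
    panel = (
        vr.load_panel(config.panel_path)
        if config.panel_path
        else fx.load_panel_fixture()
    )
    if config.annotated_path is None:
        table = fx.variant_table()
    elif str(config.annotated_path).endswith((".vcf", ".vcf.gz")):
        table = vr.read_annotated_vcf(config.annotated_path)
    else:
        table = vr.read_annotated_tsv(config.annotated_path)
    records, genotypes, samples = vr.refine_table(table, panel)
    vr.write_refined_tsv(records, out / "refined_variants.tsv")
    counts = {fc.value: c for fc, c in vr.summarize_refinement(records).items()}
    (out / "class_counts.json").write_text(json.dumps(counts, indent=2))
    log.info("refine: %d input rows -> %d retained", len(table), len(records))
    return panel, records, genotypes, samples, len(table)


@_stage("cohort")
def cohort_stage(config: RunConfig, records, genotypes, samples, out: Path) -> ch.CohortDataset:
    if len(samples) > 0:
        cases = ch.CohortDataset(
            genotypes, np.ones(len(samples), dtype=np.int8), records, "observed", list(samples)
        )
    else:
        cases = ch.sample_cases(
            [r.cohort_maf for r in records], config.n_cases, config.case_seed, records
        )
    controls = ch.build_pseudo_controls(
        [r.pop_maf for r in records], config.n_controls, records
    )
    merged = ch.merge(cases, controls)
    merged.to_tsv(out / "cohort.tsv")
    log.info(
        "cohort: %d cases + %d pseudo-controls over %d variants",
        merged.n_cases, merged.n_controls, merged.n_variants,
    )
    return merged


@_stage("mdr")
def mdr_stage(config: RunConfig, data: ch.CohortDataset, out: Path) -> mdr.SearchResult:
    result = mdr.search(
        data,
        k_min=config.k_min,
        k_max=config.k_max,
        n_folds=config.n_folds,
        fold_seed=config.fold_seed,
        threshold=config.threshold,
    )
    table = result.table.copy()
    table["loci"] = table["loci"].map(lambda t: ",".join(map(str, t)))
    table.to_csv(out / "ranked_models.tsv", sep="\t", index=False, float_format="%.6f")
    (out / "best_model.json").write_text(
        json.dumps(mdr.best_model_report(result.best), indent=2)
    )
    log.info(
        "mdr: evaluated %d combinations; best %s (testing BA %.4f)",
        len(result.table), result.best.rsids, result.best.testing_metrics.balanced_accuracy,
    )
    return result


@_stage("entropy")
def entropy_stage(config: RunConfig, data: ch.CohortDataset, out: Path):
    graph = en.build_graph(
        data,
        node_threshold=config.node_threshold,
        include_triangles=config.include_triangles and config.k_max >= 3,
    )
    graph.to_graphml(out / "network.graphml")
    graph.to_json(out / "network.json")
    tree = en.dendrogram(graph)
    tree.write_newick(out / "dendrogram.nwk")
    stats = en.graph_stats(graph, visible_only=False)
    stats.to_json(out / "network_stats.json")
    log.info(
        "entropy: %d edges, %d triangles; edge SD %.4f",
        graph.graph.number_of_edges(), len(graph.triangles), stats.edge_sd,
    )
    return graph, stats


@_stage("power")
def power_stage(config: RunConfig, records, out: Path) -> pw.PowerResult:
    p0 = float(np.mean([r.pop_maf for r in records if r.pop_maf is not None]))
    design = pw.PowerDesign(
        alpha=config.power_alpha,
        p0=p0,
        psi=config.power_psi,
        n=config.n_cases,
        m=config.n_controls / config.n_cases,
    )
    result = pw.power(design)
    payload = {"design": asdict(design), **result.to_dict()}
    (out / "power.json").write_text(json.dumps(payload, indent=2))
    log.info("power: p0=%.3f -> exact %.4f / cc %.4f", p0, result.power_exact, result.power_cc)
    return result


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run all stages; any failure aborts with the stage name and cause."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel, records, genotypes, samples, n_input = refine_stage(config, out)
    data = cohort_stage(config, records, genotypes, samples, out)
    search_result = mdr_stage(config, data, out)
    graph, stats = entropy_stage(config, data, out)
    power_result = power_stage(config, records, out)

    p = len(records)
    counts = vr.summarize_refinement(records)
    funnel = {
        "panel_genes": len(panel),
        "input_rows": n_input,
        "retained_variants": p,
        "class_counts": {fc.value: c for fc, c in counts.items() if c},
        "individuals": data.n_individuals,
        "pairs_evaluated": comb(p, 2) if config.k_max >= 2 else 0,
        "triples_evaluated": comb(p, 3) if config.k_max >= 3 else 0,
        "best_model_rsids": list(search_result.best.rsids),
        "power_exact": power_result.power_exact,
    }
    report_path = out / "report.md"
    report_path.write_text(_render_report(config, funnel, stats))
    outputs = {
        "refined_variants": str(out / "refined_variants.tsv"),
        "cohort": str(out / "cohort.tsv"),
        "ranked_models": str(out / "ranked_models.tsv"),
        "best_model": str(out / "best_model.json"),
        "network": str(out / "network.graphml"),
        "dendrogram": str(out / "dendrogram.nwk"),
        "network_stats": str(out / "network_stats.json"),
        "power": str(out / "power.json"),
        "report": str(report_path),
    }
    return PipelineReport(config=config, funnel=funnel, outputs=outputs)


def _render_report(config: RunConfig, funnel: dict, stats) -> str:
    lines = [
        "# Panel epistasis pipeline report",
        "",
        "## Funnel",
        "",
        f"- panel genes: {funnel['panel_genes']}",
        f"- annotated input rows: {funnel['input_rows']}",
        f"- retained functional panel variants: {funnel['retained_variants']}",
        f"- class counts: {funnel['class_counts']}",
        f"- individuals (cases + pseudo-controls): {funnel['individuals']}",
    ]
    if funnel["pairs_evaluated"]:
        lines.append(f"- pairwise combinations evaluated: {funnel['pairs_evaluated']}")
    if funnel["triples_evaluated"]:
        lines.append(f"- triple combinations evaluated: {funnel['triples_evaluated']}")
    lines += [
        f"- best model: {', '.join(funnel['best_model_rsids'])}",
        f"- power (exact Fisher enumeration): {funnel['power_exact']:.4f}",
        "",
        "## Network",
        "",
        f"- edge-score SD (percent of H(Y)): {stats.edge_sd:.4f}",
        f"- max betweenness: {stats.max_betweenness:.2f}",
        f"- max closeness: {stats.max_closeness:.2f}",
        "",
        "## Reproducibility",
        "",
        f"- case synthesis seed: {config.case_seed}",
        f"- fold seed: {config.fold_seed}",
        f"- folds: {config.n_folds}, k range: {config.k_min}..{config.k_max}",
        "",
    ]
    return "\n".join(lines)
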