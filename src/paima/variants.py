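"""Panel-based refinement of annotated variant tables.

An annotated cohort table (ANNOVAR-style TSV or VCF) is reduced to the
functional variants of a gene panel: a variant survives when at least one
of its annotated genes is in the panel and its functional class is one of
the classes of interest (by default non-synonymous SNVs, stop gains,
frameshifts and splice-site variants).  Surviving variants carry a
cohort minor-allele frequency computed from the genotype columns, or the
pre-computed frequency shipped with the table when no genotypes are
present.

Genotypes are coded as minor-allele counts: 0 = major homozygote,
1 = heterozygote, 2 = minor homozygote; missing genotypes are ``-1``
internally ("NA" in TSV, "./." in VCF).  A genotype column whose computed
alternate-allele frequency exceeds 0.5 is recoded ``g -> 2 - g`` so that
the code keeps counting the minor allele; the computed frequency is kept
as-is on the record and the record is flagged (``alt_freq_flag``).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Internal code for a missing genotype.
MISSING = -1

#: Missing-genotype token in flat TSV files.
NA_TOKEN = "NA"

_RSID_RE = re.compile(r"^rs[0-9]+$")


class FuncClass(str, Enum):
    """Functional class of a variant (collapsed ANNOVAR vocabulary)."""

    NSSNV = "nsSNV"
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    SPLICING = "splicing"
    SYNONYMOUS = "synonymous"
    NONCODING = "noncoding"
    OTHER = "other"


#: Classes retained by default: protein-altering or splice-disrupting.
DEFAULT_KEEP_CLASSES = frozenset(
    {FuncClass.NSSNV, FuncClass.STOP_GAIN, FuncClass.FRAMESHIFT, FuncClass.SPLICING}
)

_CLASS_ALIASES = {
    "nssnv": FuncClass.NSSNV,
    "nonsynonymous snv": FuncClass.NSSNV,
    "nonsynonymous_snv": FuncClass.NSSNV,
    "missense": FuncClass.NSSNV,
    "missense_variant": FuncClass.NSSNV,
    "stop_gain": FuncClass.STOP_GAIN,
    "stopgain": FuncClass.STOP_GAIN,
    "stop-gained": FuncClass.STOP_GAIN,
    "stop gained": FuncClass.STOP_GAIN,
    "stop_gained": FuncClass.STOP_GAIN,
    "frameshift": FuncClass.FRAMESHIFT,
    "frameshift insertion": FuncClass.FRAMESHIFT,
    "frameshift deletion": FuncClass.FRAMESHIFT,
    "frameshift_variant": FuncClass.FRAMESHIFT,
    "splicing": FuncClass.SPLICING,
    "splice": FuncClass.SPLICING,
    "splice_site": FuncClass.SPLICING,
    "synonymous": FuncClass.SYNONYMOUS,
    "synonymous snv": FuncClass.SYNONYMOUS,
    "synonymous_snv": FuncClass.SYNONYMOUS,
    "noncoding": FuncClass.NONCODING,
    "non-coding": FuncClass.NONCODING,
    "intronic": FuncClass.NONCODING,
    "intergenic": FuncClass.NONCODING,
    "utr3": FuncClass.NONCODING,
    "utr5": FuncClass.NONCODING,
    "ncrna_exonic": FuncClass.NONCODING,
    "upstream": FuncClass.NONCODING,
    "downstream": FuncClass.NONCODING,
}


def parse_func_class(token: str) -> FuncClass:
    """Map an annotation token onto :class:`FuncClass`.

    Unknown tokens are classified as :attr:`FuncClass.OTHER` with a logged
    warning; downstream filtering then drops them.
    """
    key = str(token).strip().lower().replace(".", "_")
    try:
        return FuncClass(token)
    except ValueError:
        pass
    if key in _CLASS_ALIASES:
        return _CLASS_ALIASES[key]
    log.warning("unknown functional class token %r -> classified as 'other'", token)
    return FuncClass.OTHER


@dataclass(frozen=True)
class VariantRecord:
    """One panel variant and its metadata.

    ``pop_maf`` is the database (population) minor-allele frequency;
    ``cohort_maf`` the frequency observed in the study cohort.  The cohort
    value is an alternate-allele frequency and may exceed 0.5, in which
    case ``alt_freq_flag`` is set (genotype columns are recoded downstream
    so that codes keep counting the minor allele).
    """

    rsid: str
    genes: frozenset[str]
    func_class: FuncClass
    pop_maf: float | None = None
    cohort_maf: float | None = None
    allele_change: str = ""
    drugs: frozenset[str] = field(default_factory=frozenset)
    alt_freq_flag: bool = False

    def __post_init__(self) -> None:
        if not _RSID_RE.match(self.rsid):
            raise ValueError(f"rsid {self.rsid!r} does not match rs[0-9]+")
        if not self.genes:
            raise ValueError(f"{self.rsid}: gene set must be non-empty")
        for name, val in (("pop_maf", self.pop_maf), ("cohort_maf", self.cohort_maf)):
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"{self.rsid}: {name}={val} outside [0, 1]")

    @property
    def gene_label(self) -> str:
        return ";".join(sorted(self.genes))


@dataclass(frozen=True)
class PanelDefinition:
    """A named gene panel (unique, upper-case symbols)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("panel gene set must be non-empty")
        bad = [g for g in self.genes if g != g.upper()]
        if bad:
            raise ValueError(f"panel symbols must be upper-case: {bad[:5]}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes


def load_panel(path: str | Path, name: str | None = None) -> PanelDefinition:
    """Read a gene panel from a plain-text file (one symbol per line).

    Lines starting with ``#`` are comments.  Symbols are upper-cased and
    deduplicated (duplicates produce a warning); an empty file is an error.
    """
    path = Path(path)
    symbols: list[str] = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.append(line.upper())
    if not symbols:
        raise ValueError(f"panel file {path} contains no gene symbols")
    dupes = [g for g, c in Counter(symbols).items() if c > 1]
    if dupes:
        log.warning("panel file %s lists duplicate symbols %s; deduplicating", path, dupes)
    return PanelDefinition(name=name or path.stem, genes=frozenset(symbols))


def compute_maf(genotype_column: Sequence[int] | np.ndarray) -> float:
    """Allele frequency of a genotype column coded as minor-allele counts.

    Returns ``sum(g) / (2 * #non-missing)`` over non-missing entries
    (missing = ``-1`` or NaN).  An all-missing column is an error.
    """
    g = np.asarray(genotype_column, dtype=float)
    ok = ~np.isnan(g) & (g != MISSING)
    if not ok.any():
        raise ValueError("cannot compute allele frequency from an all-missing column")
    vals = g[ok]
    if ((vals < 0) | (vals > 2)).any():
        raise ValueError("genotype codes must be 0, 1, 2 or missing")
    return float(vals.sum() / (2.0 * ok.sum()))


def split_genes(cell: str) -> frozenset[str]:
    """Split a multi-gene annotation cell on ``;`` or ``,``."""
    parts = re.split(r"[;,]", str(cell))
    genes = frozenset(p.strip().upper() for p in parts if p.strip())
    return genes


def _split_drugs(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    return frozenset(p.strip() for p in str(cell).split(";") if p.strip())


_META_COLUMNS = {"rsid", "genes", "func_class", "pop_maf", "cohort_maf", "allele_change", "drugs"}


def sample_columns(annotated: pd.DataFrame) -> list[str]:
    """Names of the per-individual genotype columns of an annotated table."""
    return [c for c in annotated.columns if c not in _META_COLUMNS]


def refine_variants(
    annotated: pd.DataFrame,
    panel: PanelDefinition,
    keep_classes: Iterable[FuncClass] = DEFAULT_KEEP_CLASSES,
) -> list[VariantRecord]:
    """Filter an annotated table down to the panel's functional variants.

    A row survives when any of its annotated genes is in the panel and its
    functional class is in ``keep_classes``.  Each surviving record gains
    a cohort allele frequency: computed from the genotype columns when
    present, else taken from a ``cohort_maf`` column.  The output is
    ordered by descending cohort frequency, ties broken by rsid.
    """
    records, _, _ = refine_table(annotated, panel, keep_classes)
    return records


def refine_table(
    annotated: pd.DataFrame,
    panel: PanelDefinition,
    keep_classes: Iterable[FuncClass] = DEFAULT_KEEP_CLASSES,
) -> tuple[list[VariantRecord], np.ndarray, list[str]]:
    """Like :func:`refine_variants` but also return recoded genotypes.

    Returns ``(records, genotypes, sample_ids)`` where ``genotypes`` is an
    ``n_samples x n_retained`` int8 matrix aligned to ``records`` (columns
    flagged ``alt_freq_flag`` recoded ``g -> 2 - g``; empty when the table
    carries no genotype columns).
    """
    keep = frozenset(keep_classes)
    required = {"rsid", "genes", "func_class"}
    missing_cols = required - set(annotated.columns)
    if missing_cols:
        raise ValueError(f"annotated table lacks required columns {sorted(missing_cols)}")
    samples = sample_columns(annotated)

    kept: list[tuple[VariantRecord, np.ndarray | None]] = []
    for _, row in annotated.iterrows():
        genes = split_genes(row["genes"])
        fclass = parse_func_class(row["func_class"])
        if fclass is FuncClass.OTHER:
            log.warning("dropping %s: unclassifiable functional annotation", row["rsid"])
            continue
        if fclass not in keep or not any(g in panel.genes for g in genes):
            continue
        column: np.ndarray | None = None
        if samples:
            raw = pd.to_numeric(row[samples], errors="coerce").to_numpy(dtype=float)
            freq = compute_maf(raw)
            flagged = freq > 0.5
            column = np.where(np.isnan(raw), MISSING, raw).astype(np.int8)
            if flagged:
                log.info(
                    "%s: alternate-allele frequency %.3f > 0.5; recoding genotypes g -> 2 - g",
                    row["rsid"], freq,
                )
                nonmiss = column != MISSING
                column[nonmiss] = 2 - column[nonmiss]
        else:
            freq = float(row["cohort_maf"]) if "cohort_maf" in annotated.columns else None
            flagged = bool(freq is not None and freq > 0.5)
        rec = VariantRecord(
            rsid=str(row["rsid"]),
            genes=genes,
            func_class=fclass,
            pop_maf=None if "pop_maf" not in annotated.columns or pd.isna(row["pop_maf"])
            else float(row["pop_maf"]),
            cohort_maf=freq,
            allele_change=str(row.get("allele_change", "") or ""),
            drugs=_split_drugs(row.get("drugs")),
            alt_freq_flag=flagged,
        )
        kept.append((rec, column))

    kept.sort(key=lambda rc: (-(rc[0].cohort_maf if rc[0].cohort_maf is not None else -1.0), rc[0].rsid))
    records = [rc[0] for rc in kept]
    if samples and kept:
        genotypes = np.column_stack([rc[1] for rc in kept]).astype(np.int8)
    else:
        genotypes = np.empty((len(samples), len(records)), dtype=np.int8)
    return records, genotypes, list(samples)


def summarize_refinement(records: Sequence[VariantRecord]) -> dict[FuncClass, int]:
    """Count retained records per functional class (all classes present)."""
    counts = Counter(rec.func_class for rec in records)
    return {fc: counts.get(fc, 0) for fc in FuncClass}


def records_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Tabulate records with the annotated-table metadata columns."""
    return pd.DataFrame(
        {
            "rsid": [r.rsid for r in records],
            "genes": [r.gene_label for r in records],
            "func_class": [r.func_class.value for r in records],
            "pop_maf": [r.pop_maf for r in records],
            "cohort_maf": [r.cohort_maf for r in records],
            "allele_change": [r.allele_change for r in records],
            "drugs": [";".join(sorted(r.drugs)) for r in records],
        }
    )


def write_refined_tsv(records: Sequence[VariantRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_annotated_tsv(path: str | Path) -> pd.DataFrame:
    """Read a flat annotated table.

    Header ``rsid  genes  func_class  [pop_maf cohort_maf allele_change
    drugs]  <sample1> ... <sampleN>``; genotype cells are 0/1/2 or ``NA``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"rsid": str}, na_values=[NA_TOKEN])
    return df


def read_annotated_vcf(path: str | Path) -> pd.DataFrame:
    """Read genotypes and gene/function annotations from a VCF.

    Uses the GT field for genotypes (``./.`` missing) and the ANNOVAR INFO
    keys ``Gene.refGene`` / ``ExonicFunc.refGene`` (falling back to
    ``Func.refGene`` for non-exonic classes) for annotations.  Returns the
    same frame layout as :func:`read_annotated_tsv`.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    for var in vcf:
        rsid = var.ID or ""
        if not _RSID_RE.match(rsid):
            log.warning("skipping VCF record without an rs identifier at %s:%s", var.CHROM, var.POS)
            continue
        gene = var.INFO.get("Gene.refGene") or var.INFO.get("Gene") or ""
        func = (
            var.INFO.get("ExonicFunc.refGene")
            or var.INFO.get("Func.refGene")
            or var.INFO.get("Func")
            or ""
        )
        codes = []
        for gt in var.genotypes:
            alleles = [a for a in gt[:-1]]
            if any(a < 0 for a in alleles):
                codes.append(MISSING)
            else:
                codes.append(int(sum(1 for a in alleles if a > 0)))
        row = {"rsid": rsid, "genes": str(gene).replace("\\x3b", ";"), "func_class": str(func)}
        row.update(dict(zip(samples, codes)))
        rows.append(row)
    return pd.DataFrame(rows)
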