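"""Shipped reference fixtures: the 128-gene PAIma panel, the 54-variant
refined table with population and cohort allele frequencies, the
SNP-number map used by the interaction analyses, and the 21-SNP
synergistic cluster.

Fixture files are verified against frozen SHA-256 checksums at load time
so silent edits fail loudly.  The variant table transcribes the printed
source verbatim, anomalies included (cohort frequencies above 0.5,
duplicated rsIDs); two rows lost to text extraction are reconstructed and
marked synthetic in the file header.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import pandas as pd

from .variants import (
    PanelDefinition,
    VariantRecord,
    load_panel,
    parse_func_class,
    split_genes,
)

_CHECKSUMS = {
    "panel_genes.txt": "135fc7ffe6742b526ad40e1d2f70c32e9f12ef7dda22a999196e211493929433",
    "table2_variants.tsv": "e71fa5184581ec9ba4b67bc761914a4d614bb3d5f9e8263445aa8260be914937",
    "table3_snp_map.tsv": "94f4d18643578527f3915decf36516ad95262f632bf827d454c663bd35caaa96",
    "cluster21_snps.txt": "cffed6d7fc949207a8bffa329febd15548cdb6f9d49834de6e2bc5536465cec2",
}

PANEL_NAME = "PAIma"


def fixture_path(name: str) -> Path:
    """Resolve (and checksum-verify) a shipped fixture file."""
    if name not in _CHECKSUMS:
        raise KeyError(f"unknown fixture {name!r}")
    path = Path(str(resources.files("paima").joinpath("data", name)))
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(
            f"fixture {name} failed its integrity check "
            f"(sha256 {digest} != expected {_CHECKSUMS[name]})"
        )
    return path


def load_panel_fixture() -> PanelDefinition:
    """The 128-gene pharmacogene panel."""
    return load_panel(fixture_path("panel_genes.txt"), name=PANEL_NAME)


def variant_table() -> pd.DataFrame:
    """The 54-row refined variant table as a DataFrame (printed order)."""
    return pd.read_csv(
        fixture_path("table2_variants.tsv"), sep="\t", comment="#", dtype={"rsid": str}
    )


def load_variants() -> list[VariantRecord]:
    """The 54 refined variants as records, in printed (cohort-frequency) order."""
    df = variant_table()
    records = []
    for _, row in df.iterrows():
        records.append(
            VariantRecord(
                rsid=row["rsid"],
                genes=split_genes(row["genes"]),
                func_class=parse_func_class(row["func_class"]),
                pop_maf=float(row["pop_maf"]),
                cohort_maf=float(row["cohort_maf"]),
                allele_change=str(row["allele_change"]),
                drugs=frozenset(
                    d.strip() for d in str(row["drugs"]).split(";") if d.strip()
                )
                if pd.notna(row["drugs"])
                else frozenset(),
                alt_freq_flag=float(row["cohort_maf"]) > 0.5,
            )
        )
    return records


def snp_map() -> pd.DataFrame:
    """SNP-number <-> rsID <-> gene map (54 rows; duplicated rsIDs kept)."""
    return pd.read_csv(fixture_path("table3_snp_map.tsv"), sep="\t", comment="#")


def load_cluster21() -> list[str]:
    """SNP numbers of the 21-SNP synergistic cluster, in reported order."""
    lines = fixture_path("cluster21_snps.txt").read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def cluster_genes(cluster: list[str] | None = None, mapping: pd.DataFrame | None = None) -> set[str]:
    """Map cluster SNP numbers to their unique gene symbols."""
    cluster = cluster if cluster is not None else load_cluster21()
    mapping = mapping if mapping is not None else snp_map()
    lut = mapping.set_index("snp_no")["gene"]
    missing = [s for s in cluster if s not in lut.index]
    if missing:
        raise KeyError(f"cluster SNP numbers missing from the map: {missing}")
    return set(lut.loc[cluster])


class Fixtures(NamedTuple):
    variants: list[VariantRecord]
    snp_map: pd.DataFrame
    panel: PanelDefinition
    cluster21: list[str]


def load_fixtures() -> Fixtures:
    """All shipped fixtures, checksum-verified."""
    return Fixtures(
        variants=load_variants(),
        snp_map=snp_map(),
        panel=load_panel_fixture(),
        cluster21=load_cluster21(),
    )


def mean_population_maf() -> float:
    """Mean of the population-frequency column of the variant table.

    This is the control exposure probability p0 of the study's power
    analysis (approximately 0.22).
    """
    return float(variant_table()["pop_maf"].mean())
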