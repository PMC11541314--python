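#!/usr/bin/env python
"""Refine the shipped annotated variant table against the 128-gene panel.

Reproduces the refinement funnel: of the panel-annotated variants, only
protein-altering or splice-disrupting ones are retained (54 variants:
48 nsSNV, 2 stop-gain, 1 frameshift, 3 splicing), ordered by descending
cohort allele frequency.
"""

import json
from pathlib import Path

from paima import fixtures as fx
from paima import variants as vr

OUT = Path("results/analysis")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel = fx.load_panel_fixture()
    table = fx.variant_table()
    records = vr.refine_variants(table, panel)
    vr.write_refined_tsv(records, OUT / "refined_variants.tsv")
    counts = {fc.value: c for fc, c in vr.summarize_refinement(records).items() if c}
    (OUT / "class_counts.json").write_text(json.dumps(counts, indent=2))

    print(f"panel genes:        {len(panel)}")
    print(f"input rows:         {len(table)}")
    print(f"retained variants:  {len(records)}")
    print(f"class counts:       {counts}")
    flagged = sum(r.alt_freq_flag for r in records)
    print(f"cohort frequency > 0.5 (alternate-allele, flagged): {flagged}")


if __name__ == "__main__":
    main()
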