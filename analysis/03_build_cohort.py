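#!/usr/bin/env python
"""Build the 1:1 analysis cohort: synthetic cases + pseudo-controls.

Cases (n=100) are drawn under Hardy-Weinberg from the cohort allele
frequencies of the 54 refined variants (seed 42); controls (n=100) are
the deterministic pseudo-control expansion of the population (database)
frequencies.  The merged 200 x 54 genotype table feeds the MDR and
entropy analyses.
"""

from pathlib import Path

from paima import cohort as ch
from paima import fixtures as fx

OUT = Path("results/analysis")
CASE_SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = fx.load_variants()
    cases = ch.sample_cases([r.cohort_maf for r in records], 100, CASE_SEED, records)
    controls = ch.build_pseudo_controls([r.pop_maf for r in records], 100, records)
    merged = ch.merge(cases, controls)
    merged.to_tsv(OUT / "cohort.tsv")

    print(f"cases:            {merged.n_cases} (HWE draws from cohort frequencies, seed {CASE_SEED})")
    print(f"pseudo-controls:  {merged.n_controls} (expected-count expansion of population frequencies)")
    print(f"variants:         {merged.n_variants}")
    print(f"written:          {OUT / 'cohort.tsv'}")


if __name__ == "__main__":
    main()
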