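# Methods

## Study design being modelled

The package analyses a 1:1 case/"pseudo-control" contrast over a fixed
panel of pharmacogene variants.  Cases are individuals genotyped at the
54 refined panel variants; controls are not individuals at all but a
deterministic expansion of public population allele frequencies to a
matched number of genotype rows.  Any systematic divergence between the
cohort's allele frequencies and the reference population therefore shows
up as case/control separation — that is the intended signal, not a
confounder, in this design.

## Variant refinement

An annotated variant table is filtered by two rules: (1) at least one
annotated gene lies in the panel (multi-gene annotations are common for
the UGT1A cluster; any panel hit retains the row and all its genes);
(2) the functional class is protein-altering or splice-disrupting
(nsSNV, stop-gain, frameshift, splicing).  Synonymous and non-coding
classes are dropped; unknown annotation tokens are classified `other`,
warned about, and dropped.  Cohort allele frequency is
`sum(genotypes) / (2 · non-missing)` with genotypes coded as
minor-allele counts (0/1/2, missing `NA`/`./.`).

A column whose computed alternate-allele frequency exceeds 0.5 is
evidence that the database "minor" allele is the cohort's major allele.
The frequency is stored as computed and the record flagged
(`alt_freq_flag`); the genotype column is recoded `g -> 2−g` so that
downstream code consistently counts the rarer allele.  The shipped
54-variant table contains 16 such rows (up to 1.0), transcribed as
printed.  Output order is descending cohort frequency, ties by rsid —
deterministic, so fixture diffs stay readable.

Two of the 54 shipped rows are reconstructions (marked in the file
header): the source table's printed form could not be fully recovered,
and the missing rows were rebuilt from the SNP-number map with
frequencies taken from public databases (rs1042597) or from the
duplicated printed row (rs1105879).  The duplicated rsIDs (rs4244285
under two gene contexts; rs1105879 twice) are kept verbatim; cleaning is
the consumer's job, fidelity the fixture's.

## Synthetic cohort generator

* **Cases** — independent Hardy-Weinberg draws, genotype ~
  Binomial(2, maf) per locus, seeded and bit-reproducible.  Defaults:
  n = 100 cases, frequencies = the cohort column of the variant table.
* **Pseudo-controls** — expected HWE genotype counts per locus, rounded
  by largest remainder to sum exactly to n (ties toward the
  heterozygote, then the minor homozygote); the column lays out all 2s,
  then 1s, then 0s.  This is deterministic by design: the emulated
  procedure adjusts aggregate frequencies to a fixed head-count rather
  than sampling individuals.  A seeded sampling mode exists for
  sensitivity checks.  Default: n = 100, frequencies = the population
  column.
* **Planted epistasis** — a penetrance table over the 3^k cells of 2 or
  3 loci (canonical testbed: the parity/XOR model, penetrance 0.9 on
  odd-sum cells and 0.1 elsewhere, which has no single-locus marginal
  effect at allele frequency 0.5).  Individuals are drawn from an HWE
  pool and accepted as case/control by Bernoulli(penetrance) until the
  quotas (default 400/400 in the validation experiments) are met;
  unreachable quotas error after a capped number of draws.  Background
  loci in the validation experiments draw frequencies from U(0.1, 0.5) —
  a realistic common-variant range.
* **LD** — loci are independent by default.  An optional Gaussian-copula
  mode correlates latent allele dosages in blocks, for studying the
  negative (redundant) interaction scores that LD produces.

What the generator does *not* emulate: haplotype structure, population
stratification, genotyping error, missingness patterns, and the
frequency aggregation across 1000 Genomes subpopulations.  Passing
recovery tests on these synthetics shows the *method* is implemented
correctly, not that the original cohort's specific findings replicate.

Note one artifact of independent simulation: duplicated rsIDs are
simulated as independent case columns but identical pseudo-control
columns, which manufactures a strong joint signal for that pair.  Real
duplicated assays would be nearly perfectly correlated in both groups.

## MDR engine

Cell labeling uses the classical ratio rule: high risk iff
cases/controls ≥ T with T defaulting to the dataset's case:control
ratio; ties are high (the conventional reading of "ratio threshold");
cases with no controls are high; unoccupied cells are `empty` and
predict low by default (`empty_cell` ∈ {low, high, exclude}).
Individuals missing a genotype at any model locus are excluded from that
model's counting and metrics — no imputation.

Cross-validation is stratified 10-fold with a fixed, recorded fold seed
(default 42).  Metrics are fold-averaged; the testing side is also
reported pooled over fold counts, since averaging conventions differ
between MDR implementations and the two can disagree at the third
decimal.  Consistency is the number of folds in which a combination
attains the fold's best training balanced accuracy within its k-class.
χ² is the uncorrected Pearson statistic (the continuity-corrected value
is also emitted); kappa uses the standard marginal-expected-agreement
form.  Degenerate margins yield NaN rather than a convention constant.

Model selection records both readings of "best": per-k winners by
training balanced accuracy, overall best by testing balanced accuracy
with consistency and then smaller k as tie-breaks.  `search` returns all
evaluated combinations (table) plus per-k winners with full detail.

## Entropy networks

Entropies are plug-in estimates in bits; interaction scores are
percentages of H(Y).  The plug-in estimator matches the MDR/ViSEN
lineage but is biased: under the permutation null the pairwise
interaction gain of two 3-level genotypes centres near
`(9 − 3 − 3 + 1)·.../(2N ln 2)` ≈ +0.014 bits at N = 200, not at zero.
A Miller-Madow correction (`estimator="miller_madow"`) removes most of
this bias (measured ≈ +0.005 at N = 200) and is what a calibration test
should use; the plug-in stays the default for tool compatibility.

Edge classes are configurable bins over the score in percent (defaults:
> 2 strong synergy, (0, 2] synergy, [−0.5, 0] additivity, < −0.5
redundancy — the source tool's colour thresholds are not numerically
published, so these are package defaults).  Node/edge display thresholds
flag elements hidden but never delete them; network statistics can be
computed on the visible or the full graph.

The dendrogram clusters variants by average linkage on the dissimilarity
`d(A,B) = max(edge) − edge(A,B)` so the strongest synergy merges first;
leaves are ordered lexicographically, which fixes tie-breaks.  Average
linkage guarantees non-decreasing merge heights.  Newick export carries
the merge heights as branch lengths.

Graph statistics: sample SD (ddof = 1) of edge scores, unnormalized
betweenness (shortest-path pair counts) and standard closeness
centrality, with maxima reported.

## Power

`p1 = Ψ p0 / (1 + p0(Ψ − 1))` (odds-ratio relation, since Ψ is an odds
ratio).  Exact power enumerates all (controls-exposed, cases-exposed)
outcome tables with X ~ Bin(mn, p0), Y ~ Bin(n, p1) and sums the joint
probability of those rejected by the two-sided Fisher exact test
("sum of small p" convention with a 1e−7 relative tolerance, as in R).
Binomial supports are truncated below ~1e−13 tail mass for large n; the
uncovered mass is reported as `truncation_error` and bounds the error.
The continuity-corrected two-proportion normal approximation
(Casagrande–Pike–Smith/Fleiss) is reported alongside; for the package's
reference design (α = 0.05, p0 = 0.22, Ψ = 2.5, n = m·n = 100) the exact
enumeration gives 0.805 and the approximation 0.802.  Sample size
bisects the monotone approximation, then walks the exact power (which is
sawtoothed in n) to the smallest qualifying n; two-sided is the default.

p0 = 0.22 is the mean of the population-frequency column of the variant
table; the cohort column would give a different value, and the choice of
column is an assumption recorded here.

## Problem sizes used in validation

Oracle-agreement tests run on ≤ 8-variant toys where brute-force
enumeration is feasible.  Recovery experiments use 20 seeds at 400
cases / 400 controls with 10 background loci (pairs) or 8 (triples);
null-calibration uses N = 200 with 100 phenotype permutations.  These
sizes give stable Monte-Carlo estimates for the ≥ 80% / ≥ 90% recovery
bounds while keeping the suite quick.

## Known limitations

* The pseudo-control construction treats aggregate frequencies as if
  they generated independent individuals; sampling variance of the
  reference panel is ignored.
* MDR as implemented has no covariate adjustment and no significance
  testing of the best model beyond cross-validation (no permutation
  p-value for the search itself).
* Entropy scores are not debiased by default (see above), and no
  per-edge significance is attached.
* Exact-power enumeration assumes independent binomial sampling in both
  groups (unconditional power of the conditional test).
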