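# Methods notes

This note records the models implemented in `genagephen`, their
assumptions, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical choices that a
maintainer would otherwise have to reverse-engineer.

## Age framework

Genes are stratified into seven ancestral branches, br0 (Euteleostomi node
or older) to br6 (youngest human-lineage node), grouped into four epochs:
Euteleostomi, Tetrapoda, Amniota, Eutheria.  Both the branch count and the
origin ages are configuration (`AgeFramework.from_yaml`); the shipped
defaults are TimeTree-derived round numbers:

| branch | clade            | origin (My) | epoch        | span T_i (My) |
|--------|------------------|-------------|--------------|---------------|
| br0    | Euteleostomi     | 435         | Euteleostomi | 83            |
| br1    | Tetrapoda        | 352         | Tetrapoda    | 33            |
| br2    | Amniota          | 319         | Amniota      | 214           |
| br3    | Eutheria         | 105         | Eutheria     | 15            |
| br4    | Euarchontoglires | 90          | Eutheria     | 16            |
| br5    | Primates         | 74          | Eutheria     | 45            |
| br6    | Catarrhini       | 29          | Eutheria     | 29            |

A branch's time span is `T_i = origin(branch) − origin(next younger)`,
with the youngest branch spanning to the present.  No time value is
hard-coded in analysis logic.

**Sparse-branch merging.**  Branches with fewer than 100 genes (strict
inequality; the floor is a parameter) are merged into their adjacent older
branch.  The merge cascades oldward — a sparse branch hands its
accumulated count to the next older branch, which may then merge further —
until every retained branch meets the floor.  The cascade is the
deterministic generalisation of a single-step merge; it is idempotent and
conserves the total gene count.  A sparse *oldest* branch is an error,
since it has no older neighbour.

## Ingest filters and classification

Gene-age records are kept only for protein-coding genes on placed nuclear
chromosomes; removals are tallied per rule (mitochondrial = MT label,
unplaced = any label outside 1–22/X/Y, RNA = any non-protein-coding
biotype) and `removed + retained = input` is asserted on every reader.
The canonical dialect is tab-separated UTF-8 with a header row and
`#`-comments.

Annotation links under neoplasm terms are removed by term-id membership in
a configured subtree set (plain-text id list, or an OBO file through
`obonet`).  Term→system mapping is a configuration table because the 22
top-level organ-system categories and their term memberships are data, not
code; a term descending from several systems yields one labelled link per
system (multi-axial annotation is the norm), and each such system counts
toward the gene's pleiotropy m.

Reproductive classification scans term names case-insensitively for
"reproduct", "male" and "female".  "female" is tested before "male"
because the former contains the latter as a substring; a term matching
"female" is therefore never counted as male-context.  Genes with only
male-context matches are `male_specific`, only female-context
`female_specific`, both kinds `both`; a gene matching only "reproduct" is
reproductive but sex-unspecific.  Classification is order-invariant by
construction (per-gene boolean aggregation).

Pleiotropy m is the gene's **global** distinct-system count over all 22
systems, never restricted to an epoch: m is a property of the gene, and
the per-stage enrichment index below reuses the same weight wherever the
gene appears.

## Emergence model

`r_i = O_i/(A_i·T_i)` assumes each branch's dated genes are exchangeable
Bernoulli trials for "became a disease gene", with probability
proportional to branch time — a constant-rate model.  Units are carried
explicitly: a rate of 0.07 % per My equals 0.07e-8 per gene per year, and
the conversions are named functions because the two scales are easy to
conflate.  The per-generation expectation `μ_d = G·g·r` additionally
assumes the simplified monogenic model (one causal gene per affected
individual) and independence across genes.  Prevalence presentation
rounds half away from zero (3.73 → "≈ 4 in 10,000").

## Pleiotropy growth

The logistic fit uses the initial-condition parameterisation
`P(t) = P_max / (1 + ((P_max−P_0)/P_0)·e^(−kt))`, which satisfies
`P(0) = P_0` exactly and approaches `P_max` from below.  Evolutionary time
t is measured from the youngest branch's origin in 100-My units: with the
default origin ages this puts the seven branches on t ∈ [0, 4.06], where a
growth rate near k ≈ 1.66 per 100 My is dimensionally sensible (per-My
units would saturate the curve within a single branch).  The unit is a
configuration constant.

`P_max = 10` and `P_0 = 4` default to the empirical extreme medians of the
branch series and are fixed during fitting; only k is free.  With a single
free parameter the problem is solved by bounded scalar least squares
(Brent-class, k ∈ (1e-9, 100], `xatol = 1e-12`) — deterministic, no random
initialisation, no covariance linearisation.  Flat data drives k to the
lower boundary and is flagged rather than reported as a fit.  Orientation
of the branch series (oldest-first) is carried as metadata so consumers
never guess the direction.

The per-epoch increase rate ΔOP_median/Δt is a finite difference of
branch medians over elapsed My.  Multi-branch epochs span their own oldest
to youngest branch; a single-branch epoch is compared against the oldest
branch of the next younger epoch.

## Phenotype enrichment index

`PEI(system, stage) = 100 · Σ_g∈stage,system 1/m_g / Σ_g∈stage Σ_systems(g) 1/m_g`.
A gene contributes once per distinct system it touches, regardless of how
many annotation terms produced the link, so duplicated terms within a
system are no-ops.  Rows sum to 100 by construction; when every m = 1 the
index degenerates to the percentage of genes per system.  Per-stage
dispersion is the population standard deviation (ddof = 0) over the
stage's 22 values.

## Chromosomal distribution

The linear model is deliberately the simplest one consistent with the
hypothesis that disease-gene counts scale with gene counts: OLS with
intercept on the 22 autosomes, X and Y excluded from fitting and judged by
their excess rate `100·(n−e)/e`.  The intercept is retained and reported.

The headline sex-bias ratios are **fraction (risk) ratios**
`(a/A)/(b/B)`, computed alongside the 2×2 cross-product odds ratio; both
are emitted under their honest names because the two are easily conflated
when fractions are small.  Significance is a two-sided Fisher exact test;
the interval is the Katz log-scale CI
`RR·exp(±1.96·√(1/a − 1/A + 1/b − 1/B))`.  Fisher's test needs integer
tables; when a baseline is a *mean* per-autosome count (the
"autosomes-on-average" convention used for the X/Y contrasts), the table
is rounded for the exact test only while the ratio itself uses the
unrounded values.

The ancient/young age split contrasts Euteleostomi-origin genes against
everything younger, refitting the autosomal OLS within each split and sex
category and recomputing the X/Y excess rates, plus the per-epoch α_d
sequence.

## X regions

All intervals are 1-based and closed, matching NCBI-style coordinates.
A gene's representative point is its **start** coordinate: deterministic,
and consistent with single-point liftover practice; genes straddling a
boundary go to the region containing the start.  PAR genes are excluded
from strata analyses.  The PAR coordinates are the GRCh38.p13 annotation
values; the conserved/added boundary and the strata interval sets for the
substitutions and segmentation-and-clustering methods ship as *editable
synthetic defaults* in `config.DEFAULT_X_REGIONS` / `x_regions.tsv` —
users analysing real data should substitute coordinate tables from the
X-strata literature.  Conservation (per-method background counts sum to
the non-PAR X gene count) is asserted in tests.

## Ka/Ks contrasts

Group comparisons use the two-sided Wilcoxon rank-sum test: the exact
Mann-Whitney null when both arms have n ≤ 25 without ties, exact
enumeration over all group splits (via permutation with full resampling
count) when small with ties, and the normal approximation with tie and
continuity correction otherwise.  The purifying-selection-only view
(Ka/Ks < 1) is the default for disease/non-disease contrasts, with the
full view retained for sensitivity.  The pleiotropy relationship bins
genes by affected-system count (1..8, ≥ 9 pooled — nine points) and
correlates bin value with the bin's median Ka/Ks (Pearson, two-sided t
test); constant medians are an error, not a zero.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with planted, recoverable parameters.  Defaults are the study conditions:
19,665 dated genes distributed 12,000/2,200/1,300/2,400/800/600/365 over
br0..br6 (old-heavy, as in real phylostratigraphic tables), constant
emergence rate r\* = 0.07 %/My, logistic pleiotropy with k\* = 1.66
(P_max = 10, P_0 = 4), genitourinary up-weighting for post-Euteleostomi
genes, sex-class weights p_male = 0.30 / p_female = 0.12 / p_both = 0.05
among genitourinary disease genes, planted X male relative risks 1.6
(ancient) and 3.0 (young) and 3.0 on Y, and Beta-distributed Ka/Ks on
[0, 1.5] with negative shifts for disease status and system count and a
positive shift for youth.

Specific laws:

* disease status: Bernoulli with `p_i = r*·T_i·10⁻²` per branch, checked
  `≤ 1` before generation;
* m: randomised rounding of the branch's logistic target plus symmetric
  two-sided geometric noise (p = 0.45), truncated to [1, 22] — the
  simplest discrete law whose branch median tracks the target (end-to-end
  fits recover k\* with < 1 % mean bias at 2,000 genes per branch);
* systems: m distinct systems drawn by Gumbel top-k with rank-decaying
  weights (1/rank^0.7), OP7 boosted 6× for young genes;
* sex class: drawn only for OP7 carriers, with the male probability
  multiplied by the planted relative risk on X/Y (capped at 0.9, and the
  cap is honoured in the ground-truth report);
* chromosome and coordinates: placement proportional to rounded hg38
  chromosome lengths, uniform start positions.

`ground_truth_report` returns closed-form expectations where they exist
(per-branch r_i = r\*, α_d = p_male/p_female with the relative-risk and
cap adjustments) and large-sample internally-seeded estimates for
quantities involving the weighted system draw (the OP7 inclusion
probability and the age-mixed X relative risk).

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about real data: real HPO term identifiers and
ontology topology (term ids are format-only), gene-density and GC
correlates of chromosome placement, linkage between neighbouring genes,
correlated annotation noise and ascertainment bias in disease-gene
discovery, per-gene Ka/Ks estimation error, and any within-chromosome
positional clustering.  Recovery results demonstrate estimator
correctness under the stated model, not robustness to violations of it.

## Problem sizes in the test suite

Recovery suites run at sizes chosen to keep sampling error well inside
the asserted tolerances: 200 replicates for coverage and bias checks,
500–2,500 genes per branch depending on the statistic (2,000/branch for
the end-to-end logistic recovery, matching the documented generator
check; 2,500/branch for X relative-risk coverage so per-replicate X hit
counts stay in the dozens).  The whole suite is CPU-only and completes in
a couple of minutes.

## Known limitations

* The constant-rate emergence model ignores gene loss and assumes branch
  assignments are error-free; r_i inherits any dating bias.
* Fixing P_max and P_0 to observed extreme medians understates the
  uncertainty of k; `fit_series(from_data=True)` recomputes them but no
  joint CI is attempted (single-parameter RSS only).
* The Katz CI and Fisher test treat genes as independent; clustered gene
  families violate this.
* The default X strata coordinates are placeholders for published tables;
  per-stratum conclusions on real data require the literature coordinate
  sets.
* Mean-per-autosome baselines weight all autosomes equally regardless of
  size; this matches the printed convention rather than a
  variance-minimising estimator.
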