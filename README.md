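# genagephen

Age-stratified analysis of human Mendelian disease genes.

Human genes differ enormously in evolutionary age: some trace back to the
Euteleostomi ancestor and beyond, others arose on the primate lineage.
`genagephen` implements, as a tested and reusable pipeline, the analyses
used to ask how gene age shapes disease phenotypes: how fast disease genes
emerge over macroevolutionary time, how pleiotropy (the number of organ
systems a gene's defects affect) grows with age, which organ systems young
and old disease genes are enriched in, and how disease genes distribute
over chromosomes — including the faster-X / faster-male excess of male
reproductive disease genes and the X-conserved versus X-added contrast.

It is written for computational biologists who have (or can emulate) three
inputs: a gene-age table (phylostratigraphy-style branch assignments), HPO
phenotype annotations mapped to 22 organ/tissue/system categories, and
pairwise ortholog Ka/Ks ratios.  Because the real datasets are large and
licensed elsewhere, the package ships a first-class synthetic-data
generator that emulates their statistical structure with planted ground
truth, so every estimator can be validated by parameter recovery.

## The models and statistics

**Emergence rate.**  For ancestral branch *i* with `O_i` disease genes out
of `A_i` dated genes and branch time `T_i` (My),

    r_i = O_i / (A_i · T_i)

is the fraction of dated genes becoming disease genes per million years.
Under a simplified monogenic model, a genome-wide rate *r* (per gene per
year) converts to the expected number of causal rare-disease genes per
individual per generation, `μ_d = G · g · r` (G coding genes, g generation
time in years), and to a rare-disease prevalence `r_RD = 10,000 · μ_d` per
10,000 individuals.

**Pleiotropy growth.**  Per-branch median organ-system counts P are fitted
against evolutionary time t (100-My units from the youngest branch's
origin) with the initial-condition logistic

    P(t) = P_max / (1 + ((P_max − P_0)/P_0) · e^(−k·t)),

with P_max and P_0 fixed to the empirical extreme medians (defaults 10 and
4) and only the growth rate k estimated, by bounded scalar nonlinear least
squares.

**Phenotype enrichment index (PEI).**  Each gene contributes weight `1/m`
to every one of its m distinct organ systems; within an evolutionary stage
a system's PEI is its percentage share of the stage's total weighted
contribution, so each stage's 22 values sum to 100.

**Chromosomal excess.**  Disease-gene counts are regressed on total dated
genes over the 22 autosomes (OLS with intercept); X and Y are judged by
their excess rate `100·(n − e)/e` against the fitted expectation.  Sex
bias is summarised by `α_d = M/F` (male/female reproductive disease gene
counts) and by fraction ratios between chromosome classes with Fisher
exact tests and Katz log-scale confidence intervals.  X genes are further
classified into PAR / X-conserved / X-added regions and evolutionary
strata from editable BED-like interval tables.

**Selective constraint.**  Disease versus non-disease Ka/Ks contrasts use
the two-sided Wilcoxon rank-sum test (exact at small n), and the
pleiotropy-constraint relationship is the Pearson correlation between
system-count bins (1..8, ≥9) and each bin's median Ka/Ks.

## Worked example

Generate a synthetic bundle at the default study conditions (19,665 dated
genes on 7 branches, constant emergence rate 0.07 %/My, logistic
pleiotropy with k\* = 1.66) and run the full pipeline:

```sh
genagephen simulate --seed 7 --out demo/bundle
# wrote bundle to demo/bundle: 19665 genes, 1003 disease genes
genagephen run --bundle demo/bundle --out demo/out
# report with 8 stage sections written to demo/out/report.json
```

Highlights of `demo/out/report.json` from that exact run:

* Per-branch emergence rates `r_i` (% per My): br0 0.071, br1 0.066,
  br2 0.071, br3 0.061, br4 0.070, br5 0.052, br6 0.066 — scattered
  around the planted constant 0.07 %/My.
* Generation model (defaults G = 19,831, g = 26.9 y, r = 0.07 %/My):
  `μ_d = 3.734e-4` causal genes per individual per generation,
  prevalence `r_RD = 3.73` per 10,000, presented as ≈ 4 in 10,000.
* Branch median system counts old→young: 10, 10, 10, 7, 7, 6, 4, and the
  constrained logistic fit k̂ = 1.823 (planted 1.66; single-replicate
  noise).
* PEI dispersion is largest in the youngest epoch (Eutheria 3.00 vs
  1.76–2.20 for older epochs): young-gene enrichment is concentrated in
  fewer systems (the boosted genitourinary system).
* Autosomal OLS of disease on total genes: slope 0.052, R² = 0.92; the
  X chromosome carries a male-reproductive fraction ratio of 1.53 versus
  the autosomal mean in this replicate.
* Ka/Ks: disease genes have a lower median than non-disease genes
  (0.108 vs 0.297, Wilcoxon p ≈ 4e-106), and median Ka/Ks falls with
  affected-system count (Pearson ρ = −0.82, p = 0.007).

Every number above is read back from files the commands actually wrote.

## Layout

```
src/genagephen/
  ingest.py         readers, filters, keyword classification, profiles
  age_framework.py  branches, epochs, branch times, sparse-branch merging
  emergence.py      r_i, μ_d, prevalence
  pleiotropy.py     median trends, Δmedian/Δt, logistic fit
  pei.py            phenotype enrichment index
  chromomap.py      per-chromosome counts, OLS, excess rates, sex ratios
  xstrata.py        PAR / X-conserved / X-added / strata classification
  selection.py      Ka/Ks contrasts and pleiotropy correlation
  synthdata.py      seeded generator with planted ground truth
  pipeline.py       end-to-end orchestration and report.json
  cli.py            `genagephen` command-line interface
```

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
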