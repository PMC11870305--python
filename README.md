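# clonetrial

Multi-environment genetic evaluation of clonal tree trials: REML variance
components and BLUP, derived genetic parameters, BLUP-GGE biplot selection,
multivariate regression trees on climate, and Mantel-based attribution of
genotype-by-environment (G×E) interaction.

The package is written for tree breeders and quantitative geneticists who
run clonal field trials across several sites and need to answer, from
long-format measurement tables: *How heritable is growth? Which clones are
best where, and which are both high-yielding and stable? Which climate
variables drive growth and its G×E?*  It was built around a published
three-site *Catalpa bungei* clonal trial series (32 clones, single- and
two-tree plots in 4–6 randomized complete blocks, heights/volumes at ages
1–5 and DBH at ages 1–9) and ships a synthetic-trial generator that
emulates that design with known ground truth, so every stage is testable
without the original data.

## Models and statistics

Single-site clone model, for one trait at one age:

    y_ijk = μ + B_j + C_i + e_ijk,   C_i ~ N(0, σ²_c),  e ~ N(0, σ²_e)

with blocks fixed.  Multi-site model:

    y_ijks = μ + S_s + BS_js + C_i + CS_is + e_ijks

with site and block-within-site fixed, clone and clone×site random.
Both are fitted by profiled REML on the variance ratios through
Henderson's mixed-model equations; clone BLUPs come from the same solve.
Derived parameters:

* coefficients of variation `CV = SD/x̄`, `GCV = √σ²_c/x̄·100`,
  `ECV = √σ²_e/x̄·100`;
* mean-basis repeatability `R = σ²_c/(σ²_c + σ²_e/K)` (single site,
  K = harmonic mean replicates per clone) and
  `R = σ²_c/(σ²_c + σ²_cs/S + σ²_e/(SBN))` across sites;
* type-B genetic correlation `r_b = σ²_c/(σ²_c + σ²_cs)` per site pair
  (near 0 ⇒ strong G×E);
* genetic gain `ΔG% = 100·(x̄_sel − x̄)·R/x̄`;
* a membership-function (min–max) composite index summing normalized
  multi-year BLUPs per clone.

Selection uses a BLUP-GGE biplot: the genotype × environment table of
per-site clone BLUPs is environment-centered (optionally scaled by each
environment's SD) and decomposed by SVD; the first two principal
components give the which-won-where polygon, mean-vs-stability along the
average-environment axis, environment discrimination/representativeness,
and the ideal-genotype ranking.  Climate drivers are assessed with
Spearman/OLS associations, a cross-validation-pruned multivariate
regression tree over 17 ClimateAP-style bioclimatic variables, and Mantel
permutation tests between per-variable between-site climate change and
the G×E dissimilarity 1 − r_b.

## Worked example

The repository is organised as an analysis: numbered drivers under
`analysis/` run each stage on the synthetic reference trial and write
tables under `results/`.

```
$ python analysis/01_simulate_trial.py
simulated 12255 measurements on 645 trees at 3 sites -> results/data/trial.csv

$ python analysis/05_gge_selection.py
height (age 5): PC1+PC2 explain 87% of G+GE; winners by site {'LY': 'C06', 'NY': 'C20', 'TS': 'C20'}; closest to ideal genotype: C20
dbh (age 9): PC1+PC2 explain 86% of G+GE; winners by site {'LY': 'C29', 'NY': 'C29', 'TS': 'C29'}; closest to ideal genotype: C29
volume (age 5): PC1+PC2 explain 89% of G+GE; winners by site {'LY': 'C20', 'NY': 'C02', 'TS': 'C02'}; closest to ideal genotype: C20
```

Reading: for 5-year height the biplot's first two axes carry 87% of the
genotype-plus-G×E signal; clone C20 wins the NY/TS sector and sits closest
to the ideal genotype (high mean projection on the average-environment
axis, small perpendicular instability), so it is the stable high-yield
pick, while C06 is a LY-specific winner.  `analysis/02`–`04` print the
variance decomposition (e.g. a G×E share of 5–8% of phenotypic variance
for the default generator), repeatabilities, composite ranks, gains, the
fitted climate tree, and the Mantel driver table.

The same chain is available as one call (`clonetrial run --seed 42
--out-dir results/pipeline`) or from Python via
`clonetrial.pipeline.run_pipeline`; reruns with the same seed are
byte-identical.

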