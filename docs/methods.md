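# Methods

This note documents the statistical models, algorithmic choices, and the
synthetic data conditions behind `clonetrial`, in the spirit of the model
documentation shipped by statsmodels or msprime.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Mixed models and REML

Two Gaussian variance-component models are fitted per trait-age.

Single site: `y_ijk = μ + B_j + C_i + e_ijk` with blocks fixed, clone
effects `C_i ~ N(0, σ²_c)` i.i.d., residuals `N(0, σ²_e)`.

Multi-site: `y_ijks = μ + S_s + BS_js + C_i + CS_is + e_ijks` with site
and block-within-site fixed and clone / clone×site random.  Treating
blocks as fixed mirrors the single-site model and keeps the estimable
random components to the three that the genetic parameters need
(σ²_c, σ²_cs, σ²_e); a `blocks="random"` switch estimates a
block-within-site variance instead for users who prefer that reading.
An all-random variant (site, clone, site×clone, residual; intercept the
only fixed effect) supports the variance-share report: block structure is
deliberately absorbed into the residual there so the four shares read
directly as environment / genetics / G×E / error and sum to one.

### Estimation

The engine (`_reml.py`) profiles out σ²_e and maximises the restricted
likelihood over the variance ratios γ_r = σ²_r/σ²_e.  All quantities are
evaluated through Henderson's mixed-model equations, so one criterion
evaluation costs a Cholesky factorisation of a (p+q)×(p+q) matrix
(p fixed-effect columns, q total random levels) independent of the number
of trees; with 32 clones × 3 sites this is a ~145×145 solve and a full
multi-site fit takes ~0.2 s.  Optimisation is bounded quasi-Newton
(L-BFGS-B, three starts, analytic gradient) followed by a guarded Newton
polish on interior coordinates using a finite-difference Hessian of the
analytic gradient; the polish drives the interior gradient norm below
1e-9, which is what makes REML agree with the balanced-ANOVA
expected-mean-squares oracle to 1e-6 absolute on interior cases.

Boundary handling: ratios are floored at 1e-8 during the search; any
ratio finishing at the floor triggers a refit with that component removed,
and the reduced model is adopted (component reported as exactly 0, its
BLUPs 0) whenever the restricted log-likelihood does not decrease by more
than 1e-7.  Under a true zero component the estimate lands on the
boundary with probability ≈ 1/2 (the chi-bar-square mixture), which the
tests assert as a 25–75% band rather than a near-certainty.

Design note: an EM iteration with an average-information polish was
considered for the optimiser; the profiled-ratio formulation was chosen
instead because profiling removes one dimension exactly, converges in a
handful of iterations at these problem sizes, and reaches oracle-level
accuracy without EM's slow crawl near boundaries.  statsmodels MixedLM
serves as an independent cross-check in the tests (agreement ~1e-3,
limited by its convergence tolerance), never as the implementation.

BLUPs are the random-effect solutions of the final mixed-model solve;
per-cell multi-site predictions are clone + clone×site, with unobserved
cells shrinking to the clone main effect alone.

## Genetic parameters

* `K` in single-site repeatability is the harmonic mean of per-clone
  surviving replicate counts (blocks × ramets) at that site-age — the
  standard reading of a "harmonic number of repeated tests".
* In multi-site repeatability, S is the site count, B the arithmetic mean
  block count across sites (layouts with 6/5/4 blocks have no single B),
  and N the harmonic mean of per-(site, block, clone) plot sizes, kept
  real-valued.
* Population and selected means are plain means over the trees entering
  the fit (no site weighting); the alternative weightings differ only in
  strongly unbalanced data and are not implemented.
* The composite multi-year index min–max normalises clone BLUPs within
  each age and sums across ages; an age where all BLUPs are equal is
  uninformative (normalisation undefined) and is skipped with a warning.
* The symbol S of the gain formula (selection differential) never meets
  the S of the repeatability formula (site count); they live in different
  functions with named arguments.

## Stem volume and units

Volume is derived, never measured:
`V = 0.000050479055 · DBH^1.9085054 · H^0.99076507` with DBH in cm, H in
m, V in m³.  A supplied volume column is accepted but cross-checked
against the formula (warning at >5% relative deviation).  The reference
gain table prints 5-year volumes under a cm³ header with values ≈ 0.03;
these magnitudes are only plausible in m³, and the package treats them as
m³ throughout (flagged here rather than silently corrected).

## BLUP-GGE biplot

The genotype × environment table holds per-site clone BLUPs for one
trait-age (single-site fits by default; multi-site per-cell predictions
are available by passing the interaction table instead).  Processing:
subtract each environment's mean (G+GE centering); by default divide each
centered column by its sample SD; SVD.  The percentage of G+GE variation
on PC k is 100·λ²_k/Σλ².  Genotypes present in fewer than two
environments are dropped and reported; remaining missing cells are
imputed with the environment mean of observed genotypes — a neutral zero
after centering — and flagged.

Singular-value partitioning (genotype-focused / environment-focused /
symmetric) affects exported display coordinates only.  Every decision
quantity — which-won-where winners, mean projections, stability
distances, ideal-genotype ranking — is computed from the SVP-invariant
rank-2 inner-product geometry (internally, genotype-focused
coordinates), so changing the SVP mode rescales a plot but can never
change a selection.  Winners are the argmax over genotypes of the rank-2
reconstruction per environment, which always lies on the convex hull of
the genotype points; angles are reported in degrees; all coordinates are
exported so any plotting layer can redraw the four views.

## Multivariate regression tree

Responses (height, DBH, volume per observational unit — by default one
row per clone × site × year of mean growth) are standardized to zero mean
and unit SD per column by default, so no trait dominates the multivariate
sum-of-squares impurity; the switch is exposed.  Split search is
exhaustive over every predictor and every midpoint between consecutive
distinct sorted values, maximizing the impurity reduction summed over
response columns; ties are broken by predictor order then lower
threshold, on values only, making the fitted tree invariant to row
order.  Growth is best-first (largest admissible reduction next) under
`min_leaf` (default 5), `min_reduction` (default 1% of root SSE — stated
because mvpart-style defaults are not reproduced verbatim) and an
optional maximum leaf count.  Rows missing a predictor value are excluded
from splits on that predictor only and routed with the larger child at
prediction time.

Pruning follows the standard weakest-link cost-complexity sequence;
10-fold cross-validation (fold assignment seeded) scores the geometric
means of consecutive α values, and the selected size is the smallest
within one standard error of the minimum CV error (1-SE rule; plain
minimisation behind a flag).  The node annotations (per-node SSE and n)
are serialized in both an indented-rule text and JSON.

## Climate statistics and Mantel attribution

Site-year trait means (age mapped to calendar year through the planting
year) are associated with each of the 17 bioclimatic variables by
Spearman rank correlation (average ranks on ties, two-sided t
approximation) and simple OLS (slope, intercept, R²).  Between-site
climate change for a variable is the mean over years of the absolute
between-site difference; G×E dissimilarity between sites is 1 − r_b.
The Mantel statistic is the Pearson correlation of upper triangles under
joint row/column relabeling, two-sided, with the +1 permutation
correction; ≤5 labels are enumerated exactly.  Both the dissimilarity
form (primary: positive r ⇒ the variable's change tracks stronger G×E)
and the raw-r_b form are reported, since correlating a difference matrix
with a similarity flips the sign.  With only three sites the p-value has
floor 1/6; the implementation warns and the calibration tests use six
synthetic sites.

## Synthetic trial generator

The generator draws from exactly the model the estimators fit: per trait,
value = μ(trait, age) + site shift + block + clone + clone×site +
residual, with one clone effect per (trait, clone) shared across ages —
growth at successive ages is the same genetic signal plus age-specific
means — and a `per_age_clone_effects` switch for the independent-ages
extreme, since how strongly clone effects correlate across ages in real
trials is not identifiable from the published material.  Mortality drops
whole trees (all ages jointly), matching how field losses occur, with a
warning when a (site, clone) cell empties.

Reference conditions (`TrialDesign.reference`,
`SimulationParams.reference`) emulate the motivating trial: sites LY
(single-tree plots × 6 blocks), NY (two-tree × 5), TS (two-tree × 4), 32
clones planted in 2009, height/volume at ages 1–5 and DBH at ages 1–9,
85% survival, and trait scales chosen to land in the published ranges
(5-year height ≈ 8–9 m, 9-year DBH ≈ 12–13 cm, 5-year volume ≈ 0.03 m³,
GCVs roughly 5–15%, repeatabilities 0.3–0.8).  Block effect SDs are
per-trait (0.15 m, 0.25 cm, 0.0015 m³): a common absolute block SD would
swamp the m³-scale volume trait.  The climate generator draws
(site, year) values from per-site normal profiles shaped on
warm-temperate continental China and enforces the definitional
identities TD = MWMT − MCMT and AHM = (MAT+10)/(MAP/1000).

What the generator does *not* emulate: spatial autocorrelation and
competition within blocks, non-Gaussian measurement error, repeated-
measures covariance beyond the shared clone effect, climate-responsive
growth curves, and non-random mortality.  Passing tests therefore
demonstrate correctness of the estimators and selection machinery under
the stated model, not robustness to field pathologies outside it.

## Monte-Carlo problem sizes

The recovery studies run at the sizes a desk check warrants: 200
replicates of the 32-clone × 3-site layout for multi-site recovery
(mean estimates within 10% of σ²_c = 1, σ²_cs = 0.5, σ²_e = 4; implied
repeatability within 0.05 of the closed form), 60 replicates for the
boundary-null band, 100 seeded runs for the pure-noise pruning guard,
and 1000 simulations × 199 permutations for Mantel type-I calibration
(rejection rate 0.05 ± 0.02).  These sizes were chosen once as adequate
for the stated tolerances.

## Published worked-example replay

The printed gain table of the motivating trial (three traits × three
sites + combined) ships as *inputs* in `worked_example.py`; the gain
column is recomputed at run time via ΔG% = 100·(x̄_sel − x̄)·R/x̄.  Because
the printed means and repeatabilities are rounded (heights/DBH to 2
decimals, volumes to 3 significant figures, R to 2 decimals), the replay
carries a first-order propagated rounding band per row; the volume rows'
bands reach ≈ 0.3–0.6 gain points, and the observed deviations (max
0.26) sit inside them.  The published data-dependent values — raw
correlations, regression R², variance proportions, regression-tree
thresholds, per-site repeatabilities — depend on the unreleased
individual-tree data and are covered qualitatively by planted-structure
tests instead of numerically.

## Known limitations

* No pedigree/kinship, multi-trait REML, spatial residual models, or
  selection-intensity gain variants.
* The Mantel analysis on a three-site trial is descriptive (p floor 1/6).
* GGE views assume the rank-2 approximation is adequate; `pct_explained`
  should be inspected before trusting the plots.
* The regression tree has no surrogate splits or categorical predictors.
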