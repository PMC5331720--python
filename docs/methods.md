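# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not emulate.

## Occurrence cleaning

Records are filtered in a fixed order: (1) basis-of-record removal
(case-insensitive match against `FOSSIL_SPECIMEN`, `LITERATURE`,
`MATERIAL_CITATION`; configurable, since the Darwin-Core vocabulary
drifts); (2) per-species coordinate deduplication on a global 2.5-arcmin
lattice anchored at (−90°, −180°), with half-open `[lo, hi)` cells and the
first record in input order kept — the resolution is standard for
distribution–climate work, the anchoring and tie-break are this package's
conventions; (3) removal of species with fewer than 10 records. The
`FilterReport` satisfies the exact conservation identity
`n_input = n_kept + removed_basis + removed_duplicate + removed_sparse`,
and the filter is idempotent. No further coordinate-cleaning heuristics
(country centroids, sea tests, taxonomic name resolution) are applied.

## Bioclim summaries and predictor preparation

Per record, from its containing grid cell: MAT = mean of the 12 monthly
temperatures (°C), TAR = warmest − coldest monthly mean (°C), MAP = annual
precipitation sum (mm), PS = 100 · SD/mean of the monthly precipitation
(population SD, CV%) — the BIO1/BIO7/BIO12/BIO15 conventions. Species
values are medians over their kept records (even counts: mean of the two
middle values); medians precede transformation and standardization.
Each predictor is tested with Shapiro–Wilk at α = 0.05; if normality is
rejected and all values exceed −1, `log(x+1)` is applied (tolerates zero
precipitation seasonality), then z-scoring (ddof = 1). VIF_j =
1/(1−R²_j) from regressing predictor j on the others with intercept;
perfect collinearity reports `inf` instead of raising.

## Köppen–Geiger engine

Covers the 14 (sub)tropical-to-warm-temperate categories Af, Am, As, Aw,
Bsh/Bsk/Bwh/Bwk, Cwa/Cwb/Csa/Csb/Cfa/Cfb; snow/polar climates and
warm-temperate cells with fewer than four months ≥ 10 °C return
`UNCLASSIFIED` (these feed the NA path of species assignment). Decision
order is the standard precedence: arid first (P_ann < 10·P_th, desert
vs. steppe at 5·P_th, suffix h/k at T_ann = 18 °C), then equatorial
(T_min ≥ 18 °C: Af at P_min ≥ 60 mm; Am at P_ann ≥ 25(100 − P_min); As
when the driest month falls in the summer half-year, ties broken toward
the earliest month; else Aw), then warm temperate (−3 < T_min < 18 °C,
Cs/Cw/Cf by the seasonal precipitation contrasts, suffix a at
T_max ≥ 22 °C, else b with ≥ 4 warm months). Summer half-years are
Apr–Sep (N) and Oct–Mar (S). The dryness threshold follows the Kottek
rule: P_th = 2·T_ann if ≥ 2/3 of annual precipitation falls in winter,
2·T_ann + 28 if ≥ 2/3 falls in summer, else 2·T_ann + 14.

The engine is validated against a deliberately independent re-derivation
(`koppen_reference.py`) that evaluates all 14 categories as complete
boolean conjunctions and asserts mutual exclusivity; the two agree on
100% of 10,000 random climates in the acceptance run.

Species are assigned at the 14-category level first — a category must
cover **strictly** more than 70% of the species' distinct occupied grid
cells — and then mapped to its major group; otherwise NA. The "range"
here is the set of occupied cells from the filtered occurrences, the
only surrogate available when flora-based range polygons are not
supplied.

## Trait analyses

Leaf architecture is coded 0 simple / 1 unifoliolate / 2 trifoliolate /
3 multifoliolate and collapsed to simple (0) vs. compound (1) for the
binary analyses. The overall climate-group contrast is an uncorrected
Pearson chi-squared on the full table; posthoc tests are all pairwise
2×2 comparisons with Yates continuity correction, Benjamini–Hochberg
adjusted (Holm/Bonferroni configurable). Region-by-leaf counts count a
species once in every region it lists (`;`-separated).

Ordinary logistic regression is fit by maximum likelihood (statsmodels);
separation or non-convergence is flagged, not raised. Firth's
bias-reduced logistic regression is implemented directly: Newton steps on
the Jeffreys-penalized score U*(β) = Xᵀ(y − μ + h(1/2 − μ)) with h the
hat-matrix diagonal and step-halving on the penalized likelihood;
estimates are finite even under complete separation.

Recursive partitioning uses Gini impurity with a minimum terminal-node
size of 25 species and a complexity gate of 1% of root impurity
(scikit-learn's tree behind a thin structure; thresholds sit at the
midpoint of the bounding data gap). The random forest is hand-bagged from
scikit-learn trees (√p candidate predictors per split) so that
importance can be computed the classical way: mean out-of-bag accuracy
drop under per-variable permutation, seeded and deterministic.

Ploidy: against a base number x (default 8), 2n = 2x is diploid, 2n = 4x
tetraploid, anything else above 2x `polyploid_other` (odd counts warn);
counts below 2x are errors.

## Mk likelihood, model choice, ancestral states, transitions

The pruning likelihood uses per-edge transition matrices exp(Q·t) from an
eigendecomposition of Q (vectorized over edges), falling back to
scaling-and-squaring when the eigenbasis is ill-conditioned; conditional
likelihoods are rescaled per node and the root is combined with a flat
1/k prior (configurable to stationary frequencies). Rates are optimized
on the log scale with L-BFGS-B in [1e-8, 1e3] per My, five multistarts,
ftol 1e-10. AIC ties break toward fewer free rates. Marginal ancestral
probabilities come from the standard two-pass (conditional ×
rest-of-tree) computation and are verified against exhaustive enumeration
on small trees to 1e-10. Transitions are counted where the MAP state of
a parent differs from the MAP (or observed tip) state of its child —
a point estimate that undercounts multiple hits on long edges; stochastic
mapping is deliberately out of scope. Polytomies are allowed everywhere;
zero-length branches are perturbed to 1e-8 My with a warning.

## Fritz–Purvis D

The contrast statistic d sums |parent − child| differences of nodal trait
values obtained by unweighted child averaging up the tree. D scales the
observed d between the mean d under tip-label shuffling (1000
permutations) and the mean d under Brownian-liability simulations
thresholded at the empirical prevalence rank (1000 simulations);
reported p-values are the fractions of null statistics at or below the
observed d. Calibration is part of the acceptance run: the mean D over
50 synthetic 200-tip datasets is 1 within ±0.15 under shuffle generation
and 0 within ±0.15 under threshold generation.

## Phylogenetic binary regression (PQL)

logit P(y=1) = Xβ + u, u ~ N(0, s²·C), with C the shared-branch-length
matrix scaled to unit mean diagonal. Estimation alternates the working
variate Z = η + (y−μ)/W with profiling s² on a REML-type criterion
(−2·[log|V| + log|XᵀV⁻¹X| + rᵀV⁻¹r] maximized over log s² ∈
[log 1e-8, log 50]); convergence when the largest parameter change falls
below 1e-6, capped at 50 iterations; s² is clamped at ≥ 0 and Wald tests
use (XᵀV⁻¹X)⁻¹. With s² fixed at 0 the iteration is exactly IRLS and
reproduces ordinary logistic regression to 1e-4. Known limitation: PQL
Wald tests are approximate — calibration sims with data generated from
the model itself (β₁ = 0, s² = 0.5, 150 tips) give a 3–4% rejection rate
at nominal 5%, and under a misspecified liability-threshold null the test
is more conservative (~1.5%).

## Recoding sensitivity experiment

Candidates are compound-leaved species whose median MAP exceeds the
threshold (default 1250 mm), recoded to simple one at a time in
descending-MAP order — the order is this package's choice; after each
step the binary Mk model (SYM ≡ ER for two states) is refit,
compound→simple transitions recounted on the MAP reconstruction, and the
PGLMM of leaf state on standardized MAP rerun. The result is the smallest
transition count with Wald p < α (default 0.05), the full trajectory, or
"not achievable" when candidates are exhausted.

## Synthetic data: what it emulates, what it does not

- **Trees**: pure-birth (Yule) simulation conditioned on the tip count
  (epoch durations Exp(k·λ), a final epoch with n lineages), giving
  exactly ultrametric chronograms. Default birth rate 0.15/My yields
  crown depths of a few tens of My, the scale of a Miocene plant
  radiation.
- **Traits**: multistate characters evolve under a user-supplied Mk
  matrix (the simulator records the true per-edge change counts so that
  transition-counting can be scored against truth); binary characters
  from a Brownian liability started at 0 and thresholded — the standard
  Brownian null of the D statistic.
- **Climate**: mean temperature falls linearly with |latitude|
  (28 − 0.4·|lat| °C), seasonal amplitude grows with |latitude|
  (0.28·|lat|, phase-flipped across the equator), and three longitudinal
  precipitation belts (evenly wet ~185 mm/month, summer-monsoonal
  190/10 mm, arid ~15 mm) guarantee all four major climate groups over a
  ≥ 40° latitude span. Default resolution 30 arcmin keeps the default
  grid small; the cleaning lattice stays at 2.5 arcmin regardless.
- **Occurrences**: each species gets a uniform range centroid and a
  1–3.5° radius; records scatter normally. Contamination defaults —
  5% fossil/literature relabels, 10% appended duplicates (half exact
  copies, half distinct points in the same 2.5-arcmin cell), 5% of
  species under-sampled at 5 records — are plausible GBIF-extract rates
  chosen once for the study conditions. The species' probability of
  simple leaves is logistic in centroid MAP with slope 0.35 log-odds per
  100 mm and intercept −0.9 at the 1000 mm reference, anchored so
  prevalence runs from roughly 15% in dry to roughly 70% in very wet
  climates — the magnitude of gradient the analyses are meant to detect.
  Default scale is 183 species × 120 records (~22k records).

Not emulated: niche-model realism, spatial autocorrelation of sampling
effort, phylogenetic structure in the climate-coupled leaf trait (it is
drawn independently across species given MAP — so synthetic D values sit
between 0 and 1 rather than at the strongly negative values typical of a
conserved real trait), and multi-region species ranges. Passing tests
therefore demonstrate correctness of the machinery under known generating
processes, not ecological realism.

`synthetic_reference_traits()` is a deterministic stand-in for a
published 338-species trait table: its marginal counts (177 twisted keel
beaks; 173 of 205 African+Madagascan species trifoliolate; 56 of 69
Asian species simple-leaved) are reproduced exactly, all other cells are
filler; it exists to exercise the counting operations.

## Problem sizes and reproducibility

The test suite and the acceptance script choose simulation sizes that
characterize each method honestly at desk scale: enumeration oracles on
trees of 4–6 tips (100 instances), D calibration on 50 datasets of 200
tips with 1000 permutations/simulations each, PGLMM recovery on 25
datasets of 200 tips and type-I calibration on 200 datasets of 150 tips,
Köppen validation on 10,000 random climates, and a full pipeline run at
183 species × 120 records. One global seed fans out to all stages via
`numpy.random.SeedSequence`; rerunning any entry point with the same seed
reproduces its outputs byte-for-byte (result files exclude paths and
timestamps; logs carry them instead).
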