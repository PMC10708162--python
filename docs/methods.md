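# Methods

## Trait pipeline

Raw measurements per leaf are LA (one-sided lamina area, mm²), LFM
(water-saturated fresh mass, mg) and LDM (oven-dry mass, mg), with the
physical invariants LA > 0, LDM > 0, LFM ≥ LDM enforced on input. The raw
quantities are averaged hierarchically: leaves within individual, then
individual means within species, both levels unweighted. SLA = LA/LDM and
LDMC = 100·LDM/LFM are computed **from the species-level averages** (ratio
of means). The alternative — per-leaf ratios averaged upward — gives
different values on unbalanced data; ratio-of-means was adopted because the
pipeline treats the derived traits as properties of the averaged species
phenotype, and it keeps LDMC inside (0, 100] whenever the mass invariants
hold. Species with incomplete collections (fewer than the nominal 4
individuals × 5 leaves) are retained with the available material; the
profile records `n_individuals` and `n_leaves`. LFM = LDM exactly (LDMC =
100 %) is accepted but logged: it is the physical boundary, reached by
sclerophyllous outliers, and it falls outside the logit domain of the S
transform (handled by clamping, below).

## CSR engine

The ordination is a fixed skeleton with pluggable calibration. Per axis
(C ← LA, S ← LDMC, R ← SLA; the mapping is validated, not configurable):

1. transform the trait: √(LA/LA_max) for C, logit(LDMC/100) for S,
   ln SLA for R;
2. min–max rescale against the calibration bounds (calib_min, calib_max)
   on the transformed scale;
3. clamp to [0, 1] — values outside a transform's domain (LDMC = 100 →
   logit = +∞) clamp to the boundary with a logged warning rather than
   raising, since they are legitimate extreme phenotypes;
4. normalise the three clamped values to percentages summing to 100. If
   all three clamp to 0 the point is undefined; it maps to the
   uninformative centre (33.3, 33.3, 33.3).

This construction makes each axis monotone in its source trait and closes
the simplex to 1e-9, both enforced by property tests.

The calibration table is versioned data, not code. The shipped default
(`calibration_synthetic.json`, version `synthetic-1.0`) has bounds chosen
so the synthetic generator's trait distributions span the informative range
of each axis: LA_max = 50,000 mm², C bounds [0, 0.35] on the √-proportion
scale, S bounds [logit(0.10), logit(0.70)], R bounds [ln 10, ln ~54.6].
It is **not** a global calibration: analyses of real floras should supply
a table derived from a worldwide reference species set. Re-deriving that
global calibration is explicitly out of scope.

### Strategy classes

The 19 Grime classes are represented by centroids in the simplex: pure
classes at the vertices, secondary classes at edge midpoints, CSR at the
barycentre, and each transitional class X/Y at the midpoint of the X and Y
centroids (C/CS = (75, 25, 0), C/CSR = (66.7, 16.7, 16.7), CS/CSR =
(41.7, 41.7, 16.7), …). A score is assigned to the nearest centroid in
Euclidean distance, ties broken lexicographically. This rule reproduces
all ten printed strategy labels in the shipped alien-species survey table,
which is the only labelled ground truth available to validate it.
Published tables print coordinates rounded to whole percent, whose sum can
miss 100 by up to 2; `classify_triplet` tolerates that, while ordination
output must close exactly.

## Community metrics

Basal area per stem is π(DBH/200)² (DBH in cm, area in m²); plot basal
area G sums over **stems**, so a multi-stemmed tree contributes once per
stem — DBH is recorded per stem and a multi-stemmed tree's cover is the
sum of its stems. G is reported per 100 m² plot. Mean DBH is over stems,
mean height over trees (one height per tree), matching how field crews
record the two quantities. "Abundance" means number of trees
(individuals), deliberately distinct from stem density when multi-stemmed
individuals occur.

Community CSR under every scheme is a weighted mean of the species scores
present in the plot, weights normalised to one, output re-closed to 100:
it therefore always lies in the convex hull of the species scores and is
invariant to rescaling the weights. The Sørensen index 2|A∩B|/(|A|+|B|)
compares the near- and off-trail plot at each elevation; 0.70 is the
conventional threshold for calling two communities similar.

## Gradient inference

All fits are ordinary least squares on a fixed design: linear, quadratic
or cubic polynomials in x, or y = a + b·ln x. Families are fixed by the
analysis design, not selected by AIC. Fit quality is the
explained-variance pseudo-R² = 1 − SS_res/SS_tot on the response scale —
the only definition that is comparable across the linear and
nonlinear-in-x families — and the p-value comes from the F test of the
fitted model against the intercept-only model (conventional for least
squares; the choice matters little at these sample sizes). A response that
is constant to rounding noise gets pseudo-R² = 0 and p = 1.

The near-/off-trail comparison of R scores uses the two-sided
Wilcoxon–Mann–Whitney test in its unpaired form (the plot pairing is a
sampling convenience, not a blocking factor in the published design):
exact enumeration when n₁ + n₂ ≤ 12 without ties, otherwise the normal
approximation with tie and continuity corrections. The two methods agree
within 0.02 on tie-free 6+6 samples (tested).

## Origin comparison (phylogenetic ANOVA)

Related species are not independent samples: under Brownian-motion (BM)
evolution the covariance of two tips is σ² × shared root path length, so
the ordinary F null is anticonservative. The test therefore: computes the
observed one-way F between natives and aliens; simulates the trait
`n_sim` times (default 10,000) under BM on the phylogeny (root value 0,
each branch adding an independent N(0, σ²·length) increment); recomputes F
for each replicate with the same group labels; and reports
p = (b+1)/(n_sim+1), where b counts simulated F ≥ observed. The +1
estimator avoids a zero p from finite simulation, so p ≥ 1/(n_sim+1)
always. σ² is fixed at 1: F is invariant to affine transformation of the
values, so the unknown rate cannot affect p (tested). BM is simulated
edge-wise via the tip × edge incidence matrix, which is vectorised,
reproduces zero-length-branch degeneracies exactly, and makes the 10,000
runs take well under a second on one CPU.

Six variables are tested: the C, S, R scores and the LA, LDMC, SLA traits.
R, LA and SLA are ln-transformed to approximate normality; R contains
exact zeros (strong CS strategists), handled by applying ln(R+1)
uniformly to the R variable — transparent and order-preserving, though
results under another zero convention could differ slightly. Bonferroni
adjustment uses m = 3 within each variable family (the three scores; the
three traits), since the two families answer separate questions and are
reported separately. Species absent from the phylogeny (e.g. tree ferns
on a seed-plant tree) are excluded from this comparison only, never from
the community analyses.

`balance_sensitivity` guards against artefacts of the unbalanced design
(typically ~70 natives vs ~10 aliens): it repeatedly subsamples the larger
group to the smaller group's size without replacement, prunes the tree,
and reruns the test. With an already balanced design every resample is the
full analysis.

## Synthetic data generator

The generator emulates the reference sampling design: 8 elevational
levels every 300 m (0–2100 m), two 100 m² plots per level (near-trail /
off-trail), all stems ≥ 1 cm DBH censused, and a leaf collection of up to
4 individuals × 5 leaves per species with ~15 % of species deliberately
incomplete. Defaults (80 species, 12.5 % alien, alien ceiling 900 m) are
the reference study conditions.

Mechanics, chosen once and documented here:

- **Occupancy**: each species occupies a contiguous elevational window
  around an optimum; native optima are Beta(2, 2) over the gradient so the
  species pool — and hence plot richness — peaks at mid-elevation; alien
  optima are uniform below the ceiling and alien windows are clipped to
  it, so no alien ever occurs above 900 m.
- **Traits**: species-true logit(LDMC) increases with the elevational
  optimum at `ldmc_elevation_slope` (default 0.6 logit units/km — no
  published effect size exists, so the default was chosen once for
  statistical detectability against 10 % leaf noise); species-true ln LA
  increases with a deterministic crowding index of the optimum at
  `la_basal_area_slope` (default 1.5 per m²/100 m²); ln SLA is negatively
  coupled to logit(LDMC) plus noise, reproducing the acquisitive–
  conservative trade-off.
- **Communities**: per plot, tree counts are Poisson with a hump-shaped
  mean damped by the crowding index (so basal area declines toward the
  open top of the gradient); species abundances are Dirichlet(0.8)-
  multinomial; stems per tree are 1 + Poisson(0.2); DBH is shifted
  lognormal with an inverse-hump median (smallest mean DBH, heaviest
  tail at mid-elevation); height declines with elevation and scales
  weakly with DBH.
- **Leaves**: each leaf multiplies the species-true LA, LDM, and water
  mass (LFM − LDM) by independent lognormal factors with mean 1 and CV
  `leaf_noise_cv`; modelling water rather than LFM keeps LFM ≥ LDM for
  every leaf at any noise level, and CV = 0 returns the truth exactly.
- **Phylogeny**: a Yule tree over all species, pendant edges extended by
  one Exp(nλ) waiting time so the simulator's stopping rule leaves no
  duplicated tips, then rescaled to unit depth. Ultrametric by
  construction; sufficient for BM nulls.
- **Randomness**: a single seed split hierarchically
  (tree / per-species traits / abundances / per-species leaves) via
  `numpy.random.SeedSequence.spawn`, so identical configs are
  byte-identical on disk and adding species does not shift the leaf noise
  of existing ones.

`truth` records the generating parameters and species-level true traits,
sufficient to score parameter recovery downstream.

What the generator does **not** emulate: taxonomy, rainfall or
disturbance history, within-plot spatial structure, dispersal limitation,
or realistic global trait ranges (the default calibration compensates for
the latter). Passing tests therefore demonstrate the correctness and
statistical calibration of the pipeline under a known generating model,
not the ecological conclusions one would draw from real field data.

## Problem sizes and numerical choices

The test suite runs the heavier checks at sizes chosen to keep the whole
suite fast while leaving Monte-Carlo error well inside the asserted
tolerances: the type-I calibration of the phylogenetic ANOVA uses 1,000
BM-null datasets (Yule trees, 60 + 20 tips) at 499 null simulations each;
the star-tree equivalence check pairs 20 datasets at 2,000 simulations;
slope-recovery uses 100 full default-size datasets. Simplex closure is
asserted to 1e-9; aggregation oracles to 1e-8; ternary round-trips to
1e-9. Ties in the nearest-centroid classifier break lexicographically;
degenerate all-zero ordination output maps to the centre; empty plots
yield G = 0 with a warning rather than an error.

## Known limitations

- The shipped calibration is synthetic-scale; CSR scores from it are
  internally consistent but not comparable to published global CSR values
  without substituting a global calibration table.
- The classifier is validated against a single ten-row labelled table;
  other published label sets could in principle use a different
  assignment rule near class boundaries.
- The phylogenetic ANOVA assumes BM; no Pagel's λ or OU alternatives are
  implemented, and polytomies are accepted as given.
- p-values for polynomial fits use the F test against the intercept-only
  model; other software may report partial-coefficient tests instead.
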