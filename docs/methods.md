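# Methods

This note documents the models and procedures implemented in `alleleniche`,
the defaults chosen where the design was genuinely open, and the limits of
what the synthetic-data checks can show.

## The maximum-entropy niche model

Given `m` presence records of one allele and a background sample of `n > m`
landscape cells, the model is the Gibbs distribution
`q_λ(x) = exp(λ·f(x))/Z` over background cells, fitted by minimizing the
convex objective

    J(λ) = −(1/m) Σ_i λ·f(x_i) + ln Z + Σ_j β_j |λ_j|.

**Features.** Each variable is min–max scaled to [0, 1] on the pooled
presence+background training range (the range is stored for later clamping).
Classes: linear (scaled value), quadratic (its square), product (pairwise
products of scaled values), hinge (forward `max(0,(x−k)/(1−k))` and reverse
`max(0,(k−x)/k)` at 8 evenly spaced interior knots per variable — a
desk-scale stand-in for the dense hinge grids of the reference MaxEnt
implementation; the count is recorded in model metadata and configurable).
All feature columns lie in [0, 1] on training data. Classes default by
presence count (m < 10: L; 10–14: LQ; 15–79: LQH; ≥ 80: LQHP) and can be
fixed by the user or tuned by AICc.

**Regularization.** `β_j = reg_multiplier · w_class(m) · s_j/√m`, with
`s_j` the feature's standard deviation over the presences (floored at 1e-3
so features constant on presences remain penalized) and `w_class` the
published per-class schedule: linear/quadratic/product interpolate
(m, w) = (10, 1.0), (30, 0.2), (100, 0.05); hinge uses 0.5 throughout.
Tuning multipliers default to {0.5, 1, 2, 4}.

**Optimizer.** The L1 term is handled by the positive/negative split
λ = a − b with a, b ≥ 0, making the objective smooth over a box; L-BFGS-B
(scipy) solves it with a monotone line search. Defaults: tol 1e-5 on the
relative objective change (gradient tolerance equal to tol), max_iter 500.
Because the problem is convex the split reaches the same optimum as
coordinate descent; the test suite checks the fitted objective against a
dense grid search on small problems and verifies the stationarity condition
`|empirical mean_j − model mean_j| ≤ β_j` per feature. Fits that stop at
max_iter return a results object flagged unconverged (with a warning)
rather than raising.

**Output scales.** *raw* is the Gibbs density renormalized to sum to 1 over
the prediction domain's unmasked cells. *cumulative*(x) = Σ of raw over
cells with raw ≤ raw(x). *cloglog* = `1 − exp(−e^H · raw′)` where `H` is
the entropy of the fitted raw distribution over the training background and
raw′ is raw rescaled by (domain size / training background size), so the
zero-coefficient model maps to `1 − e⁻¹` on any domain. Clamping (default
on for projection) truncates scaled features into [0, 1]; a companion mask
flags cells whose climate left the training range.

**AICc.** `lnL = Σ_i ln raw(x_i)` with raw normalized over the supplied
landscape (the background sample stands in for the full landscape during
tuning); `K` counts nonzero coefficients; `AICc = 2K − 2lnL +
2K(K+1)/(n−K−1)`, undefined (candidate invalid) when `n ≤ K+1`. Tuning
ties break by fewer active coefficients, then lower multiplier.

## Validation and variable selection

*AUC* uses the Mann–Whitney formulation (ties ½). *Partial ROC* restricts
the ROC to sensitivity ≥ 1 − E (E = 0.05 default) and divides the area
under the curve there by the chance-diagonal area over the same
false-positive range; per bootstrap replicate (100 by default) half the
presences are resampled with replacement, and p is the fraction of
replicates with ratio ≤ 1. *Subsampling replicates* draw
`round(test_fraction·n)` test points uniformly per replicate (default
fraction 0.25 — the original protocol does not state its percentage — and
50 replicates).

*Jackknife importance* reports, per variable, the training gain
(`ln n_bg` minus the unpenalized part of the objective) of the model using
only that variable and of the model without it. *Variable selection*
iterates: fit, drop the variable with the lowest gain-alone, until the
target count (default 4) remains; then, on background values, repeatedly
drop the lower-gain member of any pair with |Pearson r| > 0.8. The drop
criterion (gain-alone) is one concrete reading of the under-specified
"reiterative jackknife"; the full per-iteration audit trail is emitted so
alternatives can be compared. Note that with L1 penalties the *regularized*
objective nests exactly across variable subsets, but the unregularized gain
can fall below a sub-model's by up to the penalty the extra coefficients
pay (~1e-5 on the bundled fixtures); the tests assert the exact form.

## Niche overlap and randomization tests

Schoener's `D = 1 − ½ Σ|p_i − q_i|` after normalizing each surface to unit
mass — over shared unmasked cells (geographic space) or over a
Latin-hypercube sample of the hyper-rectangle of pooled training ranges
(environmental space; raw-scale scores, since D is computed on normalized
vectors and must precede any monotone transform). The *identity test*
repartitions the pooled records into the observed group sizes (one-sided
lower, add-one p-value `(1 + #{D_null ≤ D_obs})/(n_reps + 1)`, 100
randomizations by default). The *background test* replaces one group's
records with uniform draws from its background region (default: the whole
study mask; two-sided, add-one, doubled and capped at 1); the symmetric
direction is a second call. All null replicates reuse the observed models'
tuned settings — no per-replicate re-tuning — matching common practice and
keeping the tests tractable; dual-type sites enter the pooling as distinct
typed records, exactly as they appear in the occurrence table.

## Projection, thresholds and favourability

Projection re-applies the fitted model to another stack (clamped by
default) and renormalizes raw over the new domain, so projecting onto the
training stack reproduces the training prediction bit-for-bit. Scenario
members (e.g. several GCMs under one emissions pathway) are averaged
cell-wise; replicate-mean (not median) surfaces feed all downstream maps.
Thresholds are the minimum, 5th- and 10th-percentile training-presence
values, with nearest-rank percentiles (value at 1-based index ⌈q·n⌉ of the
sorted presence suitabilities) — order-statistic based and bit-exact;
classification bounds are inclusive. Favourability compares the two
alleles' cloglog surfaces cell by cell (the comparison scale is recorded in
provenance and configurable); exact ties go to the first allele and are
tallied, and percents are over shared unmasked cells.

## Geography conventions

WGS84 degrees; haversine distances on a 6371-km sphere (sub-0.5% error is
immaterial at the 10-km thinning scale). Grids are cell-centre registered,
row 0 north; point-in-cell uses half-open `[west, east) × [south, north)`
intervals. Thinning is greedy in input order and per allele (a site may
legitimately carry both alleles), with an inclusive ≥ threshold. Rasters
are ESRI ASCII grids; values are written as shortest-round-trip decimal
so write/read cycles are bit-exact.

## The synthetic world

Climate layers are Gaussian-smoothed white noise (smoothing scale 6 cells
on the standard 100×100 grid), standardized to zero mean and unit variance
over the mask; one designated pair of layers is mixed to a target Pearson
correlation (0.5 by default) to emulate the collinearity of real bioclim
variables. True niches are product-Gaussian responses
`s = exp(−Σ_v (z_v−μ_v)²/2σ_v²)` — smooth, unimodal, and recoverable by
quadratic features, matching the unimodal response curves the real system
shows. The standard world uses four layers named after the temperature- and
precipitation-seasonality variables they emulate (BIO4, BIO10, BIO13,
BIO15) with divergent niches on BIO10/BIO13: the cold/wet allele at
μ = (−1, +0.8), the warm/dry allele at μ = (+1, −0.8), both with
σ = (0.9, 1.2). Occurrences are drawn without replacement with probability
proportional to true suitability (a modelling convenience — presence data
carry no abundance interpretation), at cell centres, rejecting draws closer
than 10 km to a same-allele point; the standard world has 40 + 57 records
at 94 distinct sites with 3 dual-type sites, mirroring the study counts.
The "future" stack adds +2 standardized units to BIO10, so the warm
allele's favourability must expand — a known-direction check standing in
for real GCM deltas. Everything derives from one seed and regenerates
byte-identically.

What the synthetic checks do **not** show: the layers have neither the
covariance structure of real bioclim data nor a coastline-shaped mask;
occurrence sampling is unbiased (no survey-effort artefacts); the truth is
exactly unimodal-Gaussian, which favours quadratic features. Passing tests
demonstrate correctness of the machinery and calibration of the tests under
these idealized conditions, not performance on real survey data.

## Problem sizes used in the bundled checks

The test suite and the acceptance script scale the study design to desk
size: backgrounds of 500–2,000 cells (10,000 — the full grid — for the
niche-recovery check), 3–20 subsampling replicates, 99 randomizations for
the permutation tests, and 20 simulated datasets for the null-calibration
run. These sizes keep every check fast while leaving all statistical
conventions (add-one p-values, sidedness, thresholds, replicate averaging)
identical to the full-scale configuration, whose defaults (50 replicates,
100 randomizations, 10-km thinning, |r| ≤ 0.8, 4 variables) are preserved
in `RunConfig`.

## Known limitations

* No categorical or threshold features, sampling-bias grids, or spatially
  blocked cross-validation.
* Rasters must be pre-aligned; there is no reprojection or resampling, and
  only the ESRI ASCII grid format is read and written.
* The identity/background tests refit but never re-tune per replicate; with
  very small groups the tuned settings may overfit the observed partition.
* AICc uses the background sample as the landscape; with small backgrounds
  the likelihood normalization is itself an estimate.
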