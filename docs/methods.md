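# Methods

## Measurement model and angle features

A cell of population p carries a copy-number barcode (c_C, c_G, c_R).
Complemented fluorescence grows sub-linearly with repeats: empirically
each doubling of the repeat count multiplies the signal by roughly 1.7
(microscopy, histone-fused arrays; ~1.6 for the smaller ΔSUMOstar fusion)
rather than the ideal 2. We model the expected channel signal as

    I(n) = base_brightness · amp^log2(n)   for n ≥ 1,   I(0) = 0,

which interpolates the per-doubling fold factor as a power law in log2(n)
and reduces exactly to the linear case I(n) = base·n at amp = 2. The
per-doubling fold is the only quantity the imaging experiments report; the
power-law form is this package's choice of a smooth interpolant.

Measured intensities are modelled as

    ch = s · I(n) · ε_chan + b,   s = exp(N(0, σ_expr²)),
    ε_chan = exp(N(0, σ_chan²)),  b ~ N(bg_mean, bg_sd²),  clamped at 0,

with the expression scale s shared across a cell's channels and the
channel noise independent. Log-normal multiplicative noise is chosen
because per-cell intensity distributions are strongly right-skewed;
clamping at zero mirrors how background-corrected exports behave.

Because s is shared, it cancels in intensity *ratios*. The classifier
therefore works in the spherical-coordinate angle space of the normalized
channels (x, y, z) = (cyan, green, red):

    r = (x² + y² + z²)^½,
    Angle_CvsG  = tan⁻¹(y/x)   (degrees, two-argument form),
    Angle_RvsCG = cos⁻¹(z/r)   (degrees),

both in [0°, 90°] for nonnegative channels and invariant to any common
positive rescaling. Numerically, cos⁻¹(z/r) is evaluated as
atan2(hypot(x, y), z) — the same function, but well-conditioned near the
red axis where z/r → 1. Conventions for degenerate cells: the
two-argument arctangent sends x = 0 to 90° instead of dividing by zero;
a cell with x = y = 0 but z > 0 gets Angle_CvsG := 0° (the other angle
carries all information); a fully dark cell (r = 0) is flagged invalid,
counted in the log, and excluded from fitting rather than silently
dropped.

Preprocessing order is background subtraction (per-channel control
medians, clamped at zero) followed by pooled-median normalization — each
channel divided by its median across *all* populations combined, so
between-population level structure survives. Whether background
subtraction precedes normalization is a config switch
(`background_before_normalize`, default true).

## Default generator parameters

| parameter | default | units | rationale |
|---|---|---|---|
| amp | 1.7 | fold/doubling | measured microscopy calibration |
| base_brightness | 100 | a.u. | single-repeat channel scale |
| ref_brightness | 100 | a.u. | reference (expression) channel scale |
| sigma_expr | 0.4 | log-units | broad right-skewed per-cell spread |
| sigma_chan | 0.1 | log-units | see below |
| bg_mean, bg_sd | 2, 1 | a.u. | small residual background after correction |
| n_cells_per_population | 5000 | cells | matches ">1000 cells per population" scale |

σ_chan = 0.1 was derived analytically, not tuned: in the four-level
single-channel experiment the tightest adjacent-level boundary (×4 vs ×8)
is Δ = ln 1.7 ≈ 0.53 apart in log-ratio space, the log-ratio noise is
√2·σ_chan, and a Gaussian tail of (Δ/2)/(√2·σ_chan) ≈ 1.9 standard
deviations yields ~3% error at that boundary and ~95% overall four-level
accuracy — the qualitative operating point of the real experiment. All
quantitative accuracies obtained on synthetic data are conditional on
this noise calibration; the generator does not emulate segmentation
errors, spectral bleed-through, focus drift, or cell-cycle expression
structure, so passing tests demonstrate correctness of the *analysis*,
not expected field performance on real images.

## Classification

Training is supervised moment matching, not EM: the labeled training
split (default 80% per population, rounding toward train, seeded) gives
each population a sample mean μ_k and sample covariance Σ_k
(+ 10⁻⁶·I regularization so degenerate classes survive); the components
are concatenated into a mixture with **uniform priors** — the membership
formula P(k|x) = P(x|θ_k)/Σⱼ P(x|θⱼ) contains no weight term, and the
model type keeps weights only for generality. Densities are computed via
Cholesky factors in log space with max-subtraction, so posteriors
normalize to 1 within 10⁻⁹ even hundreds of standard deviations from all
means. Ties break toward the lowest class index and are logged (ties
have measure zero but occur with clamped data). Full covariances are
used in the 2-feature angle space. Overall accuracy is pooled per-cell
correctness; per-class accuracies (whose mean is the macro average) are
reported alongside.

The k-means alternative clusters the angle features with k ≥ the number
of populations and maps each cluster to the population holding the
majority of its members. The mapping is many-to-one, which merges
multiple clusters arising from one bimodal population; the extra-cluster
count is a user parameter because bimodality is discovered empirically,
not predicted.

## Panel selection

Pairwise discriminability of two populations is measured without labels:
the pooled pair (balanced by subsampling the larger population — unequal
sizes bias a two-component fit; switchable off) is split by a
two-component full-covariance Gaussian mixture fitted by EM from five
seeded k-means starts, and the accuracy is the better of the two
cluster↔population assignments, hence ≈ 0.5 at chance and 1.0 at perfect
separation. The panel search draws k-subsets uniformly at random
(independent draws; duplicates are harmless given ~2×10²⁰ candidate
20-subsets), scoring each by its minimum within-subset pairwise accuracy
and keeping the best (first-found on ties). Default 10⁷ draws; tests use
10⁴–10⁵ draws against an exhaustive enumerator capped at 2×10⁶ subsets.

## Spatial statistics

Clark–Evans: R = mean observed nearest-neighbor distance / (0.5/√ρ),
ρ = n/area. The area is user-supplied by default (the statistic shifts
with the area choice, so the mode is explicit and logged); bounding-box
and convex-hull fallbacks are provided. No edge correction is applied by
default, matching the plain computation; an optional boundary term adds
(0.0514 + 0.041/√n)·P/n to the CSR expectation (P = window perimeter),
which removes most of the positive bias of ignoring neighbors beyond the
window edge. At n = 2000 in a unit square the uncorrected mean R over
CSR replicates is ≈ 1.01.

Heterotypic adjacency: for each cell of a target population, the single
nearest cell among all *other* populations is found (k-d tree, identical
to the all-pairs scan), counts are tallied per population, and the null
is 100 uniform label permutations over the fixed positions — operationally
identical to shuffling positions while preserving type totals, since only
the label/position pairing matters to the counts. The statistic is
observed/null-mean per population; per-shuffle counts are retained and an
add-one-smoothed empirical upper-tail p-value is reported. Homotypic
neighbors are excluded from the search by design (the question is about
*other* populations); an include-homotypic switch is deliberately absent
because it changes the statistic's meaning, and a sensitivity analysis can
simply relabel.

The point-pattern generator's "attracted" mode relocates a stated
fraction of one label's points to within a stated radius of another
label's points. This is a positional implementation of label attraction:
the permutation null and the adjacency statistic only see the resulting
label/position structure, so it is interchangeable with reassigning
labels over fixed positions while being simpler to reason about.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: 5000 cells per level
for generator calibration, 100 CSR replicates of 2000 points for the
Clark–Evans reference, 10⁵ random draws against exhaustive panel oracles
on 8–12 populations, 100-permutation adjacency nulls. Every stochastic
path takes an explicit seed (numpy `default_rng`); identical config and
seed reproduce tables, splits, searches and shuffles bit-exactly.

## Known limitations

- The generator's noise model is stationary and channel-independent;
  real microscopy noise is neither.
- Pairwise EM accuracy is estimated on the same cells used to fit the
  two-component mixture (as in the source workflow); it is an in-sample
  separability score, not a generalization estimate.
- The max–min search is exact only in expectation over draws; for k near
  2 or n it is effectively exhaustive, in between it is a lower bound on
  the true optimum (the exhaustive oracle bounds it on small instances).
- Clark–Evans R without edge correction is biased upward by O(P/(n·√ρ));
  the default mirrors the plain computation, and the boundary-corrected
  variant is available where unbiasedness matters.
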