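# Methods

This note documents the models, estimators and numerical choices behind
`stagewalk`, in the spirit of a statistical software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. The data model

A cohort is a set of patients, each carrying a clinical stage label
(early / middle / late, collapsed from the Global Deterioration Scale) and
between 2 and 8 accelerometer recordings.  A recording is an irregularly
sampled three-axis acceleration log: strictly increasing timestamps in
seconds starting near 0, with a nominal 8 Hz rate, and values in m/s² that
mix gravity with the accelerations the patient produces.  Durations vary
freely across recordings — nothing aligns the time domains.

### The synthetic generator

No deposited dataset with this structure exists, so the generator in
`stagewalk.synthetic` emulates it.  Per recording, each axis a ∈ {x, y, z}
is

    a(t) = g·d_a  +  δ_s·e_a  +  A_s·c_a·sin(2π f_s t + φ)  +  ε(t),

with:

* **gravity** `g·d_a`: magnitude g = 9.81 m/s² projected through a
  per-recording unit orientation `d` — the canonical "phone upright in a
  pocket" direction perturbed by Gaussian tilt noise (sd 0.15 on each
  component before renormalisation).  Redrawn per recording, not per
  patient, to mimic day-to-day pocket placement; it is the dominant
  between-recording nuisance, exactly as in real pocket data.
* **stage offset** `δ_s·e_a`: stage level δ ∈ {−1, 0, +1} for
  early/middle/late times a per-axis effect size, default
  (e_x, e_y, e_z) = (1.2, 1.0, 0.15) m/s².  The effect is constant in
  time, so it shifts the mean curve without breaking stationarity, and it
  is an order of magnitude larger on x/y than on z — stage differences
  live in the horizontal plane of movement.
* **gait component**: a sinusoid at stage-dependent cadence
  (1.9 / 1.7 / 1.4 Hz) and amplitude factor (1.0 / 0.8 / 0.6) on base
  amplitudes (1.0, 1.2, 0.4) m/s², with a uniform random phase per
  recording.  A stationary stand-in for periodic gait texture; it does not
  model stride-length or stride-time variability.
* **noise** ε: AR(1) with φ = 0.6, innovation sd 0.5 m/s², initialised
  from its stationary distribution, so the whole within-recording process
  is strictly stationary after the constant — the property the windowing
  scheme relies on.

Timestamps are a jittered 8 Hz grid (uniform jitter ±20% of the interval);
durations are uniform on 120–900 s.  The default composition fixes the
study skeleton exactly: 7/18/10 patients and 41/100/46 recordings per
stage (187 in total), via fixed per-patient recording schedules within
[2, 8].

What the generator deliberately does **not** emulate: gait pathology
detail, device miscalibration, activity changes within a recording, the
accelerometer's ±3.27 g saturation (reported for the device but never used
by the analysis), and the device's Euclidean-norm channel (redundant given
the three axes).  Passing tests on this cohort therefore demonstrate that
the *procedures* behave as designed under their own assumptions — not that
real patients are classifiable at any particular accuracy.

## 2. Preprocessing

Each axis is linearly interpolated and evaluated at integer seconds
t = 1, …, T with T = round(final timestamp) (round-half-to-even; the rule
is covered by a test).  Grid points outside the observed range take the
nearest observed value; at 8 Hz this can only matter at the first grid
point and is a documented choice, not a modelling claim.  Recordings
rounding below 2 s are rejected.

With l the shortest curve length, every curve is restricted to
`t = 1+l_i, …, l+l_i`, `l_i ~ U{0, …, T_i − l}`, independently per curve
and per repetition.  Stationarity makes the windowed curves exchangeable
in distribution across draws, so no single draw is privileged; analyses
are repeated over J draws (1000 for the tests, 10 for the depth
classifier, both configurable) and summarised.  Seed policy: repetition j
draws from a stream derived from (master seed, j), so increasing J never
perturbs earlier repetitions.

## 3. Mean-equality tests

All three tests operate on one axis's windowed curves on a common grid of
length l; integrals use the trapezoidal rule with unit step.

* **Random-projection ANOVA.**  k = 30 directions uniform on the unit
  sphere in R^l (normalised Gaussian vectors); per direction the classical
  one-way ANOVA F-test with (2, n−3) degrees of freedom and its parametric
  p-value (this variant assumes Gaussianity and homoscedasticity of the
  projections).  Combination: Bonferroni `min(1, k·min p)` or the minimum
  Benjamini–Hochberg-adjusted p-value; the latter never exceeds the former.
* **Max-F bootstrap ANOVA.**  `T = max_t F(t)`.  The bootstrap resamples
  curves (not time points) with replacement within each group and centers
  every resampled group at its original sample mean curve, so the
  bootstrap world satisfies H₀; `p = (1 + #{T* ≥ T})/(B + 1)` with
  B = 999 by default, hence p ∈ [1/(B+1), 1].  Pointwise zero
  within-group variance is handled by a machine-epsilon-scaled ridge in
  the denominator (with a warning); variance zero at *every* t is an
  error.
* **L2 two-sample test.**  `T = ∫ (s̄ − ū)²`; bootstrap statistic
  `T* = ∫ (s̄* − s̄ − ū* + ū)²`; same exceedance p-value.  Applied to the
  three stage pairs separately (the k-sample L2 variant is out of scope).

Finite-sample behaviour worth knowing: with groups of only a handful of
curves the centered bootstrap is noticeably conservative for max-F and
slightly anticonservative mid-range for L2 (the bootstrap mean's variance
carries a (1 − 1/n) factor).  The calibration tests therefore run at group
sizes where the bootstrap is consistent (15–60 curves per group); the
acceptance study uses 20 curves per group on a 60-point grid with B = 499,
and 200 simulated datasets, sizes chosen to keep the full study at
desk scale.

## 4. Depth classifier

h-mode depth of a curve c with respect to a sample X:
`D(c|X, h) = mean_i K(d(c, x_i)/h)` with K(u) = exp(−u²/2) (K(0) = 1) and
d the trapezoidal L2 distance.  The per-group bandwidth h_g is the 15th
percentile of the group's pairwise L2 distances — a conventional low
quantile giving a mode-seeking depth; it is logged in every report.

Each curve maps to R³ (depth w.r.t. the early/middle/late training
groups).  Classification maximises class prior × Gaussian-product-kernel
density over that class's training depth vectors, with per-dimension
Scott's-rule bandwidths.  Two numerical guards matter:

* a class whose depth coordinate is numerically constant (every training
  curve far from some group) would collapse Scott's rule to a delta and
  zero out all densities; bandwidths are floored at 1e-3 of the pooled
  per-dimension spread;
* exact score ties (including the all-zero case) resolve to the stage with
  the largest training prevalence, then to the fixed order
  early < middle < late.  The same rule settles every majority-vote tie in
  the package.

Evaluation is leave-one-patient-out: the held-out patient's recordings
never enter the training groups, the bandwidths, or the depth vectors of
the training set.  Per window draw, the patient's label is the majority
over their curves; the final label is the majority over the (default 10)
draws.  The "xyz" mode concatenates the three per-axis windows into a
single vector before taking L2 distances; a joint three-axis depth is a
reasonable alternative reading, and concatenation is the documented choice.

## 5. Feature extraction

Per axis, raw samples are binned into half-open per-second bins (t−1, t]
(a sample at exactly t = 0 joins the first bin) with s_i = ⌈final⌉ bins,
and per-minute bins with m_i = ⌈final/60⌉ — e.g. a recording ending at
800.21 s has 801 second-bins and 14 minute-bins.  Bin-wise sum, median and
mean give three aggregate series per resolution; each series is summarised
by (sum, mean, median, min, max).  3 axes × 2 resolutions × 3 series × 5
statistics = 90 features, the classifier input width.  Empty bins
(possible under jitter) carry the previous bin's aggregates forward
(leading empties take the first non-empty bin's values); at 8 Hz they are
rare.

The kinematic block — cumulative trapezoidal integration of acceleration
to speed and again to displacement on the raw timestamp grid, then the
same 30-feature scheme per curve — extends the vector to 270 features.  It
is off by default: the 90-feature layout is the one anchored by the
network's input width, and the two published descriptions of the wider
layout are mutually inconsistent, so the package treats the kinematic
block as an opt-in extension.

Features are z-scored with training-side statistics only.

## 6. Stage classifiers

Splits are patient-grouped: shuffled patients move to the test side while
doing so strictly improves the recording-level test fraction's distance to
the target (default 0.2); every recording follows its patient; a split
leaving some stage absent from training is redrawn from a derived seed.

The network is feed-forward with logistic activations throughout, one bias
per layer, default 175 hidden neurons in one layer, trained full-batch by
Rprop+ (resilient backpropagation with weight backtracking; η⁺ = 1.2,
η⁻ = 0.5, Δ₀ = 0.1, Δmax = 50), stopping when the largest absolute
gradient drops below 0.01 or after 1000 iterations (non-convergence is
flagged, not fatal).  The default output encoding is a single logistic
unit with ordinal targets early = 0, middle = 0.5, late = 1 and decision
thresholds 0.25 / 0.75 — the simplest reading of a one-output network for
a three-stage problem; a three-unit one-hot variant with argmax decisions
is available (`output_mode="three_unit"`).

The layer sweep reads "layer setting" as hidden depth 1…11 with
~175 total neurons split equally across layers (depth-vs-width is
genuinely ambiguous; depth is the default and width is reachable through
`hidden_spec`).  Each setting trains 100 independently seeded networks
and records patient-level misclassification on the test side.  Baselines
(decision tree, random forest, SVM) use scikit-learn defaults with fixed
seeds and the same standardized features and patient-level vote.

## 7. Reproducibility

One master seed drives everything through derived, purpose-tagged streams
(`stagewalk._rng`): cohort generation, window draws per repetition,
projection directions, bootstrap resampling, splits, network
initialisation.  Reruns of `run_all` with the same config reproduce all
output tables byte-for-byte; every CSV carries the seed and a hash of the
scientific configuration.

## 8. Problem sizes used in the automated checks

Calibration and power checks in the test suite run on scaled-down
configurations chosen once for desk-scale turnaround: 200 simulated
datasets per calibration study (B = 199–499), 10–15 curves per group for
the bootstrap ANOVA checks, cohorts of 10–20 patients with 30–120 s
recordings for windowing/classifier checks, and 50 windowing repetitions
for power checks.  The acceptance study is 200 datasets × (2 × 20) curves
× 60-point grid × B = 499.  Full-scale settings (J = 1000, B = 999,
100 networks × 11 settings) remain the library defaults.

## 9. Known limitations

* The generator's stage effect enters the mean; procedures sensitive only
  to higher-order structure are exercised but not power-tested.
* The parametric projection F-test inherits its Gaussianity assumption;
  on non-Gaussian data its p-values are only approximate (the bootstrap
  tests do not share this caveat).
* Bootstrap p-values are discrete on {1/(B+1), …, 1}; with small B this
  granularity is visible in p-value histograms.
* `interpolate_to_seconds` trusts the recording's nominal time unit;
  timestamp gaps are not detected or imputed.
* Patient-level accuracy on 5–10 test patients is a coarse quantity; sweep
  distributions, not single rates, are the stable summary.
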