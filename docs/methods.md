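# Methods

## The measurement model

A specimen is a 4 mL cuvette of oil read by a TCS34725 RGBC sensor
(integration 24 ms, gain 1×) under either the sensor's white LED or a
395 nm UV LED. Ten raw readings are averaged channel-wise, then the
averaged R, G, B counts are divided by the averaged clear count C to give
the descriptors (r, g, b). Averaging precedes normalization; the
acquisition protocol lists them in that order, and normalizing first would
change nothing in the noiseless limit but weight noisy readings unequally.
Channel means are kept real-valued — rounding back to integer counts would
add quantization the sensor does not have. Descriptors are used unscaled:
they are already dimensionless ratios on a common scale, and autoscaling
three comparable channels would only amplify the least informative one.

## Synthetic data generator

The generator emulates the two study designs — 150 classification samples
(25 pure avocado + 5 adulterants × {5, 10, 20, 35, 50 %} × 5 replicates)
and 55-sample per-oil calibration series (0–50 % in 5 % steps × 5
replicates) — so the full pipeline is testable without the physical
device.

Each (oil, illuminant) pair has an endmember chromaticity, the (r, g, b)
triple of a pure oil. Blends interpolate between count-space linear mixing
and absorbance-domain (Beer–Lambert-like) mixing:

    c(f) = (1 − w)·[(1−f)·c_avo + f·c_adu] + w·exp((1−f)·ln c_avo + f·ln c_adu)

with `w = nonlinearity` clipped to [0, 1]. Defaults:

| parameter | default | meaning |
|---|---|---|
| `nonlinearity` | 1.0 | full absorbance-domain mixing; mildly curved in count space, so a kernel model has a genuine (but not contrived) edge over linear ones |
| `noise_sd` | 0.01 | relative SD of one raw reading; ~1 % is realistic for this sensor class at 24 ms integration. UV readings get 2× (weak LED, poorer photon statistics) |
| `clear_scale` | 2000 | clear-channel count magnitude |
| `n_readings_per_sample` | 10 | matches the acquisition protocol |

White-light endmembers are mutually distinct with avocado green-dominant
(chlorophyll) and olive nearest to it; the UV palette is deliberately
compressed, so UV models underperform white-light ones — the qualitative
ordering the hardware shows. `high_noise_config()` (noise_sd = 0.5) is a
deliberately degraded profile: with class separation washed out, an LDA
with empirical priors is dominated by the 84 % prior of the blended class
and collapses onto it, the documented failure mode of linear
discrimination on imbalanced overlapping data.

Per raw reading, the clear count and each channel fraction receive
independent multiplicative Gaussian noise; fractions are clipped to
[0, 1], so C ≥ max(R, G, B) holds reading-wise and survives averaging.
What the generator does **not** emulate: real oil optics and fluorescence
spectra, sensor drift, temperature effects, inter-supplier variability
within an oil type, or correlated channel noise. Passing tests therefore
demonstrate that the *pipeline* recovers structure of the assumed form at
realistic noise, not that the physical sensor separates real oils.

## Partitioning

Kennard–Stone on the pooled, unscaled (r, g, b) matrix: seed with the
maximum-distance pair, then greedily add the point maximizing the minimum
distance to the selected set. Ties break to the lowest row index, making
the split fully deterministic. Calibration size is round(fraction · n)
with ties away from zero (so 70 % of 55 → 39); an explicit size override
is available. No stratification: the split is of the dataset as a whole,
which is why test-set class shares drift from 84/16 (Kennard–Stone loads
extreme points — often pure-oil outliers — into calibration).

## Models

* **LDA**: pooled within-class covariance with divisor n − K, empirical
  priors, argmax of the usual linear discriminant score; ties go to the
  first class in order. A near-singular covariance receives a ridge of
  1e-8 · trace/d before fitting fails.
* **MLR**: OLS with intercept. A rank-deficient design is accepted only
  when the minimum-norm solution reproduces the target exactly — blends
  of a single oil pair are exactly collinear in feature space, yet
  perfectly described by a linear law; any other deficient design raises.
* **LS-SVM**: the (n+1)-dimensional dual system above, solved densely
  (n ≤ 105 throughout, so direct solves are exact and cheap). The first
  equation enforces Σα = 0; the solution is checked against that to 1e-8
  in tests. Multiclass uses one-vs-rest with shared (γ, σ²) and argmax of
  decision values; with exactly two classes the two machines are mirror
  images and the scheme reduces to the binary sign rule.

Tuning is an exhaustive grid search — γ ∈ {1e-1 … 1e4}, σ² ∈ {1e-3 … 1e2},
log-spaced — under 10-fold cross-validation on the calibration set only,
minimizing misclassification rate or RMSE. Folds are a deterministic
function of the grid seed and are stratified for classification so no fold
loses a class. Ties prefer the smallest γ (strongest regularization), then
the smallest σ².

## Validation

Per-class one-vs-rest confusion metrics with degenerate-denominator
conventions PRE = REC = F1S = 0 on empty denominators and MCC = 0 when a
marginal factor vanishes: a classifier that answers one class for
everything gets accuracy equal to the majority share but MCC 0, which is
the honest reading. ERR is computed as 100 − ACU, the exact complement.
"Overall" is the unweighted macro mean of the per-class rows.

R² is the squared Pearson correlation of actual and predicted; R0² is its
through-origin analogue computed from the fit of predicted on actual
(predicted on the ordinate — the dominant convention in the Rm²
literature; the axis choice is a config switch in `r0_squared` callers
since conventions differ). Rm² clamps a negative R² − R0² gap to zero;
cRp² clamps a negative radicand to zero with a warning, since a permuted
R² exceeding the calibration R² is itself the chance-correlation signal.

y-randomization refits the model on uniformly shuffled targets with the
**same protocol including hyperparameter re-tuning** (a config switch can
freeze the tuned pair instead), scores on the calibration samples, and
reports all scores and their mean. Default 100 permutations; experiment
runs in the test suite and the acceptance script use 2–25 permutations,
which is enough to locate the permuted mean. For a well-regularized model
on shuffled targets the calibration R² lands near d/(n−1) ≈ 0.08 for
n = 39, d = 3 — far below any real calibration R², hence cRp² > 0.5.

## Experiments

One Kennard–Stone split per experiment is shared by all models so linear
and kernel methods are compared on identical sets. Regression targets are
modelled on the percent scale (0–50), putting RMSE in percent-blend units.
Reports render as stage × metric × class grids with percent metrics at 1
decimal and unit ratios at 2; stored results keep full precision. An
`IndexAudit` records which dataset rows each stage materializes, so tests
can verify that tuning and y-randomization never touch test rows.

## Problem sizes and determinism

All pipelines are deterministic given (config, seed). The acceptance
script averages over 10 generator seeds derived from its `--seed`; its
stochastic quantities use the default designs (150 and 55 samples, the
sizes of the study itself). Dense linear algebra at these sizes keeps the
whole suite and the acceptance run in seconds.

## Known limitations

* The LS-SVM tuner is a plain grid search; it does not reproduce any
  particular toolbox's internal optimizer, so chosen (γ, σ²) are
  package-specific.
* Empirical-prior LDA is the only LDA variant; uniform priors would
  change the collapse behaviour and are intentionally not offered.
* The generator's endmember palette is a plausible invention, not a
  spectral measurement; absolute metric values on synthetic data should
  not be read as predictions for the physical device.
* No confidence intervals or ROC analysis; the validation framework
  reports the point statistics defined above.
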