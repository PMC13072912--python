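# Methods

`xrfquant` implements an end-to-end method study for quantifying trace
arsenic (and, with known limitations, lead) in rice-based foods by
benchtop energy-dispersive X-ray fluorescence (ED-XRF), using a small
feed-forward neural network to resolve the As Kα / Pb Lα spectral
overlap.  This note records the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic data can and
cannot demonstrate.

## The analytical problem

As Kα (10.52 keV) and Pb Lα (10.50 keV) are separated by 0.02 keV while a
silicon-drift detector resolves ≈ 0.135 keV FWHM at Mn Kα (≈ 0.18 keV at
10.5 keV).  The two principal lines therefore merge into one peak, and
univariate peak integration cannot attribute it to either element.  The
secondary lines (As Kβ 11.73 keV, Pb Lβ 12.62 keV) are spectrally clean
but weak: a Pb Lα emission is 1.61× more probable than Lβ, and K-shell
fluorescence yields exceed L-shell ones (ω = 0.549 for As K against
0.386 for Pb L), so at equal concentration As emits ≈ 1.42× more photons
at 10.5 keV than Pb does.  The calibration model learns the joint mapping
from two net-count windows — the overlap region 10.35–10.70 keV and the
Pb Lβ region 12.40–12.85 keV — to both concentrations simultaneously.

## Forward simulator

The raw spectra behind the published study are not publicly deposited, so
the package ships a physics-grounded simulator that generates every
dataset the pipeline consumes.

* **Lines.**  Gaussian peaks at the tabulated line energies with expected
  area `c · S · ω · branch`, where `c` is the element's total
  concentration (µg kg⁻¹) and `S` the detector sensitivity (counts per
  µg kg⁻¹ per unit emission weight at the 120 s acquisition).  Branch
  weights: Kα = Lα = 1, Pb Lβ = 1/1.61 (the stated Lα:Lβ probability
  ratio), As Kβ = 0.15 (a typical K-shell β/α ratio; the study gives
  none).  Pb K lines are omitted — a 50 kV tube cannot excite them.
  Peaks are integrated over channel bins (Gaussian CDF differences), so
  line areas are exact at any channel width.
* **Resolution.**  FWHM(E) = 0.135 · sqrt(E / 5.895) keV — the
  Fano-statistics square-root scaling of semiconductor detectors anchored
  at the instrument's quoted Mn Kα resolution.  At 10.5 keV this gives
  0.180 keV, an order of magnitude above the As Kα–Pb Lα separation, so
  the simulated overlap is genuinely unresolvable.
* **Continuum.**  A single exponential in energy,
  `A·exp(−λ(E − 10.5 keV))`, default A = 200 counts/channel and
  λ = 0.1 keV⁻¹: a smooth matrix-scatter background is all the two
  windows require; anode scatter peaks (~22 keV) lie far outside them.
  The instrument's background estimate is taken to be this continuum
  exactly (real instruments fit a smooth model; an exact one is the
  idealization of that).
* **Noise.**  Total counts are Poisson per channel; the background
  estimate stays noiseless.  Sub-seeds are derived per (standard, pellet,
  repeat) from the master seed, so any single spectrum is independently
  reproducible.
* **Sensitivity default (S = 20).**  Chosen so the lowest-As calibration
  matrix (87.8 µg kg⁻¹ intrinsic As) produces a peak-channel SNR of
  ≈ 3–4 over the continuum — a weak but identifiable peak, matching the
  qualitative description of the instrument's behaviour at that level.
  Absolute count rates are otherwise unconstrained by the published
  study, so S is a config parameter and simulated absolute counts are not
  comparable to real instrument exports.
* **Matrix effects** (absorption/enhancement, pellet geometry, drift) are
  not modelled: the study treats the rice matrix as fixed and corrects
  nothing beyond background subtraction.

**Study designs.**  The default calibration design holds 28 standards —
As-only and Pb-only ladders on the low-background Calrose unit
(intrinsic As 87.82, Pb 3.19 µg kg⁻¹) pinned to the concentration anchors
reported for the real standards (87.82…608.57 µg kg⁻¹ As,
3.19…586.27 µg kg⁻¹ Pb), plus As×Pb combinations on the second unit
(intrinsic As 137.37, Pb 4.26) — at 3 pellets × 3 repeats, i.e.
252 spectra.  The two detection-limit scenarios are 10 standards each at
total As 128.97 µg kg⁻¹, with Pb at the intrinsic level (scenario 1) or
208.95 µg kg⁻¹ (scenario 2).  The validation panel reproduces the
published ICP-MS concentrations: one certified reference material
(As 263.63, Pb 5.28), eleven commercial rice foods (As 56.84–296.72,
Pb ≤ 28.71), and four of those foods Pb-spiked at three levels each
(75.57–416.67 µg kg⁻¹ Pb), 24 standards in all.

## Calibration model

* **Features.**  Background-subtracted (net = total − background,
  deliberately *not* clamped at zero: clamping would bias exactly the
  low-signal windows the model must learn from) counts at every channel
  whose center lies inside a window (closed intervals).  On the default
  0.01 keV grid the two published windows give 36 + 46 = 82 features.
  The channel width of the real instrument is not published and no
  uniform width reproduces the reported feature count for these windows,
  so the width is a config parameter rather than a fitted constant.
* **Replicates unaveraged.**  All 9 spectra of a standard enter as
  separate rows sharing that standard's (As, Pb) targets, so the network
  trains on within-standard variability.
* **Network.**  Fully connected 82 → 256 → 128 → 2, ReLU, dropout
  p = 0.1 on hidden layers, full-batch Adam at learning rate 1e-5 for
  10,000 epochs, RMSE over both outputs jointly as the loss.  Every
  500 epochs the model is evaluated (dropout off) on an *external* test
  table — the simulated validation panel, mirroring the original
  protocol, never a random split of the training standards — and the
  state with the lowest test RMSE is kept (best-model checkpointing as
  early stopping).  The network is implemented directly in numpy so runs
  are bit-reproducible from one integer seed (fan-in uniform
  initialization, seeded dropout masks).
* **Standardization.**  Features are z-scaled per channel on training
  rows.  Targets are likewise z-scaled per element and the scaling is
  inverted at prediction time.  Target scaling is required for this
  optimizer configuration: Adam steps are bounded by ≈ the learning
  rate, so 10,000 epochs can move each weight by only ~0.1 — sufficient
  to fit unit-variance targets through a 128-unit output layer, but
  orders of magnitude short of reaching raw outputs of several hundred
  µg kg⁻¹.  Constant columns (e.g. Pb in an As-only ladder) pass through
  unscaled.
* **Outlier screen.**  One screen-and-retrain cycle: train on all
  standards, form per-standard residuals r = mean prediction − actual
  per element, compute z = r/σ_r with σ_r the sample SD (n−1) of the
  residual vector — the numerator is deliberately *not* mean-centered,
  a literal reading of the screening rule as stated, statistically
  unusual but reproduced as such — and drop standards with |z| > 2.5 on
  either element before the final fit.  The ledger records every
  screened standard with both z-scores.

  A caveat this package documents because the synthetic experiments
  expose it: residual screening presumes the preliminary model does not
  interpolate its training data.  A 54k-parameter network trained to
  convergence on 252 high-SNR rows can memorize even a grossly corrupted
  label whose concentration lies outside the test table's range (where
  checkpoint selection cannot penalize the memorization), driving that
  standard's residual into the noise band and defeating the screen.
  Outliers *inside* the test-covered range inflate test RMSE when
  memorized, so checkpointing keeps an earlier state and the screen
  catches them.

## Performance metrics

* **Calibration.**  R² = 1 − SS_res/SS_tot of per-standard mean
  predictions against actuals; SEC = sqrt(Σ(pred−actual)²/(N−1)) (the
  N−1 chemometrics convention); relative SEC = 100·SEC/working-range
  with the range an explicit argument (the published relative values
  imply a range inconsistent with the printed maxima, so no constant is
  hard-coded); slope/intercept by OLS of predicted on actual.
* **Detection limits** (Eurachem replicate approach, no true blanks):
  LOD = 3·s₀/√n, LOQ = k_Q·s₀/√n with s₀ the sample SD of the 10
  per-standard mean predictions of a scenario, k_Q = 10 (IUPAC default,
  10 % RSD), and n the number of observations averaged when reporting a
  result.  n defaults to 3: the published limit values are consistent
  with n = 3 (pellets), not the n = 9 spectra averaged elsewhere, so n
  is an explicit parameter.  LOQ/LOD = k_Q/3 identically.  Bias
  b = x̄ − x_actual.
* **Reference-method LOQ.**  10·σ_S/b from blank SD and calibration
  slope.
* **Validation agreement.**  ±20 % error (the regulatory verification
  threshold) per sample and element; when the actual concentration sits
  below the applicable LOQ the percent error is not quantitatively
  meaningful and only the absolute error (µg kg⁻¹) is reported — so
  intrinsic Pb in commercial foods is summarized in µg kg⁻¹ while
  Pb-spiked samples are summarized in percent.  Category summaries
  report mean and median absolute errors; the median of an even-count
  set is the mean of the two central values; errors are rounded for
  display only.

## Evaluation conventions on synthetic data

Held-out recovery is evaluated on a fresh replica of the 28-standard
design (same concentrations, new noise seed) rather than on the
validation panel, because an R² comparison *between elements* is only
meaningful when both span the same concentration range — the panel's As
(57–297) and Pb (0–417, mostly near zero) ranges differ by construction.
On matched ranges, As recovery is at least as good as Pb recovery,
consistent with the fluorescence-yield argument; the margin is small
because Poisson noise is the only error source the simulator models.

Passing results on this synthetic data demonstrate that the pipeline's
statistics, training loop and screening logic are implemented correctly
and that the method recovers concentrations under ideal counting
statistics.  They do not demonstrate real-instrument performance: real
rice spectra add pellet heterogeneity, matrix absorption, energy drift
and background-model error, which is why the published real-data
calibration (As R² = 0.92, SEC = 41.20 µg kg⁻¹) is far from the
near-perfect recovery seen here, and why Pb quantification that looks
easy on Poisson-only data was poor in practice.

## Numerical choices and degenerate inputs

* Window membership uses closed intervals on channel-center energies
  with a 1e-9-scaled tolerance, so window edges landing exactly on
  channel centers are included on any grid.
* Grid uniformity on file load is enforced to 1e-9 keV; spectrum CSVs
  are written with shortest-round-trip floats and parsed with
  round-trip precision, so write→load is lossless.
* Replicate SD uses divisor n−1 and is defined as 0 for a single
  observation.
* σ_r = 0 in the screen, an all-constant target matrix, an empty
  window, or a scenario file with ≠ 10 standards raise typed errors (the
  last one a warning), rather than producing silent nonsense.
* Training raises on non-finite loss; evaluation always includes the
  final epoch, so the checkpoint is never worse than the final state.

## Problem sizes

Default runs use the full study geometry: 28 × 9 = 252 calibration
spectra on a 401-channel grid (82 features), 10,000 training epochs,
10 × 9 spectra per limit scenario and 24 × 9 validation spectra.  One
full training takes on the order of a minute on a single CPU; the
complete simulate→calibrate→limits→validate pipeline runs in a few
minutes.

## Known limitations

* Only Poisson counting noise is simulated; all conclusions about
  real-world accuracy transfer qualitatively at best.
* The iterative spectral-window search that produced the published
  windows is not re-run; the windows are taken as given defaults.
* The outlier screen's blindness to interpolated outliers at full
  training length (above) is a property of the specified procedure, not
  of this implementation.
* No dead-time correction, energy recalibration, vendor-format parsing,
  speciation, or fundamental-parameter quantification.
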