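# Methods

## The generative model

Each simulated pear carries a latent flesh SSC per measured side, a
chlorophyll level, a diameter, and a peel temperature; each side yields one
reflectance spectrum on the fixed 1024-point grid between 432 and 1147 nm.

**Covariates.** Fruit-mean SSC is a truncated normal (mean 13 °Brix,
sd 1.725, truncated to [7, 19.1]); the sd is chosen so that ±2σ reproduces a
95% band of [9.5, 16.4]. Truncated normals are the simplest family matching
mean/range/±2σ summaries; no claim is made about higher moments. The two
sides of a fruit get SSC = fruit mean ± δ/2 with δ ~ N(0, 0.62²), so the
side-to-side difference has sd 0.62 °Brix. Optionally the *recorded* SSC
additionally carries refractometer/sampling noise
(`ssc_measurement_noise_sd`, default 0) that is absent from the spectrum;
this is the knob used by the noise-floor experiments, since it makes the
response noise — not the spectral noise — the binding error floor.
Chlorophyll is a latent z-score correlated with the SSC quantile at
ρ = −0.6 (riper fruit: less chlorophyll, more sugar), mapped to
1 + 0.35·z and clipped to [0, 2]; the correlation is configurable and
deliberately not deterministic, because ripeness-pigment coupling is an
association, not a law. Diameter is truncated normal on [43, 81] mm
(mean 60, sd 7). Temperature is a three-component mixture — chilled
(6 ± 1 °C, 25%), room (21 ± 3 °C, 50%), warm (35 ± 2 °C, 25%) — clipped to
[2, 40] °C.

**Spectra.** Absorbance is a smooth baseline (0.35 + 0.15·x, x the
normalized wavelength) plus Gaussian bands:

| band | center (nm) | width (nm) | amplitude | scales with |
|------|-------------|------------|-----------|-------------|
| chlorophyll | 680 | 40 | 0.090 | chl latent |
| sugar overtones | 755, 840, 920, 975, 1100 | 25–28 | 0.0038–0.0045 AU/°Brix | SSC |
| water background | 970, 1140 | 55, 90 | 0.12, 0.15 | fixed |

Sugar amplitudes are sized so the SSC-driven absorbance variance at a band
center is roughly ten times the additive noise floor, and so that the
worst-case spectra (SSC 19.1, chl 2, extreme temperatures) stay inside the
[−0.2, 0.2] interval after the per-variant SVR scaling (see below). Band
positions follow the O-H/C-H third/fourth-overtone region; widths are wider
than gas-phase lines because tissue spectra are heavily broadened.

Temperature acts only on the vibrational (sugar/water) bands: centers shift
by 0.15 nm/°C relative to 20 °C, widths broaden by 0.4%/°C of |T − 20|, and
the sugar absorptivity drifts by 0.4%/°C of (T − 20). The last term makes
the spectrum→SSC slope itself temperature-dependent; without it a measured
peel temperature adds no information beyond the spectrum, because any
band-shift confound spans a low-dimensional subspace that a linear model
removes from the spectral channels alone. With it, augmented models
(especially nonlinear ones) measurably improve RMSEP, and the improvement
vanishes when the temperature effect is switched off — the behaviour the
benchmark is designed to probe.

Reflectance is 10^(−A), multiplied by a size-dependent scatter factor
1 + 0.004·(diameter − 60 mm) (variable illumination geometry), plus
additive Gaussian detector noise (sd 0.002, reflectance units), clipped to
(0, 1]. Chronological structure: fruits are assigned to five equal
acquisition blocks A–E in order; D–E get +0.3 °Brix (harvest-season
offset) and a small absorbance baseline tilt, and the later half of E draws
diameters from a bimodal extreme-size mixture. Fruits below 42 mm are
removed by the small-fruit filter before analysis.

**What the generator does not emulate:** instrument line-shape and stray
light, detector nonlinearity and wavelength-dependent noise, peel/flesh
layering and sub-surface scattering path physics, real covariance between
ripeness, size and season, and the heavy overlap of real sugar signatures
beneath water. Passing tests therefore demonstrate correctness and the
*direction* of effects (drift hurts external validation, augmentation helps
when temperature perturbs spectra, selection removes noise wavelengths) —
not absolute real-world error levels, which on real instruments are several
times higher.

## Preprocessing

Pipeline order is fixed: log10(1/R) → optional Savitzky-Golay derivative
(window 51 points, polynomial degree 2, derivative per unit detector index —
the grid pitch is treated as uniform, matching a fixed-pitch array) → trim
75 points per edge (874 channels, ≈ 500–1100 nm) → optional restriction to
λ ≥ 730 nm → optional SNV → optional append temperature and size.

SNV uses the population (n) standard deviation and is computed per spectrum
over the *retained* spectral channels only: for the noChl variants the
restriction precedes SNV so the normalization statistics never see the
highly variable chlorophyll region, and augmented columns never enter SNV
or the derivative. SNV of absorbance is exactly invariant to a
multiplicative reflectance factor (it becomes an additive offset under the
log), which is the scatter mechanism the generator implements.

SVR input scaling follows fixed per-variant scalars (absorbance ÷ 10,
1st derivative × 100, 2nd derivative × 1000); temperature and size are
centered on their calibration means and divided by 100. Centering constants
are stored at fit time and reused verbatim for validation samples.

## Wrapper wavelength selection

For each #LV from 1 to max_lv (default 25, the most ever needed in
practice), wavelengths are eliminated one at a time — always the one with
the smallest |PLS regression coefficient| — and the 5-fold RMSECV is
recorded after every removal, down to #LV features. The fold partition is
seeded once and shared across the whole (#LV × removals) surface so cells
are comparable. The ranking is recomputed after every refit by default; a
fixed-per-#LV ranking mode exists as a cheaper option. Ties in |coefficient|
remove the lower wavelength index first (stable sort); exact ties in the
RMSECV minimum resolve to the most features removed, then the fewest latent
variables (parsimony). RMSECV is always in °Brix on the original response
scale. Augmented columns participate in every fit but are never ranked or
removed. Zero-variance columns are excluded from the PLS fit and ranked
least important. Temperature/size-augmented data types reuse the selection
of their non-augmented twin (the spectral features are the same).

## Calibration engines

**PLS** — scikit-learn's NIPALS implementation at the #LV chosen by the
wrapper; RMSEC is a seeded 10-fold cross-validated RMSE, which is a more
honest calibration error than the in-sample residual.

**MLR** — least squares with intercept; RMSEC likewise 10-fold CV. The fit
refuses problems with n_samples ≤ n_features or a rank-deficient design
(raising an explicit "not applicable" error that the benchmark records as a
skipped cell rather than silencing), mirroring how small calibration sets
must be excluded rather than overfit.

**SVR (RBF)** — analytic seeding: C_th = max(|ȳ + 3σ_y|, |ȳ − 3σ_y|);
the noise level for ε comes from the in-sample MSE of a k-nearest-neighbour
regressor (k = 5) with the small-sample correction n^{1/5}k/(n^{1/5}k − 1),
giving ε_th = 3σ̂√(ln n / n), floored at 10⁻⁴ for noiseless data; γ_th
maximizes the variance of off-diagonal RBF kernel entries over 25
log-spaced candidates in [10⁻⁴, 10²], estimated on ≤ 500 random row pairs.
Refinement does three coordinate passes in the order ε → C → γ (the order
is not prescribed by the seeding scheme; noise first, then regularization,
then kernel width). Each pass draws 30 uniform candidates from
[0.001·P_th, 3·P_th] around the *theoretical* value and keeps the 5-fold-CV
RMSE minimizer; the incumbent is always evaluated alongside the candidates,
so the final model never does worse than the theoretical-parameter model on
the shared folds. RMSEC is the best CV RMSE of the final pass.

**MLP** — one hidden layer of ⌈p/3⌉ ReLU units, Adam (learning rate 10⁻³,
batch 16), at most 300 epochs with early stopping on a 20% internal test
split (patience 20 epochs) and L2 weight decay α = 0.03. The weight decay
matters: spectral inputs are near-collinear and the signal near-linear, and
an unregularized net stalls well above the response-noise floor; pulling
the weights toward the smooth (near-linear) solution closes that gap.
Inputs are standardized and the response min-max normalized with
calibration statistics stored on the model; a constant response
short-circuits to a constant predictor. Predictions (not weights) are
averaged over n_repeats independently seeded fits — 10 at full fidelity, 3
in the fast configuration — and reported in °Brix; RMSEC is the mean over
repeats of each network's calibration RMSE. A non-finite fit is discarded
and restarted on the next derived seed.

## Validation and metrics

Internal splits shuffle *fruits* (both sides travel together) before the
80/20 partition: the two sides of one pear are near-duplicate spectra, and
sample-level splitting leaks them across the partition, inflating internal
optimism. A `by_fruit=False` flag restores literal sample-level splitting
for fidelity comparisons. External validation holds out each chronological
subset A–E in turn with no shuffling. The "Small" set is the first 150
chronological fruits with room temperature (15–27 °C) and mid-range
diameter (52–68 mm) — a one-instrument-week style uniform subset.

R² is reported two ways: the squared Pearson correlation between observed
and predicted (headline, `r2`) and the 1 − SSE/SST score (`r2_score`).
SDR and PG use the population standard deviation, which is what makes
PG = SDR exact when calibration and validation means coincide; a zero RMSEP
flags PG/SDR as infinite with a warning rather than failing. The EV*
summary is the arithmetic mean of each metric over the five rotations plus
the population sd of RMSEP (an error-bar summary); mean-of-rotations (not
pooled) R² is used and labeled as such.

## Benchmark scale and determinism

All seeds derive deterministically from one master seed (per-stage CRC-keyed
seed sequences), so a rerun reproduces the dataset, masks, hyperparameters
and summary tables exactly. Feature selection runs once per (data-type
base, calibration partition) and is cached.

The one-wavelength-at-a-time wrapper is O(max_lv × p²) PLS fits per
partition, which at p = 874 is millions of fits across the factorial grid.
The benchmark therefore exposes scale knobs with fast defaults:
`feature_stride` (default 8) subsamples the spectral grid before selection
— spectra are heavily collinear, so an ~110-channel grid retains the
information while cutting the wrapper cost ~64-fold — plus `max_lv`
(default 15) and `mlp_repeats` (default 3). Full fidelity is stride 1,
max_lv 25, 10 repeats. The test suite and the acceptance script use strides
16–64 with populations of 60–600 fruits (120–1200 spectra) and a
1650-fruit population for the heterogeneity statistics; these sizes were
chosen so the whole pipeline runs comfortably on a single core while
keeping every assertion's Monte-Carlo error well inside its tolerance.

Degenerate inputs are handled explicitly rather than silently: empty
datasets after filtering, constant spectra under SNV, zero response
variance for SVR seeding, identical rows (zero kernel variance) for γ,
rank-deficient MLR designs, and per-cell failures inside the benchmark are
recorded with a reason while the run continues.

## Known limitations

* The generator's band model is phenomenological; absolute RMSEP levels are
  optimistic relative to real instruments and should only be read
  comparatively.
* The wrapper's elimination path is greedy; it matches exhaustive
  enumeration over its own path (tested), not a global subset search.
* The SVR randomized search with 30 candidates per coordinate has visible
  seed-to-seed variance; the incumbent guarantee bounds it below the
  theoretical-parameter model but not below other draws.
* MLR inherits the wrapper's PLS-optimized mask, which is not tailored to
  least squares; this mirrors a pipeline designed once and applied to all
  engines.
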