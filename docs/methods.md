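# Methods

This note records the models, conventions and numerical choices behind
`filmdose`, and what the synthetic test conditions do and do not establish
about real films.

## Film response model

A scanned film pixel carries an integer value PV per color channel
(k-bit, typically k = 16 at 48-bit color depth).  Transmittance and optical
density are

    T = PV / (2^k - 1),        OD = -log10 T.

Dead pixels (PV = 0) are clamped to one count before the logarithm, so
defects appear as localized noise rather than infinities.

The dose-induced response of a film piece is the net change between the
pre- and post-irradiation scans, `netT = T_f - T_i` and
`netOD = OD_f - OD_i`, computed literally (negative netT for darkening
film; the calibration parameters absorb the sign).  ROI statistics use the
population standard deviation — ROIs hold thousands of pixels, and the
fixed convention keeps test values exact.  First-order propagation gives

    sigma_netOD = (1/ln 10) sqrt((sPV_f/PV_f)^2 + (sPV_i/PV_i)^2)
    sigma_netT  = sqrt(sPV_f^2 + sPV_i^2) / (2^k - 1)

both validated against 1e5-draw Monte-Carlo simulation (≤ 5% relative for
relative PV scatter up to 5%; the log-linearization starts to bias above
that).  Replicate films at the same dose are combined by inverse-variance
weighting, `w_i ∝ 1/sigma_i²`, with combined uncertainty
`sqrt(1/Σ sigma_i^-2)` — the minimum-variance unbiased combination, and the
unique choice consistent with those weights.

## Calibration

Two families, both written as dose versus net response:

* rational: `D = A·netT / (1 - B·netT)`, 2 parameters — monotone on
  netT ∈ (-1, 0] for A < 0, B > 0 and invertible in closed form,
  `netT = D/(A + B·D)`;
* power polynomial: `D = A·netOD + B·netOD^n`, 3 parameters; `n` is fitted
  as a free real exponent by default and can be fixed.

Fits use Levenberg–Marquardt on dose residuals.  Response uncertainties
enter as dose weights after projection through the local slope,
`sigma_D = |dD/dr|·sigma_r`, with the slope taken from a first unweighted
pass; if all sigmas are zero the fit is unweighted.  Rational starting
values come from an exact two-point solve on the extreme nonzero-dose
points; polynomial starts from the low-dose linear slope and a log-log
residual fit for the exponent.  A fit that does not converge raises — it is
never returned silently.  The default calibration range is 0–10 Gy
(configurable within the 0.5–20 Gy applicability window).  Model inversion
outside the rational closed form brackets the root and polishes with Brent
iteration to |ΔD| < 1e-9 Gy; the vectorized variant used by the generator
interpolates a dense monotone lookup table and applies two Newton steps.

The uncertainty interpretation matters for the weighting invariant: equal
*response* sigmas do not give equal dose weights when the slope varies, so
the meaningful reduction is that equal *projected* weights reproduce the
unweighted fit, and that uniform sigma rescaling leaves the estimate
unchanged (both tested).

## Multichannel reconstruction

Each channel predicts a dose `D_i(t) = f_i(OD_i · t)` where the scalar `t`
rescales that pixel's measured optical density.  A dose-independent
disturbance (film thickness variation, scanner shading, dust) multiplies
the measured OD of all channels equally, so the value

    t_min = argmin_t g(t),   g(t) = Σ_{i<j} (D_i(t) - D_j(t))²

that brings the three channel doses into agreement removes it; the t-map
images the disturbances.  Conventions:

* the scaling applies to the *total* measured post-scan OD; a pre-scan
  film reference is scaled too (same disturbance assumption), a scalar
  reference is trusted disturbance-free and left unscaled.  For netT
  models the transmittance is recomputed from the scaled OD.  With this
  convention a uniform injected OD scaling `s` is recovered exactly as
  `t = 1/s`;
* the unordered pair sum (3 terms) is used — the full ordered sum is
  exactly twice it with the same argmin;
* Newton–Raphson on `g'(t)` starts at `t0 = 1`, at most 100 iterations,
  step tolerance 1e-6, with analytic first and second derivatives for both
  model families (chain rule through the response scaling).  Analytic
  derivatives everywhere are strictly more accurate than a
  finite-difference fallback and both families differentiate in closed
  form.  A pixel whose curvature is non-convex or whose iterate leaves
  t ∈ [0.5, 1.5] falls back to an 80-iteration golden-section search on
  that interval; a minimum landing on the interval edge (no interior
  minimum) is flagged non-converged and filled with the red-channel
  single-channel dose — never silently interpolated.  A stationarity
  floor (|g'| below float precision of the implied step) accepts exactly
  consistent pixels at `t = 1` without iterating;
* the reported dose is the arithmetic mean of the three channel doses at
  `t_min`, clamped at zero.

The optimizer is verified against a dense 1e-4-step grid search of `g`.

**Limitation — noise amplification.**  The variance-reduction property of
the multichannel method applies to *common-mode* OD disturbances.  For
*uncorrelated* per-channel pixel noise the error propagates through the
channel-slope differences: `δt ≈ -Σ(ε_i-ε_j)(s_i-s_j) / Σ(s_i-s_j)²` with
`s_i = dD_i/dt`, and the common dose moves by `s̄·δt`.  With the default
fixture sensitivities this amplifies independent channel noise several-fold
once the PV noise fraction exceeds ≈ 0.1%.  On real films the dominant
artifact is the spatially smooth non-homogeneity the method is built for;
the synthetic variance test therefore uses the disturbance field (plus
quantization) as its noise model.

## Registration

The planned map, resampled to the film's pixel spacing, is slid over the
dose-converted film; each placement scores the normalized cross-correlation
with the template's global mean and the *local* window mean, making the
match invariant to affine intensity changes.  The map is computed by exact
row-chunked sliding-window evaluation (no FFT), so it equals the literal
double-loop definition to float precision; `skimage.feature.match_template`
serves as an independent cross-check in the tests.  Zero-variance windows
score 0 (uniform background is a legitimate candidate); a zero-variance
template is an error.

A small-angle sweep (default 0, ±1, ±2, ±3°) absorbs scanner-bed
misalignment: the template is rotated bilinearly about its center,
out-of-bounds corners filled with the template border mean (intensity-
neutral for the NCC at small angles).  Ties break toward the smaller
|angle|, then the smaller row, then column — fully deterministic.
Matching runs in dose space: after calibration the film and plan
intensities are commensurate, which a raw-PV comparison would not be.
Scanner-orientation pre-processing (vertical flip then 180° rotation,
together a horizontal mirror) defaults on and is individually togglable;
manual fiducial-based alignment is supported as an explicit offset/angle
override, not auto-detected.

## Gamma analysis

For each reference (plan) pixel above the low-dose threshold,

    gamma(r_c) = min_{r_m} sqrt(|r_c - r_m|²/DTA² + (D_ref(r_c) - D_meas(r_m))²/ΔD_norm²)

over measured pixels within `search_radius_factor × DTA` (default 3×); the
zero-displacement candidate is always included so every evaluated pixel
gets a finite value.  `ΔD_norm` is DD% of the reference maximum (global),
DD% of the local reference dose (local), or a fixed dose in Gy (absolute).
Defaults are 3%/3 mm, global, 5% threshold.  Evaluation is discrete at
pixel centers — no sub-pixel interpolation inside the minimization; finer
agreement is obtained by resampling the measured map first.  A pixel passes
at gamma ≤ 1 (inclusive), and the pass rate counts evaluated pixels only.
The radius-limited search is verified equal to an exhaustive unlimited
double-loop evaluation whenever the radius covers the map; relaxing DD or
DTA provably never lowers a pixel's pass status (tested).

## Synthetic study conditions

The generator renders a planned dose map as a film scan by inverting the
calibration law per channel, adding the base OD of unexposed film
(default 0.05 per channel), applying a smooth multiplicative disturbance,
and quantizing `PV = round((2^16-1)·T)` with round-half-even (deterministic
across platforms).  Fixture calibration truths are package constants chosen
once: rational netT models with (A, B) = (-30, 0.2), (-45, 0.3), (-70, 0.4)
for R, G, B — red steepest at low dose, mirroring the sensitivity ordering
of EBT-type film — monotone over the full 0–20 Gy range with the pole well
outside it.  Noise mechanisms:

* Gaussian PV noise, as a fraction of the local pixel value;
* salt spikes (isolated full-scale pixels) at a given probability;
* a quadratic-surface OD multiplier with a set peak deviation — smooth and
  dose-independent, matching the multichannel model's assumption.

Phantoms: a uniform square with logistic penumbra `D·S(x)·S(y)`,
`S(u) = expit((L/2 - |u|)/s)` (its integral has the closed form
`2s·ln(1+e^{L/2s})` per axis, used as a test oracle), and a stacked-square
pyramid whose nested levels add dose increments so the innermost plateau
carries the last level dose.  Registration cases embed the (optionally
rotated) plan into a larger zero-dose canvas at a known offset.  All
generators are bit-reproducible from their seed.

What the generator does **not** emulate: the lateral-response artifact of
flatbed optics, scanner-lamp polarization and orientation effects, film
batch and temperature dependence, post-irradiation darkening kinetics, or
realistic TPS fluence (an IMRT plan is stood in for by the pyramid).
Passing tests demonstrate the correctness of the algorithms under the
stated noise model, not the dosimetric accuracy of any physical film
protocol.

## Problem sizes and tolerances

Test and acceptance runs use deliberately small grids so the whole suite
executes in seconds: 16×16 maps for oracle-equivalence checks (50 pairs),
50×50 films for variance properties, a 60 mm square / 2 mm grid for
end-to-end runs, 20 seeds for stochastic recovery claims, 1e5 draws for
Monte-Carlo validation.  Key tolerances: gamma and NCC oracle equivalence
1e-10; optimizer-versus-grid 1e-4 (the grid step); noise-free fit recovery
1e-6 relative (rational) / 1e-4 (free-exponent polynomial, a flatter
objective); noisy fit recovery within 3 estimated sigmas; DICOM dose
round-trip within half the dose-grid scaling (16-bit storage scaled to the
map maximum); reconstruction round-trip within the PV quantization bound
`|dD/dr|·0.5/(2^16-1)`.
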