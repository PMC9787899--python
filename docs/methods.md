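# Methods

This note documents the models, the processing conventions, the synthetic
data generator, and the numerical choices made where the design was
genuinely open. Nothing here states a result the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal processing

Vertical force (Newtons, nominally 1000 Hz) is low-pass filtered with a
4th-order Butterworth at 60 Hz and normalized to body weight (xBW). Stance
phases are maximal runs of samples *strictly above* 20 N ("above 20 N" is
read as a strict inequality; a sample at exactly 20 N is ground contact
noise, not stance). Runs shorter than 80 ms are discarded as bounces — no
published value exists for this guard, and 80 ms is far below any plausible
running stance (~200–300 ms); it is configurable.

Microphone audio (nominally 44.1 kHz, linear amplitude) is polyphase-
resampled to 20 kHz, band-pass filtered with a 1st-order Butterworth over
5 Hz–20 kHz, full-wave rectified, and low-pass filtered at 200 Hz into a
linear envelope. Two details deserve note:

* at a 20 kHz working rate the 20 kHz upper band edge sits at Nyquist, so
  the band-pass degenerates to a 5 Hz high-pass; the implementation applies
  exactly that and logs it;
* the envelope low-pass order is unspecified in common practice write-ups;
  a 4th-order Butterworth (the biomechanics default) is used and is
  configurable.

All low-pass stages run forward–backward (zero phase) so that event timing
is not lagged; this matters because envelopes are cropped to stance windows
defined on the force channel (the two streams share an acquisition
trigger). Envelopes are computed on linear amplitude; a decibel conversion
switch exists in the config but is off by default, because the envelope is
fed to a linear-Gaussian model for which a monotone log compression changes
the meaning of the Fourier coefficients.

Foot contact angle (FCA, degrees) classifies strike style with closed outer
boundaries: rearfoot at FCA ≥ 8°, forefoot at FCA ≤ −1.6°, midfoot between.

## Fourier representation

Both vGRF and envelope curves are fitted with K = 15 harmonics plus a
constant (31 real coefficients) by linear least squares on the curve's own
sample grid. "15 terms" could also be read as 15 total coefficients (K = 7);
K is a parameter, and 15 harmonics is the default because the sharp impact
peak of a rearfoot curve needs the extra bandwidth. Least squares rather
than FFT-bin extraction keeps the fit well-defined on non-uniform or cropped
grids; the two coincide on uniform grids. Coefficients describe shape over
normalized time; the stance duration is carried separately and also serves
as a scalar predictor. Coefficient vectors are ordered (a₀, a₁..a_K,
b₁..b_K) — an arbitrary but fixed serialization convention.

## Conditional predictor

Training footsteps are stacked as joint vectors [per-mic envelope
coefficients ‖ mass, speed, stance time ‖ vGRF coefficients]. Dimensions are
standardized (variance floor 1e−12 guards constants — kg, m/s and
coefficient units are not commensurate otherwise), centered, and rotated by
SVD; principal components are retained to 99% cumulative explained variance
(configurable; no published component count exists).

Prediction solves the equality-constrained convex QP

    min_c  cᵀ Λ⁻¹ c    s.t.    W_pᵀ c = (x − μ_p) / s_p

via the substitution d = Λ^{-1/2} c, which turns the problem into a
minimum-norm least-squares solve (SVD). Two regimes follow from one code
path:

* enough components (predictor covariance full rank): the constraint is met
  exactly and the solution *is* the Gaussian conditional mean
  μ_y + Σ_yx Σ_xx⁻¹ (x − μ_x) — verified against that closed form to 1e−6
  on random joint Gaussians in the test suite;
* fewer components than predictor dimensions (typical for small training
  sets): the constraints are infeasible and are satisfied in variance-
  weighted least squares, i.e. the observed sound is projected onto the
  retained subspace before conditioning. An alternative `gaussian` method
  (conditional mean of the reconstructed low-rank covariance with a 1e−8
  Tikhonov ridge) is provided; `subspace` is the default.

The predicted coefficient vector is evaluated on a 101-point grid
(0–100% stance, the conventional normalization; no published grid exists)
using the trial's *measured* stance time — estimating stance time from the
sound alone is out of scope. LOSO evaluation refits the model per held-out
runner; a leakage test asserts that a held-out runner's predictions are
bit-identical under arbitrary corruption of that runner's force
coefficients.

## Biomechanical variables

* **Impact peak**: largest strict local maximum within the first 50 ms.
* **Deflection point** (peakless curves): for candidate times t on a 1 ms
  grid in [10, 100] ms, the signed turning angle between the 15 ms chords
  ending and starting at t is measured in a plane with time scaled ×100 (so
  a 15 ms step and typical xBW force changes have comparable magnitude —
  the aspect ratio changes angle *values* but not the argmin for
  single-kink curves; it is configurable). The most negative angle wins.
  Because the backward chord needs 15 ms of history, the effective window
  is [15, 100] ms. A curve with no concave turn returns none.
* **Loading rates** (xBW/s): LR‑1 = F(t_ip)/t_ip; LR‑2 = 0.6·F(t_ip) /
  (t₈₀ − t₂₀) with crossing times linearly interpolated; LR‑3 =
  least-squares slope over [0, 50] ms (an endpoint-difference variant is
  available; least squares is the default as the more robust reading of
  "slope within the first 50 ms"). On any affine curve the three coincide
  exactly, which the tests assert.
* **Vertical impulse**: trapezoidal area under the curve, reported both in
  xBW·s (≈ 0.3 for typical running) and integrated over percent-stance
  units (≈ 110–120). Published tables print impulse values near 108 with a
  nominal unit of xBW/s, which is dimensionally inconsistent with a
  time-integral; both conventions are therefore reported and neither is
  privileged.
* **Style from vGRF**: rearfoot iff the first 50 ms contain a local maximum
  with topographic prominence ≥ 0.05 xBW. "Prominent" has no published
  quantification; 0.05 xBW (~4% of a typical impact peak) suppresses
  filter/reconstruction ripple without masking true peaks, and is
  configurable.

Group statistics: paired t with Cohen's d computed against the SD pooled
across the two conditions (this scaling, not the difference-SD, matches the
magnitude of published effect sizes; the difference-SD variant is a config
option), one-way repeated-measures ANOVA (statsmodels, no sphericity
correction), and a 95% normal-approximation CI for means (z = 1.96, which
reproduces the published 68–86% interval for 77 ± 27% over 37 runners).
rRMSE is normalized by the *range* of the real curve (rRMSE has no single
published definition; peak normalization is available via config). The
correlation-strength taxonomy (low/moderate/strong) leaves |r| ≤ 0.1 and
0.3 < |r| ≤ 0.4 undefined; such values are reported `unclassified`.

## Synthetic cohort generator

The study's recordings are available only on request, so all quantitative
validation runs on synthetic cohorts with known ground truth. Defaults
reproduce the published cohort statistics: 37 runners, 48 ± 8 footsteps
each, 78% rearfoot strikers, mass 77 ± 11 kg, speed 2.75 ± 0.33 m/s, impact
peak 1.51 ± 0.20 xBW at 13.51 ± 0.71% stance, active peak 2.32 ± 0.17 xBW
at 42.33 ± 2.41% stance. Stance time is 0.25 ± 0.02 s (no published value;
200–300 ms is the accepted range for recreational running speeds). FCA
values are drawn consistently with the classification thresholds, with
non-rearfoot runners split midfoot:forefoot 21:9 to mirror the published
step-level fractions.

A vGRF curve is a shape-preserving piecewise cubic (PCHIP) through explicit
knots — monotone rise from zero, impact peak, valley (15% of the impact
force deep, keeping the peak prominent), active peak, monotone fall to zero.
Peaks sit exactly on knots, so detector closure is testable: on noise-free
rearfoot curves the extractors recover peak magnitudes within 1% and times
within 0.5% stance, and forefoot curves yield no impact peak by
construction.

Envelopes follow a known noisy mapping, motivated by louder footfalls under
sharper loading: gain × (0.02·|dF/dt| convolved with a 10 ms exponential
decay + 0.5·F), times smooth multiplicative log-normal noise (σ = 0.08),
with per-subject log-normal gain multipliers (σ = 0.15) as random effects so
LOSO is genuinely harder than trial-level splits. Raw-file rendering
synthesizes a 1 kHz tone amplitude-modulated by the envelope (scaled by π/2
so the rectified-sine mean reproduces the envelope), letting the full
preprocessing chain run end to end.

What the generator does **not** emulate: room acoustics and reverberation,
surface/shoe material, inter-microphone timing differences, non-stationary
background noise, and within-stance shape variation beyond the two-peak
family (e.g. mid-stance plateaus). The synthetic sound–force link is also
far more deterministic than reality. Passing LOSO tests therefore
demonstrate that the estimator correctly exploits a sound–force coupling of
this strength under subject heterogeneity — they do not certify accuracy on
real recordings, where the published experience (mean r ≈ 0.99, rRMSE
≈ 10%, style accuracy ≈ 77%) remains the reference point. Consistent with
that, the synthetic forefoot curves lack the early slope change real
forefoot strikes often show, so the deflection scan tends to return the top
of its search window on them.

## Problem sizes and numerical details

* Acceptance-level checks run at the study scale: 37 runners × ~48
  footsteps (~1800 trials), all-microphone LOSO. Unit-level tests use
  8–12-runner cohorts.
* The conditional-mean oracle test uses 100 random full-rank Gaussians of
  dimension 3–10 at tolerance 1e−6; Fourier round-trip exactness is
  asserted at 1e−8 on band-limited curves.
* Degenerate inputs: zero-variance curve pairs report Pearson r as missing
  (NaN); zero-variance paired differences report t = 0, p = 1; identical
  RM-ANOVA conditions report F = 0, p = 1; active-peak ties resolve to the
  earliest sample; missing LR‑2 crossings are reported as missing rather
  than extrapolated.
* Determinism: cohorts, preprocessing and experiments are reproducible
  byte-for-byte from (config, seed); the CLI writes manifests with config
  hashes and per-stage counts.

## Known limitations

* Stance time is taken from the force channel (or the generator); a
  sound-only deployment would need to estimate it acoustically.
* The predictor is affine in the predictor vector by construction; genuinely
  nonlinear sound–force relationships would require a different model
  class.
* `preprocess` assumes force and audio share a start trigger; arbitrary
  clock offsets are not estimated.
* The impulse unit ambiguity above means published impulse magnitudes can
  only be compared against the percent-stance-integrated variant.
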