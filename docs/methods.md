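# Methods

`insolegrf` reimplements, against synthetic ground truth, a complete
validation pipeline for a two-sensor (hindfoot + forefoot) piezoresistive
insole pressure sensor (IPS) measured against a force plate (FP): signal
conditioning, clock synchronization, two-stage calibration, Bland–Altman
agreement under stratified cross-validation, and a Monte-Carlo simulation
of overload detection during partial weight bearing (PWB). This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic data can and cannot show.

## Synthetic data model

**Subjects.** Body mass is drawn from Normal(75.2, 18.2²) kg (clipped to
45–120 kg), matching the recruited cohort of the kind of treadmill study
the pipeline targets; seven subjects form the default cohort. Each
subject carries a foot area (Normal(36, 5²) cm², metadata only), two
sensor models, per-region *coverage* fractions (U(0.65, 0.95)) — the part
of the regional force the sensor actually captures — and a *midfoot
share* m ~ U(0.05, 0.18), the fraction of stance force routed through the
unsensed midfoot. The midfoot share is kept in the anatomical-arch range;
it also pins the ground-truth total-force coefficients (below) inside the
plausible range for this sensor configuration.

**Gait waveform.** Each stance phase is built from two squared-cosine
lobes centered at 25% and 75% of stance plus a mid-stance valley bump.
On each half of stance the three terms collapse algebraically to
`v + (p − v)·cos²`, so the configured peak heights (defaults 110 and
105 %BW) and valley (75 %BW) are attained *exactly*, the waveform is
monotone between its extrema, and the curvature around each peak is
locally symmetric. That symmetry is deliberate: a symmetric peak does not
shift in time under symmetric smoothing filters, which keeps the
downstream peak-time bookkeeping honest. Cycle duration is
`1.1/√speed` s with stance occupying 64% of the cycle; per-cycle peak
heights and durations vary with 1.5% and 2% coefficients of variation.
Heel-strike ground truth is defined as the analytic time at which the
resultant first exceeds 20 N — the same definition the FP event detector
uses — and is returned by the generator.

**Regional decomposition.** Within every contiguous loaded span the
hindfoot carries the full sensed share `1 − m` until 40% of the span,
hands over to the forefoot through a cosine transition, and the forefoot
carries the full sensed share from 60% on; the midfoot share m is
constant. The three regions sum to the input at every sample by
construction. The handover window (40–60%) is kept clear of both force
peaks so each sensed channel is locally symmetric around its own peak.

**Sensor law.** Conductance is affine-quadratic in applied force:

    1/R(F) = 1/R0 + g1·F + g2·F²,   R(0) = R0,

strictly decreasing in force and invertible in closed form (the
rationalized quadratic root, stable as g2 → 0). The inverse map F(G) is
*close to but not exactly* a quadratic polynomial in G = 1/R, so the
second-order calibration fits well without being trivially exact.
Defaults: R0 ~ U(1500, 2500) Ω, g1 ~ U(6·10⁻⁶, 1.2·10⁻⁵) Ω⁻¹N⁻¹,
g2 ~ U(5·10⁻¹⁰, 2.5·10⁻⁹) Ω⁻¹N⁻². With these values the quadratic
calibration's noiseless approximation error stays below 2 %BW over the
0-to-body-weight range (g2 is the sole source of that misfit). Additive
baseline drift is linear at 0.5 Ω/s; per-trial baseline zeroing removes
its mean effect, and the residual slope maps to < 0.1 %BW because the
force–resistance gain is small near baseline. Resistance noise is
additive white Gaussian with SD 2.5 Ω (ADC-quantization scale). The noise
is deliberately small in Ω: because dF/dR grows roughly quadratically as
resistance falls, even modest additive-Ω noise produces very large force
noise at peak load, which biases per-cycle maxima upward. Real sensors of
this type additionally show hysteresis and contact-area variation, which
this generator does not model — so the synthetic sensor-fit r² (~0.999)
is tighter than the ~0.94–0.95 a physical fabric sensor yields, and the
synthetic agreement limits are narrower than a hardware study's. Passing
tests therefore demonstrate the correctness of the *pipeline*, not the
field accuracy of any physical sensor.

**Trials.** Calibration trials hold three smooth 0 → BW → 0 ramps
(cosine ease, 3 s up / 3 s down, 2 s rests) applied to a single region;
the sensor sees the ramp scaled by its coverage. Walking trials last 30 s:
FP 3-axis force at exactly 2,000 Hz (60,000 samples, fixed
vertical-dominant direction), insole resistance at a jittered ~28 Hz
(uniform ±10% period jitter, matching the reported 28 ± 1.2 Hz spread), a
stomp transient at t = 1 s, and walking from t = 3 s. The stomp is a
0.2-s raised-cosine pulse of 300 %BW with a *constant* flat-footed 60/40
hind/fore split: it must exceed the walking load in *each sensed channel*
(not just in total), and a constant split keeps both sensed pulses
time-symmetric so synchronization is unbiased. An injected IPS-vs-FP
clock offset (default 0.37 s) is stored as truth; adding it to the IPS
timestamps aligns the clocks.

**Ground-truth calibration coefficients.** Because coverage applies
identically during calibration steps and walking, it cancels through the
per-sensor calibration, and the generator-implied total-force
coefficients are `C_hind = C_fore = 1/(1 − m)` (1.06–1.22 for the default
m range). The *fitted* coefficients sit ~10% above this truth because
they also absorb the binomial filter's peak attenuation — the same
mechanism that makes physical studies report coefficients well above 1.

## Signal processing

Order per trial: resample → binomial filter → (synchronize) → sensor
calibration → baseline zeroing → swing clamping.

- **FP:** resultant = Euclidean norm of the three components, low-passed
  at 20 Hz with a fourth-order Butterworth filter, applied zero-phase
  (forward–backward) so peak timings are not lagged; a single-pass mode
  exists for textbook magnitude-response checks (at 40 Hz single-pass
  gain is 1/√(1+(40/20)⁸) ≈ 0.0624; zero-phase squares it).
- **Resampling to 2,000 Hz:** uniformly sampled inputs go through
  polyphase band-limited resampling (Kaiser-windowed FIR anti-aliasing,
  line-extension edge padding). Irregularly timestamped insole records
  are interpolated with a monotone PCHIP cubic — it cannot overshoot at
  the sharp, saturating loading transients of a resistance record. A C²
  cubic-spline option exists for smooth force records (an order of
  magnitude less peak flattening); the identity self-check uses it.
- **Binomial filter:** n = 10,000 successive (1,2,1)/4 convolutions,
  implemented in one pass with the exact binomial(2n, ½) kernel via FFT
  convolution (edge-value padding, kernel renormalized to unit DC gain).
  The kernel is Gaussian-like with variance n/2 samples², i.e.
  σ ≈ 70.7 samples ≈ 35 ms at 2,000 Hz. A naive n-fold convolution is
  retained as the test oracle for small n. This is a *heavy* filter: it
  attenuates the walking GRF lobes by roughly 2–10 %BW depending on lobe
  width (hence walking speed), which the total-force calibration absorbs
  as a gain.
- **Baseline zeroing / swing clamping:** unloaded spans are detected as
  samples with resistance within 2% of the trial maximum (the mirror of
  the 98% heel-strike rule); the mean calibrated force over those spans
  is subtracted and the force is clamped to zero there.

## Synchronization and gait events

The stomp anchors clock alignment: the FP event is the stomp force peak,
the IPS event the conductance-weighted centroid of the stomp dip, and the
coarse offset (their difference) is refined by cross-correlating the two
stomp pulses (force vs conductance, both symmetric about the pulse
center) over a ±60 ms lag window. Accuracy on synthetic trials is ~1 ms,
well inside the one-IPS-sample (~36 ms) requirement. Synchronization runs
on the resampled but *unfiltered* resistance: the binomial filter
attenuates the narrow stomp dip far more than the wide stance dips and
would bury the event.

FP heel strikes are upward 20 N crossings preceded by ≥ 0.1 s below
threshold (the debounce guard is not part of the printed protocol but is
needed against noisy re-crossings). IPS heel strikes fire at the first
sample of any span where resistance stays below 98% of the per-trial
baseline for ≥ 0.25 s, evaluated post-filter. On noise-free trials both
instruments find identical event counts; IPS events *lead* the FP events
by up to ~80 ms because the filter's leading tail crosses the (tiny) 2%
threshold early — a direct consequence of the printed filter size, so the
property test budgets 100 ms rather than a tighter bound. Cycles are the
half-open intervals between consecutive heel strikes; stomp-adjacent
events are dropped (±1 s guard), cycles 1.5× longer than the median
(gaps) are discarded, and FP/IPS cycles are paired by nearest start time
within 30% of the cycle duration. Dropped and unpaired cycles are counted,
never silently imputed.

## Calibration

**Stage one (per sensor).** Loading phases run from sensor contact (force
above 2 %BW *and* resistance below the 98% threshold) to each step's
force peak (prominence > 20 %BW); where a lab analyst would mark these
phases by hand, the two thresholds automate the identification. Each phase is downsampled at exact
150 Ω increments of (monotonized) resistance, force linearly interpolated
at each grid value; a phase spanning less than one step falls back to its
endpoints with a warning. Pooled (G = 1/R, F) pairs are fitted by least
squares with a second-order polynomial; r², the fitted resistance range,
and a monotonicity warning are recorded. Application outside the fitted
range is allowed but flagged as extrapolation (walking peaks above body
weight always extrapolate, as the protocol calibrates only up to BW).

**Stage two (total force).** At the two FP-rule peaks of every paired
cycle, rows (F_fp, F_hind, F_fore) are collected and
`F_total = C_hind·F_hind + C_fore·F_fore` is fitted by least squares with
no intercept (zero sensor force should map to zero total force). Peak
rows pool all speeds within a calibration fold. The midfoot estimate is
the total minus the raw sensor sum,
`F_mid = (C_hind−1)·F_hind + (C_fore−1)·F_fore`, so the three regional
estimates close the force balance exactly. Calibrations are per subject
and per sensor; applying one subject's calibration to another's data is
rejected by id checks.

## Agreement analysis

Differences are signed IPS − FP throughout, in %BW (0–100 scale). The
2PK assessment pairs the weight-acceptance and push-off peaks: on the FP,
the maximum in the first 30% of the cycle and the maximum after 30%; on
the IPS, the two largest local maxima with width at half-prominence above
0.05 s, ordered by time (cycles with fewer than two qualifying IPS peaks
are excluded from 2PK only). The MAX assessment pairs per-cycle absolute
maxima. Bland–Altman statistics per pooled pair set: MoD (mean of
differences), sample SD (n−1), 2S = 1.96·SD, limits of agreement
MoD ± 2S (exact arithmetic identities, asserted to machine precision), a
two-sided one-sample t-test of MoD against zero (cycles treated as
independent), and a least-squares regression of the difference on the
pair mean (standard Bland–Altman abscissa) with residual SD.

**Cross-validation.** With two repetitions at each of three speeds,
stratifying one trial per speed into each fold yields exactly 2³ = 8
distinct splits; each iteration refits the total-force calibration on the
calibration fold and evaluates both assessments on the test fold.
**Representative subset:** the iteration whose Normal(MoD, (2S/1.96)²)
distribution (MAX assessment) has the largest overlap coefficient with
the mean cross-validation distribution, computed exactly from the normal
CDFs at the density crossing points; ties break to the lowest index.

## PWB overload simulation

True maxima F ~ Normal(50, 25²) %BW; sensor error
D | F ~ Normal(s·F + b, σe²) with (s, b, σe) taken from the
difference-versus-magnitude regression of a Bland–Altman result (the line
is applied to the true force; the abscissa mismatch with the pair mean is
second-order). M = F + D; both F and M are classified against the 50 %BW
limit, ties (measure zero) counting as "above" for bit-reproducibility.
Sensitivity = P(M below | F below), specificity = P(M above | F above).
The Monte-Carlo engine draws n = 10⁷ cycles in fixed-size chunks,
deterministic given the seed. Because (F, M) is jointly bivariate normal
— means (μ, (1+s)μ+b), variances (σf², (1+s)²σf²+σe²), covariance
(1+s)σf² — both rates have closed forms through the bivariate normal CDF;
`analytic_pwb` is the exact oracle, with limit formulas for
(near-)degenerate error models (σe ≲ 10⁻⁶σf). For the symmetric case
s = b = 0, σe = 10, μ = L = 50, σf = 25 the orthant identity gives both
rates = (¼ + arcsin(25/√725)/2π)/½ ≈ 0.879, used as a frozen reference.
On the synthetic cohort the *fitted* error models have positive slope and
strongly negative intercept (the regression is extrapolated from the
80–115 %BW walking-peak range down to 50 %BW), which drives specificity
well below sensitivity; this extrapolation fragility is a real limitation
of regressing bias on magnitude over a narrow force range.

## Identity self-consistency check

Feeding the FP resultant through the insole chain as both instruments
(sampled at the insole timestamps, resampled, calibrated, segmented,
assessed) must return agreement limited only by the chain itself. Two
harness choices make the check sharp and are part of its definition here:
the total-force fit is applied within speed (the binomial filter's
attenuation is waveform-bandwidth-dependent, so each speed has its own
calibratable gain; pooling speeds would measure that spread, not the
chain), and the denoising binomial stage is disabled for the clean copy
(a noise-free signal has nothing to denoise, and heavy smoothing raises
every per-cycle maximum of an asymmetric waveform relative to its value
at the reference peak time — a measurement-chain property characterized
by the filter's own attenuation tests). The residual is MoD ≈ 0.02 %BW
and 2S ≈ 0.45 %BW — the resampling/interpolation tolerance of the chain.
The production pipeline keeps both speed pooling and the filter.

## Problem sizes and determinism

Default analysis sizes: 7 subjects × (2 calibration trials + 6 × 30-s
walking trials), 10⁷ PWB draws per engine run; the full cohort analysis
completes in well under a minute on one core, and the bundled test suite
uses the same sizes except for unit-level Monte-Carlo checks (5·10⁵
draws) and the reduced-subject pipeline shape tests. Every generator and
simulation is a pure function of (configuration, seed); rerunning any
script with the same seed reproduces its tables byte-for-byte. All stage
parameters live in `RunConfig`, whose defaults are the printed protocol
values (2,000 Hz / 20 Hz / order 4; 28 Hz nominal; binomial n = 10,000;
98% / 0.25 s; 20 N; 30% / 0.05 s; 150 Ω; 50/25/50/10⁷).

## Known limitations

- No hysteresis, creep, or contact-area dynamics in the sensor model;
  synthetic r² and agreement limits are correspondingly optimistic.
- The difference-versus-magnitude error model is linear and extrapolated
  far below the fitted force range when driving the PWB simulation.
- Gait variability is stationary Gaussian (no fatigue drift, no missteps,
  no double support asymmetries); cycle pairing has not been exercised
  against dropped-cycle-rich recordings.
- The FP force direction is fixed within a trial; resultant-vs-vertical
  calibration differences are therefore not explored.
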