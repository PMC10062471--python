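# insolegrf

Estimating resultant ground reaction force (GRF) from a two-sensor
piezoresistive insole, and validating it against a force plate.

Wearable insole pressure sensors (IPS) promise GRF measurement outside
the gait laboratory — for example, monitoring patients under a partial
weight-bearing (PWB) prescription that caps peak limb load at a fraction
of body weight. This package implements the complete validation pipeline
for such a system, driven by a synthetic gait generator with known ground
truth in place of human-subject recordings: it is aimed at biomechanics
researchers and wearable-sensor engineers who need a tested, reproducible
reference implementation of each analysis stage.

## The pipeline

1. **Synthetic study** — subjects (mass 75.2 ± 18.2 kg) walk 30-s
   treadmill trials at 0.5/1.0/1.5 m/s (two repetitions each) over a
   force plate sampling at 2,000 Hz, wearing hindfoot and forefoot
   resistive sensors sampled at ~28 Hz; calibration trials load each
   sensor three times from 0 to body weight (BW) and back. A deliberate
   "stomp" near the start of every trial marks both recordings.
2. **Processing** — resultant ‖(Fx,Fy,Fz)‖ low-passed at 20 Hz
   (4th-order Butterworth, zero-phase); insole resistance resampled to
   2,000 Hz, smoothed with a binomial filter of n = 10,000 convolutions
   (≈ Gaussian, σ ≈ 35 ms), baseline-zeroed per trial, swing phase
   clamped; clocks synchronized on the stomp.
3. **Calibration** — per sensor, least-squares quadratic of force on
   inverse resistance G = 1/R, fitted on the loading phases downsampled
   every 150 Ω:  F̂ = a₀ + a₁G + a₂G². Then a total-force scaling fitted
   at the two GRF peaks of each gait cycle, with no intercept:

       F_total = C_hind·F_hind + C_fore·F_fore

   whose excess over the raw sum, F_mid = (C_hind−1)F_hind +
   (C_fore−1)F_fore, estimates the unsensed midfoot force.
4. **Agreement** — per gait cycle, both GRF peaks (2PK) and the absolute
   maximum (MAX) are paired between instruments and summarized
   Bland–Altman style: mean of differences MoD (IPS − FP, %BW),
   2S = 1.96·SD of differences, limits of agreement MoD ± 2S, and a
   regression of bias on force magnitude — under stratified two-fold
   cross-validation (one trial per speed per fold, all 2³ = 8 splits).
5. **PWB simulation** — 10⁷ per-cycle maxima F ~ N(50, 25²) %BW are
   corrupted with the fitted error model D|F ~ N(sF + b, σe²) and
   classified against the 50 %BW limit; sensitivity and specificity come
   from both a Monte-Carlo engine and its exact bivariate-normal closed
   form.

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/02_calibrate_sensors.py
python analysis/03_agreement_analysis.py
python analysis/04_pwb_simulation.py
```

The agreement step prints, for the default seed:

```
Total-force (secondary) calibration per subject:
subject  c_hind  c_fore  c_truth
    S01   1.229   1.228    1.121
    S02   1.315   1.308    1.206
    S03   1.193   1.177    1.087
    ...

Group agreement (mean over subjects of per-subject CV means):
assessment  mod_mean_pbw  mod_sd_pbw  two_s_mean_pbw  two_s_sd_pbw  n_subjects
       2PK          1.71        0.04            6.39          0.27           7
       MAX          1.63        0.08            6.73          0.55           7
```

Reading this: the fitted scaling coefficients sit ~10% above the
generator's ground truth 1/(1 − midfoot share) because they also absorb
the smoothing filter's peak attenuation; the insole over-reads peak
forces by ~1.7 %BW on average (MoD), and 95% of per-cycle disagreements
fall within ±6–7 %BW of that bias (2S). The synthetic sensors carry only
ADC-scale noise — a physical fabric sensor with hysteresis would widen
these limits severalfold. The PWB step then shows the Monte-Carlo and
closed-form rates agreeing to ~10⁻⁴, e.g. both giving
sensitivity = specificity ≈ 0.879 for the symmetric σe = 10 %BW error
model.

The same stages are scriptable from a thin CLI
(`insolegrf simulate|process|calibrate|pwb-sim|run-all`); the library
surface in `insolegrf.*` is the primary interface.

## Layout

- `src/insolegrf/` — library: `synthetic` (generator), `processing`
  (filters/resampling), `events` (sync, heel strikes, cycles),
  `calibration` (both stages), `agreement` (peaks, Bland–Altman, CV),
  `pwb` (simulation + oracle), `pipeline` (orchestration), `io`
  (CSV/JSON formats, `RunConfig`), `cli`.
- `analysis/` — numbered narrative drivers writing tables to `results/`.
- `docs/methods.md` — model assumptions, parameter choices, numerical
  decisions, limitations.
- `tests/` — unit, property and acceptance tests.
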