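# Methods

This note documents the models, estimators and numerical choices behind
`dualpwv`, what the synthetic-data generator does and does not emulate, and
the limitations a user should keep in mind.

## The measurement model

A pulse generated at one end of a vessel (or bench tube) propagates at the
pulse wave velocity (PWV). Two Doppler sample volumes ("gates") a distance
ΔD apart record flow velocity simultaneously; the time the wave *foot*
takes to travel from the upstream to the downstream gate is the transit
time Δt, and

    PWV = ΔD / Δt        (mm / ms ≡ m/s).

The foot — the onset of the systolic upstroke — is used as the fiducial
point because it occurs during diastole, before reflected waves return,
so it is the feature least distorted along the vessel. All internal units
are milliseconds and millimetres, so PWV needs no conversion factor.

For bench validation a second, long-baseline estimator anchors two
separately acquired sites A and B to a shared pressure transducer near the
pulse source: with Δt_A and Δt_B the delays from the pressure-curve onset
to the flow foot at each site,

    PWV_AB = Δd_AB / (Δt_B − Δt_A).

On a homogeneous tube the two estimators measure the same physical speed,
which is the package's central validation property.

## Foot detection: the intersecting tangent method

Within one beat the detector:

1. smooths the beat with a Savitzky–Golay filter (default window 7
   samples, polynomial order 2) and takes the smoothed first derivative;
2. reads the maximum-upslope point: time `t_m`, amplitude `v_m`, slope
   `s_m` at the (earliest, on ties) derivative maximum;
3. reads the diastolic baseline `v_base` as the minimum, before `t_m`, of
   an order-1 (moving-average) smoothing of the beat;
4. returns `t_foot = t_m − (v_m − v_base)/s_m`, the intersection of the
   max-slope tangent with the horizontal baseline.

The intersection is a continuous-valued time: quantization to the
acquisition grid is a property of the input, not re-imposed on the output.

Choices worth recording:

- **Baseline variant.** The horizontal-line-through-the-pre-upstroke-
  minimum variant was chosen over a sloped late-diastolic tangent: it is
  the stablest at 1 ms sampling on velocity envelopes. The baseline is
  read from an order-1 rather than order-2 fit deliberately: a
  least-squares quadratic undershoots below a convex corner (by about
  `slope·dt/21` for window 7), which would bias the foot early by a
  fraction of a sample; a centered moving average never undershoots a
  convex region, so on a beat with an exactly flat pre-upstroke baseline
  the foot is exact. Both fits reproduce constants and straight lines, so
  scale, offset and time-shift invariance hold to machine precision, and
  on a piecewise-linear beat the detected foot equals the breakpoint with
  zero error.
- **Slope read.** By default the slope is taken at the single
  max-derivative sample (deterministic; exact on a linear upstroke). A
  regression over the contiguous samples with derivative ≥ 80% of the
  maximum is available behind `slope_window=True` for noisy upstrokes.
- **Edge policy.** Savitzky–Golay edges use polynomial extension
  (scipy's `mode="interp"`), preserving the constant/line exactness at
  the boundaries.
- **Degenerate beats.** An exactly flat beat, or one whose maximum
  smoothed slope is non-positive, raises a detection error; in batch
  detection such failures are recorded per beat, never raised, so one bad
  beat cannot abort a recording.

## PWV estimation and averaging

Beats are segmented per channel (upstrokes = local derivative maxima above
half the global maximum slope, separated by ≥ 100 ms — admitting both a
4.5 Hz bench pump and 60–80 bpm human rates), foot-detected, and paired
across channels by upstroke order within half a pulse period. Per-beat
values pass a plausibility screen (Δt ∈ (0, 100] ms, PWV ∈ [0.5, 30] m/s,
both configurable) that catches pairing errors and channel swaps; excluded
beats carry an explicit reason. The reported PWV is the **arithmetic mean
of the surviving per-beat PWVs** (not ΔD divided by the mean Δt) — the
difference between the two conventions is second-order in the timing
error, but the per-beat mean matches how repeated measurements are
averaged in practice and yields a per-beat SD for free. Presentation
rounds to 2 decimals; nothing is rounded internally.

Why averaging matters: at ΔD = 40 mm and Δt = 8 ms, `d(PWV)/dΔt ≈
−0.6 m/s per ms`, so even a ±0.5 ms timing error moves a single-beat
estimate by ±0.3 m/s. With per-beat timing errors decorrelated, averaging
N beats shrinks the spread roughly as 1/√N; ten beats bring the bench
configuration to ≈ 0.1 m/s.

The long-baseline estimator applies the *same* foot detector to the
pressure channel (treated as just another waveform), pairs pressure onset
→ flow foot within each recording, then matches beats across the A and B
recordings by pressure-onset order. Because the transit difference is
~70 ms rather than ~8 ms, the same per-foot timing error perturbs it an
order of magnitude less — the simulation studies reproduce this precision
ordering (long-baseline CV ≪ dual-gate CV across seeded sessions).

## The tube simulator

The generator emulates a bench rig: a pump drives a pulse train down a
homogeneous compliant tube; flow is sampled at two gate positions and
optionally a pressure tap near the pump.

- **Pulse template**: raised-cosine upstroke (width W) then exponential
  decay. Its tangent geometry is analytic — maximum slope `a·π/(2W)` at
  `W/2`, intersecting-tangent foot at `W·(1/2 − 1/π)` after onset — so it
  doubles as an exact oracle for the detector. Default W = 30 ms
  (pump-like); the artery-like scenario uses 60 ms.
- **Propagation**: pure delay `distance/PWV` applied at continuous
  precision before sampling, optional exponential amplitude attenuation
  per mm and an optional low-pass standing in for dispersion. The wave
  speed is given directly or via Moens–Korteweg √(E·h/(2·r·ρ)).
- **Bench defaults** (the conditions of the validation studies): true PWV
  5.0 m/s, 450 mm tube, gates 205/245 mm (ΔD = 40 mm), pressure tap at
  10 mm, pulse rate 4.5 Hz, 10 beats, dt = 1 ms, additive white Gaussian
  noise with SD = 1% of pulse amplitude per channel.
- **Phase jitter**: each beat's onset is jittered uniformly within ±dt/2
  before sampling, so grid-quantization error decorrelates across beats
  and multi-beat averaging is effective, as it is on a real rig where the
  pump and sampling clocks are unsynchronized.
- **Determinism**: one integer seed drives every random draw; identical
  seeds give bit-identical recordings.

What the generator does **not** model — and hence what passing tests do
not certify about clinical data: Doppler spectral broadening and speckle
(noise is white Gaussian, not multiplicative), wave reflections
(absorbed on the rig, present in arteries), beat-to-beat shape variability
and respiratory modulation, insonation-angle effects (irrelevant to
timing, but real envelopes are angle-scaled), and probe/vessel motion.
Recovery results on synthetic data bound the method's *numerical* error,
not its full in-vivo error budget.

## Statistics

- `CV% = 100 · SD(a−b) / mean(all 2n values)` — the paired-repeatability
  CV; SD uses the n−1 denominator (everywhere in the package). The grand
  mean is taken over the concatenated 2n values; for equal-length pairs
  this equals the mean of per-pair means.
- Bland–Altman: bias = mean difference, limits of agreement at
  bias ± 1.96·SD(differences), with per-pair (mean, difference) points
  exported for plotting; Pearson r accompanies agreement plots.
- Paired t equals the one-sample t of the differences against zero
  (df = n−1); the unpaired test defaults to pooled-variance Student with
  a Welch option. Degenerate inputs (zero variance) raise rather than
  return misleading values.

One documented inconsistency in the embedded summaries: the in-vivo cohort
means (6.29 ± 1.04 vs 5.31 ± 0.72 m/s, n = 45 per group) imply an
unpaired-t p-value far below 0.001, not the 0.019 sometimes quoted with
them; the package therefore exercises that comparison only as a
Monte-Carlo power property (significance at α = 0.05 in ≥ 99% of seeded
replicates) and does not treat the printed p as reproducible.

## Problem sizes and tolerances

The seeded validation studies use 200 sessions for dual-gate recovery
(|bias| < 0.1 m/s, SD < 0.2 m/s observed ≈ 0.02 and 0.09) and 100 paired
sessions for the method-consistency comparison (mean agreement within
0.15 m/s, observed ≈ 0.03); the noise-free fine-grid check (dt = 0.01 ms)
recovers the true speed to < 0.01 m/s (observed exactly, because a
transit that is an integer number of fine-grid samples cancels identically
between channels). These sizes give comfortably stable Monte-Carlo
estimates while keeping the whole suite around half a minute. Exact
checks (table arithmetic, CV formula, closed-form foot) are asserted at
printed precision or at 1e-9 absolute.

## Known limitations

- The foot detector offers only the intersecting-tangent definition;
  maximum-second-derivative and threshold-crossing feet are future flags.
- No resampling of non-uniform clinical exports: input must be uniformly
  sampled (checked to 1e-6 relative tolerance).
- Beat pairing assumes simultaneous channels; it is not a general
  beat-matching algorithm across independently clocked recordings (the
  pressure reference is the supported cross-recording anchor).
- Propagation is delay–attenuation only: no 1-D transmission-line
  hemodynamics, no reflections, no nonlinear steepening.
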