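# dualpwv

**Local pulse wave velocity from dual-gate Doppler velocity waveforms.**

Pulse wave velocity (PWV) — the speed at which the pressure/flow pulse
travels along a vessel — is the standard noninvasive surrogate for arterial
stiffness: by the Moens–Korteweg relation, PWV = √(E·h / (2·r·ρ)), so wave
speed rises with the wall's elastic modulus *E*. Carotid–femoral PWV
averages stiffness over a long, heterogeneous arterial path; *local* PWV
over a few centimetres of one artery is diagnostically more specific but
much harder to measure, because the transit time over a ~40 mm segment is
only ~8 ms and the acquisition grid of a clinical dual-Doppler system is
1 ms.

`dualpwv` is a signal-processing toolkit for exactly that measurement. It
is written for engineers and researchers working with dual-gate pulsed
Doppler (two sample volumes recording flow velocity simultaneously along
one vessel) or with bench rigs that validate such methods. It provides:

- **Wave-foot detection by the intersecting tangent method** — the foot of
  each beat is the intersection of the tangent at the maximum systolic
  upslope with the horizontal diastolic baseline,
  `t_foot = t_m − (v_m − v_base)/s_m`, reported at sub-sample resolution.
- **Transit-time and PWV estimation** — the dual-gate local estimator
  `PWV = ΔD/Δt` averaged over the beats of a recording, and the
  pressure-referenced long-baseline estimator
  `PWV_AB = Δd_AB/(Δt_B − Δt_A)` used as bench ground truth.
- **A homogeneous-tube pulse-propagation simulator** — pure
  delay(-attenuation) propagation of a raised-cosine/exponential pulse
  train with per-beat phase jitter, Gaussian channel noise, an optional
  pressure tap, and exact ground truth for parameter-recovery studies.
- **Reproducibility statistics** — the paired-difference coefficient of
  variation `CV% = 100·SD(a−b)/mean(all)`, Bland–Altman limits of
  agreement, paired/unpaired t tests and Shapiro–Wilk normality.

## Worked example

Simulate a 10-beat bench acquisition on a 450 mm tube with true wave speed
5.0 m/s (gates 40 mm apart, 1 ms sampling, 1% noise), then estimate PWV:

```bash
$ cat scenario.yaml
pwv_true: 5.0
length_mm: 450.0
gate_positions: [205.0, 245.0]
pressure_tap_position: 10.0
n_beats: 10
seed: 42

$ dualpwv simulate scenario.yaml --outdir out
$ dualpwv pwv out/recording.csv --meta out/meta.yaml
PWV: 5.27 m/s  (n=10 beats, SD 0.51 m/s, distance 40.0 mm)
beat  transit_ms  pwv_mps  status
   0       8.129     4.92  ok
   1       7.425     5.39  ok
   ...
   9       7.331     5.46  ok
```

The true transit time is 8.0 ms; single-beat estimates scatter by several
tenths of a m/s because a fraction of a millisecond of timing error over
8 ms moves ΔD/Δt substantially — which is precisely why the estimator
averages ten consecutive beats (here to 5.27 m/s, within the expected
spread of the 5.0 m/s truth).

Reproducibility statistics on paired measurements (here, the embedded
ten-measurement bench validation table, long-baseline vs local estimates):

```bash
$ dualpwv repro pairs.csv
n pairs:                10
Mean +/- SD (m/s):      5.09 +/- 0.23
Mean diff +/- SD (m/s): -0.127 +/- 0.20
CV (%):                 3.97
Limits of agreement:    [-0.524, 0.269] m/s
Pearson r:              0.720
Paired t:               t=-1.990, df=9, p=0.078
```

The two estimators agree within their variability (p = 0.078): on a
homogeneous tube the 40 mm local measurement recovers the same wave speed
as the 350–390 mm reference.

The same pipeline is available as a library:

```python
from dualpwv import dual_gate_pwv, simulate, bench_scenario

result = simulate(bench_scenario(seed=42))
est = dual_gate_pwv(result.recording)
print(f"{est.pwv:.2f} m/s from {est.n_beats} beats (truth {result.truth.pwv_true})")
```

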