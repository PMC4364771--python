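"""Synthetic pulse propagation in a homogeneous compliant tube.

The simulator emulates a bench rig: a peristaltic pump drives a pulse train
down a homogeneous rubber tube; flow velocity is sampled at chosen axial
gate positions and, optionally, a pressure transducer taps the tube near
the pump.  Propagation is a pure delay at the tube's wave speed (plus
optional exponential amplitude attenuation and an optional low-pass to
mimic dispersion): for a homogeneous tube with reflections absorbed this is
exactly the physics the foot-to-foot method assumes, and it gives an exact
ground truth to validate against.

The wave speed is either given directly or derived from wall properties by
the Moens–Korteweg relation PWV = sqrt(E·h / (2·r·ρ)).

The per-beat pulse onsets carry a sub-sample jitter (uniform within ±dt/2)
so that the sampling-grid quantization error decorrelates across beats and
multi-beat averaging actually reduces it — the same rationale as averaging
ten consecutive beats on a 1 ms acquisition system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ParameterError
from .pwv import DualGateRecording, ReferenceDelayRecording
from .waveform import SampledWaveform

__all__ = [
    "MoensKortewegWall",
    "TubeModel",
    "PulseShape",
    "SimScenario",
    "SimTruth",
    "SimResult",
    "moens_korteweg",
    "pulse_template",
    "propagate",
    "simulate",
    "bench_scenario",
    "carotid_scenario",
]


def moens_korteweg(E: float, h: float, r: float, rho: float) -> float:
    """Moens–Korteweg wave speed sqrt(E·h / (2·r·ρ)), in m/s.

    Parameters are SI: wall elastic modulus E (Pa), wall thickness h (m),
    lumen radius r (m), fluid density ρ (kg/m³).
    """
    for name, v in (("E", E), ("h", h), ("r", r), ("rho", rho)):
        if not v > 0:
            raise ParameterError(f"{name} must be positive, got {v}")
    return math.sqrt(E * h / (2.0 * r * rho))


@dataclass(frozen=True)
class MoensKortewegWall:
    """Wall/fluid properties determining the tube wave speed (SI units)."""

    E: float
    h: float
    r: float
    rho: float

    @property
    def pwv(self) -> float:
        return moens_korteweg(self.E, self.h, self.r, self.rho)


@dataclass(frozen=True)
class TubeModel:
    """Ground-truth tube: geometry plus wave speed.

    Exactly one of ``pwv_true`` (m/s) or ``wall`` (Moens–Korteweg
    parameters) must be supplied.
    """

    length_mm: float
    pwv_true: float | None = None
    wall: MoensKortewegWall | None = None
    #: fractional amplitude loss per mm of travel
    attenuation_per_mm: float = 0.0
    #: optional low-pass cutoff applied to propagated pulses (Hz)
    dispersion_cutoff_hz: float | None = None

    def __post_init__(self) -> None:
        if (self.pwv_true is None) == (self.wall is None):
            raise ParameterError("supply exactly one of pwv_true or wall parameters")
        if self.pwv_true is not None and not self.pwv_true > 0:
            raise ParameterError(f"pwv_true must be positive, got {self.pwv_true}")
        if not self.length_mm > 0:
            raise ParameterError(f"length_mm must be positive, got {self.length_mm}")
        if not 0 <= self.attenuation_per_mm < 1:
            raise ParameterError("attenuation_per_mm must be in [0, 1)")

    @property
    def pwv(self) -> float:
        """Wave speed in m/s (≡ mm/ms)."""
        return self.pwv_true if self.pwv_true is not None else self.wall.pwv


@dataclass(frozen=True)
class PulseShape:
    """Raised-cosine upstroke followed by an exponential decay.

    The template is zero before its onset, rises as
    a·(1 − cos(π·τ/W))/2 over the upstroke width W, and decays as
    a·exp(−(τ−W)/τ_d) afterwards.  Its tangent geometry is analytic, which
    makes it an exact oracle for the foot detector:

    * maximum slope a·π/(2W) at τ = W/2,
    * intersecting-tangent foot at τ = W·(1/2 − 1/π) ≈ 0.1817·W after the
      true onset.

    Defaults are pump-like (sharp 30 ms upstroke); use ~60 ms for an
    artery-like beat.
    """

    upstroke_ms: float = 30.0
    decay_ms: float = 60.0
    amplitude: float = 50.0

    def __post_init__(self) -> None:
        if not (self.upstroke_ms > 0 and self.decay_ms > 0 and self.amplitude > 0):
            raise ParameterError("pulse shape parameters must be positive")

    def value(self, tau) -> np.ndarray:
        """Template amplitude at time ``tau`` (ms) after the onset."""
        tau = np.asarray(tau, dtype=float)
        w, a = self.upstroke_ms, self.amplitude
        out = np.zeros_like(tau)
        rising = (tau >= 0) & (tau < w)
        out[rising] = 0.5 * a * (1.0 - np.cos(np.pi * tau[rising] / w))
        decaying = tau >= w
        out[decaying] = a * np.exp(-(tau[decaying] - w) / self.decay_ms)
        return out

    @property
    def max_slope(self) -> float:
        return self.amplitude * math.pi / (2.0 * self.upstroke_ms)

    @property
    def max_slope_offset_ms(self) -> float:
        """Time of maximum upslope after the onset (the inflection, W/2)."""
        return self.upstroke_ms / 2.0

    @property
    def tangent_foot_offset_ms(self) -> float:
        """Intersecting-tangent foot after the onset: W·(1/2 − 1/π)."""
        return self.upstroke_ms * (0.5 - 1.0 / math.pi)


def pulse_template(
    shape: PulseShape, dt: float, duration_ms: float, onset_ms: float = 0.0,
    t0: float = 0.0, label: str = "template",
) -> SampledWaveform:
    """Sample one noise-free pulse on a uniform grid."""
    if dt <= 0 or duration_ms <= dt:
        raise ParameterError("need dt > 0 and duration > dt")
    n = int(round(duration_ms / dt))
    t = t0 + np.arange(n) * dt
    return SampledWaveform(shape.value(t - onset_ms), dt=dt, t0=t0, label=label)


def propagate(w: SampledWaveform, from_mm: float, to_mm: float, tube: TubeModel) -> SampledWaveform:
    """Propagate a sampled pulse between two axial positions.

    Pure delay |to − from| / PWV applied at continuous (sub-sample)
    precision by interpolation, amplitude scaled by
    (1 − attenuation_per_mm)^distance, optional low-pass when the tube sets
    a dispersion cutoff.
    """
    for name, p in (("from_mm", from_mm), ("to_mm", to_mm)):
        if not 0 <= p <= tube.length_mm:
            raise ParameterError(f"{name}={p} outside tube [0, {tube.length_mm}] mm")
    dist = abs(to_mm - from_mm)
    delay = dist / tube.pwv  # mm / (mm/ms) = ms
    gain = (1.0 - tube.attenuation_per_mm) ** dist
    y = gain * np.interp(w.times - delay, w.times, w.samples,
                         left=w.samples[0], right=w.samples[-1])
    if tube.dispersion_cutoff_hz is not None:
        fs_hz = 1000.0 / w.dt
        b, a = butter(2, tube.dispersion_cutoff_hz, fs=fs_hz)
        y = filtfilt(b, a, y)
    return w.with_samples(y)


@dataclass
class SimScenario:
    """Acquisition settings for one synthetic recording session.

    Defaults are the bench conditions used throughout the validation tests:
    pump rate 4.5 Hz, 10 beats, 1 ms sampling, noise 1% of pulse amplitude,
    pump-like pulse shape, per-beat onset jitter on.
    """

    tube: TubeModel
    gate_positions: tuple[float, float] = (205.0, 245.0)
    pressure_tap_position: float | None = None
    pulse_rate_hz: float = 4.5
    n_beats: int = 10
    dt_ms: float = 1.0
    noise_sd: float = 0.01  # fraction of pulse amplitude
    seed: int = 0
    pulse_shape: PulseShape = field(default_factory=PulseShape)
    lead_in_ms: float = 120.0
    jitter: bool = True

    def __post_init__(self) -> None:
        if len(self.gate_positions) != 2:
            raise ParameterError("exactly two gate positions required")
        for p in self.gate_positions:
            if not 0 <= p <= self.tube.length_mm:
                raise ParameterError(f"gate position {p} outside tube")
        if self.gate_positions[0] == self.gate_positions[1]:
            raise ParameterError("gate separation must be non-zero")
        if self.pressure_tap_position is not None and not (
            0 <= self.pressure_tap_position <= self.tube.length_mm
        ):
            raise ParameterError("pressure tap outside tube")
        if not self.pulse_rate_hz > 0:
            raise ParameterError("pulse_rate_hz must be positive")
        if not self.pulse_rate_hz <= 5.0:
            raise ParameterError("pump pulse rate limited to 5 Hz")
        if not self.dt_ms > 0:
            raise ParameterError("dt_ms must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.n_beats < 1:
            raise ParameterError("n_beats must be >= 1")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth attached to a simulated recording."""

    pwv_true: float
    onsets_ms: np.ndarray
    gate_positions: tuple[float, float]
    gate_distance_mm: float
    transit_ms: float
    #: true wave-onset arrival time per beat at each gate (and pressure tap)
    arrival_ms: dict

    def tangent_feet(self, position_key, shape: PulseShape) -> np.ndarray:
        """Per-beat intersecting-tangent foot times of the noise-free pulse."""
        return self.arrival_ms[position_key] + shape.tangent_foot_offset_ms


@dataclass
class SimResult:
    recording: DualGateRecording
    references: dict | None
    truth: SimTruth
    scenario: SimScenario


def _train(times: np.ndarray, onsets: np.ndarray, shape: PulseShape,
           delay: float, gain: float) -> np.ndarray:
    y = np.zeros_like(times)
    for on in onsets:
        y += shape.value(times - on - delay)
    return gain * y


def simulate(scenario: SimScenario) -> SimResult:
    """Run one synthetic acquisition; identical seeds give identical output.

    Returns the simultaneous dual-gate recording at ``gate_positions`` and,
    when a pressure tap is configured, one pressure-referenced recording per
    gate (flow at the gate plus the shared pressure curve), each with
    independent channel noise — mirroring the fact that on the bench the
    two reference acquisitions are taken separately.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    shape = sc.pulse_shape
    tube = sc.tube
    period = 1000.0 / sc.pulse_rate_hz
    jit = rng.uniform(-sc.dt_ms / 2, sc.dt_ms / 2, sc.n_beats) if sc.jitter else np.zeros(sc.n_beats)
    onsets = sc.lead_in_ms + np.arange(sc.n_beats) * period + jit
    duration = sc.lead_in_ms + sc.n_beats * period + period / 2
    n = int(round(duration / sc.dt_ms))
    times = np.arange(n) * sc.dt_ms

    def flow_channel(pos: float, label: str) -> SampledWaveform:
        delay = pos / tube.pwv
        gain = (1.0 - tube.attenuation_per_mm) ** pos
        y = _train(times, onsets, shape, delay, gain)
        if sc.noise_sd > 0:
            y = y + rng.normal(0.0, sc.noise_sd * shape.amplitude, n)
        return SampledWaveform(y, dt=sc.dt_ms, t0=0.0, label=label)

    def pressure_channel() -> SampledWaveform:
        pshape = replace(shape, amplitude=1.0)
        delay = sc.pressure_tap_position / tube.pwv
        y = _train(times, onsets, pshape, delay, 1.0)
        if sc.noise_sd > 0:
            y = y + rng.normal(0.0, sc.noise_sd * pshape.amplitude, n)
        return SampledWaveform(y, dt=sc.dt_ms, t0=0.0, label="pressure")

    p1, p2 = sc.gate_positions
    ch1 = flow_channel(p1, "ch1")
    ch2 = flow_channel(p2, "ch2")
    distance = abs(p2 - p1)
    recording = DualGateRecording(
        ch1, ch2, gate_distance=distance,
        meta=f"simulated tube, seed={sc.seed}",
        max_gate_mm=max(45.0, tube.length_mm),
    )

    arrivals = {p1: onsets + p1 / tube.pwv, p2: onsets + p2 / tube.pwv}
    references = None
    if sc.pressure_tap_position is not None:
        arrivals["pressure"] = onsets + sc.pressure_tap_position / tube.pwv
        references = {}
        for pos, lab in ((p1, "A"), (p2, "B")):
            references[lab] = ReferenceDelayRecording(
                flow=flow_channel(pos, f"flow_{lab}"),
                pressure_ref=pressure_channel(),
                meta=f"simulated reference at {pos} mm, seed={sc.seed}",
            )

    truth = SimTruth(
        pwv_true=tube.pwv,
        onsets_ms=onsets,
        gate_positions=(p1, p2),
        gate_distance_mm=distance,
        transit_ms=distance / tube.pwv,
        arrival_ms=arrivals,
    )
    return SimResult(recording=recording, references=references, truth=truth, scenario=sc)


def bench_scenario(seed: int = 0, **overrides) -> SimScenario:
    """The rubber-tube bench: 450 mm tube at 5.0 m/s, gates 40 mm apart
    mid-tube, pressure tap 10 mm from the pump."""
    kw = dict(
        tube=TubeModel(length_mm=450.0, pwv_true=5.0),
        gate_positions=(205.0, 245.0),
        pressure_tap_position=10.0,
        seed=seed,
    )
    kw.update(overrides)
    return SimScenario(**kw)


def carotid_scenario(seed: int = 0, **overrides) -> SimScenario:
    """An artery-like recording: slower beat (66/min), softer upstroke,
    gates 40 mm apart along a short straight segment."""
    kw = dict(
        tube=TubeModel(length_mm=60.0, pwv_true=5.3),
        gate_positions=(10.0, 50.0),
        pulse_rate_hz=1.1,
        pulse_shape=PulseShape(upstroke_ms=60.0, decay_ms=200.0, amplitude=80.0),
        lead_in_ms=300.0,
        seed=seed,
    )
    kw.update(overrides)
    return SimScenario(**kw)
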