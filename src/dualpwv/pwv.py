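"""Transit-time and pulse-wave-velocity estimation.

Two estimators are provided:

* :func:`dual_gate_pwv` — the local method: two Doppler sample volumes a
  known distance ΔD apart record flow velocity simultaneously; the foot of
  each beat is detected on both channels, the transit time Δt is the foot
  difference, and PWV = ΔD/Δt.  With ΔD around 40 mm and Δt around 8 ms, a
  sub-millisecond timing error moves a single-beat estimate by several
  tenths of a m/s, so the estimate is averaged over the beats of the
  recording.

* :func:`reference_delay_pwv` — the long-baseline bench reference: at each
  of two sites A and B the flow waveform is recorded together with a shared
  pressure transducer near the pulse source.  The delay from pressure onset
  to flow foot (Δt_A, Δt_B, same intersecting-tangent detector on both
  channels) anchors each site to the common clock, and
  PWV_AB = Δd_AB / (Δt_B − Δt_A).

Units are ms and mm throughout, so PWV values are in m/s with no
conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import numpy as np

from .errors import EstimationError, ParameterError
from .foot import FootTime, detect_feet
from .waveform import SampledWaveform, segment_beats

__all__ = [
    "DualGateRecording",
    "ReferenceDelayRecording",
    "EstimatorConfig",
    "ExcludedBeat",
    "PWVEstimate",
    "transit_time",
    "pwv_from",
    "dual_gate_pwv",
    "reference_delay_pwv",
]


@dataclass(eq=False)
class DualGateRecording:
    """Two simultaneously sampled velocity channels plus the gate separation.

    ``max_gate_mm`` models the acquisition system's maximum sample-volume
    separation (45 mm for the clinical dual-Doppler mode); pass a larger
    bound for synthetic rigs.
    """

    ch1: SampledWaveform
    ch2: SampledWaveform
    gate_distance: float
    meta: str = ""
    max_gate_mm: float = 45.0

    def __post_init__(self) -> None:
        a, b = self.ch1, self.ch2
        if a.n != b.n or a.dt != b.dt or a.t0 != b.t0:
            raise ParameterError("channels must share dt, t0 and sample count")
        if not 0 < self.gate_distance <= self.max_gate_mm:
            raise ParameterError(
                f"gate_distance must be in (0, {self.max_gate_mm}] mm, "
                f"got {self.gate_distance}"
            )


@dataclass(eq=False)
class ReferenceDelayRecording:
    """Flow at one site plus the shared pressure-transducer reference."""

    flow: SampledWaveform
    pressure_ref: SampledWaveform
    meta: str = ""

    def __post_init__(self) -> None:
        a, b = self.flow, self.pressure_ref
        if a.dt != b.dt or a.t0 != b.t0:
            raise ParameterError("flow and pressure channels must share dt and t0")


@dataclass
class EstimatorConfig:
    """Detector and averaging options shared by both estimators.

    The plausibility bands guard against pairing errors: a beat whose
    transit time or PWV falls outside them is excluded (with a reason), not
    folded into the average.  Defaults are wide enough for both a rubber
    bench tube and human arteries.
    """

    window: int = 7
    order: int = 2
    slope_window: bool = False
    slope_fraction: float = 0.5
    min_period_ms: float = 100.0
    pwv_band: tuple[float, float] = (0.5, 30.0)
    transit_band_ms: tuple[float, float] = (0.0, 100.0)
    #: beats pair across channels only within this fraction of the pulse period
    max_lag_fraction: float = 0.5
    #: cap on the number of surviving beats averaged (None = all)
    n_beats: int | None = None


@dataclass(frozen=True)
class ExcludedBeat:
    beat_index: int
    reason: str


@dataclass
class PWVEstimate:
    """An averaged PWV with its per-beat provenance.

    ``pwv`` is the arithmetic mean of the surviving per-beat values (m/s);
    ``sd`` their n−1 standard deviation (NaN for a single beat).
    """

    pwv: float
    per_beat: list[float]
    transit_times: list[float]
    distance: float
    sd: float
    excluded: list[ExcludedBeat] = field(default_factory=list)
    method: str = ""

    @property
    def n_beats(self) -> int:
        return len(self.per_beat)


def transit_time(foot_upstream: FootTime | float, foot_downstream: FootTime | float) -> float:
    """Transit time Δt (ms): downstream foot minus upstream foot.

    Accepts :class:`FootTime` objects or bare foot instants in ms.  A
    non-positive result indicates non-physical ordering and is flagged (the
    beat is excluded) by the estimators, not here.
    """
    up = foot_upstream.t_foot if isinstance(foot_upstream, FootTime) else float(foot_upstream)
    dn = foot_downstream.t_foot if isinstance(foot_downstream, FootTime) else float(foot_downstream)
    return dn - up


def pwv_from(distance: float, dt_ms: float) -> float:
    """PWV = distance / transit time; mm over ms, hence m/s."""
    if not distance > 0:
        raise ParameterError(f"distance must be positive, got {distance}")
    if not dt_ms > 0:
        raise ParameterError(f"transit time must be positive, got {dt_ms}")
    return distance / dt_ms


# ---------------------------------------------------------------------------
# beat pairing and averaging


def _pulse_period(feet: list[FootTime], fallback: float) -> float:
    if len(feet) < 2:
        return fallback
    return float(median(np.diff([f.t_foot for f in feet])))


def _pair_feet(
    feet1: list[FootTime], feet2: list[FootTime], max_lag: float
) -> tuple[list[tuple[FootTime, FootTime]], list[ExcludedBeat]]:
    """Pair each channel-1 foot with the nearest subsequent channel-2 foot.

    A foot pairs only within ``max_lag`` ms; unpaired beats are excluded
    with a reason.  Feet are consumed in order, so pairing is deterministic.
    """
    pairs: list[tuple[FootTime, FootTime]] = []
    dropped: list[ExcludedBeat] = []
    j = 0
    for f1 in feet1:
        while j < len(feet2) and feet2[j].t_foot < f1.t_foot - 1e-9:
            j += 1
        if j < len(feet2) and feet2[j].t_foot - f1.t_foot <= max_lag:
            pairs.append((f1, feet2[j]))
            j += 1
        else:
            dropped.append(
                ExcludedBeat(f1.beat_index, "unpaired: no downstream foot within max lag")
            )
    return pairs, dropped


def _screen(dtt: float, distance: float, cfg: EstimatorConfig, beat_index: int):
    """Per-beat plausibility screen; returns (pwv, None) or (None, exclusion)."""
    lo_t, hi_t = cfg.transit_band_ms
    if dtt <= lo_t:
        return None, ExcludedBeat(beat_index, f"non-physical ordering: transit {dtt:.3f} ms <= 0")
    if dtt > hi_t:
        return None, ExcludedBeat(beat_index, f"transit {dtt:.3f} ms above band {hi_t} ms")
    v = pwv_from(distance, dtt)
    lo_v, hi_v = cfg.pwv_band
    if not lo_v <= v <= hi_v:
        return None, ExcludedBeat(
            beat_index, f"PWV {v:.3f} m/s outside band [{lo_v}, {hi_v}] m/s"
        )
    return v, None


def _average(
    rows: list[tuple[int, float, float]],
    excluded: list[ExcludedBeat],
    distance: float,
    cfg: EstimatorConfig,
    method: str,
) -> PWVEstimate:
    if cfg.n_beats is not None:
        rows = rows[: cfg.n_beats]
    if not rows:
        reasons = "; ".join(f"beat {e.beat_index}: {e.reason}" for e in excluded) or "no beats found"
        raise EstimationError(f"no surviving beats ({reasons})")
    per_beat = [v for _, _, v in rows]
    transits = [t for _, t, _ in rows]
    sd = float(np.std(per_beat, ddof=1)) if len(per_beat) > 1 else float("nan")
    return PWVEstimate(
        pwv=float(np.mean(per_beat)),
        per_beat=per_beat,
        transit_times=transits,
        distance=distance,
        sd=sd,
        excluded=excluded,
        method=method,
    )


def dual_gate_pwv(rec: DualGateRecording, config: EstimatorConfig | None = None) -> PWVEstimate:
    """Local PWV from a simultaneous dual-gate recording.

    Beats are segmented and foot-detected independently on each channel,
    paired by upstroke order within half a pulse period, screened by the
    plausibility bands, and averaged.
    """
    cfg = config or EstimatorConfig()
    excluded: list[ExcludedBeat] = []
    feet = []
    for w in (rec.ch1, rec.ch2):
        beats = segment_beats(
            w, min_period=cfg.min_period_ms, slope_fraction=cfg.slope_fraction,
            window=cfg.window, order=cfg.order,
        )
        res = detect_feet(w, beats, window=cfg.window, order=cfg.order,
                          slope_window=cfg.slope_window)
        excluded.extend(
            ExcludedBeat(f.beat_index, f"{w.label or 'channel'}: {f.reason}")
            for f in res.failures
        )
        feet.append(res.feet)
    period = _pulse_period(feet[0], fallback=2 * cfg.min_period_ms)
    pairs, dropped = _pair_feet(feet[0], feet[1], max_lag=cfg.max_lag_fraction * period)
    excluded.extend(dropped)
    rows: list[tuple[int, float, float]] = []
    for f1, f2 in pairs:
        dtt = transit_time(f1, f2)
        v, exc = _screen(dtt, rec.gate_distance, cfg, f1.beat_index)
        if exc is not None:
            excluded.append(exc)
        else:
            rows.append((f1.beat_index, dtt, v))
    return _average(rows, excluded, rec.gate_distance, cfg, method="dual_gate")


def _pressure_to_flow_delays(
    rec: ReferenceDelayRecording, cfg: EstimatorConfig, tag: str
) -> tuple[list[tuple[int, float]], list[ExcludedBeat]]:
    """Per-beat delay (ms) from pressure-curve onset to flow foot."""
    excluded: list[ExcludedBeat] = []
    feet = []
    for w in (rec.pressure_ref, rec.flow):
        beats = segment_beats(
            w, min_period=cfg.min_period_ms, slope_fraction=cfg.slope_fraction,
            window=cfg.window, order=cfg.order,
        )
        res = detect_feet(w, beats, window=cfg.window, order=cfg.order,
                          slope_window=cfg.slope_window)
        excluded.extend(
            ExcludedBeat(f.beat_index, f"{tag} {w.label or 'channel'}: {f.reason}")
            for f in res.failures
        )
        feet.append(res.feet)
    period = _pulse_period(feet[0], fallback=2 * cfg.min_period_ms)
    pairs, dropped = _pair_feet(feet[0], feet[1], max_lag=cfg.max_lag_fraction * period)
    excluded.extend(
        ExcludedBeat(e.beat_index, f"{tag}: {e.reason}") for e in dropped
    )
    delays = []
    for fp, ff in pairs:
        d = transit_time(fp, ff)
        if d < 0:
            excluded.append(
                ExcludedBeat(fp.beat_index, f"{tag}: flow foot before pressure onset")
            )
        else:
            delays.append((fp.beat_index, d))
    return delays, excluded


def reference_delay_pwv(
    rec_a: ReferenceDelayRecording,
    rec_b: ReferenceDelayRecording,
    distance_ab: float,
    config: EstimatorConfig | None = None,
) -> PWVEstimate:
    """Segment PWV over A→B referenced to a shared pressure transducer.

    Per beat, PWV = Δd_AB / (Δt_B − Δt_A) where Δt is the delay from
    pressure onset to flow foot at each site; beats are matched across the
    two recordings by pressure-onset order.
    """
    if not distance_ab > 0:
        raise ParameterError(f"distance must be positive, got {distance_ab}")
    cfg = config or EstimatorConfig()
    delays_a, exc_a = _pressure_to_flow_delays(rec_a, cfg, tag="site A")
    delays_b, exc_b = _pressure_to_flow_delays(rec_b, cfg, tag="site B")
    excluded = exc_a + exc_b
    rows: list[tuple[int, float, float]] = []
    for k, ((ia, da), (_, db)) in enumerate(zip(delays_a, delays_b)):
        dtt = db - da
        v, exc = _screen(dtt, distance_ab, cfg, ia)
        if exc is not None:
            excluded.append(exc)
        else:
            rows.append((ia, dtt, v))
    if len(delays_a) != len(delays_b):
        excluded.append(
            ExcludedBeat(-1, f"{abs(len(delays_a) - len(delays_b))} beat(s) without a match "
                             "in the other recording")
        )
    return _average(rows, excluded, distance_ab, cfg, method="reference_delay")
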