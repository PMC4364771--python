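"""Wave-foot detection by the intersecting tangent method.

The foot (onset) of a pulse wave is the fiducial point used for transit
timing because it is the part of the waveform least disturbed by wave
reflections.  The intersecting tangent method defines it geometrically: draw
the tangent to the waveform at the point of maximum systolic upslope and the
horizontal line through the diastolic baseline; the foot is their
intersection,

    t_foot = t_m - (v_m - v_base) / s_m

where ``t_m`` is the time of maximum upslope, ``v_m`` the amplitude there,
``s_m`` the slope, and ``v_base`` the baseline amplitude.  The intersection
is reported at full floating-point resolution, so the foot routinely falls
between samples even on a coarse (1 ms) acquisition grid — the estimator
adds no quantization of its own.

Two deliberate numerical choices:

* the slope and amplitude at the upstroke are read from an order-2
  Savitzky–Golay fit, which reproduces a linear upstroke exactly;
* the baseline minimum is read from an order-1 (moving-average) fit.  A
  centered moving average never undershoots a convex foot, so on a beat
  whose pre-upstroke region is exactly flat the baseline is exact, whereas
  a quadratic local fit dips slightly below the corner and would bias the
  foot early by a fraction of a sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DetectionError
from .waveform import BeatSegment, SampledWaveform, derivative, smooth

__all__ = [
    "TangentFit",
    "FootTime",
    "FootFailure",
    "FootDetectionResult",
    "fit_upstroke_tangent",
    "intersecting_tangent_foot",
    "detect_feet",
]


@dataclass(frozen=True)
class TangentFit:
    """Geometry of the max-upslope tangent and the diastolic baseline.

    Attributes
    ----------
    t_m, v_m, s_m
        Time (ms), amplitude and slope (units/ms) at the maximum systolic
        upslope; ``s_m > 0``.
    v_base, t_base
        Baseline amplitude and the time (ms) at which it was read;
        ``t_base <= t_m`` and ``v_base < v_m``.
    """

    t_m: float
    v_m: float
    s_m: float
    v_base: float
    t_base: float

    def __post_init__(self) -> None:
        if not (self.s_m > 0):
            raise DetectionError(f"no systolic upstroke: max slope {self.s_m:g} <= 0")
        if not (self.v_m > self.v_base):
            raise DetectionError(
                f"no systolic upstroke: amplitude {self.v_m:g} not above baseline {self.v_base:g}"
            )
        if self.t_base > self.t_m:
            raise DetectionError("baseline read after the upstroke")


@dataclass(frozen=True)
class FootTime:
    """A sub-sample wave-foot instant and the tangent geometry behind it."""

    t_foot: float
    fit: TangentFit
    beat_index: int = -1
    #: slope at the upstroke and a local signal-to-noise summary
    quality: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FootFailure:
    beat_index: int
    reason: str


@dataclass(frozen=True)
class FootDetectionResult:
    feet: list[FootTime]
    failures: list[FootFailure]

    def foot_times(self) -> np.ndarray:
        return np.array([f.t_foot for f in self.feet])


def _shrunk(window: int, n: int) -> int:
    win = min(window, n if n % 2 else n - 1)
    if win < 3:
        raise DetectionError(f"beat too short for tangent fitting ({n} samples)")
    return win


def fit_upstroke_tangent(
    w: SampledWaveform,
    beat: BeatSegment,
    window: int = 7,
    order: int = 2,
    slope_window: bool = False,
) -> TangentFit:
    """Fit the max-upslope tangent and diastolic baseline within one beat.

    With ``slope_window=True`` the slope and its anchor point come from a
    straight-line regression over the contiguous run of samples whose
    smoothed derivative is at least 80% of the maximum, instead of the
    single max-derivative sample; this trades a little determinism of the
    anchor for robustness on noisy upstrokes.
    """
    if beat.end > w.n:
        raise DetectionError("beat window exceeds waveform length")
    seg = SampledWaveform(
        w.samples[beat.slice()], dt=w.dt, t0=w.time_at(beat.start), label=w.label
    )
    if np.ptp(seg.samples) == 0:
        raise DetectionError("no systolic upstroke: flat beat")
    win = _shrunk(window, seg.n)
    ordr = min(max(order, 1), win - 1)
    sm = smooth(seg, window=win, order=ordr).samples
    d = derivative(seg, window=win, order=ordr).samples

    idx = int(np.argmax(d))  # earliest on ties
    s_m = float(d[idx])
    if s_m <= 0:
        raise DetectionError(f"no systolic upstroke: max slope {s_m:g} <= 0")
    t = seg.times
    if slope_window:
        lo = idx
        while lo > 0 and d[lo - 1] >= 0.8 * s_m:
            lo -= 1
        hi = idx
        while hi < seg.n - 1 and d[hi + 1] >= 0.8 * s_m:
            hi += 1
        coeffs = np.polyfit(t[lo : hi + 1], sm[lo : hi + 1], 1)
        s_m = float(coeffs[0])
        t_m = float(0.5 * (t[lo] + t[hi]))
        v_m = float(np.polyval(coeffs, t_m))
        if s_m <= 0:
            raise DetectionError(f"no systolic upstroke: regression slope {s_m:g} <= 0")
    else:
        t_m = float(t[idx])
        v_m = float(sm[idx])

    # baseline: earliest minimum of the moving-average signal up to the upstroke
    base = smooth(seg, window=win, order=1).samples
    stop = max(idx, 1)
    b = int(np.argmin(base[: stop + 1]))
    v_base = float(base[b])
    t_base = float(t[b])
    return TangentFit(t_m=t_m, v_m=v_m, s_m=s_m, v_base=v_base, t_base=t_base)


def intersecting_tangent_foot(
    fit: TangentFit, beat_index: int = -1, snr: float = math.nan
) -> FootTime:
    """Foot time from the tangent/baseline intersection closed form."""
    t_foot = fit.t_m - (fit.v_m - fit.v_base) / fit.s_m
    clamped = False
    if t_foot < fit.t_base:
        t_foot = fit.t_base
        clamped = True
    return FootTime(
        t_foot=float(t_foot),
        fit=fit,
        beat_index=beat_index,
        quality={"slope": fit.s_m, "snr": snr, "clamped": clamped},
    )


def detect_feet(
    w: SampledWaveform,
    beats: list[BeatSegment],
    window: int = 7,
    order: int = 2,
    slope_window: bool = False,
) -> FootDetectionResult:
    """Run the intersecting tangent method on every beat of a segmentation.

    Per-beat detection failures are recorded in the result, not raised, so a
    single flat or artefactual beat does not abort a recording.
    """
    feet: list[FootTime] = []
    failures: list[FootFailure] = []
    for i, beat in enumerate(beats):
        try:
            fit = fit_upstroke_tangent(w, beat, window=window, order=order,
                                       slope_window=slope_window)
        except DetectionError as exc:
            failures.append(FootFailure(beat_index=i, reason=str(exc)))
            continue
        raw = w.samples[beat.slice()]
        seg = SampledWaveform(raw, dt=w.dt, t0=w.time_at(beat.start))
        win = _shrunk(window, seg.n)
        resid = raw - smooth(seg, window=win, order=min(max(order, 1), win - 1)).samples
        resid_sd = float(np.std(resid))
        snr = (fit.v_m - fit.v_base) / resid_sd if resid_sd > 0 else math.inf
        feet.append(intersecting_tangent_foot(fit, beat_index=i, snr=snr))
    return FootDetectionResult(feet=feet, failures=failures)
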