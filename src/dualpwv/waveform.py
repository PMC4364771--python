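"""Uniformly sampled waveforms and the pre-processing they share downstream.

The carrier type is :class:`SampledWaveform`: a 1-D amplitude array on a
strictly uniform time grid.  Internal units are fixed throughout the
package — time in milliseconds, distance in millimetres — so a velocity of
1 mm/ms is exactly 1 m/s and transit-time arithmetic needs no conversion
factors.

Smoothing and differentiation use local polynomial (Savitzky–Golay) fits,
which reproduce constants and straight lines exactly; that exactness is what
makes the intersecting-tangent foot detector downstream exact on
piecewise-linear beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .errors import FormatError, ParameterError

__all__ = [
    "SampledWaveform",
    "BeatSegment",
    "read_waveform",
    "read_channels",
    "write_waveform",
    "write_channels",
    "smooth",
    "derivative",
    "segment_beats",
]

#: Relative tolerance for declaring a time column uniformly sampled.
UNIFORM_RTOL = 1e-6


@dataclass(eq=False)
class SampledWaveform:
    """A uniformly sampled 1-D signal.

    Parameters
    ----------
    samples
        Amplitude values in channel units (e.g. velocity in cm/s, pressure
        in a.u.).
    dt
        Sampling interval in milliseconds; must be positive.
    t0
        Time of the first sample in milliseconds.
    label
        Free-text channel name.
    """

    samples: np.ndarray
    dt: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ParameterError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ParameterError("a waveform needs at least 2 samples")
        if not np.isfinite(self.dt) or self.dt <= 0:
            raise ParameterError(f"dt must be positive, got {self.dt!r}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        """Time of every sample: ``t0 + i * dt``, in ms."""
        return self.t0 + np.arange(self.n) * self.dt

    def time_at(self, index: int) -> float:
        return self.t0 + index * self.dt

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "SampledWaveform":
        """Copy carrying new samples on the same time grid."""
        return replace(self, samples=samples, label=self.label if label is None else label)

    def shifted(self, delta_ms: float) -> "SampledWaveform":
        return replace(self, t0=self.t0 + delta_ms)


@dataclass(frozen=True)
class BeatSegment:
    """Half-open sample-index window ``[start, end)`` holding one pulse cycle.

    ``upstroke_index`` marks the sample of maximum systolic upslope inside
    the window.
    """

    start: int
    end: int
    upstroke_index: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.upstroke_index < self.end):
            raise ParameterError(
                f"invalid beat window: start={self.start}, "
                f"upstroke={self.upstroke_index}, end={self.end}"
            )

    def slice(self) -> slice:
        return slice(self.start, self.end)


# ---------------------------------------------------------------------------
# delimited-text I/O


def _read_table(path) -> pd.DataFrame:
    """Read a comma- or tab-delimited table with a header row."""
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: cannot parse delimited text ({exc})") from exc
    return df

def _uniform_dt(t: np.ndarray, path) -> float:
    """Validate a strictly increasing, constant-step time column; return the step."""
    if t.size < 2:
        raise FormatError(f"{path}: need at least 2 rows")
    steps = np.diff(t)
    ref = steps[0]
    if ref <= 0:
        raise FormatError(f"{path}: time not strictly increasing at data row 2")
    bad = np.nonzero(np.abs(steps - ref) > UNIFORM_RTOL * abs(ref))[0]
    if bad.size:
        # +2: one for the step index offset, one for 1-based data rows
        raise FormatError(
            f"{path}: non-uniform time step at data row {bad[0] + 2} "
            f"(step {steps[bad[0]]:g} ms, expected {ref:g} ms)"
        )
    return float(ref)


def read_waveform(path, column: str | None = None, time_column: str = "t_ms") -> SampledWaveform:
    """Read one channel of a delimited-text waveform file.

    The file must have a header row, a ``t_ms`` time column with a constant
    positive step, and at least one amplitude column.  ``column`` selects the
    amplitude column; by default the first non-time column is used.
    """
    df = _read_table(path)
    if time_column not in df.columns:
        raise FormatError(f"{path}: missing time column {time_column!r}")
    if column is None:
        others = [c for c in df.columns if c != time_column]
        if not others:
            raise FormatError(f"{path}: no amplitude column")
        column = others[0]
    elif column not in df.columns:
        raise FormatError(f"{path}: missing column {column!r}")
    t = df[time_column].to_numpy(dtype=float)
    dt = _uniform_dt(t, path)
    return SampledWaveform(df[column].to_numpy(dtype=float), dt=dt, t0=float(t[0]), label=str(column))


def read_channels(path, time_column: str = "t_ms") -> dict[str, SampledWaveform]:
    """Read every amplitude column of a waveform file, keyed by header name."""
    df = _read_table(path)
    if time_column not in df.columns:
        raise FormatError(f"{path}: missing time column {time_column!r}")
    t = df[time_column].to_numpy(dtype=float)
    dt = _uniform_dt(t, path)
    out: dict[str, SampledWaveform] = {}
    for c in df.columns:
        if c == time_column:
            continue
        out[c] = SampledWaveform(df[c].to_numpy(dtype=float), dt=dt, t0=float(t[0]), label=str(c))
    if not out:
        raise FormatError(f"{path}: no amplitude column")
    return out


def write_channels(path, channels: list[SampledWaveform], time_column: str = "t_ms",
                   fmt: str = "%.6f") -> None:
    """Write waveforms sharing one grid as a comma-delimited file.

    Numeric formatting is fixed so identical inputs give byte-identical files.
    """
    first = channels[0]
    for w in channels[1:]:
        if w.n != first.n or w.dt != first.dt or w.t0 != first.t0:
            raise ParameterError("all channels must share the same time grid")
    names = [w.label or f"ch{i + 1}" for i, w in enumerate(channels)]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join([time_column] + names) + "\n")
        cols = [first.times] + [w.samples for w in channels]
        for row in zip(*cols):
            fh.write(",".join(fmt % v for v in row) + "\n")


def write_waveform(w: SampledWaveform, path, **kw) -> None:
    """Write a single waveform; see :func:`write_channels`."""
    write_channels(path, [w], **kw)


# ---------------------------------------------------------------------------
# smoothing and differentiation


def _check_savgol(window: int, order: int, n: int) -> None:
    if window % 2 == 0 or window < 3:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    if window > n:
        raise ParameterError(f"window {window} exceeds signal length {n}")
    if not (0 <= order < window):
        raise ParameterError(f"order must satisfy 0 <= order < window, got {order}")


def smooth(w: SampledWaveform, window: int = 7, order: int = 2) -> SampledWaveform:
    """Local-polynomial (Savitzky–Golay) smoothing.

    Constants and, for ``order >= 1``, straight lines pass through
    unchanged; ``dt`` and ``t0`` are preserved.  Edges are handled by scipy's
    polynomial-extension policy, which keeps those exactness guarantees at
    the boundaries.
    """
    _check_savgol(window, order, w.n)
    y = savgol_filter(w.samples, window, order, mode="interp")
    return w.with_samples(y)


def derivative(w: SampledWaveform, window: int = 7, order: int = 2) -> SampledWaveform:
    """Smoothed first derivative, in amplitude units per millisecond."""
    _check_savgol(window, order, w.n)
    if order < 1:
        raise ParameterError("derivative needs polynomial order >= 1")
    y = savgol_filter(w.samples, window, order, deriv=1, delta=w.dt, mode="interp")
    return w.with_samples(y, label=f"d({w.label})/dt" if w.label else "")


# ---------------------------------------------------------------------------
# beat segmentation


def segment_beats(
    w: SampledWaveform,
    min_period: float = 100.0,
    slope_fraction: float = 0.5,
    window: int = 7,
    order: int = 2,
) -> list[BeatSegment]:
    """Split a pulse train into single-beat windows.

    Candidate upstrokes are local maxima of the smoothed derivative that
    exceed ``slope_fraction`` of the global maximum slope and are separated
    by at least ``min_period`` ms.  Each segment runs from the pre-upstroke
    minimum of the smoothed signal to the pre-upstroke minimum of the next
    beat (the last segment runs to the end of the record).  A flat record
    yields an empty list.
    """
    if min_period <= 0:
        raise ParameterError(f"min_period must be positive, got {min_period}")
    if not 0 < slope_fraction <= 1:
        raise ParameterError(f"slope_fraction must be in (0, 1], got {slope_fraction}")
    win = min(window, w.n if w.n % 2 else w.n - 1)
    if win < 3:
        return []
    ordr = min(max(order, 1), win - 1)
    d = derivative(w, window=win, order=ordr).samples
    s = smooth(w, window=win, order=ordr).samples
    smax = float(d.max())
    if smax <= 0:
        return []
    spacing = max(1, int(round(min_period / w.dt)))
    upstrokes, _ = find_peaks(d, height=slope_fraction * smax, distance=spacing)
    if upstrokes.size == 0:
        return []
    # pre-upstroke minimum: earliest argmin of the smoothed signal between
    # the previous upstroke (or record start) and this upstroke
    starts = []
    prev = 0
    for p in upstrokes:
        starts.append(prev + int(np.argmin(s[prev : p + 1])))
        prev = int(p)
    segments: list[BeatSegment] = []
    for j, p in enumerate(upstrokes):
        start = starts[j]
        end = starts[j + 1] if j + 1 < len(upstrokes) else w.n
        if start < p < end:
            segments.append(BeatSegment(start=start, end=end, upstroke_index=int(p)))
    return segments
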