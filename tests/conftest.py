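import numpy as np
import pytest

from dualpwv.simulate import PulseShape, bench_scenario, simulate
from dualpwv.waveform import BeatSegment, SampledWaveform


@pytest.fixture(scope="session")
def bench_result():
    """One bench-default simulated session (10 beats, 1 ms, 1% noise)."""
    return simulate(bench_scenario(seed=7))


@pytest.fixture(scope="session")
def pump_shape():
    return PulseShape(upstroke_ms=30.0, decay_ms=60.0, amplitude=50.0)


def ramp_beat(kink_ms=100.0, slope=1.0, baseline=0.0, n=300, dt=1.0, t0=0.0):
    """Piecewise-linear beat: flat baseline, then a linear upstroke from the kink.

    The intersecting-tangent foot of this beat is the kink, exactly.
    """
    t = t0 + np.arange(n) * dt
    v = baseline + slope * np.clip(t - (t0 + kink_ms), 0.0, None)
    w = SampledWaveform(v, dt=dt, t0=t0, label="ramp")
    beat = BeatSegment(start=0, end=n, upstroke_index=n // 2)
    return w, beat
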