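import numpy as np
import pytest

from dualpwv.errors import ParameterError
from dualpwv.foot import detect_feet
from dualpwv.pwv import dual_gate_pwv
from dualpwv.simulate import (
    PulseShape,
    SimScenario,
    TubeModel,
    bench_scenario,
    carotid_scenario,
    moens_korteweg,
    propagate,
    pulse_template,
    simulate,
)
from dualpwv.waveform import segment_beats


class TestMoensKorteweg:
    def test_hand_value(self):
        # E=400 kPa, h=1 mm, r=3.5 mm, rho=1000 kg/m^3
        v = moens_korteweg(400e3, 1e-3, 3.5e-3, 1000.0)
        assert v == pytest.approx(np.sqrt(400e3 * 1e-3 / (2 * 3.5e-3 * 1000.0)))
        assert v == pytest.approx(7.559, abs=0.001)

    def test_sqrt_scaling_in_E(self):
        assert moens_korteweg(4e5, 1e-3, 3e-3, 1000) == pytest.approx(
            2 * moens_korteweg(1e5, 1e-3, 3e-3, 1000)
        )

    def test_h_r_ratio_invariance(self):
        a = moens_korteweg(2e5, 1e-3, 3e-3, 1000)
        b = moens_korteweg(2e5, 2e-3, 6e-3, 1000)
        assert a == pytest.approx(b)

    def test_monotonic(self):
        base = moens_korteweg(2e5, 1e-3, 3e-3, 1000)
        assert moens_korteweg(3e5, 1e-3, 3e-3, 1000) > base
        assert moens_korteweg(2e5, 2e-3, 3e-3, 1000) > base
        assert moens_korteweg(2e5, 1e-3, 4e-3, 1000) < base
        assert moens_korteweg(2e5, 1e-3, 3e-3, 1100) < base

    @pytest.mark.parametrize("args", [(0, 1, 1, 1), (1, -1, 1, 1), (1, 1, 0, 1), (1, 1, 1, 0)])
    def test_nonpositive_rejected(self, args):
        with pytest.raises(ParameterError):
            moens_korteweg(*args)

    def test_tube_requires_one_speed_source(self):
        with pytest.raises(ParameterError):
            TubeModel(length_mm=100.0)


class TestPulseTemplate:
    def test_peak_equals_amplitude(self, pump_shape):
        w = pulse_template(pump_shape, dt=0.5, duration_ms=300.0, onset_ms=50.0)
        assert w.samples.max() == pytest.approx(pump_shape.amplitude)

    def test_zero_before_onset(self, pump_shape):
        w = pulse_template(pump_shape, dt=1.0, duration_ms=300.0, onset_ms=97.3)
        assert np.all(w.samples[w.times < 97.3] == 0.0)

    def test_tangent_foot_matches_analytic_offset(self, pump_shape):
        from dualpwv.foot import fit_upstroke_tangent, intersecting_tangent_foot
        from dualpwv.waveform import BeatSegment

        onset = 100.0
        w = pulse_template(pump_shape, dt=1.0, duration_ms=300.0, onset_ms=onset)
        beat = BeatSegment(0, w.n, upstroke_index=int(onset + 15))
        foot = intersecting_tangent_foot(fit_upstroke_tangent(w, beat)).t_foot
        assert abs(foot - (onset + pump_shape.tangent_foot_offset_ms)) <= w.dt


class TestPropagate:
    def test_zero_distance_identity(self, pump_shape):
        tube = TubeModel(length_mm=100.0, pwv_true=5.0)
        w = pulse_template(pump_shape, dt=1.0, duration_ms=200.0, onset_ms=50.0)
        assert np.allclose(propagate(w, 20.0, 20.0, tube).samples, w.samples)

    def test_delay_matches_distance_over_speed(self, pump_shape):
        tube = TubeModel(length_mm=100.0, pwv_true=5.0)
        w = pulse_template(pump_shape, dt=0.1, duration_ms=300.0, onset_ms=50.0)
        out = propagate(w, 10.0, 50.0, tube)  # 40 mm at 5 m/s -> 8 ms
        expected = pulse_template(pump_shape, dt=0.1, duration_ms=300.0, onset_ms=58.0)
        assert np.allclose(out.samples, expected.samples, atol=1e-3 * pump_shape.amplitude)

    def test_long_baseline_delay(self, pump_shape):
        # 389.3 mm at 5.24 m/s is a 74.3 ms transit at 0.1 ms rounding
        tube = TubeModel(length_mm=400.0, pwv_true=5.24)
        delay = 389.3 / tube.pwv
        assert round(delay, 1) == 74.3

    def test_position_outside_tube(self, pump_shape):
        tube = TubeModel(length_mm=100.0, pwv_true=5.0)
        w = pulse_template(pump_shape, dt=1.0, duration_ms=200.0)
        with pytest.raises(ParameterError):
            propagate(w, 0.0, 150.0, tube)

    def test_attenuation(self, pump_shape):
        tube = TubeModel(length_mm=100.0, pwv_true=5.0, attenuation_per_mm=0.01)
        w = pulse_template(pump_shape, dt=1.0, duration_ms=200.0, onset_ms=20.0)
        out = propagate(w, 0.0, 50.0, tube)
        assert out.samples.max() == pytest.approx(0.99**50 * pump_shape.amplitude, rel=1e-3)


class TestSimulate:
    def test_metadata_truth(self):
        res = simulate(bench_scenario(seed=0, gate_positions=(100.0, 140.0)))
        assert res.truth.gate_distance_mm == pytest.approx(40.0)
        assert res.truth.transit_ms == pytest.approx(8.0)
        assert res.recording.gate_distance == pytest.approx(40.0)

    def test_same_seed_bit_identical(self):
        a = simulate(bench_scenario(seed=123))
        b = simulate(bench_scenario(seed=123))
        assert np.array_equal(a.recording.ch1.samples, b.recording.ch1.samples)
        assert np.array_equal(a.recording.ch2.samples, b.recording.ch2.samples)
        for lab in ("A", "B"):
            assert np.array_equal(a.references[lab].pressure_ref.samples,
                                  b.references[lab].pressure_ref.samples)

    def test_different_seed_differs(self):
        a = simulate(bench_scenario(seed=1))
        b = simulate(bench_scenario(seed=2))
        assert not np.array_equal(a.recording.ch1.samples, b.recording.ch1.samples)

    def test_fine_grid_noise_free_recovery(self):
        res = simulate(bench_scenario(seed=5, noise_sd=0.0, dt_ms=0.01))
        est = dual_gate_pwv(res.recording)
        assert abs(est.pwv - 5.0) <= 0.005

    def test_ground_truth_foot_delay_fine_grid(self):
        """Noise-free fine-grid foot-to-foot delay equals distance/pwv_true
        within 2 fine-grid samples."""
        res = simulate(bench_scenario(seed=5, noise_sd=0.0, dt_ms=0.01, n_beats=3))
        feet = []
        for w in (res.recording.ch1, res.recording.ch2):
            r = detect_feet(w, segment_beats(w))
            feet.append(r.foot_times())
        delays = feet[1][: len(feet[0])] - feet[0][: len(feet[1])]
        assert np.all(np.abs(delays - res.truth.transit_ms) <= 2 * 0.01)

    def test_averaging_reduces_quantization_spread(self):
        """Per-beat estimates scatter much more than 10-beat averages."""
        per_beat, means = [], []
        for s in range(30):
            est = dual_gate_pwv(simulate(bench_scenario(seed=700 + s)).recording)
            per_beat.extend(est.per_beat)
            means.append(est.pwv)
        assert np.std(means, ddof=1) < 0.5 * np.std(per_beat, ddof=1)

    def test_carotid_scenario_runs(self):
        res = simulate(carotid_scenario(seed=3))
        est = dual_gate_pwv(res.recording)
        assert abs(est.pwv - 5.3) <= 0.7

    @pytest.mark.parametrize(
        "override",
        [dict(gate_positions=(10.0, 10.0)), dict(pulse_rate_hz=0.0),
         dict(pulse_rate_hz=6.0), dict(dt_ms=0.0), dict(noise_sd=-0.1),
         dict(gate_positions=(10.0, 900.0))],
    )
    def test_invalid_scenarios(self, override):
        with pytest.raises(ParameterError):
            SimScenario(tube=TubeModel(length_mm=450.0, pwv_true=5.0), **override)

    def test_shape_validation(self):
        with pytest.raises(ParameterError):
            PulseShape(upstroke_ms=0.0)
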