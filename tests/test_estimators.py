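"""Estimators: amplitudes, cubic E_GABA intercept, slopes, IE, curve fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendrinh.engine import Trace
from dendrinh.estimators import (EstimationError, IVDataset, discharge_probability,
                                 fit_egaba, fit_ie_exponential, fit_sigmoid,
                                 inhibitory_effect, iv_slope, peak_amplitude)
from dendrinh.model import SynapseSpec, synapse_peak_time, synapse_waveform


def make_trace(values, dt=0.1):
    return Trace(dt, 0.0, np.asarray(values, float), 0, "voltage")


class TestPeakAmplitude:
    def test_flat_trace(self):
        tr = make_trace(np.full(2000, -65.0))
        assert peak_amplitude(tr, (0, 50), (60, 150)) == 0.0

    def test_double_exponential_peak_recovered(self):
        dt = 0.01
        t = np.arange(0, 200, dt)
        s = SynapseSpec(0, 2.7, 0.5, 30.0, 0.0, (60.0,))
        tr = make_trace(-65.0 + synapse_waveform(s, t), dt=dt)
        amp = peak_amplitude(tr, (0, 59.9), (60, 199), "positive")
        assert amp == pytest.approx(2.7, abs=1e-6)

    def test_auto_polarity_negative(self):
        dt = 0.1
        t = np.arange(0, 300, dt)
        s = SynapseSpec(0, 1.6, 5.0, 60.0, 0.0, (60.0,))
        tr = make_trace(-65.0 - synapse_waveform(s, t), dt=dt)
        amp = peak_amplitude(tr, (0, 59.9), (60, 299), "auto")
        assert amp == pytest.approx(-1.6, abs=1e-4)

    def test_window_ordering_enforced(self):
        tr = make_trace(np.zeros(1000))
        with pytest.raises(ValueError):
            peak_amplitude(tr, (0, 60), (50, 90))


class TestFitEgaba:
    def test_noiseless_linear_crossing(self):
        vh = np.arange(-90.0, -39.0, 5.0)
        data = IVDataset(vh, 0.2 * (vh + 65.0), "mv")
        assert fit_egaba(data) == pytest.approx(-65.0, abs=0.01)

    def test_cubic_distortion_still_recovers_intercept(self):
        vh = np.arange(-90.0, -39.0, 5.0)
        drive = vh + 57.9
        data = IVDataset(vh, 10 * drive + 0.01 * drive ** 3, "pa")
        assert fit_egaba(data) == pytest.approx(-57.9, abs=0.05)

    def test_same_sign_amplitudes_error(self):
        vh = np.arange(-90.0, -39.0, 5.0)
        with pytest.raises(EstimationError):
            fit_egaba(IVDataset(vh, np.full_like(vh, 5.0) + 0.01 * (vh + 90),
                                "pa"))

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_egaba(IVDataset([-70, -60, -50], [1, 2, 3], "pa"))
        with pytest.raises(ValueError):
            fit_egaba(IVDataset([-70, -65, -60, -61], [1, 2, 3, 4], "pa"))


class TestIvSlope:
    def test_exact_line(self):
        vh = np.arange(-90.0, -49.0, 5.0)
        data = IVDataset(vh, 10.0 * (vh + 65.0), "pa")
        slope, r2 = iv_slope(data)
        assert slope == pytest.approx(10.0)
        assert r2 == pytest.approx(1.0)

    def test_na_unit_conversion(self):
        vh = np.arange(-90.0, -49.0, 5.0)
        slope, _ = iv_slope(IVDataset(vh, 0.01 * (vh + 65.0), "na"))
        assert slope == pytest.approx(10.0)

    def test_degenerate(self):
        with pytest.raises(ValueError):
            iv_slope(IVDataset([-70.0, -70.0], [1.0, 2.0], "pa"))
        with pytest.raises(ValueError):
            iv_slope(IVDataset([-70.0, -60.0], [1.0, 2.0], "mv"))


class TestInhibitoryEffect:
    @pytest.mark.parametrize("epsp, psp, expected", [
        (5.0, 5.0, 0.0),
        (10.0, 6.1, 0.39),
        (10.0, 10.1, -0.01),
    ])
    def test_examples(self, epsp, psp, expected):
        assert inhibitory_effect(epsp, psp).ie == pytest.approx(expected)

    @given(epsp=st.floats(0.1, 30.0), ratio=st.floats(-0.5, 1.5),
           scale=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, epsp, ratio, scale):
        psp = ratio * epsp
        a = inhibitory_effect(epsp, psp).ie
        b = inhibitory_effect(scale * epsp, scale * psp).ie
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)

    def test_requires_positive_epsp(self):
        with pytest.raises(ValueError):
            inhibitory_effect(0.0, 1.0)


class TestFitIeExponential:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        a = np.linspace(1.0, 25.0, 30)
        ie = 0.05 + 0.6 * np.exp(-a / 6.0) + rng.normal(0, 0.02, a.size)
        fit = fit_ie_exponential(np.column_stack([a, ie]))
        assert fit["offset"] == pytest.approx(0.05, abs=0.05)
        assert fit["A"] == pytest.approx(0.6, rel=0.15)
        assert fit["lam_mv"] == pytest.approx(6.0, rel=0.15)
        assert fit["grid_mv"][0] == 1.0 and fit["grid_mv"][-1] == 25.0

    def test_constant_data(self):
        a = np.linspace(1.0, 20.0, 10)
        fit = fit_ie_exponential(np.column_stack([a, np.full(10, 0.3)]))
        assert abs(fit["A"]) < 0.05
        assert fit["offset"] == pytest.approx(0.3, abs=0.05)

    def test_increasing_data_negative_amplitude(self):
        a = np.linspace(1.0, 20.0, 12)
        ie = 0.5 - 0.4 * np.exp(-a / 5.0)
        fit = fit_ie_exponential(np.column_stack([a, ie]))
        assert fit["A"] < 0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_ie_exponential([(1, 0.1), (2, 0.2), (3, 0.3)])


class TestFitSigmoid:
    def test_exact_recovery(self):
        g = np.linspace(0, 20, 15)
        p = 0.95 / (1 + np.exp(-(g - 8.0) / 1.5))
        fit = fit_sigmoid(np.column_stack([g, p]))
        assert not fit["degenerate"]
        assert fit["p_max"] == pytest.approx(0.95, rel=0.01)
        assert fit["g_half_ns"] == pytest.approx(8.0, rel=0.01)
        assert fit["slope_ns"] == pytest.approx(1.5, rel=0.01)

    def test_all_zero_flagged(self):
        fit = fit_sigmoid([(g, 0.0) for g in range(6)])
        assert fit["degenerate"]

    def test_translation_moves_g_half(self):
        g = np.linspace(0, 20, 15)
        p = 1.0 / (1 + np.exp(-(g - 6.0) / 1.5))
        p_shift = 1.0 / (1 + np.exp(-(g - 10.0) / 1.5))
        f1 = fit_sigmoid(np.column_stack([g, p]))
        f2 = fit_sigmoid(np.column_stack([g, p_shift]))
        assert f2["g_half_ns"] > f1["g_half_ns"]


class TestDischargeProbability:
    def _result(self, times):
        from dendrinh.engine import SimulationResult
        tr = Trace(0.1, 0.0, np.full(100, -65.0), 0, "voltage")
        return SimulationResult([tr], {0: times}, {})

    def test_counts(self):
        results = [self._result(ts) for ts in ([10.0], [11.0], [], [12.0])]
        stats = discharge_probability(results)
        assert stats["spikes_per_trial"] == pytest.approx(0.75)
        assert stats["p_any_spike"] == pytest.approx(0.75)
        assert stats["n_trials"] == 4

    def test_multiple_spikes_per_trial_and_window(self):
        results = [self._result([5.0, 10.0, 30.0]), self._result([])]
        stats = discharge_probability(results, window_ms=(0.0, 20.0))
        assert stats["spikes_per_trial"] == pytest.approx(1.0)
        assert stats["p_any_spike"] == pytest.approx(0.5)

    def test_matches_hand_count(self):
        rng = np.random.default_rng(3)
        rasters = [sorted(rng.uniform(0, 100, rng.integers(0, 5)))
                   for _ in range(20)]
        stats = discharge_probability([self._result(list(r)) for r in rasters])
        assert stats["spikes_per_trial"] == pytest.approx(
            sum(len(r) for r in rasters) / 20)
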