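"""Engine: cable-equation oracles, clamps, measurements, spike detection."""

import math

import numpy as np
import pytest

from dendrinh.engine import (Trace, detect_spikes, find_holding_current,
                             integrate, measure_rin, nernst_potential,
                             resting_potential, steady_state_input_resistance,
                             voltage_clamp_run)
from dendrinh.model import (ChannelDensities, ClampSpec, EGabaSpec, GGabaSpec,
                            GradientSpec, NoiseSpec, PassiveProfile, RmSpec,
                            SynapseSpec, CellModel)
from dendrinh.morphology import MaxSegLength, discretize

from conftest import straight_cable


def make_cell(morph, r_m=10.0, c_m=0.9, r_a=170.0, e_leak=-70.0,
              max_seg=5.0, with_ih=False):
    """Passive cell with uniform R_m; Ih off unless requested."""
    seg = discretize(morph, MaxSegLength(max_seg))
    passive = PassiveProfile(r_a, {"all": c_m},
                             RmSpec("exponential_gradient", r_m, r_m, 5.0))
    channels = ChannelDensities({"soma": 0.0, "axon": 0.0, "dendrite": 0.0},
                                0.0, 1.0 if with_ih else 0.0)
    gradients = GradientSpec(EGabaSpec(uniform_mv=-70.0),
                             GGabaSpec(uniform_ns=10.0))
    return CellModel(seg, passive, channels, gradients, "custom",
                     e_leak_mv=e_leak, v_init_mv=e_leak)


def single_compartment(r_m=10.0, c_m=0.9, size_um=15.0):
    return make_cell(straight_cable(1, 1e-7, 1e-4, soma_radius_um=size_um / 2),
                     r_m=r_m, c_m=c_m)


class TestMembraneCharging:
    def test_tau_m_is_rm_cm(self):
        """PVI somatic values: tau_m = 10 kOhm*cm^2 * 0.9 uF/cm^2 = 9 ms."""
        cell = single_compartment(r_m=10.0, c_m=0.9)
        clamp = ClampSpec("current", i_hold_pa=0.0, schedule=((10.0, 50.0),))
        res = integrate(cell, [clamp], dt_ms=0.01, duration_ms=110.0,
                        record_sites=(0,))
        v = res.trace(0)
        v_inf = v.window(100.0, 109.9).mean() + 70.0
        v_tau = float(v.window(10.0 + 9.0, 10.0 + 9.0)[0]) + 70.0
        assert v_tau / v_inf == pytest.approx(1.0 - math.exp(-1.0), rel=0.01)

    def test_passive_linearity(self):
        cell = single_compartment()
        deflections = []
        for i_pa in (20.0, 40.0):
            clamp = ClampSpec("current", i_hold_pa=0.0, schedule=((5.0, i_pa),))
            res = integrate(cell, [clamp], dt_ms=0.025, duration_ms=100.0,
                            record_sites=(0,))
            deflections.append(res.trace(0).values[-1] + 70.0)
        assert deflections[1] == pytest.approx(2 * deflections[0], rel=1e-3)

    def test_charge_balance_sealed_cell(self):
        # with R_m enormous the injected charge equals sum(C dV)
        cell = make_cell(straight_cable(20, 10.0, 1.0), r_m=1e6)
        i_pa, t_on, t_off = 100.0, 5.0, 45.0
        clamp = ClampSpec("current", i_hold_pa=0.0,
                          schedule=((t_on, i_pa), (t_off, 0.0)))
        res = integrate(cell, [clamp], dt_ms=0.01, duration_ms=200.0,
                        record_sites=(0,))
        dv = res.trace(0).values[-1] + 70.0    # all compartments equilibrate
        q_injected = i_pa * 1e-3 * (t_off - t_on)     # nA*ms = pC
        q_stored = cell.c_nf.sum() * dv               # nF*mV = pC
        assert q_stored == pytest.approx(q_injected, rel=5e-3)


class TestCableOracles:
    def test_steady_state_cosh_attenuation(self):
        """Sealed uniform cable: V(x) = V(0) cosh((L-x)/lam)/cosh(L/lam)."""
        n, spacing, radius = 500, 1.0, 1.0
        cell = make_cell(straight_cable(n, spacing, radius,
                                        soma_radius_um=radius),
                         r_m=10.0, c_m=0.9, r_a=170.0, max_seg=1.0)
        # inject at the distal end, read the attenuation toward the soma end
        distal = cell.cell.n - 1
        clamp = ClampSpec("current", site=distal, i_hold_pa=50.0)
        sites = [distal, cell.cell.locate(250.0, primary=0), 0]
        res = integrate(cell, [clamp], dt_ms=0.025, duration_ms=300.0,
                        record_sites=sites)
        lam_um = math.sqrt(10.0e3 * (2 * radius * 1e-4) / (4 * 170.0)) * 1e4
        L = n * spacing
        v_end = res.trace(distal).values[-1] + 70.0

        def theory(x_from_injection):
            return (math.cosh((L - x_from_injection) / lam_um)
                    / math.cosh(L / lam_um))

        for site in sites[1:]:
            x = L - float(cell.cell.path_distance_um[site])
            v = res.trace(site).values[-1] + 70.0
            assert v / v_end == pytest.approx(theory(x), rel=0.01)

    def test_passive_reciprocity(self, pvi_passive):
        """Transfer resistance soma->dendrite equals dendrite->soma."""
        cell = pvi_passive.passive_variant(drop_ih=True)
        dend = cell.cell.locate(200.0, primary=1)
        i_pa = 20.0

        def steady(inj_site, rec_site):
            clamp = ClampSpec("current", site=inj_site, i_hold_pa=i_pa)
            res = integrate(cell, [clamp], dt_ms=0.05, duration_ms=900.0,
                            record_sites=(rec_site,))
            return res.trace(rec_site).values[-1] - cell.e_leak_mv

        assert steady(0, dend) == pytest.approx(steady(dend, 0), rel=1e-3)

    def test_dt_convergence(self):
        cell = make_cell(straight_cable(40, 10.0, 1.0))
        syn = SynapseSpec(cell.cell.locate(200.0, primary=0), 5.0, 0.1, 8.0,
                          0.0, (10.0,))
        peaks = []
        for dt in (0.05, 0.025):
            res = integrate(cell, [syn], dt_ms=dt, duration_ms=60.0,
                            record_sites=(0,))
            peaks.append(res.trace(0).values.max())
        assert peaks[0] == pytest.approx(peaks[1], rel=5e-3)


class TestVoltageClamp:
    def test_peak_current_ideal_clamp(self):
        """Negligible leak, R_s = 0: peak I = g (V_h - E) = -0.100 nA."""
        cell = make_cell(straight_cable(1, 1e-7, 1e-4, soma_radius_um=2.5),
                         r_m=1e5)
        syn = SynapseSpec(0, 10.0, 0.1, 20.0, -60.0, (50.0,))
        clamp = ClampSpec("voltage", v_h_mv=-70.0, r_s_mohm=0.0)
        tr = voltage_clamp_run(cell, clamp, syn, dt_ms=0.01,
                               duration_ms=120.0, baseline_subtract=True)
        assert tr.values.min() == pytest.approx(-0.100, rel=0.01)

    def test_series_resistance_two_resistor_oracle(self):
        cell = make_cell(straight_cable(1, 1e-7, 1e-4, soma_radius_um=2.5),
                         r_m=1e5)
        syn = SynapseSpec(0, 10.0, 0.1, 20.0, -60.0, (50.0,))
        peaks = {}
        for rs in (0.0, 10.0):
            clamp = ClampSpec("voltage", v_h_mv=-70.0, r_s_mohm=rs)
            tr = voltage_clamp_run(cell, clamp, syn, dt_ms=0.01,
                                   duration_ms=120.0, baseline_subtract=True)
            peaks[rs] = tr.values.min()
        assert abs(peaks[10.0]) < abs(peaks[0.0])
        # I = g (V_h - E) / (1 + g R_s): 10 nS * -10 mV / 1.1
        assert peaks[10.0] == pytest.approx(-0.1 / 1.1, rel=0.01)

    def test_clamp_at_reversal_gives_zero(self):
        cell = make_cell(straight_cable(1, 1e-7, 1e-4, soma_radius_um=2.5),
                         r_m=1e5)
        syn = SynapseSpec(0, 10.0, 0.1, 20.0, -60.0, (50.0,))
        clamp = ClampSpec("voltage", v_h_mv=-60.0, r_s_mohm=0.0)
        tr = voltage_clamp_run(cell, clamp, syn, dt_ms=0.01,
                               duration_ms=120.0, baseline_subtract=True)
        assert abs(tr.values).max() < 1e-3    # < 1 pA


class TestMeasurements:
    def test_rin_isolated_compartment(self):
        cell = single_compartment(r_m=10.0, size_um=15.0)
        area_cm2 = math.pi * 15e-4 * 15e-4
        expected = 10.0e3 / area_cm2 * 1e-6   # Ohm -> MOhm
        assert measure_rin(cell, settle_ms=100.0, pulse_ms=200.0) \
            == pytest.approx(expected, rel=1e-3)
        assert steady_state_input_resistance(cell) \
            == pytest.approx(expected, rel=1e-3)

    def test_pulse_protocol_matches_steady_state(self, gc_passive):
        assert measure_rin(gc_passive) == pytest.approx(
            steady_state_input_resistance(gc_passive), rel=0.01)

    def test_holding_current_at_rest_is_zero(self, gc_passive):
        v_rest = resting_potential(gc_passive)
        assert abs(find_holding_current(gc_passive, v_rest,
                                        settle_ms=300.0)) < 1.0

    def test_holding_current_ohmic_oracle(self):
        cell = single_compartment(r_m=10.0)
        rin = steady_state_input_resistance(cell)
        i = find_holding_current(cell, -65.0, settle_ms=300.0)
        assert i == pytest.approx((-65.0 + 70.0) / rin * 1e3, rel=0.02)

    def test_target_out_of_range(self, gc_passive):
        with pytest.raises(ValueError, match="30 mV"):
            find_holding_current(gc_passive, -120.0)


class TestSpikeDetection:
    def test_constant_trace_empty(self):
        tr = Trace(0.1, 0.0, np.full(1000, -65.0), 0, "voltage")
        assert detect_spikes(tr) == []

    def test_constructed_waveform_onset(self):
        dt = 0.01
        t = np.arange(0, 50, dt)
        v = np.full_like(t, -65.0)
        # ramp at 5 V/s (= 5 mV/ms) from 20 ms, then 105 V/s from 30 ms
        v += np.clip(t - 20.0, 0, None) * 5.0
        v += np.clip(t - 30.0, 0, None) * 100.0
        spikes = detect_spikes(Trace(dt, 0.0, v, 0, "voltage"))
        assert len(spikes) == 1
        assert spikes[0]["time_ms"] == pytest.approx(30.0, abs=2 * dt)

    def test_refractory_grouping(self):
        dt = 0.01
        t = np.arange(0, 20, dt)
        v = -65.0 + 30.0 * np.exp(-((t - 10.0) / 0.3) ** 2)
        spikes = detect_spikes(Trace(dt, 0.0, v, 0, "voltage"))
        assert len(spikes) == 1

    def test_requires_voltage_trace(self):
        tr = Trace(0.1, 0.0, np.zeros(100), 0, "current")
        with pytest.raises(TypeError):
            detect_spikes(tr)


class TestNernst:
    def test_equal_concentrations(self):
        assert nernst_potential(10.0, 10.0, -1, 32.0) == 0.0

    @pytest.mark.parametrize("c_in, expected", [(12.0, -63.3), (17.0, -54.2)])
    def test_chloride_pipette_solutions(self, c_in, expected):
        # bath: 125 NaCl + 2.5 KCl + 2*2 CaCl2 + 2*1 MgCl2 = 133.5 mM Cl-
        assert nernst_potential(c_in, 133.5, -1, 32.0) \
            == pytest.approx(expected, abs=0.3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nernst_potential(0.0, 10.0, -1, 32.0)
        with pytest.raises(ValueError):
            nernst_potential(10.0, 10.0, 0, 32.0)


class TestDeterminism:
    def test_identical_seeds_identical_spikes(self, pvi_spiking):
        def run():
            syn = pvi_spiking.exc_synapse(150.0, primary=0, g_max_ns=12.0,
                                          onset_times_ms=(30.0,))
            noise = NoiseSpec(site=0, seed=4)
            res = integrate(pvi_spiking,
                            [syn, noise, ClampSpec("current", i_hold_pa=40.0)],
                            dt_ms=0.01, duration_ms=60.0, record_sites=(0,),
                            seed=9, detect=True)
            return res.spike_times[0], res.trace(0).values

        (s1, v1), (s2, v2) = run(), run()
        assert s1 == s2
        assert np.array_equal(v1, v2)

    def test_non_finite_state_reported(self):
        cell = single_compartment()
        with pytest.raises(FloatingPointError, match="step"):
            integrate(cell, [], dt_ms=0.025, duration_ms=10.0,
                      record_sites=(0,), v_init_mv=float("nan"))
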