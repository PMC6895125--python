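"""Model assembly: passive profiles, gradients, synapse waveforms, presets."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendrinh.model import (ChannelDensities, EGabaSpec, GGabaSpec,
                            GradientSpec, PassiveProfile, RmSpec, SynapseSpec,
                            CellModel, egaba_at, ggaba_at, preset_cell_model,
                            rm_at, synapse_peak_time, synapse_waveform,
                            pvi_gradients, gc_gradients)
from dendrinh.morphology import Structure, discretize

from conftest import straight_cable


PVI_PASSIVE = PassiveProfile(170.0, {"all": 0.9},
                             RmSpec("exponential_gradient", 10.0, 100.0, 5.0))
GC_PASSIVE = PassiveProfile(
    210.0, {"soma": 1.0, "primary_dendrite": 1.0, "axon": 1.0, "dendrite": 1.6},
    RmSpec("stepwise", region_table=((20.0, 80.0), (math.inf, 50.0))))


class TestRm:
    def test_pvi_soma(self):
        assert rm_at(PVI_PASSIVE, 0.0, 320.0) == pytest.approx(10.0)

    def test_pvi_distal_tip(self):
        # R_distal - (R_distal - R_soma) e^-tau at d = d_max
        expected = 100.0 - 90.0 * math.exp(-5.0)
        assert rm_at(PVI_PASSIVE, 320.0, 320.0) == pytest.approx(expected)
        assert expected == pytest.approx(99.39, abs=0.01)

    def test_gc_regions(self):
        assert rm_at(GC_PASSIVE, 0.0, 320.0) == 80.0
        assert rm_at(GC_PASSIVE, 19.9, 320.0) == 80.0
        assert rm_at(GC_PASSIVE, 20.1, 320.0) == 50.0

    def test_range_error(self):
        with pytest.raises(ValueError):
            rm_at(PVI_PASSIVE, 400.0, 320.0)


class TestGradients:
    def test_pvi_egaba_midpoint(self):
        assert egaba_at(pvi_gradients(), 150.0) == pytest.approx(-63.5)

    def test_gc_egaba_distal_clamp(self):
        g = gc_gradients()
        assert egaba_at(g, 250.0) == pytest.approx(-74.4)
        assert egaba_at(g, 300.0) == pytest.approx(-74.4)

    def test_egaba_soma_extrapolation(self):
        # linear extrapolation below the proximal anchor
        g = pvi_gradients()
        slope = (-69.1 + 57.9) / 200.0
        assert egaba_at(g, 0.0) == pytest.approx(-57.9 - slope * 50.0)

    def test_uniform_egaba(self):
        spec = EGabaSpec(uniform_mv=-65.0)
        for d in (0.0, 100.0, 400.0):
            assert egaba_at(spec, d) == -65.0

    def test_ggaba_uniform_and_linear(self):
        assert ggaba_at(GGabaSpec(uniform_ns=10.0), 250.0) == 10.0
        lin = GGabaSpec(anchors=((50.0, 14.0), (250.0, 46.0)))
        assert ggaba_at(lin, 150.0) == pytest.approx(30.0)
        assert ggaba_at(lin, 50.0) == pytest.approx(14.0)
        assert ggaba_at(lin, 10.0) == pytest.approx(14.0)   # clamped
        assert ggaba_at(lin, 400.0) == pytest.approx(46.0)  # clamped

    def test_monotone_between_anchors(self):
        g = pvi_gradients("gradient")
        d = np.linspace(50.0, 250.0, 41)
        eg = [egaba_at(g, x) for x in d]
        gg = [ggaba_at(g, x) for x in d]
        assert np.all(np.diff(eg) < 0)
        assert np.all(np.diff(gg) > 0)

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            EGabaSpec()
        with pytest.raises(ValueError):
            EGabaSpec(anchors=((250.0, -69.1), (50.0, -57.9)))
        with pytest.raises(ValueError):
            GGabaSpec(anchors=((50.0, 14.0), (250.0, -1.0)))


class TestSynapseWaveform:
    def test_zero_at_onset_and_decay(self):
        s = SynapseSpec(0, 10.0, 0.1, 20.0, -70.0, (5.0,))
        assert synapse_waveform(s, 5.0) == pytest.approx(0.0)
        assert synapse_waveform(s, 4.0) == 0.0
        assert synapse_waveform(s, 400.0) < 1e-6

    def test_peak_time_closed_form(self):
        tp = synapse_peak_time(0.1, 20.0)
        assert tp == pytest.approx(0.1 * 20.0 / 19.9 * math.log(200.0))
        assert tp == pytest.approx(0.533, abs=1e-3)

    @given(tau_r=st.floats(0.05, 5.0), ratio=st.floats(1.5, 200.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_peak_normalization(self, tau_r, ratio):
        tau_d = tau_r * ratio
        s = SynapseSpec(0, 7.5, tau_r, tau_d, 0.0, (0.0,))
        tp = synapse_peak_time(tau_r, tau_d)
        assert synapse_waveform(s, tp) == pytest.approx(7.5, rel=1e-6)

    def test_invalid_taus(self):
        with pytest.raises(ValueError):
            SynapseSpec(0, 1.0, 20.0, 0.1, 0.0)


class TestBuildCell:
    def test_pvi_cm(self, pvi_active):
        soma = pvi_active.cell.soma_index
        assert pvi_active.cm_uf_cm2[soma] == pytest.approx(0.9)

    def test_gc_cm_regions(self, gc_active):
        cc = gc_active.cell
        soma = cc.soma_index
        assert gc_active.cm_uf_cm2[soma] == pytest.approx(1.0)
        distal = cc.locate(250.0, primary=0)
        assert gc_active.cm_uf_cm2[distal] == pytest.approx(1.6)
        proximal = cc.locate(10.0, primary=0)
        assert gc_active.cm_uf_cm2[proximal] == pytest.approx(1.0)

    def test_ih_unit_conversion(self, pvi_active):
        # 1 pS/um^2 enters as 0.1 mS/cm^2
        assert np.allclose(pvi_active.g_ih_ms_cm2, 0.1)

    def test_passive_variant_drops_na_k_keeps_ih(self, pvi_active):
        p = pvi_active.passive_variant()
        assert np.all(p.g_na_us == 0.0)
        assert np.all(p.g_k_us == 0.0)
        assert np.any(p.g_ih_us > 0.0)
        assert np.all(p.g_pas_us == pytest.approx(pvi_active.g_pas_us))
        p2 = pvi_active.passive_variant(drop_ih=True)
        assert np.all(p2.g_ih_us == 0.0)

    def test_axonal_na_requires_axon(self):
        m = straight_cable(20, 10.0, 1.0)     # no axon
        with pytest.raises(ValueError, match="axon"):
            preset_cell_model(discretize(m), "PVI", spiking=True)

    def test_config_round_trip(self, gc_active, gc_seg):
        cfg = gc_active.to_config()
        rebuilt = CellModel.from_config(gc_seg, cfg)
        for attr in ("c_nf", "g_pas_us", "g_na_us", "g_k_us", "g_ih_us",
                     "g_axial_us"):
            assert np.array_equal(getattr(rebuilt, attr),
                                  getattr(gc_active, attr)), attr
        assert rebuilt.parameter_hash() == gc_active.parameter_hash()

    def test_gaba_synapse_pulls_gradients(self, pvi_active):
        syn = pvi_active.gaba_synapse(250.0, primary=0)
        assert syn.g_max_ns == pytest.approx(14.0)          # uniform default
        assert syn.e_rev_mv == pytest.approx(-69.1, abs=0.3)

    def test_densities_validation(self):
        with pytest.raises(ValueError):
            ChannelDensities({"soma": -1.0}, 20.0, 1.0)
        with pytest.raises(ValueError):
            ChannelDensities({"soma": 1.0}, 20.0, 1.0, kinetics_id="nope")
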