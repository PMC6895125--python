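"""Protocols: conductance mapping, IE mapping/surface, discharge, IPSP spread.

The heavier protocol runs use reduced holding-potential grids and few trial
counts; the full default conditions are exercised by the acceptance suite.
"""

import numpy as np
import pytest

from dendrinh.model import GGabaSpec, preset_cell_model
from dendrinh.morphology import GeometryParams, discretize, generate_synthetic_morphology
from dendrinh.protocols import (PlacementError, protocol_conductance_mapping,
                                protocol_discharge, protocol_ie_mapping,
                                protocol_ie_surface, protocol_ipsp_propagation,
                                seven_site_placements)

from conftest import straight_cable
from test_engine import make_cell

VH_SMALL = (-90.0, -80.0, -70.0, -60.0, -50.0)


class TestConductanceMapping:
    def test_reference_normalization_and_monotone_decay(self, pvi_passive):
        prof = protocol_conductance_mapping(
            pvi_passive, distances_um=(50.0, 150.0, 250.0),
            vh_grid_mv=VH_SMALL)
        assert prof.g_norm[0] == pytest.approx(1.0)
        assert np.all(np.diff(prof.g_est_ns) < 0)
        assert prof.g_est_ns[0] < 14.0    # attenuation only loses conductance

    def test_collapsed_distances_on_stub_cell(self):
        # a stub dendrite: every requested distance resolves to the same
        # compartment, so the normalized profile is identically 1
        cell = make_cell(straight_cable(1, 10.0, 1.0), r_m=50.0,
                         max_seg=50.0)
        prof = protocol_conductance_mapping(
            cell, distances_um=(4.0, 6.0), vh_grid_mv=VH_SMALL)
        assert np.allclose(prof.g_norm, 1.0)

    def test_distance_beyond_dendrite(self, pvi_passive):
        with pytest.raises(PlacementError):
            protocol_conductance_mapping(pvi_passive,
                                         distances_um=(50.0, 900.0))


class TestIEMapping:
    def test_zero_gaba_gives_zero_ie(self, gc_active):
        cell = preset_cell_model(gc_active.cell, "GC", ggaba=0.0)
        prof = protocol_ie_mapping(cell, gaba_locations_um=(50.0, 250.0))
        assert np.allclose(prof.ie, 0.0, atol=1e-6)
        assert list(prof.relative_location_um) == [-100.0, 100.0]

    def test_spiking_epsp_rejected(self, pvi_spiking):
        with pytest.raises(RuntimeError, match="spike"):
            protocol_ie_mapping(pvi_spiking, exc_g_ns=500.0,
                                gaba_locations_um=(50.0,))


class TestIESurface:
    @pytest.fixture(scope="class")
    def surface(self, pvi_active):
        return protocol_ie_surface(
            pvi_active, site="on_path",
            egaba_grid_mv=(-75.0, -65.0, -55.0),
            ggaba_grid_ns=(0.0, 10.0, 30.0))

    def test_zero_conductance_column(self, surface):
        assert np.allclose(surface["ie"][:, 0], 0.0)

    def test_monotone_in_ggaba_below_rest(self, surface):
        # for hyperpolarizing E_GABA the IE grows with conductance
        row = surface["ie"][0]          # E_GABA = -75 mV < holding
        assert np.all(np.diff(row) >= -1e-9)
        assert row[-1] > row[1] * 0.99

    def test_shunt_stronger_on_path(self):
        """At E_GABA = holding potential (pure shunt, no driving force) the
        on-path placement between input and soma weakens the somatic EPSP
        more than the same shunt placed distal to the input (reduced-cable
        shunting-circuit oracle)."""
        cell = make_cell(straight_cable(30, 10.0, 1.5), r_m=30.0,
                         e_leak=-65.0)
        out_on = protocol_ie_surface(cell, site="on_path",
                                     egaba_grid_mv=(-65.0,),
                                     ggaba_grid_ns=(30.0,),
                                     exc_g_ns=2.0, holding_mv=-65.0)
        out_off = protocol_ie_surface(cell, site="off_path",
                                      egaba_grid_mv=(-65.0,),
                                      ggaba_grid_ns=(30.0,),
                                      exc_g_ns=2.0, holding_mv=-65.0)
        ie_on = out_on["ie"][0, 0]
        ie_off = out_off["ie"][0, 0]
        assert ie_on > 0.05
        assert ie_off < ie_on - 0.03


class TestSevenSites:
    def test_distinct_branches_and_determinism(self, pvi_spiking):
        a = seven_site_placements(pvi_spiking, "off_path", seed=5,
                                  exclude_primary=0)
        b = seven_site_placements(pvi_spiking, "off_path", seed=5,
                                  exclude_primary=0)
        assert a == b
        secs = [s for s, _ in a]
        assert len(set(secs)) == 7
        cc = pvi_spiking.cell
        for sec, dist in a:
            assert 200.0 <= dist <= 250.0
            assert 0 not in set(cc.primary[cc.section == sec])

    def test_too_few_branches(self):
        gp = GeometryParams.for_cell_type("PVI")
        gp.n_apical = 3
        m = generate_synthetic_morphology("PVI", gp, seed=2, calibrate=False)
        cell = preset_cell_model(discretize(m), "PVI", spiking=True)
        with pytest.raises(PlacementError):
            seven_site_placements(cell, "on_path", seed=0)


class TestDischarge:
    def test_zero_drive_silent_and_dominance(self, pvi_spiking):
        ctrl = protocol_discharge(pvi_spiking, (0.0, 12.0), "control",
                                  n_trials=10, seed=2, fit=False)
        inh = protocol_discharge(pvi_spiking, (0.0, 12.0), "on_path",
                                 n_trials=10, seed=2, fit=False)
        assert ctrl.spikes_per_trial[0] == 0.0
        # control dominates the inhibited curve pointwise (binomial slack)
        slack = 1.0 / np.sqrt(ctrl.n_trials)
        assert np.all(ctrl.spikes_per_trial >= inh.spikes_per_trial - slack)

    def test_rerun_equality(self, gc_spiking):
        a = protocol_discharge(gc_spiking, (14.0,), "off_path", n_trials=10,
                               seed=7, fit=False)
        b = protocol_discharge(gc_spiking, (14.0,), "off_path", n_trials=10,
                               seed=7, fit=False)
        assert np.array_equal(a.spikes_per_trial, b.spikes_per_trial)
        assert np.array_equal(a.p_any_spike, b.p_any_spike)

    def test_minimum_trials_enforced(self, pvi_spiking):
        with pytest.raises(ValueError, match="10 trials"):
            protocol_discharge(pvi_spiking, (10.0,), "control", n_trials=3,
                               fit=False)


class TestIpspPropagation:
    @pytest.fixture(scope="class")
    def spread(self, pvi_active):
        return protocol_ipsp_propagation(pvi_active)

    def test_normalized_at_site_is_one(self, spread):
        assert spread["normalized"][0] == pytest.approx(1.0)
        assert spread["distance_from_site_um"][0] == pytest.approx(0.0, abs=3)

    def test_amplitude_attenuates_toward_soma(self, spread):
        amps = np.abs(spread["amplitude_mv"])
        # compare induction site against soma end; allow local wiggles
        assert amps[-1] < amps[0]
        assert np.all(spread["amplitude_mv"] < 0)   # hyperpolarizing
        assert np.all(np.diff(spread["distance_from_site_um"]) > 0)

    def test_pvi_ipsps_larger_than_gc(self, spread, gc_active):
        gc = protocol_ipsp_propagation(gc_active)

        def amp_at(out, d):
            i = np.argmin(np.abs(out["distance_from_site_um"] - d))
            return abs(out["amplitude_mv"][i])

        assert amp_at(spread, 150.0) > amp_at(gc, 150.0)
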