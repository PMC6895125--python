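"""In-silico experimental protocols.

Each protocol is a pure function of (cell model, parameters, seed) that
drives the engine and returns a small result object:

* :func:`protocol_conductance_mapping` — somatic voltage-clamp slope-
  conductance estimates for GABA synapses stepped along an apical dendrite
  (50 um steps), normalized to the most proximal (50 um) site.
* :func:`protocol_ie_mapping` — inhibitory effect of a single GABAergic
  input at locations on- and off-path relative to a dendritic excitatory
  input at 150 um.
* :func:`protocol_ie_surface` — IE over an (E_GABA, G_GABA) grid for on-
  (50 um) and off-path (250 um) inhibition.
* :func:`protocol_discharge` — spikes/trial vs excitatory conductance with
  seven-site on- or off-path GABAergic volleys under somatic background
  noise.
* :func:`protocol_ipsp_propagation` — IPSP amplitude along the dendritic
  path for a distal (250 um) inhibitory input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .engine import (ClampSpec, NoiseSpec, SynapseSpec, Trace, integrate,
                     find_holding_current)
from .estimators import (IVDataset, discharge_probability, fit_sigmoid,
                         inhibitory_effect, iv_slope, peak_amplitude)
from .model import CellModel, EGabaSpec, GGabaSpec, GradientSpec, egaba_at, ggaba_at

__all__ = [
    "AttenuationProfile", "IEProfile", "DischargeCurve", "PlacementError",
    "protocol_conductance_mapping", "protocol_ie_mapping",
    "protocol_ie_surface", "protocol_discharge", "protocol_ipsp_propagation",
    "DEFAULT_DISTANCES_UM", "DEFAULT_VH_GRID_MV",
]

DEFAULT_DISTANCES_UM = (50.0, 100.0, 150.0, 200.0, 250.0)
DEFAULT_VH_GRID_MV = tuple(np.arange(-90.0, -49.0, 5.0))


class PlacementError(LookupError):
    """A requested synapse placement could not be satisfied."""


@dataclass
class AttenuationProfile:
    """Somatic slope-conductance estimates vs synapse distance, normalized to
    the reference (most proximal, 50 um) site."""

    distances_um: np.ndarray
    g_est_ns: np.ndarray
    g_norm: np.ndarray
    reference_distance_um: float = 50.0

    def __post_init__(self):
        self.distances_um = np.asarray(self.distances_um, float)
        self.g_est_ns = np.asarray(self.g_est_ns, float)
        self.g_norm = np.asarray(self.g_norm, float)
        if np.any(np.diff(self.distances_um) <= 0):
            raise ValueError("distances must be unique and ascending")

    def norm_at(self, distance_um: float) -> float:
        i = np.argmin(np.abs(self.distances_um - distance_um))
        if abs(self.distances_um[i] - distance_um) > 1e-6:
            raise KeyError(f"no entry at {distance_um} um")
        return float(self.g_norm[i])


@dataclass
class IEProfile:
    """Inhibitory effect vs GABA location relative to the excitatory input
    site (negative = on-path, toward the soma)."""

    relative_location_um: np.ndarray
    ie: np.ndarray
    epsp_amp_mv: float
    details: list = field(default_factory=list)

    def __post_init__(self):
        self.relative_location_um = np.asarray(self.relative_location_um, float)
        self.ie = np.asarray(self.ie, float)


@dataclass
class DischargeCurve:
    """Spikes/trial vs excitatory conductance for one inhibition condition."""

    g_exc_ns: np.ndarray
    spikes_per_trial: np.ndarray
    p_any_spike: np.ndarray
    condition: str
    n_trials: int
    seed: int
    sigmoid: dict = field(default_factory=dict)

    def __post_init__(self):
        self.g_exc_ns = np.asarray(self.g_exc_ns, float)
        self.spikes_per_trial = np.asarray(self.spikes_per_trial, float)
        self.p_any_spike = np.asarray(self.p_any_spike, float)
        if self.n_trials < 10:
            raise ValueError("need at least 10 trials per point")


# ---------------------------------------------------------------------------
# Somatic slope-conductance mapping along the dendrite
# ---------------------------------------------------------------------------

def _slope_at_site(cell: CellModel, distance_um: float, primary: int,
                   g_local_ns: float, e_rev_mv: float,
                   vh_grid_mv: Sequence[float], r_s_mohm: float,
                   tau_decay_ms: float, dt_ms: float,
                   settle_ms: float = 100.0, record_ms: float = 120.0) -> float:
    """Somatic slope-conductance estimate (nS) for one synapse placement."""
    onset = settle_ms
    peaks = []
    syn = cell.gaba_synapse(distance_um, primary=primary, g_max_ns=g_local_ns,
                            tau_decay_ms=tau_decay_ms, e_rev_mv=e_rev_mv,
                            onset_times_ms=(onset,))
    for vh in vh_grid_mv:
        clamp = ClampSpec("voltage", site=cell.cell.soma_index, v_h_mv=vh,
                          r_s_mohm=r_s_mohm)
        res = integrate(cell, [clamp, syn], dt_ms=dt_ms,
                        duration_ms=settle_ms + record_ms,
                        record_sites=(cell.cell.soma_index,))
        cur = res.electrode_current
        peaks.append(peak_amplitude(cur, (onset - 50.0, onset - dt_ms),
                                    (onset, onset + record_ms - dt_ms),
                                    polarity="auto") * 1e3)  # nA -> pA
    slope, _ = iv_slope(IVDataset(np.asarray(vh_grid_mv), np.asarray(peaks), "pa"))
    return slope


def protocol_conductance_mapping(
        cell: CellModel,
        distances_um: Sequence[float] = DEFAULT_DISTANCES_UM,
        vh_grid_mv: Sequence[float] = DEFAULT_VH_GRID_MV,
        ggaba_spec: GGabaSpec | None = None,
        primary: int = 0,
        r_s_mohm: float = 10.0,
        tau_decay_ms: float = 20.0,
        dt_ms: float = 0.025) -> AttenuationProfile:
    """Map apparent somatic G_GABA along an apical dendrite.

    Runs a somatic voltage clamp (series resistance ``r_s_mohm``) per holding
    potential and distance, measures baseline-subtracted peak currents, takes
    the I-V slope as the conductance estimate, and normalizes to the most
    proximal site.  The cell should be a passive variant (Na/K removed), as
    in the corresponding voltage-clamp simulations.
    """
    distances = np.asarray(sorted(distances_um), float)
    if distances[-1] > cell.cell.max_dendrite_path_um() + 25.0:
        raise PlacementError(
            f"requested distance {distances[-1]} um exceeds the dendrite")
    spec = ggaba_spec if ggaba_spec is not None else cell.gradients.ggaba
    g_est = []
    for d in distances:
        g_local = ggaba_at(spec, d)
        e_rev = egaba_at(cell.gradients, d)
        g_est.append(_slope_at_site(cell, d, primary, g_local, e_rev,
                                    vh_grid_mv, r_s_mohm, tau_decay_ms, dt_ms))
    g_est = np.asarray(g_est)
    ref = np.argmin(np.abs(distances - 50.0))
    return AttenuationProfile(distances, g_est, g_est / g_est[ref],
                              reference_distance_um=float(distances[ref]))


# ---------------------------------------------------------------------------
# Inhibitory-effect mapping and surfaces
# ---------------------------------------------------------------------------

def _psp_amplitude(trace: Trace, onset_ms: float, search_ms: float,
                   dt_ms: float) -> float:
    return peak_amplitude(trace, (onset_ms - 50.0, onset_ms - dt_ms),
                          (onset_ms, onset_ms + search_ms), polarity="positive")


def protocol_ie_mapping(
        cell: CellModel,
        exc_distance_um: float = 150.0,
        exc_g_ns: float | None = None,
        gaba_locations_um: Sequence[float] = DEFAULT_DISTANCES_UM,
        primary: int = 0,
        egaba_uniform_mv: float | None = None,
        gaba_lead_ms: float = 4.0,
        holding_mv: float | None = None,
        dt_ms: float = 0.025,
        settle_ms: float = 60.0) -> IEProfile:
    """Inhibitory effect vs GABA location for a single-site pairing.

    The excitatory input sits at ``exc_distance_um`` (default 150 um, 5 nS
    for PVIs / 3 nS for GCs); GABAergic inputs are placed one location at a
    time with onset ``gaba_lead_ms`` before the excitation.  Three runs per
    location (EPSP alone, IPSP alone, paired) yield IE via
    1 - PSP/EPSP on baseline-subtracted positive peak amplitudes.
    """
    if exc_g_ns is None:
        exc_g_ns = 5.0 if cell.cell_type == "PVI" else 3.0
    if holding_mv is None:
        holding_mv = -65.0 if cell.cell_type == "PVI" else -70.0
    i_hold = find_holding_current(cell, holding_mv)
    hold = ClampSpec("current", site=cell.cell.soma_index, i_hold_pa=i_hold)
    t_exc = settle_ms + gaba_lead_ms
    search_ms = 100.0 if cell.cell_type == "PVI" else 200.0
    duration = t_exc + search_ms + 20.0
    soma = cell.cell.soma_index

    exc = cell.exc_synapse(exc_distance_um, primary=primary, g_max_ns=exc_g_ns,
                           onset_times_ms=(t_exc,))
    res_e = integrate(cell, [hold, exc], dt_ms=dt_ms, duration_ms=duration,
                      record_sites=(soma,), v_init_mv=holding_mv, detect=True)
    if res_e.spike_times.get(soma):
        raise RuntimeError(
            "control EPSP triggered a spike; reduce the excitatory conductance")
    epsp = _psp_amplitude(res_e.trace(soma), t_exc, search_ms, dt_ms)

    rel, ies, details = [], [], []
    for d in gaba_locations_um:
        e_rev = egaba_uniform_mv
        gaba = cell.gaba_synapse(d, primary=primary, e_rev_mv=e_rev,
                                 onset_times_ms=(settle_ms,))
        res_i = integrate(cell, [hold, gaba], dt_ms=dt_ms, duration_ms=duration,
                          record_sites=(soma,), v_init_mv=holding_mv)
        ipsp = peak_amplitude(res_i.trace(soma),
                              (settle_ms - 50.0, settle_ms - dt_ms),
                              (settle_ms, settle_ms + search_ms), "auto")
        res_p = integrate(cell, [hold, gaba, exc], dt_ms=dt_ms,
                          duration_ms=duration, record_sites=(soma,),
                          v_init_mv=holding_mv)
        psp = _psp_amplitude(res_p.trace(soma), t_exc, search_ms, dt_ms)
        r = inhibitory_effect(epsp, psp, location_um=float(d))
        rel.append(float(d) - exc_distance_um)
        ies.append(r.ie)
        details.append({"distance_um": float(d), "ipsp_amp_mv": ipsp,
                        "psp_amp_mv": psp, "epsp_amp_mv": epsp,
                        "g_gaba_ns": gaba.g_max_ns, "e_gaba_mv": gaba.e_rev_mv})
    order = np.argsort(rel)
    return IEProfile(np.asarray(rel)[order], np.asarray(ies)[order],
                     epsp_amp_mv=epsp,
                     details=[details[i] for i in order])


def protocol_ie_surface(
        cell: CellModel,
        site: Literal["on_path", "off_path"] = "on_path",
        egaba_grid_mv: Sequence[float] = (-80.0, -75.0, -70.0, -65.0, -60.0, -55.0),
        ggaba_grid_ns: Sequence[float] = (0.0, 5.0, 10.0, 20.0, 40.0, 60.0),
        exc_distance_um: float = 150.0,
        exc_g_ns: float | None = None,
        primary: int = 0,
        gaba_lead_ms: float = 4.0,
        holding_mv: float | None = None,
        dt_ms: float = 0.025,
        settle_ms: float = 60.0) -> dict:
    """IE over an (E_GABA, G_GABA) grid for on-path (50 um) or off-path
    (250 um) inhibition.  Returns {'egaba_mv', 'ggaba_ns', 'ie'} with
    ie[i, j] for E_GABA i and G_GABA j."""
    if exc_g_ns is None:
        exc_g_ns = 5.0 if cell.cell_type == "PVI" else 3.0
    if holding_mv is None:
        holding_mv = -65.0 if cell.cell_type == "PVI" else -70.0
    gaba_d = 50.0 if site == "on_path" else 250.0
    i_hold = find_holding_current(cell, holding_mv)
    hold = ClampSpec("current", site=cell.cell.soma_index, i_hold_pa=i_hold)
    t_exc = settle_ms + gaba_lead_ms
    search_ms = 100.0 if cell.cell_type == "PVI" else 200.0
    duration = t_exc + search_ms + 20.0
    soma = cell.cell.soma_index

    exc = cell.exc_synapse(exc_distance_um, primary=primary, g_max_ns=exc_g_ns,
                           onset_times_ms=(t_exc,))
    res_e = integrate(cell, [hold, exc], dt_ms=dt_ms, duration_ms=duration,
                      record_sites=(soma,), v_init_mv=holding_mv)
    epsp = _psp_amplitude(res_e.trace(soma), t_exc, search_ms, dt_ms)

    ie = np.zeros((len(egaba_grid_mv), len(ggaba_grid_ns)))
    for i, eg in enumerate(egaba_grid_mv):
        for j, gg in enumerate(ggaba_grid_ns):
            if gg == 0.0:
                ie[i, j] = 0.0
                continue
            gaba = cell.gaba_synapse(gaba_d, primary=primary, g_max_ns=gg,
                                     e_rev_mv=eg, onset_times_ms=(settle_ms,))
            res_p = integrate(cell, [hold, gaba, exc], dt_ms=dt_ms,
                              duration_ms=duration, record_sites=(soma,),
                              v_init_mv=holding_mv)
            psp = _psp_amplitude(res_p.trace(soma), t_exc, search_ms, dt_ms)
            ie[i, j] = inhibitory_effect(epsp, psp).ie
    return {"egaba_mv": np.asarray(egaba_grid_mv, float),
            "ggaba_ns": np.asarray(ggaba_grid_ns, float),
            "ie": ie, "site": site, "epsp_amp_mv": epsp}


# ---------------------------------------------------------------------------
# Seven-site discharge protocol
# ---------------------------------------------------------------------------

ON_PATH_BAND_UM = (50.0, 100.0)
OFF_PATH_BAND_UM = (200.0, 250.0)


def seven_site_placements(cell: CellModel, condition: str, seed: int,
                          n_sites: int = 7,
                          exclude_primary: int | None = None) -> list[tuple[int, float]]:
    """Choose ``n_sites`` (section, distance) placements on distinct apical
    branches within the on- or off-path distance band, seeded.

    Branches on ``exclude_primary`` are skipped so the volley lands on
    different apical dendrites than the excitatory input, mirroring the
    distributed uncaging-site arrangement."""
    band = ON_PATH_BAND_UM if condition == "on_path" else OFF_PATH_BAND_UM
    secs = cell.cell.sections_in_band(*band)
    if exclude_primary is not None:
        cc = cell.cell
        sec_primary = {int(s): int(cc.primary[cc.section == s][0]) for s in secs}
        secs = [s for s in secs if sec_primary[s] != exclude_primary]
    if len(secs) < n_sites:
        raise PlacementError(
            f"only {len(secs)} distinct branches available in {band} um band")
    rng = np.random.default_rng([seed, 7])
    chosen = rng.choice(len(secs), size=n_sites, replace=False)
    out = []
    for k in sorted(chosen):
        sec = secs[k]
        dist = float(rng.uniform(*band))
        out.append((sec, dist))
    return out


def protocol_discharge(
        cell: CellModel,
        g_exc_grid_ns: Sequence[float],
        condition: Literal["control", "on_path", "off_path"] = "control",
        per_synapse_ggaba_ns: float | None = None,
        n_trials: int = 40,
        seed: int = 0,
        exc_distance_um: float = 150.0,
        primary: int = 0,
        gaba_lead_ms: float = 20.0,
        inter_pulse_ms: float = 2.0,
        tau_decay_gaba_ms: float = 20.0,
        holding_mv: float | None = None,
        dt_ms: float = 0.01,
        settle_ms: float = 30.0,
        window_after_exc_ms: float = 50.0,
        count_window_ms: float = 50.0,
        fit: bool = True) -> DischargeCurve:
    """Discharge probability vs excitatory conductance with 7-site dendritic
    inhibition under somatic background noise.

    The GABAergic volley starts ``gaba_lead_ms`` before the excitation, its
    seven sites activated sequentially at ``inter_pulse_ms`` intervals on
    distinct apical branches in the on-path (50-100 um) or off-path
    (200-250 um) band.  Per-synapse peak conductances default to the
    condition-specific reference values (PVI 14/54 nS on/off; GC 7.5 nS).
    Spikes are counted per trial from the somatic voltage (dV/dt criterion)
    in a window after the excitatory onset.
    """
    if holding_mv is None:
        holding_mv = -65.0 if cell.cell_type == "PVI" else -70.0
    if per_synapse_ggaba_ns is None and condition != "control":
        if cell.cell_type == "PVI":
            per_synapse_ggaba_ns = 14.0 if condition == "on_path" else 54.0
        else:
            per_synapse_ggaba_ns = 7.5
    i_hold = find_holding_current(cell, holding_mv)
    hold = ClampSpec("current", site=cell.cell.soma_index, i_hold_pa=i_hold)
    soma = cell.cell.soma_index
    t_exc = settle_ms + gaba_lead_ms
    duration = t_exc + window_after_exc_ms

    gaba_syns: list[SynapseSpec] = []
    if condition != "control":
        for k, (sec, dist) in enumerate(
                seven_site_placements(cell, condition, seed,
                                      exclude_primary=primary)):
            onset = settle_ms + k * inter_pulse_ms
            gaba_syns.append(cell.gaba_synapse(
                dist, primary=None, section=sec,
                g_max_ns=per_synapse_ggaba_ns,
                tau_decay_ms=tau_decay_gaba_ms, onset_times_ms=(onset,)))

    spt, pany = [], []
    for g_exc in g_exc_grid_ns:
        exc = cell.exc_synapse(exc_distance_um, primary=primary,
                               g_max_ns=g_exc, onset_times_ms=(t_exc,))
        runs = []
        for trial in range(n_trials):
            noise = NoiseSpec(site=soma, seed=trial)
            res = integrate(cell, [hold, exc, noise] + gaba_syns,
                            dt_ms=dt_ms, duration_ms=duration,
                            record_sites=(soma,), seed=seed,
                            v_init_mv=holding_mv, detect=True)
            runs.append(res)
        stats = discharge_probability(runs, site=soma,
                                      window_ms=(t_exc, t_exc + count_window_ms))
        spt.append(stats["spikes_per_trial"])
        pany.append(stats["p_any_spike"])

    curve = DischargeCurve(np.asarray(g_exc_grid_ns, float),
                           np.asarray(spt), np.asarray(pany),
                           condition=condition, n_trials=n_trials, seed=seed)
    if fit and len(curve.g_exc_ns) >= 5:
        try:
            curve.sigmoid = fit_sigmoid(
                np.column_stack([curve.g_exc_ns,
                                 np.clip(curve.p_any_spike, 0, 1)]))
        except Exception:   # a degenerate curve is data, not an error
            curve.sigmoid = {"degenerate": True}
    return curve


# ---------------------------------------------------------------------------
# IPSP propagation along the dendrite
# ---------------------------------------------------------------------------

def protocol_ipsp_propagation(
        cell: CellModel,
        site_distance_um: float = 250.0,
        per_synapse_ggaba_ns: float | None = None,
        primary: int = 0,
        tau_decay_ms: float = 20.0,
        holding_mv: float | None = None,
        dt_ms: float = 0.025,
        settle_ms: float = 60.0,
        search_ms: float = 150.0) -> dict:
    """IPSP peak amplitude at every compartment along the path from a distal
    inhibitory input (default 250 um) to the soma.

    Returns {'distance_from_site_um', 'path_distance_um', 'amplitude_mv',
    'normalized'}; ``normalized`` is relative to the amplitude at the
    induction site.
    """
    if holding_mv is None:
        holding_mv = -65.0 if cell.cell_type == "PVI" else -70.0
    if per_synapse_ggaba_ns is None:
        per_synapse_ggaba_ns = 54.0 if cell.cell_type == "PVI" else 7.5
    i_hold = find_holding_current(cell, holding_mv)
    hold = ClampSpec("current", site=cell.cell.soma_index, i_hold_pa=i_hold)
    syn = cell.gaba_synapse(site_distance_um, primary=primary,
                            g_max_ns=per_synapse_ggaba_ns,
                            tau_decay_ms=tau_decay_ms,
                            onset_times_ms=(settle_ms,))
    path = cell.cell.path_to_root(int(syn.site))
    res = integrate(cell, [hold, syn], dt_ms=dt_ms,
                    duration_ms=settle_ms + search_ms,
                    record_sites=path, v_init_mv=holding_mv)
    pd_site = float(cell.cell.path_distance_um[int(syn.site)])
    dist, amps, pds = [], [], []
    for idx in path:
        tr = res.trace(idx)
        amp = peak_amplitude(tr, (settle_ms - 50.0, settle_ms - dt_ms),
                             (settle_ms, settle_ms + search_ms), "negative")
        pd_i = float(cell.cell.path_distance_um[idx])
        dist.append(pd_site - pd_i)
        amps.append(amp)
        pds.append(pd_i)
    dist = np.asarray(dist)
    amps = np.asarray(amps)
    order = np.argsort(dist)
    norm = amps / amps[order[0]]
    return {"distance_from_site_um": dist[order],
            "path_distance_um": np.asarray(pds)[order],
            "amplitude_mv": amps[order],
            "normalized": (amps / amps[np.argmin(np.abs(dist))])[order]}
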