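"""Biophysical cell-model assembly.

Materializes per-compartment passive parameters, voltage-gated channel
densities and the somato-dendritic E_GABA / G_GABA gradients onto a
:class:`~dendrinh.morphology.SegmentedCell`, producing the
:class:`CellModel` consumed by the integration engine.

Built-in presets follow the dentate gyrus parameter sets:

PVI (fast-spiking interneuron)
    R_a 170 Ohm*cm, C_m 0.9 uF/cm^2, R_m exponential gradient 10 -> 100
    kOhm*cm^2 with dimensionless constant tau = 5 over normalized path
    distance, g_Na 25/25/1 mS/cm^2 (soma/axon/dendrite; 55/85/0 in the
    spiking preset), g_K 20 mS/cm^2, g_Ih 1 pS/um^2, E_GABA linear
    (50 um, -57.9 mV) -> (250 um, -69.1 mV), G_GABA uniform 14 nS (or a
    linear 14 -> 54 nS gradient).

GC (granule cell)
    R_a 210 Ohm*cm, C_m 1.0 uF/cm^2 at soma and primary dendrites and
    1.6 uF/cm^2 elsewhere (spine compensation), R_m 80 kOhm*cm^2 at soma
    and perisomatic dendrites (< 20 um) and 50 kOhm*cm^2 beyond, a reduced
    Na + delayed-rectifier spiking set, E_GABA linear
    (50 um, -78.2 mV) -> (250 um, -74.4 mV), G_GABA uniform 10 nS.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Literal, Sequence

import numpy as np

from .morphology import SegmentedCell, Structure

__all__ = [
    "RmSpec", "PassiveProfile", "ChannelDensities", "Kinetics", "KINETICS",
    "EGabaSpec", "GGabaSpec", "GradientSpec",
    "SynapseSpec", "ClampSpec", "NoiseSpec",
    "rm_at", "egaba_at", "ggaba_at", "synapse_waveform", "synapse_peak_time",
    "CellModel", "build_cell", "preset_cell_model",
    "pvi_gradients", "gc_gradients",
]

PS_PER_UM2_TO_MS_PER_CM2 = 0.1  # 1 pS/um^2 == 0.1 mS/cm^2


# ---------------------------------------------------------------------------
# Passive membrane
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RmSpec:
    """Specific membrane resistivity profile (kOhm*cm^2).

    ``exponential_gradient``: R_m(d) = R_distal - (R_distal - R_soma)
    * exp(-tau * d / d_max) with tau dimensionless over normalized path
    distance.  ``stepwise``: lookup in ``region_table``, a sorted tuple of
    (upper_path_distance_um, value) with the last entry catching everything.
    """

    form: Literal["exponential_gradient", "stepwise"]
    soma_value: float = 10.0
    distal_value: float = 100.0
    tau: float = 5.0
    region_table: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.form == "exponential_gradient":
            if self.soma_value <= 0 or self.distal_value <= 0:
                raise ValueError("R_m values must be positive")
            if self.tau <= 0:
                raise ValueError("exponential gradient requires tau > 0")
        elif self.form == "stepwise":
            if not self.region_table:
                raise ValueError("stepwise R_m requires a region table")
            if any(v <= 0 for _, v in self.region_table):
                raise ValueError("R_m values must be positive")
        else:
            raise ValueError(f"unknown R_m form {self.form!r}")


@dataclass(frozen=True)
class PassiveProfile:
    """Passive parameters: axial resistivity, regional C_m and the R_m rule.

    ``c_m_regions`` maps region names to uF/cm^2; recognized regions are
    ``soma``, ``axon``, ``primary_dendrite`` and ``dendrite`` with fallback to
    ``all``.
    """

    r_a_ohm_cm: float
    c_m_regions: dict[str, float]
    r_m: RmSpec

    def __post_init__(self):
        if self.r_a_ohm_cm <= 0:
            raise ValueError("R_a must be positive")
        if any(v <= 0 for v in self.c_m_regions.values()):
            raise ValueError("C_m values must be positive")

    def c_m_for(self, region: str) -> float:
        if region in self.c_m_regions:
            return self.c_m_regions[region]
        if region == "primary_dendrite" and "dendrite" in self.c_m_regions:
            return self.c_m_regions["dendrite"]
        return self.c_m_regions["all"]


def rm_at(profile: PassiveProfile, d_um: float, d_max_um: float) -> float:
    """R_m (kOhm*cm^2) at path distance ``d_um`` for a tree of maximal
    dendritic path distance ``d_max_um``."""
    if d_um < 0 or d_um > d_max_um + 1e-9:
        raise ValueError(f"path distance {d_um} outside [0, {d_max_um}]")
    spec = profile.r_m
    if spec.form == "exponential_gradient":
        return spec.distal_value - (spec.distal_value - spec.soma_value) \
            * math.exp(-spec.tau * d_um / d_max_um)
    for upper, value in spec.region_table:
        if d_um < upper:
            return value
    return spec.region_table[-1][1]


# ---------------------------------------------------------------------------
# Channels and kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Kinetics:
    """Named voltage-gated kinetics table.

    Na and K(DR) rates are the standard fast-spiking interneuron set with a
    common temperature factor ``phi`` and rigid per-channel voltage shifts
    (positive = activation curves moved depolarized) used to position the
    spike threshold; Ih is a first-order gate with a Boltzmann activation
    curve and a fixed time constant.
    """

    name: str
    phi: float = 5.0
    phi_m: float = 1.0                    # extra speed factor on Na activation
    v_shift_na_mv: float = 0.0
    v_shift_h_mv: float | None = None     # None: follow v_shift_na_mv
    v_shift_k_mv: float = 0.0
    ih_v_half_mv: float = -110.0
    ih_k_mv: float = 10.0
    ih_tau_ms: float = 50.0


# Voltage shifts calibrated once against the in vitro spike-onset voltages
# (dV/dt > 20 V/s criterion): PVI spiking preset ~ -41.8 mV, GC ~ -46 mV.
KINETICS: dict[str, Kinetics] = {
    "fs_interneuron": Kinetics("fs_interneuron", phi_m=3.0,
                               v_shift_na_mv=-4.0, v_shift_h_mv=10.0),
    "gc_reduced": Kinetics("gc_reduced", phi_m=3.0,
                           v_shift_na_mv=-4.0, v_shift_h_mv=10.0),
    # subthreshold variants: unshifted rates give the near-linear dendritic
    # integration of the low-Na / high-K dendrites
    "fs_interneuron_sub": Kinetics("fs_interneuron_sub"),
    "gc_reduced_sub": Kinetics("gc_reduced_sub"),
}


@dataclass(frozen=True)
class ChannelDensities:
    """Maximal conductance densities.  g_Na per structure in mS/cm^2, g_K
    uniform in mS/cm^2, g_Ih uniform in pS/um^2 (converted as
    1 pS/um^2 = 0.1 mS/cm^2)."""

    g_na_ms_cm2: dict[str, float]
    g_k_ms_cm2: float
    g_ih_ps_um2: float
    e_na_mv: float = 55.0
    e_k_mv: float = -90.0
    e_h_mv: float = -30.0
    kinetics_id: str = "fs_interneuron"

    def __post_init__(self):
        if any(v < 0 for v in self.g_na_ms_cm2.values()) \
                or self.g_k_ms_cm2 < 0 or self.g_ih_ps_um2 < 0:
            raise ValueError("conductance densities must be non-negative")
        if self.kinetics_id not in KINETICS:
            raise ValueError(f"unknown kinetics table {self.kinetics_id!r}")


# ---------------------------------------------------------------------------
# E_GABA / G_GABA gradients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EGabaSpec:
    """GABA_A reversal potential along the somato-dendritic axis (mV).

    Either ``uniform`` or linear between two (distance_um, mV) anchors with
    linear extrapolation from the proximal anchor toward the soma and clamping
    at the distal-anchor value beyond it.
    """

    uniform_mv: float | None = None
    anchors: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self):
        if (self.uniform_mv is None) == (self.anchors is None):
            raise ValueError("specify exactly one of uniform_mv or anchors")
        if self.anchors is not None:
            (d0, v0), (d1, v1) = self.anchors
            if not d1 > d0:
                raise ValueError("anchor distances must be strictly increasing")
            if not (math.isfinite(v0) and math.isfinite(v1)):
                raise ValueError("E_GABA anchor values must be finite")


@dataclass(frozen=True)
class GGabaSpec:
    """Peak GABA_A conductance per synapse along the axis (nS); uniform or
    linear between anchors, clamped outside the anchor interval."""

    uniform_ns: float | None = None
    anchors: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self):
        if (self.uniform_ns is None) == (self.anchors is None):
            raise ValueError("specify exactly one of uniform_ns or anchors")
        if self.uniform_ns is not None and self.uniform_ns < 0:
            raise ValueError("G_GABA must be non-negative")
        if self.anchors is not None:
            (d0, g0), (d1, g1) = self.anchors
            if not d1 > d0:
                raise ValueError("anchor distances must be strictly increasing")
            if g0 < 0 or g1 < 0:
                raise ValueError("G_GABA must be non-negative everywhere")


@dataclass(frozen=True)
class GradientSpec:
    egaba: EGabaSpec
    ggaba: GGabaSpec


def egaba_at(spec: GradientSpec | EGabaSpec, d_um: float) -> float:
    """E_GABA (mV) at path distance ``d_um``: linear between anchors,
    linearly extrapolated to the soma, clamped beyond the distal anchor."""
    eg = spec.egaba if isinstance(spec, GradientSpec) else spec
    if eg.uniform_mv is not None:
        return eg.uniform_mv
    (d0, v0), (d1, v1) = eg.anchors
    if d_um >= d1:
        return v1
    slope = (v1 - v0) / (d1 - d0)
    return v0 + slope * (d_um - d0)


def ggaba_at(spec: GradientSpec | GGabaSpec, d_um: float) -> float:
    """G_GABA (nS) at path distance ``d_um``; clamped outside the anchors."""
    gg = spec.ggaba if isinstance(spec, GradientSpec) else spec
    if gg.uniform_ns is not None:
        return gg.uniform_ns
    (d0, g0), (d1, g1) = gg.anchors
    if d_um <= d0:
        return g0
    if d_um >= d1:
        return g1
    return g0 + (g1 - g0) * (d_um - d0) / (d1 - d0)


def pvi_gradients(ggaba: Literal["uniform", "gradient"] | float = "uniform") -> GradientSpec:
    """Experimentally constrained PVI gradients: E_GABA (50, -57.9) ->
    (250, -69.1) mV; G_GABA uniform 14 nS or the linear 14 -> 54 nS
    gradient."""
    eg = EGabaSpec(anchors=((50.0, -57.9), (250.0, -69.1)))
    if ggaba == "uniform":
        gg = GGabaSpec(uniform_ns=14.0)
    elif ggaba == "gradient":
        gg = GGabaSpec(anchors=((50.0, 14.0), (250.0, 54.0)))
    else:
        gg = GGabaSpec(uniform_ns=float(ggaba))
    return GradientSpec(eg, gg)


def gc_gradients(ggaba: float = 10.0) -> GradientSpec:
    """Experimentally constrained GC gradients: E_GABA (50, -78.2) ->
    (250, -74.4) mV; G_GABA uniform (default 10 nS)."""
    return GradientSpec(EGabaSpec(anchors=((50.0, -78.2), (250.0, -74.4))),
                        GGabaSpec(uniform_ns=float(ggaba)))


# ---------------------------------------------------------------------------
# Point processes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynapseSpec:
    """Double-exponential point conductance, peak-normalized to ``g_max_ns``.

    ``site`` is either a compartment index or a ``(primary, distance_um)``
    placement resolved against the cell's morphology.
    """

    site: int | tuple[int, float]
    g_max_ns: float
    tau_rise_ms: float
    tau_decay_ms: float
    e_rev_mv: float
    onset_times_ms: tuple[float, ...] = (0.0,)

    def __post_init__(self):
        if not (self.tau_decay_ms > self.tau_rise_ms > 0):
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.g_max_ns < 0:
            raise ValueError("g_max must be non-negative")


def synapse_peak_time(tau_rise_ms: float, tau_decay_ms: float) -> float:
    """Time-to-peak of the double exponential (ms after onset)."""
    tr, td = tau_rise_ms, tau_decay_ms
    return tr * td / (td - tr) * math.log(td / tr)


def _norm_factor(tau_rise_ms: float, tau_decay_ms: float) -> float:
    tp = synapse_peak_time(tau_rise_ms, tau_decay_ms)
    return 1.0 / (math.exp(-tp / tau_decay_ms) - math.exp(-tp / tau_rise_ms))


def synapse_waveform(s: SynapseSpec, t_ms):
    """Conductance (nS) at time(s) ``t_ms``, summed over onsets.  Zero at each
    onset, peak exactly ``g_max_ns`` per onset, -> 0 as t -> infinity."""
    t = np.asarray(t_ms, dtype=float)
    g = np.zeros_like(t)
    N = _norm_factor(s.tau_rise_ms, s.tau_decay_ms)
    for t0 in s.onset_times_ms:
        dt = t - t0
        active = dt >= 0
        g = g + np.where(
            active,
            s.g_max_ns * N * (np.exp(-np.clip(dt, 0, None) / s.tau_decay_ms)
                              - np.exp(-np.clip(dt, 0, None) / s.tau_rise_ms)),
            0.0)
    return g if g.shape else float(g)


@dataclass(frozen=True)
class ClampSpec:
    """Somatic electrode: voltage clamp through a series resistance ``r_s``
    or constant/scheduled current injection.

    ``schedule`` optionally lists (time_ms, level) steps — command voltage in
    mV for voltage mode, current in pA for current mode — applied on top of
    the base ``v_h_mv`` / ``i_hold_pa``.
    """

    mode: Literal["voltage", "current"]
    site: int = 0
    v_h_mv: float = -70.0
    r_s_mohm: float = 10.0
    i_hold_pa: float = 0.0
    schedule: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.mode not in ("voltage", "current"):
            raise ValueError("mode must be 'voltage' or 'current'")
        if self.r_s_mohm < 0:
            raise ValueError("series resistance must be non-negative")


@dataclass(frozen=True)
class NoiseSpec:
    """Ornstein-Uhlenbeck excitatory/inhibitory point conductances at one
    compartment (the standard point-conductance background model); samples are
    floored at zero when applied.  Defaults follow the in vitro background:
    means 0.25 / 5 nS reversing at 0 / -70 mV; sd = mean/3, tau 2.7 / 10.5 ms.
    """

    site: int = 0
    g_e_mean_ns: float = 0.25
    g_i_mean_ns: float = 5.0
    e_e_mv: float = 0.0
    e_i_mv: float = -70.0
    g_e_sd_ns: float | None = None
    g_i_sd_ns: float | None = None
    tau_e_ms: float = 2.7
    tau_i_ms: float = 10.5
    seed: int = 0

    def __post_init__(self):
        if self.g_e_mean_ns < 0 or self.g_i_mean_ns < 0:
            raise ValueError("mean conductances must be non-negative")
        if self.tau_e_ms <= 0 or self.tau_i_ms <= 0:
            raise ValueError("noise time constants must be positive")

    @property
    def sd_e(self) -> float:
        return self.g_e_mean_ns / 3.0 if self.g_e_sd_ns is None else self.g_e_sd_ns

    @property
    def sd_i(self) -> float:
        return self.g_i_mean_ns / 3.0 if self.g_i_sd_ns is None else self.g_i_sd_ns


# ---------------------------------------------------------------------------
# Cell model
# ---------------------------------------------------------------------------

class CellModel:
    """Per-compartment materialization of a biophysical parameter set.

    Carries the segmented morphology plus numpy vectors of C_m, R_m, channel
    densities and reversal potentials, the E_GABA/G_GABA gradient spec, and
    the bookkeeping the engine needs (areas, axial conductances).
    """

    def __init__(self, cell: SegmentedCell, passive: PassiveProfile,
                 channels: ChannelDensities, gradients: GradientSpec,
                 cell_type: str, passive_only: bool = False,
                 drop_ih: bool = False, e_leak_mv: float = -70.0,
                 v_init_mv: float | None = None):
        self.cell = cell
        self.passive = passive
        self.channels = channels
        self.gradients = gradients
        self.cell_type = cell_type
        self.passive_only = passive_only
        self.drop_ih = drop_ih
        self.e_leak_mv = e_leak_mv
        self.v_init_mv = e_leak_mv if v_init_mv is None else v_init_mv
        self.kinetics = KINETICS[channels.kinetics_id]

        n = cell.n
        struct = cell.structure
        is_soma = struct == int(Structure.SOMA)
        is_axon = struct == int(Structure.AXON)
        is_dend = struct == int(Structure.DENDRITE)
        d_max = cell.max_dendrite_path_um()
        self.d_max_um = d_max

        # primary dendrite = first unbranched section off the soma
        soma_children_secs = {
            int(cell.section[i]) for i in range(n)
            if cell.parent_index[i] >= 0
            and struct[cell.parent_index[i]] == int(Structure.SOMA)
            and is_dend[i]}
        is_primary_dend = is_dend & np.isin(cell.section, list(soma_children_secs))

        region = np.where(is_soma, "soma",
                          np.where(is_axon, "axon",
                                   np.where(is_primary_dend,
                                            "primary_dendrite", "dendrite")))
        self.cm_uf_cm2 = np.array([passive.c_m_for(r) for r in region])
        pd_for_rm = np.where(is_dend, np.minimum(cell.path_distance_um, d_max), 0.0)
        self.rm_kohm_cm2 = np.array(
            [rm_at(passive, d, d_max) for d in pd_for_rm])

        gna = np.zeros(n)
        gna[is_soma] = channels.g_na_ms_cm2.get("soma", 0.0)
        gna[is_axon] = channels.g_na_ms_cm2.get("axon", 0.0)
        gna[is_dend] = channels.g_na_ms_cm2.get("dendrite", 0.0)
        if channels.g_na_ms_cm2.get("axon", 0.0) > 0 and not np.any(is_axon) \
                and not passive_only:
            raise ValueError(
                "preset assigns axonal g_Na but the morphology has no axon")
        gk = np.full(n, channels.g_k_ms_cm2)
        gih = np.full(n, channels.g_ih_ps_um2 * PS_PER_UM2_TO_MS_PER_CM2)
        if passive_only:
            gna[:] = 0.0
            gk[:] = 0.0
        if drop_ih:
            gih[:] = 0.0
        self.g_na_ms_cm2 = gna
        self.g_k_ms_cm2 = gk
        self.g_ih_ms_cm2 = gih

        # derived engine quantities
        area_cm2 = cell.membrane_area_um2 * 1e-8
        self.area_cm2 = area_cm2
        self.c_nf = self.cm_uf_cm2 * area_cm2 * 1e3          # uF -> nF
        self.g_pas_us = area_cm2 / self.rm_kohm_cm2 * 1e3    # 1/kOhm -> uS... (mS)*1e3
        self.g_na_us = gna * area_cm2 * 1e3                  # mS -> uS
        self.g_k_us = gk * area_cm2 * 1e3
        self.g_ih_us = gih * area_cm2 * 1e3
        self.g_axial_us = self._axial_conductances()

    def _axial_conductances(self) -> np.ndarray:
        cell = self.cell
        ra = self.passive.r_a_ohm_cm
        n = cell.n
        g = np.zeros(n)
        L_cm = cell.length_um * 1e-4
        r_cm = cell.diameter_um * 1e-4 / 2.0
        half_r_ohm = ra * (L_cm / 2.0) / (math.pi * r_cm ** 2)
        for i in range(1, n):
            p = cell.parent_index[i]
            g[i] = 1e6 / (half_r_ohm[i] + half_r_ohm[p])
        return g

    # -- placements -------------------------------------------------------

    def resolve_site(self, site: int | tuple[int, float] | str) -> int:
        if isinstance(site, str):
            if site == "soma":
                return self.cell.soma_index
            raise LookupError(f"unknown site {site!r}")
        if isinstance(site, tuple):
            primary, dist = site
            return self.cell.locate(dist, primary=int(primary))
        return int(site)

    def gaba_synapse(self, distance_um: float, primary: int = 0,
                     section: int | None = None,
                     g_max_ns: float | None = None,
                     tau_rise_ms: float = 0.1, tau_decay_ms: float = 20.0,
                     onset_times_ms: tuple[float, ...] = (0.0,),
                     e_rev_mv: float | None = None) -> SynapseSpec:
        """GABA_A synapse at a path distance, with peak conductance and
        reversal pulled from the cell's G_GABA / E_GABA gradients unless
        overridden."""
        idx = self.cell.locate(distance_um, primary=primary, section=section)
        d = float(self.cell.path_distance_um[idx])
        g = ggaba_at(self.gradients, d) if g_max_ns is None else g_max_ns
        e = egaba_at(self.gradients, d) if e_rev_mv is None else e_rev_mv
        return SynapseSpec(site=idx, g_max_ns=g, tau_rise_ms=tau_rise_ms,
                           tau_decay_ms=tau_decay_ms, e_rev_mv=e,
                           onset_times_ms=tuple(onset_times_ms))

    def exc_synapse(self, distance_um: float = 150.0, primary: int = 0,
                    g_max_ns: float = 5.0, tau_rise_ms: float = 0.1,
                    tau_decay_ms: float = 8.0,
                    onset_times_ms: tuple[float, ...] = (0.0,)) -> SynapseSpec:
        idx = self.cell.locate(distance_um, primary=primary)
        return SynapseSpec(site=idx, g_max_ns=g_max_ns, tau_rise_ms=tau_rise_ms,
                           tau_decay_ms=tau_decay_ms, e_rev_mv=0.0,
                           onset_times_ms=tuple(onset_times_ms))

    # -- variants and serialization --------------------------------------

    def passive_variant(self, drop_ih: bool | None = None) -> "CellModel":
        """Copy with Na and K conductances removed (Ih retained by default,
        matching the voltage-clamp simulation conditions)."""
        return CellModel(self.cell, self.passive, self.channels,
                         self.gradients, self.cell_type, passive_only=True,
                         drop_ih=self.drop_ih if drop_ih is None else drop_ih,
                         e_leak_mv=self.e_leak_mv, v_init_mv=self.v_init_mv)

    def to_config(self) -> dict:
        def grad(spec):
            return {"uniform": spec.uniform_mv if isinstance(spec, EGabaSpec)
                    else spec.uniform_ns,
                    "anchors": None if spec.anchors is None
                    else [list(a) for a in spec.anchors]}
        return {
            "cell_type": self.cell_type,
            "passive": {
                "r_a_ohm_cm": self.passive.r_a_ohm_cm,
                "c_m_uf_cm2": dict(self.passive.c_m_regions),
                "r_m": asdict(self.passive.r_m) | {
                    "region_table": [list(r) for r in self.passive.r_m.region_table]},
            },
            "channels": asdict(self.channels),
            "gradients": {"egaba_mv": grad(self.gradients.egaba),
                          "ggaba_ns": grad(self.gradients.ggaba)},
            "passive_only": self.passive_only,
            "drop_ih": self.drop_ih,
            "e_leak_mv": self.e_leak_mv,
            "v_init_mv": self.v_init_mv,
        }

    @staticmethod
    def from_config(cell: SegmentedCell, config: dict) -> "CellModel":
        p = config["passive"]
        rm = p["r_m"]
        passive = PassiveProfile(
            p["r_a_ohm_cm"], dict(p["c_m_uf_cm2"]),
            RmSpec(rm["form"], rm["soma_value"], rm["distal_value"], rm["tau"],
                   tuple(tuple(r) for r in rm["region_table"])))
        ch = dict(config["channels"])
        channels = ChannelDensities(
            dict(ch["g_na_ms_cm2"]), ch["g_k_ms_cm2"], ch["g_ih_ps_um2"],
            ch["e_na_mv"], ch["e_k_mv"], ch["e_h_mv"], ch["kinetics_id"])
        g = config["gradients"]

        def eg(d, cls, key):
            if d["uniform"] is not None:
                return cls(**{key: d["uniform"]})
            return cls(anchors=tuple(tuple(a) for a in d["anchors"]))
        gradients = GradientSpec(eg(g["egaba_mv"], EGabaSpec, "uniform_mv"),
                                 eg(g["ggaba_ns"], GGabaSpec, "uniform_ns"))
        return CellModel(cell, passive, channels, gradients,
                         config["cell_type"], config["passive_only"],
                         config["drop_ih"], config["e_leak_mv"],
                         config["v_init_mv"])

    def parameter_hash(self) -> str:
        h = hashlib.sha256()
        h.update(json.dumps(self.to_config(), sort_keys=True).encode())
        for arr in (self.c_nf, self.g_pas_us, self.g_na_us, self.g_k_us,
                    self.g_ih_us, self.g_axial_us):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]

    def __repr__(self) -> str:
        kind = "passive" if self.passive_only else "active"
        return (f"<CellModel {self.cell_type} ({kind}): "
                f"{self.cell.n} compartments>")


def build_cell(cell: SegmentedCell, passive: PassiveProfile,
               channels: ChannelDensities, gradients: GradientSpec,
               cell_type: str = "custom", **kwargs) -> CellModel:
    """Assemble a :class:`CellModel` from explicit specs."""
    return CellModel(cell, passive, channels, gradients, cell_type, **kwargs)


def preset_cell_model(cell: SegmentedCell, cell_type: str,
                      spiking: bool = False, passive_only: bool = False,
                      drop_ih: bool = False,
                      ggaba: Literal["uniform", "gradient"] | float = "uniform",
                      egaba_uniform_mv: float | None = None) -> CellModel:
    """Built-in PVI / GC presets (see module docstring for the values).

    ``spiking`` selects the high-density Na/K set used for the discharge
    protocols; ``ggaba='gradient'`` selects the fitted linear PVI G_GABA
    gradient; ``egaba_uniform_mv`` overrides the E_GABA gradient with a
    uniform value (the gradient-swap controls).
    """
    ct = cell_type.upper()
    if ct == "PVI":
        passive = PassiveProfile(170.0, {"all": 0.9},
                                 RmSpec("exponential_gradient", 10.0, 100.0, 5.0))
        gna = {"soma": 55.0, "axon": 85.0, "dendrite": 0.0} if spiking \
            else {"soma": 25.0, "axon": 25.0, "dendrite": 1.0}
        channels = ChannelDensities(
            gna, 20.0, 1.0,
            kinetics_id="fs_interneuron" if spiking else "fs_interneuron_sub")
        gradients = pvi_gradients(ggaba)
        e_leak, v_init = -82.0, -65.0
    elif ct == "GC":
        passive = PassiveProfile(
            210.0, {"soma": 1.0, "primary_dendrite": 1.0, "axon": 1.0,
                    "dendrite": 1.6},
            RmSpec("stepwise", region_table=((20.0, 80.0), (math.inf, 50.0))))
        gna = {"soma": 120.0, "axon": 160.0, "dendrite": 0.0} if spiking \
            else {"soma": 40.0, "axon": 60.0, "dendrite": 0.0}
        channels = ChannelDensities(
            gna, 20.0, 0.5,
            kinetics_id="gc_reduced" if spiking else "gc_reduced_sub")
        gradients = gc_gradients(10.0 if ggaba == "uniform" else ggaba)
        e_leak, v_init = -70.0, -70.0
    else:
        raise ValueError(f"unknown cell type {cell_type!r}")
    if egaba_uniform_mv is not None:
        gradients = GradientSpec(EGabaSpec(uniform_mv=egaba_uniform_mv),
                                 gradients.ggaba)
    return CellModel(cell, passive, channels, gradients, ct,
                     passive_only=passive_only, drop_ih=drop_ih,
                     e_leak_mv=e_leak, v_init_mv=v_init)
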