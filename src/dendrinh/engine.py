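"""Simulation engine: integrate cell models and measure from the results.

`integrate` drives the backward-Euler tree solver in :mod:`dendrinh._solver`
with synapses, electrode clamps and stochastic background conductances;
measurement primitives (input resistance, holding current, spike detection,
Nernst potentials) live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._solver import simulate_kernel
from .model import CellModel, ClampSpec, NoiseSpec, SynapseSpec, _norm_factor

__all__ = [
    "Trace", "SimulationResult", "integrate", "voltage_clamp_run",
    "measure_rin", "find_holding_current", "detect_spikes",
    "nernst_potential", "steady_state_input_resistance", "resting_potential",
]

GAS_CONSTANT = 8.314462618       # J / (mol K)
FARADAY = 96485.33212            # C / mol
_IDEAL_CLAMP_RS_MOHM = 1e-4      # 100 Ohm stands in for a perfect electrode


@dataclass
class Trace:
    """Uniformly sampled recording at one site."""

    dt_ms: float
    t0_ms: float
    values: np.ndarray
    site: int
    kind: Literal["voltage", "current", "conductance"]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace needs at least two samples")
        if not np.all(np.isfinite(self.values)):
            raise FloatingPointError("trace contains non-finite values")

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + self.dt_ms * np.arange(self.values.size)

    def window(self, t_lo_ms: float, t_hi_ms: float) -> np.ndarray:
        t = self.times_ms
        sel = (t >= t_lo_ms) & (t <= t_hi_ms)
        if not sel.any():
            raise ValueError(f"empty window [{t_lo_ms}, {t_hi_ms}] ms")
        return self.values[sel]


@dataclass
class SimulationResult:
    traces: list[Trace]
    spike_times: dict[int, list[float]]
    metadata: dict

    def trace(self, site: int, kind: str = "voltage") -> Trace:
        for tr in self.traces:
            if tr.site == site and tr.kind == kind:
                return tr
        raise LookupError(f"no {kind} trace recorded at site {site}")

    @property
    def electrode_current(self) -> Trace:
        for tr in self.traces:
            if tr.kind == "current":
                return tr
        raise LookupError("no electrode current recorded (no voltage clamp)")


def _schedule_to_array(base: float, schedule, dt: float, nsteps: int) -> np.ndarray:
    arr = np.full(nsteps, float(base))
    for t_on, level in schedule:
        arr[int(round(t_on / dt)):] = float(level)
    return arr


def integrate(cell: CellModel,
              stimuli: Iterable[SynapseSpec | ClampSpec | NoiseSpec] = (),
              dt_ms: float = 0.025,
              duration_ms: float = 100.0,
              record_sites: Sequence = ("soma",),
              seed: int = 0,
              v_init_mv: float | None = None,
              detect: bool = False,
              dvdt_threshold: float = 20.0) -> SimulationResult:
    """Integrate the cable equation with the supplied stimuli.

    Solves C_m dV/dt = -sum g_x (V - E_x) + axial coupling + injected
    current per compartment with backward Euler on the tree (one linear solve
    per step).  Deterministic for a fixed ``seed``.  At most one voltage
    clamp and one noise process are supported per run.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    if duration_ms < dt_ms:
        raise ValueError("duration must cover at least one step")
    nsteps = int(round(duration_ms / dt_ms))
    n = cell.cell.n

    synapses = [s for s in stimuli if isinstance(s, SynapseSpec)]
    clamps = [s for s in stimuli if isinstance(s, ClampSpec)]
    noises = [s for s in stimuli if isinstance(s, NoiseSpec)]
    vclamps = [c for c in clamps if c.mode == "voltage"]
    iclamps = [c for c in clamps if c.mode == "current"]
    if len(vclamps) > 1 or len(noises) > 1:
        raise ValueError("at most one voltage clamp and one noise process")

    # synapses
    nsyn = len(synapses)
    syn_comp = np.zeros(nsyn, dtype=np.int64)
    syn_g = np.zeros(nsyn)
    syn_e = np.zeros(nsyn)
    syn_fr = np.zeros(nsyn)
    syn_fd = np.zeros(nsyn)
    events: list[tuple[int, int]] = []
    for s_i, s in enumerate(synapses):
        idx = cell.resolve_site(s.site)
        if not 0 <= idx < n:
            raise LookupError(f"synapse site {s.site} out of range")
        syn_comp[s_i] = idx
        syn_g[s_i] = s.g_max_ns * 1e-3 * _norm_factor(s.tau_rise_ms, s.tau_decay_ms)
        syn_e[s_i] = s.e_rev_mv
        syn_fr[s_i] = math.exp(-dt_ms / s.tau_rise_ms)
        syn_fd[s_i] = math.exp(-dt_ms / s.tau_decay_ms)
        for t0 in s.onset_times_ms:
            step = int(round(t0 / dt_ms))
            if 0 <= step < nsteps:
                events.append((step, s_i))
    events.sort()
    on_step = np.array([e[0] for e in events], dtype=np.int64)
    on_syn = np.array([e[1] for e in events], dtype=np.int64)

    # voltage clamp
    clamp_idx = -1
    g_clamp = 0.0
    vcmd = np.zeros(1)
    if vclamps:
        c = vclamps[0]
        clamp_idx = cell.resolve_site(c.site)
        rs = max(c.r_s_mohm, _IDEAL_CLAMP_RS_MOHM)
        g_clamp = 1.0 / rs            # 1/MOhm = uS
        vcmd = _schedule_to_array(c.v_h_mv, c.schedule, dt_ms, nsteps)

    # current injections: static per-compartment + one scheduled site
    iinj_static = np.zeros(n)
    inj_idx = -1
    inj_na = np.zeros(1)
    scheduled = [c for c in iclamps if c.schedule]
    if len(scheduled) > 1:
        raise ValueError("at most one scheduled current clamp")
    for c in iclamps:
        idx = cell.resolve_site(c.site)
        if c.schedule:
            inj_idx = idx
            inj_na = _schedule_to_array(c.i_hold_pa, c.schedule, dt_ms, nsteps) * 1e-3
        else:
            iinj_static[idx] += c.i_hold_pa * 1e-3

    # background noise
    noise_idx = -1
    ge_m = gi_m = fe = fi = se = si = e_e = e_i = 0.0
    xi = np.zeros((1, 2))
    if noises:
        nz = noises[0]
        noise_idx = cell.resolve_site(nz.site)
        ge_m = nz.g_e_mean_ns * 1e-3
        gi_m = nz.g_i_mean_ns * 1e-3
        fe = math.exp(-dt_ms / nz.tau_e_ms)
        fi = math.exp(-dt_ms / nz.tau_i_ms)
        se = nz.sd_e * 1e-3 * math.sqrt(1.0 - fe * fe)
        si = nz.sd_i * 1e-3 * math.sqrt(1.0 - fi * fi)
        e_e = nz.e_e_mv
        e_i = nz.e_i_mv
        rng = np.random.default_rng([seed, nz.seed])
        xi = rng.standard_normal((nsteps, 2))

    rec_idx = np.array([cell.resolve_site(s) for s in record_sites],
                       dtype=np.int64)
    for idx in rec_idx:
        if not 0 <= idx < n:
            raise LookupError(f"record site {idx} out of range")

    if v_init_mv is None:
        v_init_mv = vcmd[0] if clamp_idx >= 0 else cell.v_init_mv
    v0 = np.full(n, float(v_init_mv))

    kin = cell.kinetics
    vrec, ielec = simulate_kernel(
        cell.cell.parent_index, cell.g_axial_us, cell.c_nf / dt_ms,
        cell.g_pas_us, np.full(n, cell.e_leak_mv),
        cell.g_na_us, cell.g_k_us, cell.g_ih_us,
        cell.channels.e_na_mv, cell.channels.e_k_mv, cell.channels.e_h_mv,
        kin.v_shift_na_mv,
        kin.v_shift_na_mv if kin.v_shift_h_mv is None else kin.v_shift_h_mv,
        kin.v_shift_k_mv, kin.phi, kin.phi_m, kin.ih_v_half_mv, kin.ih_k_mv, kin.ih_tau_ms,
        syn_comp, syn_g, syn_e, syn_fr, syn_fd, on_step, on_syn,
        clamp_idx, g_clamp, vcmd,
        inj_idx, inj_na, iinj_static,
        noise_idx, ge_m, gi_m, fe, fi, se, si, e_e, e_i, xi,
        v0, dt_ms, nsteps, rec_idx)

    if not np.all(np.isfinite(vrec)):
        bad = np.argwhere(~np.isfinite(vrec))
        raise FloatingPointError(
            f"integration diverged at step {int(bad[0][1])} "
            f"(site {int(rec_idx[bad[0][0]])})")

    traces = [Trace(dt_ms, 0.0, vrec[k], int(rec_idx[k]), "voltage")
              for k in range(len(rec_idx))]
    if clamp_idx >= 0:
        traces.append(Trace(dt_ms, 0.0, ielec, clamp_idx, "current"))

    spike_times: dict[int, list[float]] = {}
    if detect:
        for tr in traces:
            if tr.kind == "voltage":
                spike_times[tr.site] = [s["time_ms"]
                                        for s in detect_spikes(tr, dvdt_threshold)]

    metadata = {"dt_ms": dt_ms, "duration_ms": duration_ms, "seed": seed,
                "model_hash": cell.parameter_hash()}
    return SimulationResult(traces, spike_times, metadata)


def voltage_clamp_run(cell: CellModel, clamp: ClampSpec, synapse: SynapseSpec,
                      dt_ms: float = 0.025, duration_ms: float = 250.0,
                      baseline_subtract: bool = False) -> Trace:
    """Somatic voltage clamp during one synaptic event; returns the electrode
    current trace (nA).  The electrode is an ideal source in series with
    ``clamp.r_s_mohm`` into the clamped compartment."""
    if clamp.mode != "voltage":
        raise ValueError("voltage_clamp_run requires a voltage-mode clamp")
    res = integrate(cell, [clamp, synapse], dt_ms=dt_ms,
                    duration_ms=duration_ms,
                    record_sites=(clamp.site,))
    tr = res.electrode_current
    if baseline_subtract:
        onset = min(synapse.onset_times_ms)
        base = tr.window(max(0.0, onset - 50.0), onset - dt_ms).mean()
        tr = Trace(tr.dt_ms, tr.t0_ms, tr.values - base, tr.site, tr.kind)
    return tr


# ---------------------------------------------------------------------------
# Linear steady-state helpers (passive + linearized Ih)
# ---------------------------------------------------------------------------

def _chord_system(cell: CellModel, v: np.ndarray,
                  g_extra_us: np.ndarray | None = None,
                  b_extra_na: np.ndarray | None = None):
    """Conductance matrix G (uS) and source vector b (nA) of the passive
    tree with Ih at its chord conductance for voltage profile ``v``."""
    n = cell.cell.n
    parent = cell.cell.parent_index
    kin = cell.kinetics
    q = 1.0 / (1.0 + np.exp((v - kin.ih_v_half_mv) / kin.ih_k_mv))
    diag = cell.g_pas_us + cell.g_ih_us * q
    b = cell.g_pas_us * cell.e_leak_mv + cell.g_ih_us * q * cell.channels.e_h_mv
    if g_extra_us is not None:
        diag = diag + g_extra_us
    if b_extra_na is not None:
        b = b + b_extra_na
    rows, cols, vals = list(range(n)), list(range(n)), list(diag)
    for i in range(1, n):
        p = int(parent[i])
        g = cell.g_axial_us[i]
        vals[i] += g
        vals[p] += g
        rows += [i, p]
        cols += [p, i]
        vals += [-g, -g]
    G = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return G, b


def _steady_voltage(cell: CellModel, iinj_na: np.ndarray | None = None,
                    clamp: tuple[int, float] | None = None,
                    iters: int = 60, tol: float = 1e-10) -> np.ndarray:
    """Nonlinear (Ih chord) steady state, optionally with the soma clamped
    (``clamp`` = (compartment, command mV) through an ideal electrode)."""
    n = cell.cell.n
    v = np.full(n, cell.e_leak_mv)
    b_inj = np.zeros(n) if iinj_na is None else np.asarray(iinj_na, float)
    g_extra = None
    if clamp is not None:
        idx, vc = clamp
        g_extra = np.zeros(n)
        g_extra[idx] = 1.0 / _IDEAL_CLAMP_RS_MOHM
        b_inj = b_inj + g_extra * 0.0
        b_clamp = np.zeros(n)
        b_clamp[idx] = g_extra[idx] * vc
        b_inj = b_inj + b_clamp
        v[:] = vc
    for _ in range(iters):
        G, b = _chord_system(cell, v, g_extra_us=g_extra)
        v_new = spla.spsolve(G, b + b_inj)
        dv = np.max(np.abs(v_new - v))
        v = v_new
        if dv < tol:
            break
    return v


def resting_potential(cell: CellModel) -> float:
    """Somatic resting potential (mV) of the passive+Ih steady state."""
    return float(_steady_voltage(cell)[cell.cell.soma_index])


def steady_state_input_resistance(cell: CellModel, dv_mv: float = -10.0) -> float:
    """Somatic input resistance (MOhm) of the passive(+Ih) model.

    Computed as the secant over a ``dv_mv`` somatic voltage-clamp step
    between two fully re-equilibrated steady states — the infinite-duration
    limit of the pulse protocol in :func:`measure_rin`, with which it agrees
    to well under 1%.
    """
    soma = cell.cell.soma_index
    v_rest = resting_potential(cell)

    def electrode_current(vc: float) -> float:
        v = _steady_voltage(cell, clamp=(soma, vc))
        return (vc - v[soma]) / _IDEAL_CLAMP_RS_MOHM

    i0 = electrode_current(v_rest)
    i1 = electrode_current(v_rest + dv_mv)
    return dv_mv / (i1 - i0)


def measure_rin(cell: CellModel, dv_mv: float = -10.0,
                settle_ms: float = 300.0, pulse_ms: float = 1000.0,
                dt_ms: float = 0.025) -> float:
    """Input resistance (MOhm) from the current response at the end of a
    -10 mV, 1 s somatic voltage-clamp pulse from rest."""
    v_rest = resting_potential(cell)
    clamp = ClampSpec("voltage", site=cell.cell.soma_index, v_h_mv=v_rest,
                      r_s_mohm=0.0,
                      schedule=((settle_ms, v_rest + dv_mv),))
    res = integrate(cell, [clamp], dt_ms=dt_ms,
                    duration_ms=settle_ms + pulse_ms,
                    record_sites=(cell.cell.soma_index,),
                    v_init_mv=v_rest)
    cur = res.electrode_current
    i_base = cur.window(settle_ms - 20.0, settle_ms - dt_ms).mean()
    i_end = cur.window(settle_ms + pulse_ms - 20.0, settle_ms + pulse_ms).mean()
    di = i_end - i_base
    if abs(di) < 1e-12:
        raise RuntimeError("input-resistance measurement: no current change")
    return dv_mv / di


def find_holding_current(cell: CellModel, v_target_mv: float,
                         settle_ms: float = 500.0, dt_ms: float = 0.05,
                         tol_mv: float = 0.1, max_iter: int = 30) -> float:
    """Somatic holding current (pA) that settles the soma at ``v_target_mv``.

    Secant iteration on the steady somatic voltage after ``settle_ms`` of
    integration, seeded by the linearized input resistance.
    """
    v_rest = resting_potential(cell)
    if abs(v_target_mv - v_rest) > 30.0:
        raise ValueError(
            f"target {v_target_mv} mV is more than 30 mV from rest ({v_rest:.1f} mV)")
    rin = steady_state_input_resistance(cell)

    def settled_v(i_pa: float) -> float:
        res = integrate(
            cell, [ClampSpec("current", site=0, i_hold_pa=i_pa)],
            dt_ms=dt_ms, duration_ms=settle_ms, record_sites=(0,),
            v_init_mv=v_target_mv)
        return float(res.trace(0).window(settle_ms - 10.0, settle_ms).mean())

    i0 = 0.0
    v0 = settled_v(i0)
    if abs(v0 - v_target_mv) < tol_mv:
        return i0
    i1 = (v_target_mv - v0) / rin * 1e3   # mV/MOhm = nA -> pA
    for _ in range(max_iter):
        v1 = settled_v(i1)
        if abs(v1 - v_target_mv) < tol_mv:
            return i1
        if abs(v1 - v0) < 1e-12:
            break
        i0, i1, v0 = i1, i1 + (v_target_mv - v1) * (i1 - i0) / (v1 - v0), v1
    raise RuntimeError(
        f"holding-current search did not converge (last V = {v1:.2f} mV)")


# ---------------------------------------------------------------------------
# Spike detection and Nernst potentials
# ---------------------------------------------------------------------------

def detect_spikes(trace: Trace, dvdt_threshold_v_s: float = 20.0,
                  min_below_ms: float = 1.0,
                  refractory_ms: float = 2.0) -> list[dict]:
    """Spike onsets from a voltage trace by the dV/dt-threshold criterion.

    Onset = first sample where the centered-difference dV/dt exceeds the
    threshold after having been below it for at least ``min_below_ms``;
    the onset voltage is linearly interpolated at the crossing.  Events
    within ``refractory_ms`` are grouped.  mV/ms equals V/s.
    """
    if trace.kind != "voltage":
        raise TypeError("spike detection requires a voltage trace")
    v = trace.values
    dt = trace.dt_ms
    dvdt = np.gradient(v, dt)
    above = dvdt > dvdt_threshold_v_s
    min_below = max(1, int(round(min_below_ms / dt)))
    spikes: list[dict] = []
    below_run = min_below  # trace start counts as quiescent
    last_t = -math.inf
    for i in range(v.size):
        if above[i]:
            if below_run >= min_below:
                t = trace.t0_ms + i * dt
                if i > 0 and above[i] and not above[i - 1]:
                    # interpolate the crossing between samples i-1 and i
                    f = (dvdt_threshold_v_s - dvdt[i - 1]) / (dvdt[i] - dvdt[i - 1])
                    t = trace.t0_ms + (i - 1 + f) * dt
                    v_on = v[i - 1] + f * (v[i] - v[i - 1])
                else:
                    v_on = v[i]
                if t - last_t >= refractory_ms:
                    spikes.append({"time_ms": float(t),
                                   "threshold_mv": float(v_on)})
                    last_t = t
            below_run = 0
        else:
            below_run += 1
    return spikes


def nernst_potential(c_in_mm: float, c_out_mm: float, z: int,
                     temperature_c: float) -> float:
    """Nernst equilibrium potential (mV): E = (R T / z F) ln(c_out/c_in).

    For chloride (z = -1) with external concentration above internal this is
    negative, matching the physiological sign convention.
    """
    if c_in_mm <= 0 or c_out_mm <= 0:
        raise ValueError("concentrations must be positive")
    if z == 0:
        raise ValueError("valence must be non-zero")
    t_k = temperature_c + 273.15
    return (GAS_CONSTANT * t_k / (z * FARADAY)) * math.log(c_out_mm / c_in_mm) * 1e3
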