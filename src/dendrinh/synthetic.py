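"""Synthetic "experimental" datasets with recorded ground truth.

Every generator is seed-deterministic and records the truth needed to score
any downstream estimate without re-simulation:

* :func:`gen_iv_dataset` — IPSP/IPSC amplitude-vs-holding-potential data
  with a known reversal potential, for validating the cubic-intercept
  E_GABA estimator and the I-V slope conductance.
* :func:`gen_sweep_set` — EPSP/IPSP/PSP sweep triplets with the in vitro
  amplitude and kinetics statistics plus additive noise, for validating the
  inhibitory-effect pipeline.
* :func:`gen_attenuation_target` — in vitro-style normalized G_GABA vs
  distance profiles (PVI-like ending at 0.61, GC-like at 0.15).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .engine import Trace
from .estimators import IVDataset
from .model import SynapseSpec, synapse_peak_time, synapse_waveform
from .protocols import AttenuationProfile

__all__ = [
    "SyntheticIV", "SweepSet", "gen_iv_dataset", "gen_sweep_set",
    "gen_attenuation_target", "double_exp_from_shape",
    "PVI_EPSP_STATS", "GC_EPSP_STATS", "PVI_IPSP_STATS", "GC_IPSP_STATS",
]


# Amplitude (mV) and kinetics (ms) statistics of the in vitro signals
# (mean, sd across sweeps): EPSP rise 1.6 / 3.4 ms and half-duration
# 18.9 / 57.9 ms for PVI / GC; uncIPSP half-durations 63.4 / 128.3 ms.
PVI_EPSP_STATS = {"amp_mv": (4.3, 0.7), "rise_ms": (1.6, 0.3),
                  "half_width_ms": (18.9, 1.7)}
GC_EPSP_STATS = {"amp_mv": (7.3, 0.6), "rise_ms": (3.4, 0.4),
                 "half_width_ms": (57.9, 3.9)}
PVI_IPSP_STATS = {"amp_mv": (-0.9, 0.2), "rise_ms": (5.6, 0.5),
                  "half_width_ms": (63.4, 8.9)}
GC_IPSP_STATS = {"amp_mv": (-1.6, 0.3), "rise_ms": (14.2, 1.4),
                 "half_width_ms": (128.3, 9.7)}


@dataclass
class SyntheticIV:
    dataset: IVDataset
    truth: dict
    noise_sd: float
    seed: int


@dataclass
class SweepSet:
    """EPSP/IPSP/PSP trace triplets plus per-set ground truth."""

    sweeps: list[dict]            # each: {'epsp': Trace, 'ipsp': Trace, 'psp': Trace}
    truth: dict
    noise_sd_mv: float
    seed: int

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)


def gen_iv_dataset(e_true_mv: float, g: float,
                   vh_grid_mv: Sequence[float] = tuple(np.arange(-90.0, -39.0, 5.0)),
                   noise_sd: float = 0.0,
                   curvature: float = 0.0,
                   seed: int = 0,
                   amplitude_kind: Literal["pa", "mv"] = "pa") -> SyntheticIV:
    """Amplitude = g * (V_h - E_true) + curvature * (V_h - E_true)^3 + noise.

    With ``amplitude_kind='pa'`` the slope ``g`` is a conductance in nS;
    with 'mv' it is an IPSP-amplitude gain in mV per mV of driving force.
    ``noise_sd`` is in the amplitude unit.
    """
    vh = np.asarray(vh_grid_mv, float)
    if vh.size < 4:
        raise ValueError("need at least 4 holding potentials")
    rng = np.random.default_rng(seed)
    drive = vh - e_true_mv
    amp = g * drive + curvature * drive ** 3
    amp = amp + rng.normal(0.0, noise_sd, size=vh.shape)
    return SyntheticIV(IVDataset(vh, amp, amplitude_kind),
                       truth={"e_gaba_mv": float(e_true_mv), "g": float(g),
                              "curvature": float(curvature)},
                       noise_sd=noise_sd, seed=seed)


def double_exp_from_shape(rise_2080_ms: float, half_width_ms: float,
                          tol: float = 0.01) -> tuple[float, float]:
    """Invert (20-80% rise time, half-duration) to double-exponential
    (tau_rise, tau_decay), to ``tol`` relative accuracy."""
    if half_width_ms <= rise_2080_ms:
        raise ValueError("half-width must exceed the rise time")

    def shape(logtaus):
        tr, td = np.exp(logtaus)
        if td <= tr * 1.0001:
            return np.array([1e3, 1e3])
        norm = 1.0 / (math.exp(-synapse_peak_time(tr, td) / td)
                      - math.exp(-synapse_peak_time(tr, td) / tr))

        def w(t):
            return norm * (math.exp(-t / td) - math.exp(-t / tr))

        tp = synapse_peak_time(tr, td)
        t20 = optimize.brentq(lambda t: w(t) - 0.2, 1e-12, tp)
        t80 = optimize.brentq(lambda t: w(t) - 0.8, 1e-12, tp)
        t_lo = optimize.brentq(lambda t: w(t) - 0.5, 1e-12, tp)
        t_hi = optimize.brentq(lambda t: w(t) - 0.5, tp, tp + 200.0 * td)
        return np.array([(t80 - t20) / rise_2080_ms - 1.0,
                         (t_hi - t_lo) / half_width_ms - 1.0])

    x0 = np.log([max(rise_2080_ms / 1.5, 1e-3), half_width_ms / math.log(2.0)])
    sol = optimize.least_squares(shape, x0, xtol=1e-14, ftol=1e-14,
                                 diff_step=1e-6)
    resid = np.abs(shape(sol.x))
    if np.any(resid > tol):
        raise RuntimeError(
            f"kinetics inversion residual {resid} exceeds tolerance {tol}")
    tr, td = np.exp(sol.x)
    return float(tr), float(td)


def _sample_stats(rng, stats: dict) -> dict:
    out = {}
    for key, (mean, sd) in stats.items():
        val = rng.normal(mean, sd)
        if key != "amp_mv":
            val = max(val, 0.1 * abs(mean))   # kinetics must stay positive
        out[key] = val
    return out


def gen_sweep_set(cell_type: str = "PVI",
                  n_sweeps: int = 24,
                  epsp_stats: dict | None = None,
                  ipsp_stats: dict | None = None,
                  interaction: Literal["linear_sum", "driving_force"] = "linear_sum",
                  delta_t_ms: float = 4.0,
                  noise_sd_mv: float = 0.2,
                  seed: int = 0,
                  dt_ms: float = 0.1,
                  duration_ms: float = 400.0,
                  e_gaba_rel_mv: float = -5.0) -> SweepSet:
    """Generate EPSP/IPSP/PSP sweep triplets with known truth.

    EPSP and IPSP waveforms are double exponentials matched (by numeric
    inversion) to per-sweep sampled rise times and half-durations.  The PSP
    is the linear sum, or — under ``interaction='driving_force'`` — the
    solution of a single-compartment conductance model in which the
    IPSP-generating conductance acts through the instantaneous driving force
    (V - E_GABA), E_GABA sitting ``e_gaba_rel_mv`` relative to baseline
    (0 = pure shunt).  The noiseless truth (amplitudes and IE) is recorded
    before white Gaussian noise of ``noise_sd_mv`` is added.
    """
    ct = cell_type.upper()
    if epsp_stats is None:
        epsp_stats = PVI_EPSP_STATS if ct == "PVI" else GC_EPSP_STATS
    if ipsp_stats is None:
        ipsp_stats = PVI_IPSP_STATS if ct == "PVI" else GC_IPSP_STATS
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_ms, dt_ms)
    t_gaba = 100.0
    t_exc = t_gaba + delta_t_ms

    sweeps = []
    truth_rows = []
    for _ in range(n_sweeps):
        es = _sample_stats(rng, epsp_stats)
        js = _sample_stats(rng, ipsp_stats)
        if es["half_width_ms"] <= es["rise_ms"] or js["half_width_ms"] <= js["rise_ms"]:
            raise ValueError("sampled kinetics unrealizable (half-width < rise)")
        etr, etd = double_exp_from_shape(es["rise_ms"], es["half_width_ms"])
        itr, itd = double_exp_from_shape(js["rise_ms"], js["half_width_ms"])
        e_amp = max(es["amp_mv"], 0.2)
        i_amp = js["amp_mv"]

        e_spec = SynapseSpec(0, 1.0, etr, etd, 0.0, (t_exc,))
        i_spec = SynapseSpec(0, 1.0, itr, itd, 0.0, (t_gaba,))
        e_wave = e_amp * synapse_waveform(e_spec, t)
        i_wave = i_amp * synapse_waveform(i_spec, t)

        if interaction == "linear_sum":
            psp = e_wave + i_wave
        elif interaction == "driving_force":
            psp = _driving_force_psp(t, e_wave, i_wave, e_gaba_rel_mv)
        else:
            raise ValueError(f"unknown interaction {interaction!r}")

        epsp_amp = float(e_wave.max())
        psp_amp = float(psp.max())
        ipsp_amp = float(i_wave.min()) if i_amp < 0 else float(i_wave.max())
        truth_rows.append({
            "epsp_amp_mv": epsp_amp, "ipsp_amp_mv": ipsp_amp,
            "psp_amp_mv": psp_amp,
            "true_ie": 1.0 - psp_amp / epsp_amp,
            "epsp_rise_ms": es["rise_ms"],
            "epsp_half_width_ms": es["half_width_ms"],
            "ipsp_rise_ms": js["rise_ms"],
            "ipsp_half_width_ms": js["half_width_ms"],
            "delta_t_ms": delta_t_ms,
        })
        sweeps.append({
            "epsp": Trace(dt_ms, 0.0, e_wave + rng.normal(0, noise_sd_mv, t.size), 0, "voltage"),
            "ipsp": Trace(dt_ms, 0.0, i_wave + rng.normal(0, noise_sd_mv, t.size), 0, "voltage"),
            "psp": Trace(dt_ms, 0.0, psp + rng.normal(0, noise_sd_mv, t.size), 0, "voltage"),
        })

    truth = {"sweeps": truth_rows,
             "t_gaba_ms": t_gaba, "t_exc_ms": t_exc,
             "mean_true_ie": float(np.mean([r["true_ie"] for r in truth_rows])),
             "interaction": interaction}
    return SweepSet(sweeps, truth, noise_sd_mv, seed)


def _driving_force_psp(t: np.ndarray, e_wave_mv: np.ndarray,
                       i_wave_mv: np.ndarray, e_gaba_rel_mv: float) -> np.ndarray:
    """PSP from a leaky single compartment in which the inhibitory input is a
    conductance acting through (V - E_GABA).

    The excitatory drive is injected as the current that would alone
    reproduce ``e_wave_mv``; the inhibitory conductance time course is scaled
    so that alone it would produce ``i_wave_mv`` at the linear level.
    Voltages are relative to baseline; tau_m = 15 ms, unit leak.
    """
    tau_m = 15.0
    dt = t[1] - t[0]
    # leak-normalized drives: g_l = 1, currents in "mV" units
    i_exc = e_wave_mv + tau_m * np.gradient(e_wave_mv, dt)
    if abs(e_gaba_rel_mv) < 1e-9:
        # pure shunt: conductance waveform proportional to the IPSP current
        g_i = np.abs(i_wave_mv + tau_m * np.gradient(i_wave_mv, dt)) / 5.0
    else:
        g_i = (i_wave_mv + tau_m * np.gradient(i_wave_mv, dt)) / e_gaba_rel_mv
        g_i = np.clip(g_i, 0.0, None)
    v = np.zeros_like(t)
    for k in range(1, t.size):
        g_tot = 1.0 + g_i[k]
        v_inf = (i_exc[k] + g_i[k] * e_gaba_rel_mv) / g_tot
        f = math.exp(-dt * g_tot / tau_m)
        v[k] = v_inf + (v[k - 1] - v_inf) * f
    return v


def gen_attenuation_target(style: Literal["PVI_like", "GC_like"] = "PVI_like",
                           anchors: Sequence[tuple[float, float]] | None = None,
                           distances_um: Sequence[float] = (50.0, 100.0, 150.0, 200.0, 250.0),
                           ) -> AttenuationProfile:
    """In vitro-style normalized G_GABA attenuation profile.

    Defaults follow a smooth exponential through g_norm(50) = 1 and the
    in vitro endpoints g_norm(250) = 0.61 (PVI-like) or 0.15 (GC-like).
    Explicit ``anchors`` (distance, g_norm) override the defaults and must be
    monotonically non-increasing.
    """
    distances = np.asarray(distances_um, float)
    if anchors is None:
        end = 0.61 if style == "PVI_like" else 0.15
        tau = (distances[-1] - distances[0]) / math.log(1.0 / end)
        norm = np.exp(-(distances - distances[0]) / tau)
    else:
        anchors = sorted(anchors)
        d_a = np.array([a[0] for a in anchors], float)
        g_a = np.array([a[1] for a in anchors], float)
        if np.any(np.diff(g_a) > 0):
            raise ValueError("anchor g_norm values must be non-increasing")
        distances = d_a
        norm = g_a / g_a[0]
    return AttenuationProfile(distances, norm.copy(), norm,
                              reference_distance_um=float(distances[0]))
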