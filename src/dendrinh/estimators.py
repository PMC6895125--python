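"""Derived statistics and curve fits applied to traces and amplitude tables.

Implements the experimental analysis conventions: baseline-subtracted peak
amplitudes, the cubic-intercept E_GABA estimate, slope-conductance (G_GABA)
from current-voltage relationships, the inhibitory effect
IE = 1 - PSP/EPSP, the single-exponential IE-vs-EPSP-amplitude fit, the
sigmoid discharge fit, and spikes-per-trial bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .engine import SimulationResult, Trace

__all__ = [
    "IVDataset", "IEResult", "peak_amplitude", "fit_egaba", "iv_slope",
    "inhibitory_effect", "fit_ie_exponential", "fit_sigmoid",
    "discharge_probability", "EstimationError",
]


class EstimationError(RuntimeError):
    """A fit or estimate could not be produced from the supplied data."""


@dataclass
class IVDataset:
    """Holding-potential / response-amplitude pairs.

    ``amplitude_kind`` records the response unit: 'pa' or 'na' for clamp
    currents, 'mv' for postsynaptic potential amplitudes.
    """

    v_h_mv: np.ndarray
    amplitude: np.ndarray
    amplitude_kind: Literal["pa", "na", "mv"] = "pa"

    def __post_init__(self):
        self.v_h_mv = np.asarray(self.v_h_mv, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.v_h_mv.shape != self.amplitude.shape or self.v_h_mv.ndim != 1:
            raise ValueError("v_h and amplitude must be matching 1-d arrays")
        if np.unique(self.v_h_mv).size < 2:
            raise ValueError("need at least two distinct holding potentials")

    @property
    def n(self) -> int:
        return self.v_h_mv.size


@dataclass(frozen=True)
class IEResult:
    """Inhibitory effect of one pairing: IE = 1 - PSP/EPSP (dimensionless;
    negative = the GABAergic input boosted the EPSP)."""

    ie: float
    epsp_amp_mv: float
    psp_amp_mv: float
    location_um: float = math.nan


def peak_amplitude(trace: Trace,
                   baseline_window_ms: tuple[float, float],
                   search_window_ms: tuple[float, float],
                   polarity: Literal["positive", "negative", "auto"] = "auto",
                   ) -> float:
    """Signed peak amplitude: extremum in the search window minus the
    baseline mean.  Hyperpolarizing deflections come out negative."""
    b0, b1 = baseline_window_ms
    s0, s1 = search_window_ms
    if b1 > s0:
        raise ValueError("baseline window must precede the search window")
    base = float(trace.window(b0, b1).mean())
    seg = trace.window(s0, s1) - base
    if polarity == "positive":
        return float(seg.max())
    if polarity == "negative":
        return float(seg.min())
    return float(seg[np.argmax(np.abs(seg))])


def fit_egaba(data: IVDataset, root_margin_mv: float = 5.0) -> float:
    """E_GABA (mV) as the x-axis intercept of a third-order polynomial fit to
    the amplitude-voltage relationship.

    The real root within [min(V_h) - margin, max(V_h) + margin] is returned;
    with several candidates, the one nearest the interpolated zero-crossing
    of the data itself is chosen.
    """
    if data.n < 4:
        raise ValueError("cubic fit needs at least 4 points")
    if np.ptp(data.v_h_mv) < 15.0:
        raise ValueError("holding potentials must span at least 15 mV")
    coeffs = np.polyfit(data.v_h_mv, data.amplitude, 3)
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-8].real
    lo = data.v_h_mv.min() - root_margin_mv
    hi = data.v_h_mv.max() + root_margin_mv
    cands = real[(real >= lo) & (real <= hi)]
    if cands.size == 0:
        raise EstimationError(
            f"no real cubic root in [{lo:.1f}, {hi:.1f}] mV "
            f"(coefficients {coeffs.tolist()})")
    if cands.size == 1:
        return float(cands[0])
    # several roots: pick the one closest to the empirical zero crossing
    order = np.argsort(data.v_h_mv)
    v, a = data.v_h_mv[order], data.amplitude[order]
    sign_change = np.flatnonzero(np.diff(np.sign(a)) != 0)
    if sign_change.size:
        i = sign_change[0]
        x0 = v[i] - a[i] * (v[i + 1] - v[i]) / (a[i + 1] - a[i])
    else:
        x0 = v[np.argmin(np.abs(a))]
    return float(cands[np.argmin(np.abs(cands - x0))])


def iv_slope(data: IVDataset) -> tuple[float, float]:
    """Slope conductance (nS) and R^2 of the ordinary least-squares line
    through a current-voltage relationship (pA/mV = nS)."""
    if data.amplitude_kind not in ("pa", "na"):
        raise ValueError("slope conductance requires current amplitudes")
    if np.ptp(data.v_h_mv) == 0:
        raise ValueError("degenerate I-V: no spread in holding potential")
    res = stats.linregress(data.v_h_mv, data.amplitude)
    slope = res.slope * (1e3 if data.amplitude_kind == "na" else 1.0)
    return float(slope), float(res.rvalue ** 2)


def inhibitory_effect(epsp_amp_mv: float, psp_amp_mv: float,
                      location_um: float = math.nan) -> IEResult:
    """IE = 1 - PSP/EPSP.  Requires a depolarizing control EPSP."""
    if epsp_amp_mv <= 0:
        raise ValueError("EPSP amplitude must be positive")
    return IEResult(1.0 - psp_amp_mv / epsp_amp_mv, epsp_amp_mv, psp_amp_mv,
                    location_um)


def fit_ie_exponential(pairs: Sequence[tuple[float, float]],
                       grid_mv: np.ndarray | None = None) -> dict:
    """Single-exponential fit IE(a) = offset + A * exp(-a / lam) to
    (EPSP amplitude, IE) pairs, evaluated on the 1-25 mV extrapolation grid
    used for averaging across cells.

    Returns {'A', 'lam_mv', 'offset', 'grid_mv', 'ie_grid'}.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.shape[0] < 5:
        raise ValueError("need at least 5 (amplitude, IE) pairs")
    a, ie = pairs[:, 0], pairs[:, 1]
    if np.ptp(a) < 5.0:
        raise ValueError("EPSP amplitudes must span at least 5 mV")

    def f(x, offset, amp, lam):
        return offset + amp * np.exp(-x / lam)

    amp0 = float(ie[np.argmin(a)] - ie[np.argmax(a)])
    p0 = (float(ie[np.argmax(a)]), amp0 if amp0 != 0 else 0.1,
          max(np.ptp(a) / 3.0, 1.0))
    try:
        popt, _ = optimize.curve_fit(
            f, a, ie, p0=p0,
            bounds=([-2.0, -10.0, 0.1], [2.0, 10.0, 200.0]), maxfev=20000)
    except RuntimeError as exc:
        resid = ie - f(a, *p0)
        raise EstimationError(
            f"exponential IE fit did not converge (residual rms "
            f"{np.sqrt(np.mean(resid ** 2)):.3f})") from exc
    grid = np.arange(1.0, 25.0 + 1e-9, 1.0) if grid_mv is None \
        else np.asarray(grid_mv, float)
    return {"offset": float(popt[0]), "A": float(popt[1]),
            "lam_mv": float(popt[2]), "grid_mv": grid,
            "ie_grid": f(grid, *popt)}


def fit_sigmoid(curve: Sequence[tuple[float, float]]) -> dict:
    """Logistic fit p(g) = p_max / (1 + exp(-(g - g_half)/slope)) to
    (G_exc, discharge probability) points.

    Returns {'p_max', 'g_half_ns', 'slope_ns', 'degenerate'}; all-zero or
    all-one data are flagged degenerate instead of fitted.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.shape[0] < 5:
        raise ValueError("need at least 5 (G_exc, p) points")
    g, p = curve[:, 0], curve[:, 1]
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if np.allclose(p, p[0]):
        return {"p_max": float(p[0]), "g_half_ns": math.nan,
                "slope_ns": math.nan, "degenerate": True}

    def f(x, pmax, half, slope):
        return pmax / (1.0 + np.exp(-(x - half) / slope))

    p0 = (max(p.max(), 0.05), float(g[np.argmin(np.abs(p - p.max() / 2))]),
          max(np.ptp(g) / 10.0, 1e-3))
    popt, _ = optimize.curve_fit(
        f, g, np.clip(p, 0.0, 1.05), p0=p0,
        bounds=([1e-6, g.min() - np.ptp(g), 1e-4],
                [1.05, g.max() + np.ptp(g), 10 * np.ptp(g)]), maxfev=20000)
    return {"p_max": float(popt[0]), "g_half_ns": float(popt[1]),
            "slope_ns": float(popt[2]), "degenerate": False}


def discharge_probability(results: Iterable[SimulationResult],
                          site: int = 0,
                          window_ms: tuple[float, float] | None = None) -> dict:
    """Spikes per trial across repeated runs.

    Returns {'spikes_per_trial', 'p_any_spike', 'n_trials', 'counts'};
    ``spikes_per_trial`` may exceed 1 when single trials fire bursts.
    """
    counts = []
    for res in results:
        times = res.spike_times.get(site)
        if times is None:
            raise ValueError(f"no detected spike times at site {site}; "
                             "run the simulation with detect=True")
        if window_ms is not None:
            t0, t1 = window_ms
            times = [t for t in times if t0 <= t <= t1]
        counts.append(len(times))
    if not counts:
        raise ValueError("need at least one trial")
    counts = np.asarray(counts)
    return {"spikes_per_trial": float(counts.mean()),
            "p_any_spike": float((counts > 0).mean()),
            "n_trials": int(counts.size),
            "counts": counts}
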