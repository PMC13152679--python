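"""Rise–decay kinetic model and fitting.

Sensor responses to a brief release event are modeled as

    y(x) = α · (1 − exp(−x/τON)) · exp(−x/τOFF) + β,    x = t − t0 ≥ 0,

where α is a scale factor, β a constant offset, τON the rise time constant
and τOFF the decay time constant.  The model peaks at
x* = τON·ln(1 + τOFF/τON) with peak amplitude α·f(τON, τOFF) + β, where the
attenuation factor f < 1 is computed by :func:`peak_factor`; initialization
corrects α by f so the fitted scale is not systematically underestimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import Trace

__all__ = [
    "KineticFit",
    "rise_decay",
    "peak_time",
    "peak_factor",
    "fit_rise_decay",
    "average_trials",
    "fit_grid",
]


def rise_decay(
    x: np.ndarray, alpha: float, beta: float, tau_on: float, tau_off: float
) -> np.ndarray:
    """Evaluate α(1−e^(−x/τON))·e^(−x/τOFF) + β for x ≥ 0 (0 + β before)."""
    x = np.asarray(x, dtype=float)
    y = np.where(
        x >= 0,
        alpha * (1.0 - np.exp(-np.clip(x, 0, None) / tau_on))
        * np.exp(-np.clip(x, 0, None) / tau_off),
        0.0,
    )
    return y + beta


def peak_time(tau_on: float, tau_off: float) -> float:
    """Time of the model maximum after onset: τON·ln(1 + τOFF/τON)."""
    return tau_on * np.log(1.0 + tau_off / tau_on)


def peak_factor(tau_on: float, tau_off: float) -> float:
    """Peak value of (1−e^(−x/τON))·e^(−x/τOFF); always in (0, 1)."""
    xs = peak_time(tau_on, tau_off)
    return float((1.0 - np.exp(-xs / tau_on)) * np.exp(-xs / tau_off))


@dataclass
class KineticFit:
    """Fitted rise–decay parameters for one trace."""

    alpha: float
    beta: float
    tau_on: float
    tau_off: float
    sse: float
    converged: bool
    t0: float = 0.0

    def predict(self, x: np.ndarray) -> np.ndarray:
        return rise_decay(x, self.alpha, self.beta, self.tau_on, self.tau_off)


def _residuals(p: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    alpha, beta, log_ton, log_toff = p
    return rise_decay(x, alpha, beta, np.exp(log_ton), np.exp(log_toff)) - y


def fit_rise_decay(
    trace: Trace,
    t0: float = 0.0,
    n_restarts: int = 3,
    seed: int = 12345,
    t_max: float | None = None,
) -> KineticFit:
    """Fit the rise–decay model to a ΔF/F trace by nonlinear least squares.

    Parameters
    ----------
    trace : Trace
        ΔF/F time series; times come from ``trace.times`` (relative to
        ``trace.t0_frame``).
    t0 : float
        Fit origin in seconds (typically the stimulus onset); only samples
        with t ≥ t0 enter the fit.
    n_restarts : int
        Number of jittered multi-start restarts (±50% log-uniform on the τ
        initial values, seeded) tried in addition to the data-driven start;
        the product model has shallow valleys when τON ≈ τOFF.
    t_max : float, optional
        Right edge of the fit window in seconds (default: end of trace).

    Returns
    -------
    KineticFit
        Best parameters by SSE across all starts.  ``converged`` is False if
        no start converged; best-effort parameters are still returned.
    """
    t = trace.times
    mask = t >= t0
    if t_max is not None:
        mask &= t <= t_max
    x = t[mask] - t0
    y = trace.values[mask]
    if len(x) < 8:
        raise ValueError(f"need at least 8 frames after t0, got {len(x)}")

    dt = 1.0 / trace.frame_rate
    duration = float(x[-1]) if x[-1] > 0 else dt

    # data-driven initialization
    pre = trace.values[t < t0]
    beta0 = float(pre.mean()) if len(pre) else float(y[0])
    i_pk = int(np.argmax(y))
    peak = float(y[i_pk])
    ttp = max(float(x[i_pk]), dt)
    ton0 = max(ttp / 2.0, dt / 4.0)
    # decay time: first post-peak sample below beta + (peak-beta)/e
    target = beta0 + (peak - beta0) / np.e
    post = np.nonzero(y[i_pk:] <= target)[0]
    toff0 = float(x[i_pk + post[0]] - x[i_pk]) if len(post) and post[0] > 0 else duration / 3.0
    toff0 = max(toff0, dt / 4.0)
    alpha0 = (peak - beta0) / peak_factor(ton0, toff0)

    lo_tau, hi_tau = dt / 10.0, 10.0 * duration
    bounds = (
        [-np.inf, -np.inf, np.log(lo_tau), np.log(lo_tau)],
        [np.inf, np.inf, np.log(hi_tau), np.log(hi_tau)],
    )

    rng = np.random.default_rng(seed)
    starts = [(ton0, toff0)]
    for _ in range(n_restarts):
        jit = np.exp(rng.uniform(np.log(0.5), np.log(1.5), size=2))
        starts.append((ton0 * jit[0], toff0 * jit[1]))

    best = None
    any_ok = False
    for ton_i, toff_i in starts:
        ton_i = float(np.clip(ton_i, lo_tau * 1.01, hi_tau * 0.99))
        toff_i = float(np.clip(toff_i, lo_tau * 1.01, hi_tau * 0.99))
        a_i = (peak - beta0) / peak_factor(ton_i, toff_i)
        p0 = np.array([a_i if a_i != 0 else alpha0, beta0, np.log(ton_i), np.log(toff_i)])
        try:
            res = least_squares(_residuals, p0, args=(x, y), bounds=bounds, method="trf")
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res.x, bool(res.success))
        any_ok = any_ok or bool(res.success)

    if best is None:
        return KineticFit(np.nan, np.nan, np.nan, np.nan, np.inf, False, t0=t0)
    sse, p, ok = best
    return KineticFit(
        alpha=float(p[0]),
        beta=float(p[1]),
        tau_on=float(np.exp(p[2])),
        tau_off=float(np.exp(p[3])),
        sse=sse,
        converged=ok,
        t0=t0,
    )


def average_trials(traces: list[Trace]) -> tuple[Trace, Trace]:
    """Pointwise mean and sample SD across aligned repeated-trial traces.

    Traces must share length and frame rate and be aligned to their stimulus
    frames.  A single trial returns (trace, zeros) with a warning.
    """
    if not traces:
        raise ValueError("no traces to average")
    n = len(traces[0])
    fr = traces[0].frame_rate
    t0 = traces[0].t0_frame
    for tr in traces[1:]:
        if len(tr) != n or tr.frame_rate != fr or tr.t0_frame != t0:
            raise ValueError("trials must share length, frame rate and alignment")
    stack = np.stack([tr.values for tr in traces])
    mean = Trace(stack.mean(axis=0), fr, t0_frame=t0)
    if len(traces) == 1:
        warnings.warn("single trial: SD trace is zero", stacklevel=2)
        sd = Trace(np.zeros(n), fr, t0_frame=t0)
    else:
        sd = Trace(stack.std(axis=0, ddof=1), fr, t0_frame=t0)
    return mean, sd


def fit_grid(
    response_map,
    bins: int = 20,
    seed: int = 12345,
) -> tuple[pd.DataFrame, dict]:
    """Fit the rise–decay model to every active grid square.

    Parameters
    ----------
    response_map : GridResponseMap
        Output of :func:`dopamap.hotspots.detect_active_rois`; carries the
        per-square ΔF/F traces and the stimulus frame.
    bins : int
        Number of histogram bins for the τON/τOFF summaries.

    Returns
    -------
    (table, histograms)
        ``table``: one row per active square with columns
        ``row, col, alpha, beta, tau_on, tau_off, sse, converged``.
        ``histograms``: dict with keys ``tau_on``/``tau_off`` mapping to
        ``{"counts", "bin_edges"}`` over converged fits, plus ``n_failed``.
    """
    fr = response_map.frame_rate
    t0 = response_map.stim_frame / fr
    rows = []
    for r, c in np.argwhere(response_map.active):
        tr = Trace(response_map.traces[r, c], fr)
        try:
            fit = fit_rise_decay(tr, t0=t0, seed=seed)
        except ValueError:
            fit = KineticFit(np.nan, np.nan, np.nan, np.nan, np.inf, False, t0=t0)
        rows.append(
            {
                "row": int(r),
                "col": int(c),
                "alpha": fit.alpha,
                "beta": fit.beta,
                "tau_on": fit.tau_on,
                "tau_off": fit.tau_off,
                "sse": fit.sse,
                "converged": fit.converged,
            }
        )
    cols = ["row", "col", "alpha", "beta", "tau_on", "tau_off", "sse", "converged"]
    table = pd.DataFrame(rows, columns=cols)
    good = table[table["converged"]] if len(table) else table
    hists: dict = {"n_failed": int(len(table) - len(good))}
    for key in ("tau_on", "tau_off"):
        vals = good[key].to_numpy() if len(good) else np.array([])
        counts, edges = np.histogram(vals, bins=bins) if len(vals) else (np.array([]), np.array([]))
        hists[key] = {"counts": counts.tolist(), "bin_edges": edges.tolist()}
    return table, hists
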