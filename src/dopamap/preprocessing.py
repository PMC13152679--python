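"""ΔF/F conversion, photobleach correction, low-pass filtering, FWHM.

Two baseline conventions are supported, matching the two acquisition
protocols the pipeline serves:

* ``prestim_mean`` — F0 is the mean intensity over the frames before the
  stimulus (evoked-release trials);
* ``trial_median`` — F0 is the median intensity over the whole trial
  (spontaneous-activity recordings, where no pre-stimulus epoch exists).

Slow photobleaching is removed by fitting a double exponential plus a
constant and subtracting the exponential part, keeping the asymptotic level
so ΔF/F stays interpretable.  The low-pass filter is a third-order
Butterworth applied forward–backward (zero phase) by default so that
event-triggered timing is not lagged; a causal single-pass mode is exposed
for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import least_squares

from .io import MovieStack, Trace

__all__ = [
    "BaselineSpec",
    "BleachFit",
    "compute_dff",
    "correct_bleach",
    "lowpass",
    "profile_fwhm",
]


@dataclass(frozen=True)
class BaselineSpec:
    """How F0 is defined for ΔF/F = (F − F0)/F0."""

    mode: str = "prestim_mean"  # prestim_mean | trial_median
    prestim_end: int | None = None  # exclusive end of the baseline window

    def __post_init__(self) -> None:
        if self.mode not in ("prestim_mean", "trial_median"):
            raise ValueError(f"unknown baseline mode {self.mode!r}")
        if self.mode == "prestim_mean" and self.prestim_end is not None and self.prestim_end < 2:
            raise ValueError("prestim_end must be at least 2 frames")


def _resolve_prestim_end(spec: BaselineSpec, stim_frames: tuple[int, ...], n: int) -> int:
    if spec.prestim_end is not None:
        end = spec.prestim_end
    elif stim_frames:
        end = stim_frames[0]
    else:
        raise ValueError(
            "prestim_mean baseline needs prestim_end or stimulus frames in the data"
        )
    if not 2 <= end <= n:
        raise ValueError(f"baseline window [0, {end}) invalid for {n} frames")
    return end


def compute_dff(x: Trace | MovieStack, spec: BaselineSpec) -> Trace | MovieStack:
    """Convert intensities to ΔF/F = (F − F0)/F0 under the given baseline.

    For movies F0 is computed per pixel before any spatial aggregation
    (aggregate first and then call this on the mean trace for the other
    order).  Non-positive F0 anywhere is rejected, naming the offending
    pixel or trace — it signals a dead or clipped region.
    """
    if isinstance(x, MovieStack):
        data = x.data.astype(float)
        if spec.mode == "prestim_mean":
            end = _resolve_prestim_end(spec, x.stim_frames, x.n_frames)
            f0 = data[:end].mean(axis=0)
        else:
            f0 = np.median(data, axis=0)
        bad = np.argwhere(f0 <= 0)
        if len(bad):
            y, xpix = bad[0]
            raise ValueError(
                f"non-positive baseline F0 at pixel (y={y}, x={xpix}); "
                f"{len(bad)} pixels affected"
            )
        return x.with_data((data - f0) / f0)
    data = x.values
    if spec.mode == "prestim_mean":
        end = _resolve_prestim_end(spec, (), len(data)) if spec.prestim_end is not None else None
        if end is None:
            raise ValueError("prestim_mean on a bare trace requires prestim_end")
        f0 = data[:end].mean()
    else:
        f0 = float(np.median(data))
    if f0 <= 0:
        raise ValueError(f"non-positive baseline F0 = {f0} for trace")
    return x.with_values((data - f0) / f0)


@dataclass
class BleachFit:
    """Double-exponential photobleach fit y(t) = A1·e^(−t/τ1) + A2·e^(−t/τ2) + C."""

    a1: float
    tau1: float
    a2: float
    tau2: float
    c: float
    converged: bool
    residual_norm: float

    def curve(self, t: np.ndarray) -> np.ndarray:
        return self.a1 * np.exp(-t / self.tau1) + self.a2 * np.exp(-t / self.tau2) + self.c


def _bleach_residuals(p, t, y, w):
    a1, lt1, a2, lt2, c = p
    model = a1 * np.exp(-t / np.exp(lt1)) + a2 * np.exp(-t / np.exp(lt2)) + c
    return (model - y) * w


def correct_bleach(
    x: Trace, weights: np.ndarray | None = None
) -> tuple[Trace, BleachFit]:
    """Fit and subtract a double-exponential photobleach trend.

    The full trace is fitted to A1·e^(−t/τ1) + A2·e^(−t/τ2) + C by bounded
    nonlinear least squares (τ ∈ (2 frame periods, 10× duration], A ≥ 0);
    initial τ values come from log-linear fits of the first and last thirds.
    The corrected trace is x − fit + C, so the asymptotic level is kept.
    ``weights`` (same length as the trace) can emphasize the early frames
    where bleaching is fastest; unweighted by default.

    On non-convergence the input is returned unchanged with
    ``converged=False`` — data are never silently altered.
    """
    y = x.values
    n = len(y)
    if n < 8:
        raise ValueError("bleach correction needs at least 8 frames")
    t = np.arange(n) / x.frame_rate
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w < 0):
        raise ValueError("weights must be nonnegative, one per frame")

    dt = 1.0 / x.frame_rate
    duration = t[-1]
    lo, hi = 2.0 * dt, 10.0 * duration

    # initialization from log-linear fits of the first / last thirds
    c0 = float(min(np.mean(y[-max(3, n // 10):]), np.min(y)))
    span = float(y[0] - c0)
    eps = max(abs(span), np.ptp(y), 1e-12) * 1e-9
    r = np.clip(y - c0, eps, None)
    third = max(3, n // 3)

    def _loglin_tau(sl):
        coef = np.polyfit(t[sl], np.log(r[sl]), 1)
        return -1.0 / coef[0] if coef[0] < 0 else None

    tau_fast = _loglin_tau(slice(0, third)) or duration / 10.0
    tau_slow = _loglin_tau(slice(n - third, n)) or duration
    tau_fast = float(np.clip(tau_fast, lo * 1.01, hi * 0.99))
    tau_slow = float(np.clip(max(tau_slow, 2.0 * tau_fast), lo * 1.01, hi * 0.99))
    a_tot = max(span, 0.0)
    p0 = np.array([0.5 * a_tot, np.log(tau_fast), 0.5 * a_tot, np.log(tau_slow), c0])
    # identifiability bounds: when a decay is much slower than the record it
    # trades off against C, so amplitudes are capped near the observed range
    # and C is kept within one range of the data — the subtracted trend can
    # then never dwarf the signal it is correcting.
    rng_y = float(np.ptp(y)) or 1.0
    bounds = (
        [0.0, np.log(lo), 0.0, np.log(lo), float(np.min(y)) - 0.25 * rng_y],
        [2.0 * rng_y, np.log(hi), 2.0 * rng_y, np.log(hi), float(np.max(y))],
    )
    p0[0] = min(p0[0], 1.9 * rng_y)
    p0[2] = min(p0[2], 1.9 * rng_y)
    try:
        # soft-L1 loss so brief transients riding on the bleach trend act as
        # outliers instead of bending the fitted exponentials
        res = least_squares(
            _bleach_residuals, p0, args=(t, y, w), bounds=bounds, method="trf",
            x_scale="jac", max_nfev=5000, loss="soft_l1", f_scale=0.03 * rng_y,
        )
    except Exception:
        res = None
    if res is None or not res.success:
        fit = BleachFit(np.nan, np.nan, np.nan, np.nan, np.nan, False,
                        residual_norm=np.inf)
        return x, fit
    a1, lt1, a2, lt2, c = res.x
    fit = BleachFit(
        a1=float(a1), tau1=float(np.exp(lt1)), a2=float(a2), tau2=float(np.exp(lt2)),
        c=float(c), converged=True, residual_norm=float(np.linalg.norm(res.fun)),
    )
    corrected = y - fit.curve(t) + fit.c
    return x.with_values(corrected), fit


def lowpass(
    x: Trace, cutoff: float = 0.68, order: int = 3, zero_phase: bool = True
) -> Trace:
    """Third-order Butterworth low-pass, zero-phase by default.

    Forward–backward application squares the magnitude response, so the gain
    at the cutoff frequency is exactly 1/2 and symmetric pulses are not
    shifted in time.  The cutoff must lie below Nyquist; at 1.47 Hz sampling
    Nyquist is 0.735 Hz, so the 0.68 Hz default is valid but close — the
    filter is built in second-order sections for numerical stability there.
    """
    nyq = x.frame_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below Nyquist ({nyq} Hz at "
            f"{x.frame_rate} Hz sampling)"
        )
    sos = signal.butter(order, cutoff, btype="low", fs=x.frame_rate, output="sos")
    if zero_phase:
        out = signal.sosfiltfilt(sos, x.values)
    else:
        out = signal.sosfilt(sos, x.values)
    return x.with_values(out)


def profile_fwhm(z: np.ndarray, intensity: np.ndarray) -> float:
    """Full width at half maximum of an intensity profile.

    The minimum is subtracted as baseline, the two half-maximum crossings
    around the peak are located by linear interpolation, and the width is
    their separation (same units as ``z``).  Invariant to affine intensity
    rescaling.  A profile truncated before it falls to half maximum on
    either side is rejected (incomplete stack).
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if z.shape != y.shape or z.ndim != 1 or len(z) < 3:
        raise ValueError("z and intensity must be matching 1-D arrays, length >= 3")
    if np.any(np.diff(z) <= 0):
        raise ValueError("z must be strictly increasing")
    y = y - y.min()
    i_pk = int(np.argmax(y))
    if i_pk in (0, len(y) - 1):
        raise ValueError("profile maximum lies on the boundary; no interior peak")
    half = y[i_pk] / 2.0

    def _cross(idx_from, step):
        i = i_pk
        while 0 <= i + step < len(y):
            j = i + step
            if y[j] <= half:
                # interpolate between i (above) and j (at/below)
                frac = (y[i] - half) / (y[i] - y[j])
                return z[i] + frac * (z[j] - z[i])
            i = j
        raise ValueError(
            "profile does not fall to half maximum on one side; incomplete profile"
        )

    left = _cross(i_pk, -1)
    right = _cross(i_pk, +1)
    return float(right - left)
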