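"""Growth-curve transformation and trait extraction.

Corrected OD series are log-ratio transformed, L(t) = ln(OD_t / OD_i), and
three traits are read off nonparametrically: the lag time lambda (tangent
construction), the maximum specific growth rate mu (sliding-window OLS
slope of L), and the carrying capacity kappa (plateau OD). The dynamic
measuring point Phi is the time at which a reference culture's growth rate
first drops below a fraction (default 5%) of mu; cumulative growth is then
summarized as the area under L(t) from inoculation to Phi, and treatment
effects as the ratio AUC_treated / AUC_control (delta AUC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GrowthCurve",
    "GrowthTraits",
    "PhiPoint",
    "AUCResult",
    "smooth_series",
    "log_transform",
    "estimate_traits",
    "aggregate_replicates",
    "find_phi",
    "compute_auc",
    "relative_auc",
]


@dataclass
class GrowthCurve:
    """Corrected-OD series and its log-ratio transform."""

    times: np.ndarray
    od_corr: np.ndarray
    od_init: float
    log_ratio: np.ndarray
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od_corr = np.asarray(self.od_corr, dtype=float)
        self.log_ratio = np.asarray(self.log_ratio, dtype=float)
        if not (len(self.times) == len(self.od_corr) == len(self.log_ratio)):
            raise ValueError("times, od_corr and log_ratio must have equal length")
        if self.od_init <= 0:
            raise ValueError("od_init must be positive")
        if not np.all(np.isfinite(self.log_ratio)):
            raise ValueError("log_ratio must be finite everywhere")


@dataclass
class GrowthTraits:
    """Lag (min), max specific rate (1/min), carrying capacity (OD), and
    the window-center time (min) at which the max rate occurred."""

    lag_lambda: float
    mu_max: float
    kappa: float
    t_mu: float


@dataclass
class PhiPoint:
    """The dynamic measuring point: first time the reference culture's
    rate falls below ``threshold_fraction`` of mu, plus an optional
    additive shift (capped at the end of the observation window)."""

    phi: float
    threshold_fraction: float = 0.05
    shift: float = 0.0
    reference_group: str = ""
    reached: bool = True


@dataclass
class AUCResult:
    auc: float
    phi_used: PhiPoint
    delta_auc: float | None = None
    rel_auc_vs_empty: float | None = None
    flags: tuple[str, ...] = ()


def _check_window(w: int, n: int, name: str) -> None:
    if w < 1 or w % 2 == 0:
        raise ValueError(f"{name} must be an odd integer >= 1, got {w}")
    if w > n:
        raise ValueError(f"{name}={w} exceeds series length {n}")


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    # symmetric window, shrunk near the ends so output length == input length
    half = window // 2
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = np.median(x[i - h : i + h + 1])
    return out


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = np.mean(x[i - h : i + h + 1])
    return out


def smooth_series(od: np.ndarray, despike_window: int = 5, avg_window: int = 3) -> np.ndarray:
    """Running-median despike followed by a centered moving average.

    Micro-cultures aggregate and sediment, producing isolated spikes in
    individual readings; the median pass removes those, the mean pass
    suppresses detector noise. Endpoints use shrunken symmetric windows so
    the output has the input length.
    """
    od = np.asarray(od, dtype=float)
    _check_window(despike_window, len(od), "despike_window")
    _check_window(avg_window, len(od), "avg_window")
    return _moving_average(_running_median(od, despike_window), avg_window)


def log_transform(
    od_corr: np.ndarray,
    times: np.ndarray,
    init_cycles: int = 3,
    od_floor: float = 1e-4,
) -> GrowthCurve:
    """Build the log-ratio curve L(t) = ln(od_corr(t) / od_init).

    ``od_init`` is the mean of the first ``init_cycles`` corrected readings
    (averaging suppresses first-cycle noise), clamped below at ``od_floor``;
    the same floor is applied to every reading before division so blank-level
    readings cannot produce -inf.
    """
    od_corr = np.asarray(od_corr, dtype=float)
    times = np.asarray(times, dtype=float)
    if init_cycles < 1 or init_cycles > len(od_corr):
        raise ValueError(f"init_cycles must be in [1, {len(od_corr)}]")
    if od_floor <= 0:
        raise ValueError("od_floor must be positive")
    flags: list[str] = []
    od_init = max(float(np.mean(od_corr[:init_cycles])), od_floor)
    floored = np.maximum(od_corr, od_floor)
    log_ratio = np.log(floored / od_init)
    if np.all(od_corr <= od_floor):
        flags.append("degenerate_curve")
    return GrowthCurve(times, od_corr, od_init, log_ratio, tuple(flags))


def _window_slopes(times: np.ndarray, y: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """OLS slope of y vs t in every full sliding window; returns (centers, slopes)."""
    n = len(y)
    half = window // 2
    centers = times[half : n - half]
    slopes = np.empty(len(centers))
    for j, i in enumerate(range(half, n - half)):
        t = times[i - half : i + half + 1]
        v = y[i - half : i + half + 1]
        tc = t - t.mean()
        denom = float(tc @ tc)
        slopes[j] = float(tc @ (v - v.mean())) / denom if denom > 0 else 0.0
    return centers, slopes


def estimate_traits(curve: GrowthCurve, slope_window: int = 5) -> GrowthTraits:
    """Extract lambda, mu and kappa from a log-ratio curve.

    mu is the maximum sliding-window OLS slope of L(t) (earliest window on
    ties, floored at 0); kappa is the maximum corrected OD; lambda is the
    time where the maximal-slope tangent through (t_mu, L(t_mu)) crosses
    L = 0, floored at 0 (and defined 0 for a non-growing curve).
    """
    if slope_window < 3 or slope_window % 2 == 0:
        raise ValueError("slope_window must be an odd integer >= 3")
    if len(curve.times) < slope_window:
        raise ValueError("curve shorter than slope window")
    centers, slopes = _window_slopes(curve.times, curve.log_ratio, slope_window)
    i_best = int(np.argmax(slopes))  # argmax returns the earliest maximum
    mu_max = max(float(slopes[i_best]), 0.0)
    t_mu = float(centers[i_best])
    kappa = float(np.max(curve.od_corr))
    if mu_max > 0:
        l_at = float(np.interp(t_mu, curve.times, curve.log_ratio))
        lag = max(0.0, t_mu - l_at / mu_max)
    else:
        lag = 0.0
    return GrowthTraits(lag_lambda=lag, mu_max=mu_max, kappa=kappa, t_mu=t_mu)


def aggregate_replicates(curves: list[GrowthCurve]) -> tuple[GrowthCurve, np.ndarray]:
    """Pointwise mean curve across replicates, with per-time SEM of L(t)."""
    if not curves:
        raise ValueError("need at least one curve")
    t0 = curves[0].times
    for c in curves[1:]:
        if len(c.times) != len(t0) or np.any(c.times != t0):
            raise ValueError("replicate curves must share the same time grid")
    L = np.vstack([c.log_ratio for c in curves])
    od = np.vstack([c.od_corr for c in curves])
    n = len(curves)
    mean_L = L.mean(axis=0)
    mean_od = od.mean(axis=0)
    sem = L.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean_L)
    od_init = float(np.mean([c.od_init for c in curves]))
    flags = tuple(sorted({f for c in curves for f in c.flags}))
    return GrowthCurve(t0, mean_od, od_init, mean_L, flags), sem


def find_phi(
    reference: GrowthCurve,
    traits: GrowthTraits,
    threshold_fraction: float = 0.05,
    shift: float = 0.0,
    slope_window: int = 5,
    reference_group: str = "",
) -> PhiPoint:
    """Locate Phi on the reference curve.

    Window slopes are scanned for times after t_mu; Phi is the first time
    (linearly interpolated between adjacent window centers) at which the
    slope falls below ``threshold_fraction * mu_max``. If the rate never
    drops below threshold within the observation window, Phi falls back to
    the last time with ``reached=False`` and a warning. The returned phi
    includes the additive shift, capped at the last observed time.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must be in (0, 1)")
    if shift < 0:
        raise ValueError("shift must be >= 0")
    if traits.mu_max <= 0:
        raise ValueError("Phi is undefined on a non-growing reference (mu_max = 0)")
    centers, slopes = _window_slopes(reference.times, reference.log_ratio, slope_window)
    thr = threshold_fraction * traits.mu_max
    last_time = float(reference.times[-1])
    mask = centers >= traits.t_mu
    c = centers[mask]
    s = slopes[mask]
    phi = None
    for j in range(len(c)):
        if s[j] < thr:
            if j == 0:
                phi = float(c[0])
            else:
                # linear interpolation of the slope crossing between centers
                frac = (s[j - 1] - thr) / (s[j - 1] - s[j])
                phi = float(c[j - 1] + frac * (c[j] - c[j - 1]))
            break
    reached = phi is not None
    if not reached:
        warnings.warn(
            "growth rate never fell below threshold; Phi capped at the last observed time",
            stacklevel=2,
        )
        phi = last_time
    phi = min(phi + shift, last_time)
    return PhiPoint(
        phi=phi,
        threshold_fraction=threshold_fraction,
        shift=shift,
        reference_group=reference_group,
        reached=reached,
    )


def compute_auc(curve: GrowthCurve, phi: PhiPoint, clip_negative: bool = True) -> AUCResult:
    """Trapezoidal area under L(t) on [0, phi].

    The final partial interval is linearly interpolated. Negative log-ratios
    (blank-level noise before growth) are clipped to 0 by default, since
    cumulative growth cannot be negative in this readout.
    """
    t = curve.times
    L = np.clip(curve.log_ratio, 0.0, None) if clip_negative else curve.log_ratio.copy()
    flags: list[str] = []
    end = phi.phi
    if end > t[-1]:
        flags.append("phi_beyond_grid")
        end = float(t[-1])
    keep = t <= end
    tt = t[keep]
    LL = L[keep]
    if end > tt[-1]:
        LL = np.append(LL, np.interp(end, t, L))
        tt = np.append(tt, end)
    if tt[0] > 0.0:
        tt = np.insert(tt, 0, 0.0)
        LL = np.insert(LL, 0, LL[0])
    auc = float(np.trapezoid(LL, tt))
    return AUCResult(auc=auc, phi_used=phi, flags=tuple(flags))


def relative_auc(
    auc_treated: AUCResult, auc_control: AUCResult, eps_scale: float = 1e-6
) -> float:
    """delta AUC = AUC_treated / AUC_control, both taken at the same Phi."""
    if auc_treated.phi_used.phi != auc_control.phi_used.phi:
        raise ValueError("treated and control AUC must be computed at the same Phi")
    eps = eps_scale * max(auc_control.phi_used.phi, 1.0)
    if auc_control.auc <= eps:
        raise ZeroDivisionError("control AUC is (near) zero; delta AUC undefined")
    return auc_treated.auc / auc_control.auc
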