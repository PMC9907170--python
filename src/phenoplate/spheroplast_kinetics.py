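"""Spheroplast osmotic-shock bursting kinetics.

On hypotonic shock, wall-less yeast cells swell and burst within seconds,
producing a rapid initial drop in OD650 followed by a slower settling
phase. Traces are fitted with a two-phase exponential

    y(t) = A1 * exp(-t / tau1) + A2 * exp(-t / tau2)

and the fast-phase amplitude A1 — the amplitude attached to the smallest
positive time constant — serves as a relative index of membrane water
permeability. The slow term may carry a negative amplitude and/or a
negative time constant (a slow drift), but a burst fit must have at least
one positive time constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BurstTrace",
    "BurstKinetics",
    "REFERENCE_BURST_PARAMS",
    "evaluate_two_phase",
    "fit_two_phase",
    "rank_permeability",
]


@dataclass
class BurstTrace:
    """Change-in-OD650 trace, seconds resolution (typically 0-5 s at 0.1 s)."""

    times: np.ndarray
    od650: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od650 = np.asarray(self.od650, dtype=float)
        if len(self.times) < 10:
            raise ValueError("a burst trace needs at least 10 points")
        if len(self.times) != len(self.od650):
            raise ValueError("times and od650 must have equal length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.od650)):
            raise ValueError("od650 values must be finite")

    def baseline_subtract(self, tail_s: float = 0.5) -> "BurstTrace":
        """Subtract the mean of the final ``tail_s`` seconds."""
        tail = self.od650[self.times >= self.times[-1] - tail_s]
        return BurstTrace(self.times, self.od650 - float(tail.mean()))


@dataclass
class BurstKinetics:
    """Fitted two-phase parameters; (a1, tau1) is the fast phase."""

    a1: float
    tau1: float
    a2: float
    tau2: float
    rss: float = 0.0

    def __post_init__(self) -> None:
        if self.tau1 <= 0:
            raise ValueError("fast-phase time constant tau1 must be positive")
        if self.tau2 == 0:
            raise ValueError("tau2 must be nonzero")


#: Reference two-phase parameter sets for the four benchmark lines
#: (fitted curves of the published spheroplast bursting assay).
REFERENCE_BURST_PARAMS: dict[str, BurstKinetics] = {
    "empty": BurstKinetics(a1=0.00881, tau1=0.243, a2=-0.05398, tau2=-6.47128),
    "AtPIP1;5": BurstKinetics(a1=0.02937, tau1=0.09966, a2=0.13874, tau2=3.76055),
    "AtPIP2;1": BurstKinetics(a1=0.10037, tau1=0.15797, a2=0.10763, tau2=3.51469),
    "AtPIP2;7": BurstKinetics(a1=0.16814, tau1=0.18973, a2=0.07791, tau2=2.43538),
}


def evaluate_two_phase(params: BurstKinetics, t) -> np.ndarray | float:
    """y(t) = a1 exp(-t/tau1) + a2 exp(-t/tau2)."""
    tt = np.asarray(t, dtype=float)
    y = params.a1 * np.exp(-tt / params.tau1) + params.a2 * np.exp(-tt / params.tau2)
    return float(y) if np.isscalar(t) else y


def _model(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    a1, tau1, a2, tau2 = theta
    # clip exponents so wild line-search steps cannot overflow
    e1 = np.exp(np.clip(-t / tau1, -700.0, 700.0))
    e2 = np.exp(np.clip(-t / tau2, -700.0, 700.0))
    return a1 * e1 + a2 * e2


def _amplitudes_for_taus(t: np.ndarray, y: np.ndarray, tau_a: float, tau_b: float):
    """Linear least-squares amplitudes given fixed time constants."""
    B = np.column_stack([np.exp(-t / tau_a), np.exp(-t / tau_b)])
    amps, *_ = np.linalg.lstsq(B, y, rcond=None)
    return amps


def fit_two_phase(
    trace: BurstTrace,
    *,
    baseline_subtract: bool = False,
    tau1_grid: tuple[float, ...] = (0.05, 0.1, 0.2, 0.5),
    tau2_grid: tuple[float, ...] = (1.0, 3.0, 10.0, -10.0),
) -> BurstKinetics:
    """Unconstrained two-phase exponential fit with multi-start initialization.

    Every (tau1, tau2) pair on the start grids seeds a Levenberg-Marquardt
    run, amplitudes initialized by a linear solve at the fixed taus; the
    lowest-RSS converged fit wins. After convergence the term with the
    smallest positive time constant is labeled the fast phase (a1, tau1).
    A fit with no positive time constant is rejected.
    """
    if baseline_subtract:
        trace = trace.baseline_subtract()
    t, y = trace.times, trace.od650
    best: tuple[float, np.ndarray] | None = None
    for tau1 in tau1_grid:
        for tau2 in tau2_grid:
            if tau1 == tau2:
                continue
            try:
                a, b = _amplitudes_for_taus(t, y, tau1, tau2)
            except np.linalg.LinAlgError:
                continue
            x0 = np.array([a, tau1, b, tau2])
            try:
                sol = least_squares(
                    lambda th: _model(th, t) - y, x0, method="lm", max_nfev=2000
                )
            except (ValueError, FloatingPointError):
                continue
            if not np.all(np.isfinite(sol.x)) or np.any(sol.x[[1, 3]] == 0):
                continue
            rss = float(sol.fun @ sol.fun)
            if best is None or rss < best[0] - 1e-15:
                best = (rss, sol.x)
    if best is None:
        raise RuntimeError("two-phase fit failed to converge from every start")
    rss, theta = best
    terms = [(theta[1], theta[0]), (theta[3], theta[2])]  # (tau, amplitude)
    positive = [trm for trm in terms if trm[0] > 0]
    if not positive:
        raise RuntimeError("no positive time constant; trace has no resolvable burst phase")
    # a vanishing-amplitude term (nested single-exponential case) cannot be
    # the burst phase, unless nothing else qualifies
    amp_tol = 1e-6 * max(abs(theta[0]), abs(theta[2]))
    significant = [trm for trm in positive if abs(trm[1]) > amp_tol]
    fast = min(significant or positive, key=lambda trm: trm[0])
    slow = terms[0] if terms[1] is fast else terms[1]
    return BurstKinetics(a1=fast[1], tau1=fast[0], a2=slow[1], tau2=slow[0], rss=rss)


def rank_permeability(fits: dict[str, BurstKinetics]) -> list[str]:
    """Names ordered by descending fast-phase amplitude A1.

    Ties break toward the smaller (faster) tau1, then alphabetically.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to rank")
    return sorted(fits, key=lambda n: (-fits[n].a1, fits[n].tau1, n))
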