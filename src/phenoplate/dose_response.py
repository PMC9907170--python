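"""Dose-response curves on delta-AUC and treatment-concentration selection.

For an inhibitory compound the per-concentration mean delta AUC is anchored
at the untreated control (delta AUC = 1 by construction); for a
growth-promoting (nutrient) series it is anchored at the maximal
supplementation. A four-parameter logistic (4PL)

    dAUC(c) = bottom + (top - bottom) / (1 + (c / ec50)^hill)

is fitted (orientation flipped for promoting series), and the two
treatment concentrations recommended for a screen are the tested doses
whose fitted response is nearest the configured targets — by default 0.75
and 0.5, i.e. the commencement of pronounced growth inhibition on the
upper shoulder / linear range of the curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseTable",
    "FourPLFit",
    "build_dose_response",
    "fit_four_pl",
    "recommend_concentrations",
]


@dataclass
class DoseResponseTable:
    concentrations: np.ndarray
    delta_auc_mean: np.ndarray
    delta_auc_sem: np.ndarray
    n: np.ndarray
    direction: str = "inhibitory"
    conc_unit: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.delta_auc_mean = np.asarray(self.delta_auc_mean, dtype=float)
        self.delta_auc_sem = np.asarray(self.delta_auc_sem, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if self.direction not in ("inhibitory", "promoting"):
            raise ValueError(f"direction must be inhibitory or promoting, got {self.direction!r}")
        if len(set(self.concentrations)) != len(self.concentrations):
            raise ValueError("concentrations must be distinct")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration": self.concentrations,
                "delta_auc_mean": self.delta_auc_mean,
                "delta_auc_sem": self.delta_auc_sem,
                "n": self.n,
            }
        )


@dataclass
class FourPLFit:
    bottom: float
    top: float
    ec50: float | None
    hill: float | None
    rss: float
    direction: str = "inhibitory"
    flat_response: bool = False

    def predict(self, c) -> np.ndarray | float:
        cc = np.asarray(c, dtype=float)
        if self.flat_response or self.ec50 is None:
            y = np.full_like(cc, 0.5 * (self.top + self.bottom), dtype=float)
        else:
            y = _four_pl(cc, self.bottom, self.top, self.ec50, self.hill, self.direction)
        return float(y) if np.isscalar(c) else y


def _four_pl(c, bottom, top, ec50, hill, direction):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(c > 0, (c / ec50) ** hill, 0.0)
    if direction == "inhibitory":
        # c -> 0 gives top; c -> inf gives bottom
        return bottom + (top - bottom) / (1.0 + ratio)
    # promoting: c -> 0 gives bottom; c -> inf gives top
    with np.errstate(invalid="ignore"):
        frac = np.where(np.isinf(ratio), 1.0, ratio / (1.0 + ratio))
    return bottom + (top - bottom) * frac


def build_dose_response(
    rows: pd.DataFrame,
    direction: str = "inhibitory",
    conc_unit: str = "",
) -> DoseResponseTable:
    """Per-concentration mean and SEM of delta AUC for one genotype.

    ``rows`` needs columns ``concentration`` and ``delta_auc_vs_control``.
    The reference condition (zero dose for inhibitory, maximal dose for
    promoting) must be present; a promoting series is renormalized so the
    maximal-concentration mean equals 1.
    """
    need = {"concentration", "delta_auc_vs_control"}
    if not need.issubset(rows.columns):
        raise ValueError(f"rows must have columns {sorted(need)}")
    rows = rows.dropna(subset=["delta_auc_vs_control"])
    grp = rows.groupby("concentration")["delta_auc_vs_control"]
    mean = grp.mean()
    sem = grp.sem().fillna(0.0)
    n = grp.count()
    concs = mean.index.to_numpy(dtype=float)
    if len(concs) < 3:
        raise ValueError("need at least 3 distinct concentrations including the reference")
    if direction == "inhibitory":
        if 0.0 not in concs:
            raise ValueError("inhibitory series must include the untreated (0) reference")
    means = mean.to_numpy(dtype=float)
    sems = sem.to_numpy(dtype=float)
    if direction == "promoting":
        anchor = means[np.argmax(concs)]
        if anchor <= 0:
            raise ValueError("promoting series has non-positive response at max dose")
        means = means / anchor
        sems = sems / anchor
    return DoseResponseTable(
        concentrations=concs,
        delta_auc_mean=means,
        delta_auc_sem=sems,
        n=n.to_numpy(dtype=int),
        direction=direction,
        conc_unit=conc_unit,
    )


def fit_four_pl(
    table: DoseResponseTable,
    *,
    flat_tol: float = 0.05,
    max_nfev: int = 500,
) -> FourPLFit:
    """Least-squares 4PL fit with multi-start initialization.

    Starts combine hill in {0.5, 1, 2, 4} with a geometric ec50 grid over
    the tested positive-concentration range; the best RSS wins. With fewer
    than 4 distinct concentrations the top asymptote is fixed at 1 and only
    3 parameters are fitted. A span |top - bottom| below ``flat_tol`` is
    reported as a flat response with no ec50.
    """
    c = table.concentrations
    y = table.delta_auc_mean
    direction = table.direction
    fix_top = len(c) < 4
    pos = c[c > 0]
    if len(pos) < 2:
        raise ValueError("need at least two positive concentrations to fit")
    ec50_grid = np.geomspace(pos.min(), pos.max(), 5)
    hill_grid = (0.5, 1.0, 2.0, 4.0)
    y_lo, y_hi = float(y.min()), float(y.max())

    def resid(theta):
        if fix_top:
            bottom, ec50, hill = theta
            top = 1.0
        else:
            bottom, top, ec50, hill = theta
        return _four_pl(c, bottom, top, np.exp(ec50), np.exp(hill), direction) - y

    best = None
    for h0 in hill_grid:
        for e0 in ec50_grid:
            if fix_top:
                x0 = np.array([y_lo, np.log(e0), np.log(h0)])
            else:
                x0 = np.array([y_lo, y_hi, np.log(e0), np.log(h0)])
            try:
                sol = least_squares(resid, x0, method="lm", max_nfev=max_nfev)
            except (ValueError, FloatingPointError):
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            rss = float(sol.fun @ sol.fun)
            if best is None or rss < best[0] - 1e-15:
                best = (rss, sol.x)
    if best is None:
        raise RuntimeError("4PL fit failed to converge from every start")
    rss, theta = best
    if fix_top:
        bottom, top = float(theta[0]), 1.0
        ec50, hill = float(np.exp(theta[1])), float(np.exp(theta[2]))
    else:
        bottom, top = float(theta[0]), float(theta[1])
        ec50, hill = float(np.exp(theta[2])), float(np.exp(theta[3]))
    if bottom > top:
        # canonical orientation: top is the high-response asymptote
        bottom, top = top, bottom
    if abs(top - bottom) < flat_tol:
        warnings.warn("response span below flat-response tolerance; no ec50 reported", stacklevel=2)
        return FourPLFit(
            bottom=bottom, top=top, ec50=None, hill=None, rss=rss,
            direction=direction, flat_response=True,
        )
    return FourPLFit(
        bottom=bottom, top=top, ec50=ec50, hill=hill, rss=rss, direction=direction
    )


def recommend_concentrations(
    fit: FourPLFit,
    tested: np.ndarray,
    targets: tuple[float, float] = (0.75, 0.5),
) -> list[float]:
    """Pick one tested dose per target response level, ascending.

    Each target gets the tested concentration whose fitted response is
    nearest that level; a duplicate pick is nudged to the adjacent tested
    dose. If every tested dose is already saturating (fitted response
    below 0.1), the two smallest tested doses are returned.
    """
    tested = np.unique(np.asarray(tested, dtype=float))
    tested = tested[tested > 0]
    if len(tested) == 0:
        raise ValueError("no positive tested concentrations")
    if fit.flat_response:
        raise ValueError("flat dose response; no concentration recommendation possible")
    if len(tested) == 1:
        warnings.warn("single tested dose; returning it for both targets", stacklevel=2)
        return [float(tested[0]), float(tested[0])]
    fitted = np.asarray(fit.predict(tested), dtype=float)
    if np.all(fitted < 0.1):
        picks = sorted(tested)[:2]
        return [float(p) for p in picks]
    chosen: list[int] = []
    for target in sorted(targets, reverse=True):
        i = int(np.argmin(np.abs(fitted - target)))
        if i in chosen:
            # nudge to an adjacent untaken dose, preferring the next one up
            for j in (i + 1, i - 1, i + 2, i - 2):
                if 0 <= j < len(tested) and j not in chosen:
                    i = j
                    break
        chosen.append(i)
    return sorted(float(tested[i]) for i in chosen)
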