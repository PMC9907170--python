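"""Detector-nonlinearity calibration of recorded OD650.

Plate readers compress OD at high cell density: a reading of 1.0 can
correspond to a true 1-cm-path OD above 3. The correction used here is a
zero-intercept quartic

    od_true = c4*x**4 + c3*x**3 + c2*x**2 + c1*x,    x = recorded OD - blank

fitted to a dilution series whose "true" ODs follow from the dilution
factors. The relationship is spectrophotometer-dependent, so the model
carries an ``instrument_id`` and the pipeline refuses to mix instruments
unless overridden.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .plate_io import WellTimeSeries

__all__ = [
    "CalibrationModel",
    "DilutionPoint",
    "CalibrationError",
    "PUBLISHED_CALIBRATION",
    "blank_correct",
    "true_od_from_dilution",
    "fit_calibration",
    "apply_calibration",
    "invert_calibration",
    "load_calibration",
    "save_calibration",
]


class CalibrationError(ValueError):
    """Calibration cannot be fitted, applied, or inverted."""


class ExtrapolationWarning(UserWarning):
    """Recorded OD beyond the calibrated domain; polynomial extrapolated."""


@dataclass
class CalibrationModel:
    """Zero-intercept quartic mapping recorded OD to true 1-cm-path OD."""

    c1: float
    c2: float
    c3: float
    c4: float
    domain: tuple[float, float] = (0.0, 1.4)
    r_squared: float = 1.0
    instrument_id: str = "unknown"

    def __post_init__(self) -> None:
        for c in (self.c1, self.c2, self.c3, self.c4):
            if not np.isfinite(c):
                raise CalibrationError("non-finite coefficient")
        if not (0.0 <= self.r_squared <= 1.0):
            raise CalibrationError(f"r_squared {self.r_squared} outside [0, 1]")
        if not _is_monotone(self.coefficients, self.domain[1]):
            raise CalibrationError("calibration polynomial is not increasing on its domain")

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3, self.c4])

    @property
    def max_true_od(self) -> float:
        return float(_poly(self.coefficients, self.domain[1]))


@dataclass
class DilutionPoint:
    """One dilution-series measurement: relative concentration and reading."""

    dilution_factor: float
    od_recorded: float

    def __post_init__(self) -> None:
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be positive")
        if self.od_recorded < 0:
            raise ValueError("od_recorded must be >= 0")


def _poly(coefs: np.ndarray, x):
    c1, c2, c3, c4 = coefs
    x = np.asarray(x, dtype=float)
    return x * (c1 + x * (c2 + x * (c3 + x * c4)))


def _is_monotone(coefs: np.ndarray, x_max: float, n: int = 2001) -> bool:
    c1, c2, c3, c4 = coefs
    x = np.linspace(0.0, x_max, n)
    deriv = c1 + 2 * c2 * x + 3 * c3 * x**2 + 4 * c4 * x**3
    return bool(np.all(deriv > 0))


#: The published Spectrostar Nano calibration: y = 1.9481x^4 - 4.2474x^3
#: + 5.0329x^2 + 0.3441x, valid on recorded OD in [0, 1.4].
PUBLISHED_CALIBRATION = CalibrationModel(
    c1=0.3441,
    c2=5.0329,
    c3=-4.2474,
    c4=1.9481,
    domain=(0.0, 1.4),
    r_squared=0.999,
    instrument_id="spectrostar-nano-published",
)


def blank_correct(
    series: WellTimeSeries,
    blanks: list[WellTimeSeries],
    *,
    scalar_blank: float | None = None,
    grid_tol_min: float | None = None,
) -> WellTimeSeries:
    """Subtract the per-cycle mean of the blank wells, flooring at 0.

    All wells on a plate share a cycle grid; ``grid_tol_min`` (default one
    cycle interval) bounds the allowed misalignment. ``scalar_blank`` is an
    escape hatch when no blank wells were run.
    """
    if not blanks:
        if scalar_blank is None:
            raise CalibrationError(
                "no blank wells; pass scalar_blank to subtract a constant background"
            )
        corrected = np.maximum(series.od_raw - scalar_blank, 0.0)
        return WellTimeSeries(series.plate_id, series.well, series.times, corrected)
    tol = grid_tol_min
    if tol is None:
        tol = float(np.median(np.diff(series.times)))
    stack = []
    for b in blanks:
        if len(b.times) != len(series.times) or np.any(np.abs(b.times - series.times) > tol):
            raise CalibrationError(
                f"blank well {b.well} time grid does not match sample well {series.well}"
            )
        stack.append(b.od_raw)
    blank_mean = np.mean(stack, axis=0)
    corrected = np.maximum(series.od_raw - blank_mean, 0.0)
    return WellTimeSeries(series.plate_id, series.well, series.times, corrected)


def true_od_from_dilution(
    points: list[DilutionPoint], anchor_true_od: float
) -> list[tuple[float, float]]:
    """Assign true ODs to a dilution series by proportionality.

    The least-concentrated point (smallest dilution factor) is the anchor,
    assumed within the linear detection regime; its true OD must be supplied.
    Every other point's true OD scales with its dilution factor.
    """
    if anchor_true_od <= 0:
        raise ValueError("anchor_true_od must be positive")
    if not points:
        return []
    f0 = min(p.dilution_factor for p in points)
    return [(p.od_recorded, anchor_true_od * p.dilution_factor / f0) for p in points]


def fit_calibration(
    pairs: list[tuple[float, float]],
    instrument_id: str = "unknown",
    *,
    min_pairs: int = 8,
    required_span: tuple[float, float] = (0.05, 0.8),
) -> CalibrationModel:
    """Least-squares fit of the zero-intercept quartic to (recorded, true) pairs.

    The design matrix uses the monomial basis {x, x^2, x^3, x^4}; no
    constant term, so apply(0) = 0 structurally. The fitted polynomial must
    be strictly increasing on [0, max recorded OD] or the fit is rejected.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < min_pairs:
        raise CalibrationError(f"need at least {min_pairs} (recorded, true) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if x.min() > required_span[0] or x.max() < required_span[1]:
        raise CalibrationError(
            f"recorded ODs must span at least [{required_span[0]}, {required_span[1]}]"
        )
    X = np.column_stack([x, x**2, x**3, x**4])
    coefs, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 4:
        raise CalibrationError("rank-deficient design; need spread in recorded OD")
    resid = y - X @ coefs
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    x_max = float(x.max())
    if not _is_monotone(coefs, x_max):
        raise CalibrationError("fitted polynomial is non-monotone on the data domain")
    return CalibrationModel(
        c1=float(coefs[0]),
        c2=float(coefs[1]),
        c3=float(coefs[2]),
        c4=float(coefs[3]),
        domain=(0.0, x_max),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        instrument_id=instrument_id,
    )


def apply_calibration(model: CalibrationModel, od_recorded):
    """Evaluate the calibration polynomial elementwise.

    Values above the fitted domain are extrapolated with a warning rather
    than rejected, because growth curves can slightly exceed the dilution
    series used to fit the model. Negative inputs are an error.
    """
    x = np.asarray(od_recorded, dtype=float)
    if np.any(x < 0):
        raise CalibrationError("recorded OD must be >= 0 (blank-correct first)")
    if np.any(x > model.domain[1]):
        warnings.warn(
            f"recorded OD above calibrated domain [0, {model.domain[1]}]; extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    y = _poly(model.coefficients, x)
    return float(y) if np.isscalar(od_recorded) else y


def invert_calibration(model: CalibrationModel, od_true: float) -> float:
    """Recorded OD that produces ``od_true``, by root finding on the monotone domain."""
    if od_true < 0:
        raise CalibrationError("od_true must be >= 0")
    if od_true == 0:
        return 0.0
    hi = model.domain[1]
    if od_true > model.max_true_od:
        raise CalibrationError(
            f"od_true {od_true:.4g} exceeds attainable range (max {model.max_true_od:.4g})"
        )
    f = lambda x: _poly(model.coefficients, x) - od_true
    return float(brentq(f, 0.0, hi, xtol=1e-10))


def save_calibration(model: CalibrationModel, path) -> None:
    obj = {
        "instrument_id": model.instrument_id,
        "coefficients": [model.c1, model.c2, model.c3, model.c4],
        "domain": list(model.domain),
        "r_squared": model.r_squared,
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")


def load_calibration(path) -> CalibrationModel:
    with open(path) as fh:
        obj = json.load(fh)
    c1, c2, c3, c4 = obj["coefficients"]
    return CalibrationModel(
        c1=c1,
        c2=c2,
        c3=c3,
        c4=c4,
        domain=tuple(obj.get("domain", (0.0, 1.4))),
        r_squared=float(obj.get("r_squared", 1.0)),
        instrument_id=str(obj.get("instrument_id", "unknown")),
    )
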