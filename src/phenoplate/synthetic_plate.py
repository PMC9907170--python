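"""Synthetic micro-cultivation plate generator.

Emulates the study conditions the analysis assumes: 96-well, 200 ul
micro-cultures read every 10 minutes for 250 cycles, with lag /
exponential / stationary dynamics, treatment effects on the three growth
traits, detector compression of high ODs, a constant blank offset,
additive recorded-scale noise, and sporadic sedimentation spikes.

The underlying true curve is the Zwietering form of the Gompertz model,

    L(t) = A * exp(-exp((mu_m * e / A) * (lambda - t) + 1)),

chosen because its parameters are exactly the lag, the maximal log-ratio
slope, and the asymptotic log-ratio — so generator parameters double as
the ground truth for trait-recovery tests. Recorded readings are obtained
by pushing true OD through the *inverse* calibration polynomial, which is
precisely the compression the analysis is meant to undo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import plate_io
from .od_calibration import CalibrationModel, invert_calibration
from .plate_io import PlateMap, PlateMapEntry, WellTimeSeries
from .spheroplast_kinetics import BurstKinetics, BurstTrace, evaluate_two_phase

__all__ = [
    "WellSimSpec",
    "HillEffect",
    "TreatmentEffectModel",
    "NoiseSpec",
    "ScreenDesign",
    "gompertz_log_ratio",
    "apply_treatment",
    "measure_plate",
    "simulate_screen",
    "simulate_burst_trace",
    "simulate_dilution_series",
    "default_time_grid",
]

#: Default cycle grid: 250 cycles at 10 minutes per cycle.
CYCLE_MINUTES = 10.0
N_CYCLES = 250


def default_time_grid(n_cycles: int = N_CYCLES, cycle_min: float = CYCLE_MINUTES) -> np.ndarray:
    return np.arange(n_cycles, dtype=float) * cycle_min


@dataclass
class WellSimSpec:
    """Ground-truth growth parameters for one simulated well."""

    od_init: float = 0.05
    lag_lambda: float = 300.0
    mu_max: float = 0.01
    asym_A: float = 4.0

    def __post_init__(self) -> None:
        if min(self.od_init, self.lag_lambda, self.mu_max, self.asym_A) <= 0:
            raise ValueError("all WellSimSpec parameters must be positive")
        if self.asym_A > 6:
            raise ValueError("asym_A above 6 gives unattainably high carrying capacity")

    @property
    def kappa(self) -> float:
        return self.od_init * math.exp(self.asym_A)

    @property
    def effective_lag(self) -> float:
        """Tangent-construction lag of the *observed* log-ratio curve.

        The Gompertz log-ratio is not exactly zero at t = 0; dividing by
        the initial OD shifts the curve down by L(0), which moves the
        tangent intercept to exactly lag_lambda + L(0) / mu_max. For
        realistic parameters (lag long relative to the rise time A/(mu*e))
        the correction is negligible.
        """
        k = self.mu_max * math.e / self.asym_A
        L0 = self.asym_A * math.exp(-math.exp(k * self.lag_lambda + 1.0))
        return self.lag_lambda + L0 / self.mu_max


@dataclass
class HillEffect:
    """Saturating per-trait effect: emax * c^h / (ec50^h + c^h)."""

    emax: float
    ec50: float
    hill: float = 2.0

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValueError("ec50 and hill must be positive")

    def __call__(self, dose: float) -> float:
        if dose <= 0:
            return 0.0
        r = (dose / self.ec50) ** self.hill
        return self.emax * r / (1.0 + r)


_NO_EFFECT = HillEffect(emax=0.0, ec50=1.0)


@dataclass
class TreatmentEffectModel:
    """How a treatment dose perturbs the growth parameters.

    ``toxic``: lag multiplied by (1 + Hill), rate and asymptote by
    (1 - Hill) — the classic longer-lag / slower-rate / lower-yield triad.
    ``nutrient``: rate and asymptote rise saturably from a depleted
    baseline toward the full-supplementation values.
    ``freeze_thaw``: each cycle leaves a fraction ``survivorship`` of the
    inoculum viable; traits are untouched and the lag extends emergently
    because the curve starts lower.
    """

    kind: str = "toxic"
    on_lambda: HillEffect = field(default_factory=lambda: _NO_EFFECT)
    on_mu: HillEffect = field(default_factory=lambda: _NO_EFFECT)
    on_kappa: HillEffect = field(default_factory=lambda: _NO_EFFECT)
    survivorship: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("toxic", "nutrient", "freeze_thaw"):
            raise ValueError(f"unknown treatment kind {self.kind!r}")
        if not (0.0 < self.survivorship <= 1.0):
            raise ValueError("survivorship must be in (0, 1]")


@dataclass
class NoiseSpec:
    """Measurement-noise model on the recorded-OD scale."""

    od_sd: float = 0.003
    spike_prob: float = 0.002
    spike_scale: float = 1.5
    blank_offset: float = 0.08
    replicate_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.spike_prob <= 1.0):
            raise ValueError("spike_prob must be in [0, 1]")
        if self.od_sd < 0 or self.replicate_cv < 0:
            raise ValueError("noise SDs must be >= 0")


def gompertz_log_ratio(spec: WellSimSpec, t) -> np.ndarray | float:
    """Zwietering-Gompertz log-ratio L(t); true OD is od_init * exp(L)."""
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("time must be >= 0")
    A, mu, lam = spec.asym_A, spec.mu_max, spec.lag_lambda
    L = A * np.exp(-np.exp((mu * math.e / A) * (lam - tt) + 1.0))
    return float(L) if np.isscalar(t) else L


def apply_treatment(spec: WellSimSpec, model: TreatmentEffectModel, dose: float) -> WellSimSpec:
    """Return the perturbed spec for ``dose`` (concentration, or cycle count
    for freeze-thaw)."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if model.kind == "toxic":
        mult_mu = 1.0 - model.on_mu(dose)
        mult_kappa = 1.0 - model.on_kappa(dose)
        if mult_mu <= 0 or mult_kappa <= 0:
            raise ValueError("toxic effect multiplier fell to <= 0; reduce emax")
        return replace(
            spec,
            lag_lambda=spec.lag_lambda * (1.0 + model.on_lambda(dose)),
            mu_max=spec.mu_max * mult_mu,
            asym_A=spec.asym_A * mult_kappa,
        )
    if model.kind == "nutrient":
        # saturating rise from a depleted baseline toward the spec values
        return replace(
            spec,
            mu_max=spec.mu_max * (1.0 - model.on_mu.emax + model.on_mu(dose)),
            asym_A=spec.asym_A * (1.0 - model.on_kappa.emax + model.on_kappa(dose)),
        )
    # freeze_thaw: dose = number of cycles
    n = int(round(dose))
    od0 = max(spec.od_init * model.survivorship**n, 1e-6)
    return replace(spec, od_init=od0)


def true_od_series(spec: WellSimSpec, times: np.ndarray) -> np.ndarray:
    return spec.od_init * np.exp(np.asarray(gompertz_log_ratio(spec, times)))


def measure_plate(
    true_plate: dict[str, np.ndarray],
    times: np.ndarray,
    calib: CalibrationModel,
    noise: NoiseSpec,
    *,
    blank_wells: tuple[str, ...] = ("A12", "D12", "H12"),
    plate_id: str = "plate1",
    rng: np.random.Generator | None = None,
) -> list[WellTimeSeries]:
    """Turn per-well true-OD series into recorded readings.

    recorded = inverse_calibration(true) + blank_offset + N(0, od_sd), with
    individual readings multiplied by ``spike_scale`` with probability
    ``spike_prob`` (sedimentation/aggregation artifacts). Blank wells emit
    blank_offset plus noise. Deterministic for a given seed.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    out = []
    for well, true_od in sorted(true_plate.items()):
        true_od = np.asarray(true_od, dtype=float)
        rec = np.array([invert_calibration(calib, v) for v in true_od])
        rec = rec + noise.blank_offset + rng.normal(0.0, noise.od_sd, size=rec.shape)
        spikes = rng.random(rec.shape) < noise.spike_prob
        rec = np.where(spikes, rec * noise.spike_scale, rec)
        out.append(WellTimeSeries(plate_id, well, times, np.maximum(rec, 0.0)))
    for well in blank_wells:
        rec = noise.blank_offset + rng.normal(0.0, noise.od_sd, size=times.shape)
        out.append(WellTimeSeries(plate_id, well, times, np.maximum(rec, 0.0)))
    return out


@dataclass
class ScreenDesign:
    """Factorial design of a simulated screen.

    ``genotypes`` maps name -> untreated WellSimSpec; ``treatment`` applies
    at each dose in ``doses`` with ``replicates`` wells per cell.
    ``control_genotype`` is flagged as the empty-vector control in the map.
    """

    genotypes: dict[str, WellSimSpec]
    treatment: TreatmentEffectModel
    treatment_name: str = "treatment"
    conc_unit: str = "mM"
    doses: tuple[float, ...] = (0.0, 0.5, 1.0)
    replicates: int = 3
    control_genotype: str = "empty"
    n_cycles: int = N_CYCLES
    cycle_min: float = CYCLE_MINUTES


_WELL_ORDER = [f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13)]


def simulate_screen(
    design: ScreenDesign,
    calib: CalibrationModel,
    noise: NoiseSpec,
) -> tuple[list[WellTimeSeries], PlateMap]:
    """Simulate a full screen; returns recorded series plus their plate map.

    Genotype trait specs get small seeded replicate-level jitter (CV from
    ``noise.replicate_cv``). Designs exceeding 93 sample wells per plate
    split across plates, each with 3 blanks.
    """
    rng = np.random.default_rng(noise.seed)
    times = default_time_grid(design.n_cycles, design.cycle_min)
    cells = []
    for gname, spec in sorted(design.genotypes.items()):
        ref_dose = _reference_dose(design)
        for dose in design.doses:
            for rep in range(1, design.replicates + 1):
                cells.append((gname, spec, dose, rep, dose == ref_dose))

    blanks_per_plate = 3
    capacity = 96 - blanks_per_plate
    series: list[WellTimeSeries] = []
    entries: dict[tuple[str, str], PlateMapEntry] = {}
    sample_wells = [w for w in _WELL_ORDER if w not in ("A12", "D12", "H12")]
    for p_start in range(0, len(cells), capacity):
        plate_cells = cells[p_start : p_start + capacity]
        pid = f"plate{p_start // capacity + 1}"
        true_plate: dict[str, np.ndarray] = {}
        for (gname, spec, dose, rep, is_ref), well in zip(plate_cells, sample_wells):
            jitter = rng.normal(1.0, noise.replicate_cv, size=3)
            jittered = replace(
                spec,
                lag_lambda=spec.lag_lambda * max(jitter[0], 0.5),
                mu_max=spec.mu_max * max(jitter[1], 0.5),
                asym_A=min(spec.asym_A * max(jitter[2], 0.5), 6.0),
            )
            treated = apply_treatment(jittered, design.treatment, dose)
            true_plate[well] = true_od_series(treated, times)
            entries[(pid, well)] = PlateMapEntry(
                well=well,
                genotype=gname,
                vector="empty" if gname == design.control_genotype else gname,
                treatment=design.treatment_name,
                concentration=dose,
                conc_unit=design.conc_unit,
                replicate=rep,
                role="sample",
                is_reference_condition=is_ref,
                is_empty_vector=gname == design.control_genotype,
            )
        series.extend(
            measure_plate(true_plate, times, calib, noise, plate_id=pid, rng=rng)
        )
        for bw in ("A12", "D12", "H12"):
            entries[(pid, bw)] = PlateMapEntry(well=bw, role="blank")
    pm = PlateMap(entries)
    pm.validate()
    return series, pm


def _reference_dose(design: ScreenDesign) -> float:
    if design.treatment.kind == "nutrient":
        return max(design.doses)
    return min(design.doses)


def write_screen(series, pm, ts_path, map_path) -> None:
    plate_io.write_plate_timeseries(series, ts_path)
    plate_io.write_plate_map(pm, map_path)


def simulate_burst_trace(
    params: BurstKinetics,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> BurstTrace:
    """Sample the two-phase curve (default 0-5 s at 0.1 s) plus optional noise."""
    if grid is None:
        grid = np.arange(0.0, 5.0 + 1e-9, 0.1)
    grid = np.asarray(grid, dtype=float)
    y = np.asarray(evaluate_two_phase(params, grid), dtype=float)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=y.shape)
    return BurstTrace(grid, y)


def simulate_dilution_series(
    calib: CalibrationModel,
    anchor_true: float,
    factors,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Dilution points whose recorded ODs come from the inverse calibration."""
    from .od_calibration import DilutionPoint

    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("dilution factors must be positive")
    rng = np.random.default_rng(seed)
    points = []
    f0 = factors.min()
    for f in factors:
        true_od = anchor_true * f / f0
        rec = invert_calibration(calib, true_od)
        if noise_sd > 0:
            rec *= 1.0 + rng.normal(0.0, noise_sd)
        points.append(DilutionPoint(dilution_factor=float(f), od_recorded=max(rec, 0.0)))
    return points
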