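"""End-to-end screen analysis.

Composes the stages in the order the data are produced: blank correction
-> nonlinearity calibration -> smoothing -> log-ratio transform -> traits
and the genotype-specific measuring point Phi on the reference condition
-> AUC to Phi for every well -> delta AUC versus the genotype's reference
-> normalization to the empty-vector control -> comparison statistics.
Everything is driven by a single config object; warnings are collected as
data rows, not prose.
"""

from __future__ import annotations

import hashlib
import json
import warnings as _warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import growth_curves as gc
from . import screen_stats as ss
from .od_calibration import CalibrationModel, apply_calibration, blank_correct
from .plate_io import PlateMap, ResultRow, ResultTable, WellTimeSeries

__all__ = ["ScreenConfig", "ScreenResult", "run_screen", "run_phi_shift_sweep"]


@dataclass
class ScreenConfig:
    """All tunables of a screen analysis, in one hashable object."""

    despike_window: int = 5
    avg_window: int = 3
    init_cycles: int = 3
    od_floor: float = 1e-4
    slope_window: int = 5
    phi_threshold: float = 0.05
    phi_shift: float = 0.0
    clip_negative: bool = True
    direction: str = "toxic"  # toxic -> untreated reference; nutrient -> max dose
    control_genotype: str = "empty"
    alpha_levels: tuple[float, float] = (0.05, 0.01)
    global_phi: bool = False  # one Phi from the control genotype for all lines
    instrument_override: bool = False
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenConfig":
        kwargs = {}
        for key, val in d.items():
            if key == "alpha_levels":
                val = tuple(val)
            kwargs[key] = val
        return cls(**kwargs)


@dataclass
class ScreenResult:
    results: ResultTable
    comparisons: dict[tuple[str, float], ss.ComparisonTable]
    phi_by_genotype: dict[str, gc.PhiPoint]
    warnings: pd.DataFrame
    config_hash: str = ""

    def results_frame(self) -> pd.DataFrame:
        return self.results.to_frame()


def _well_curves(
    series: list[WellTimeSeries],
    plate_map: PlateMap,
    model: CalibrationModel,
    cfg: ScreenConfig,
    warn_rows: list[dict],
) -> dict[tuple[str, str], gc.GrowthCurve]:
    """Blank-correct, calibrate, smooth and log-transform every sample well."""
    by_plate: dict[str, list[WellTimeSeries]] = {}
    for s in series:
        by_plate.setdefault(s.plate_id, []).append(s)
    curves: dict[tuple[str, str], gc.GrowthCurve] = {}
    for pid, plate_series in sorted(by_plate.items()):
        blank_wells = {w for (p, w), e in plate_map.entries.items() if p == pid and e.role == "blank"}
        blanks = sorted(
            (s for s in plate_series if s.well in blank_wells), key=lambda s: s.well
        )
        for s in sorted(plate_series, key=lambda s: s.well):
            entry = plate_map.entries.get((pid, s.well))
            if entry is None or entry.role != "sample":
                continue
            corrected = blank_correct(s, blanks)
            with _warnings.catch_warnings(record=True) as wlist:
                _warnings.simplefilter("always")
                od_true = apply_calibration(model, corrected.od_raw)
            for w in wlist:
                warn_rows.append(
                    {"plate_id": pid, "well": s.well, "kind": "extrapolated_calibration",
                     "detail": str(w.message)}
                )
            smoothed = gc.smooth_series(od_true, cfg.despike_window, cfg.avg_window)
            curve = gc.log_transform(smoothed, s.times, cfg.init_cycles, cfg.od_floor)
            for f in curve.flags:
                warn_rows.append({"plate_id": pid, "well": s.well, "kind": f, "detail": ""})
            curves[(pid, s.well)] = curve
    return curves


def _reference_wells(plate_map: PlateMap, genotype: str, cfg: ScreenConfig) -> list[tuple[str, str]]:
    entries = [(k, e) for k, e in plate_map.samples() if e.genotype == genotype]
    flagged = [k for k, e in entries if e.is_reference_condition]
    if flagged:
        return flagged
    concs = [e.concentration for _, e in entries]
    ref_conc = max(concs) if cfg.direction == "nutrient" else min(concs)
    return [k for k, e in entries if e.concentration == ref_conc]


def run_screen(
    series: list[WellTimeSeries],
    plate_map: PlateMap,
    model: CalibrationModel,
    cfg: ScreenConfig | None = None,
) -> ScreenResult:
    """Analyze a full screen.

    Per genotype: the reference-condition replicates are averaged, traits
    and Phi computed on that mean curve, and AUC to that Phi computed for
    every well of the genotype. delta AUC compares each well against the
    genotype's mean reference AUC; rel_auc_vs_empty then standardizes each
    condition's mean delta AUC to the empty-vector control's. Comparison
    tables (LSD marks and Tukey letters over genotypes) are produced per
    treated condition.
    """
    cfg = cfg or ScreenConfig()
    warn_rows: list[dict] = []
    for w in plate_map.warnings:
        warn_rows.append({"plate_id": "", "well": "", "kind": "plate_map", "detail": w})
    curves = _well_curves(series, plate_map, model, cfg, warn_rows)

    genotypes = sorted({e.genotype for _, e in plate_map.samples()})
    if cfg.control_genotype not in genotypes:
        raise ValueError(f"control genotype {cfg.control_genotype!r} absent from plate map")

    phi_by_genotype: dict[str, gc.PhiPoint] = {}
    ref_auc: dict[str, float] = {}
    excluded: set[str] = set()

    def _phi_for(genotype: str) -> gc.PhiPoint | None:
        ref_keys = [k for k in _reference_wells(plate_map, genotype, cfg) if k in curves]
        if not ref_keys:
            warn_rows.append(
                {"plate_id": "", "well": "", "kind": "missing_reference",
                 "detail": f"genotype {genotype} has no reference-condition wells; excluded"}
            )
            return None
        mean_curve, _ = gc.aggregate_replicates([curves[k] for k in ref_keys])
        traits = gc.estimate_traits(mean_curve, cfg.slope_window)
        if traits.mu_max <= 0:
            warn_rows.append(
                {"plate_id": "", "well": "", "kind": "non_growing_reference",
                 "detail": f"genotype {genotype}; excluded"}
            )
            return None
        with _warnings.catch_warnings(record=True) as wlist:
            _warnings.simplefilter("always")
            phi = gc.find_phi(
                mean_curve, traits, cfg.phi_threshold, cfg.phi_shift,
                cfg.slope_window, reference_group=genotype,
            )
        for w in wlist:
            warn_rows.append(
                {"plate_id": "", "well": "", "kind": "phi_not_reached",
                 "detail": f"genotype {genotype}: {w.message}"}
            )
        return phi

    if cfg.global_phi:
        phi = _phi_for(cfg.control_genotype)
        if phi is None:
            raise ValueError("control genotype reference curve does not grow; no global Phi")
        for g in genotypes:
            phi_by_genotype[g] = phi
    else:
        for g in genotypes:
            phi = _phi_for(g)
            if phi is None:
                excluded.add(g)
            else:
                phi_by_genotype[g] = phi

    # per-well traits and AUC at the genotype's Phi
    rows: list[ResultRow] = []
    well_info: list[tuple[str, str, float, float]] = []  # genotype, treatment, conc, delta
    per_well: list[dict] = []
    for (pid, well), e in plate_map.samples():
        if (pid, well) not in curves or e.genotype in excluded:
            continue
        curve = curves[(pid, well)]
        phi = phi_by_genotype[e.genotype]
        traits = gc.estimate_traits(curve, cfg.slope_window)
        auc = gc.compute_auc(curve, phi, cfg.clip_negative)
        per_well.append(
            {"pid": pid, "well": well, "entry": e, "traits": traits, "auc": auc}
        )

    # genotype-level mean reference AUC
    for g in genotypes:
        if g in excluded:
            continue
        ref_keys = set(_reference_wells(plate_map, g, cfg))
        vals = [
            d["auc"].auc for d in per_well
            if d["entry"].genotype == g and (d["pid"], d["well"]) in ref_keys
        ]
        if vals:
            ref_auc[g] = float(np.mean(vals))

    # delta AUC per well, then empty-vector standardization per condition
    delta_rows: list[dict] = []
    for d in per_well:
        e = d["entry"]
        flags = list(d["auc"].flags)
        delta = None
        if e.genotype in ref_auc and ref_auc[e.genotype] > 1e-9:
            delta = d["auc"].auc / ref_auc[e.genotype]
        else:
            flags.append("no_reference_auc")
        delta_rows.append({**d, "delta": delta, "flags": flags})

    cond_means: dict[tuple[str, str, float], float] = {}
    for d in delta_rows:
        if d["delta"] is None:
            continue
        e = d["entry"]
        key = (e.genotype, e.treatment, e.concentration)
        cond_means.setdefault(key, [])
        cond_means[key].append(d["delta"])
    cond_means = {k: float(np.mean(v)) for k, v in cond_means.items()}

    for d in delta_rows:
        e = d["entry"]
        rel = None
        ctrl_key = (cfg.control_genotype, e.treatment, e.concentration)
        if d["delta"] is not None and ctrl_key in cond_means and cond_means[ctrl_key] > 1e-9:
            rel = d["delta"] / cond_means[ctrl_key]
        t = d["traits"]
        rows.append(
            ResultRow(
                genotype=e.genotype,
                treatment=e.treatment,
                concentration=e.concentration,
                replicate=e.replicate,
                lag_lambda=t.lag_lambda,
                mu_max=t.mu_max,
                kappa=t.kappa,
                phi_used=phi_by_genotype[e.genotype].phi,
                auc=d["auc"].auc,
                delta_auc_vs_control=d["delta"],
                rel_auc_vs_empty=rel,
                flags=";".join(d["flags"]),
            )
        )

    # comparison statistics per treated (non-reference) condition
    comparisons: dict[tuple[str, float], ss.ComparisonTable] = {}
    df = ResultTable(rows).to_frame()
    treated = df.dropna(subset=["delta_auc_vs_control"])
    for (trt, conc), grp in treated.groupby(["treatment", "concentration"]):
        groups = []
        for g, gg in grp.groupby("genotype"):
            vals = gg["delta_auc_vs_control"].to_numpy(dtype=float)
            if len(vals) >= 2:
                groups.append(ss.GroupData(g, vals, is_control=(g == cfg.control_genotype)))
        if len(groups) >= 2 and any(g.is_control for g in groups):
            table = ss.anova_lsd(groups, cfg.alpha_levels)
            letters = ss.tukey_letters(groups, cfg.alpha_levels[0])
            table.frame["tukey_letters"] = table.frame["group"].map(letters)
            comparisons[(trt, float(conc))] = table

    warn_df = pd.DataFrame(warn_rows, columns=["plate_id", "well", "kind", "detail"])
    return ScreenResult(
        results=ResultTable(rows),
        comparisons=comparisons,
        phi_by_genotype=phi_by_genotype,
        warnings=warn_df,
        config_hash=cfg.config_hash(),
    )


def run_phi_shift_sweep(
    series: list[WellTimeSeries],
    plate_map: PlateMap,
    model: CalibrationModel,
    cfg: ScreenConfig,
    shifts: list[float],
) -> pd.DataFrame:
    """Recompute delta AUC at Phi shifted by each value in ``shifts``.

    AUC is non-decreasing in the shift for every culture (asserted); the
    delta AUC of slow-recovering cultures typically rises with the shift
    because the control contributes little once plateaued.
    """
    frames = []
    prev_auc: dict[tuple, float] = {}
    for shift in shifts:
        if shift < 0:
            raise ValueError("shifts must be >= 0")
        res = run_screen(series, plate_map, model,
                         ScreenConfig(**{**asdict(cfg), "phi_shift": float(shift),
                                         "alpha_levels": cfg.alpha_levels}))
        df = res.results_frame()
        df.insert(0, "phi_shift", float(shift))
        for _, r in df.iterrows():
            key = (r["genotype"], r["treatment"], r["concentration"], r["replicate"])
            if key in prev_auc and r["auc"] < prev_auc[key] - 1e-9:
                raise AssertionError("AUC decreased with increasing Phi shift")
            prev_auc[key] = r["auc"]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
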