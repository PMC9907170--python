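"""Tabular I/O for the plate pipeline.

Three artifact kinds flow through the analysis: per-well OD time series
(long or wide CSV), a plate map assigning genotype / treatment / role
metadata to wells, and the tidy per-well result table written at the end.
Times are minutes throughout growth data; well coordinates are A1..H12
(case-insensitive on input, normalized to upper case).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WellTimeSeries",
    "PlateMapEntry",
    "PlateMap",
    "ResultRow",
    "ResultTable",
    "PlateFormatError",
    "PlateValidationError",
    "read_plate_timeseries",
    "write_plate_timeseries",
    "read_plate_map",
    "write_plate_map",
    "write_results",
    "read_results",
]

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")

TIMESERIES_COLUMNS = ["plate_id", "well", "time_min", "od_raw"]
PLATE_MAP_COLUMNS = [
    "well",
    "genotype",
    "vector",
    "treatment",
    "concentration",
    "conc_unit",
    "replicate",
    "role",
    "is_reference_condition",
    "is_empty_vector",
]
RESULT_COLUMNS = [
    "genotype",
    "treatment",
    "concentration",
    "replicate",
    "lag_lambda",
    "mu_max",
    "kappa",
    "phi_used",
    "auc",
    "delta_auc_vs_control",
    "rel_auc_vs_empty",
    "flags",
]


class PlateFormatError(ValueError):
    """A file does not match the expected CSV dialect."""


class PlateValidationError(ValueError):
    """Parsed content violates a plate-level invariant."""


def normalize_well(well: str) -> str:
    w = str(well).strip().upper()
    if not _WELL_RE.match(w):
        raise PlateValidationError(f"not a 96-well coordinate: {well!r}")
    return w


@dataclass
class WellTimeSeries:
    """Raw recorded-OD trace for one well.

    ``times`` are minutes, strictly increasing; ``od_raw`` are the
    plate-reader OD650 readings on the recorded (compressed) scale.
    """

    plate_id: str
    well: str
    times: np.ndarray
    od_raw: np.ndarray

    def __post_init__(self) -> None:
        self.well = normalize_well(self.well)
        self.times = np.asarray(self.times, dtype=float)
        self.od_raw = np.asarray(self.od_raw, dtype=float)
        if self.times.shape != self.od_raw.shape or self.times.ndim != 1:
            raise PlateValidationError("times and od_raw must be 1-D and equal length")
        if len(self.times) < 2:
            raise PlateValidationError("a time series needs at least 2 readings")
        if not np.all(np.diff(self.times) > 0):
            raise PlateValidationError(f"times not strictly increasing for well {self.well}")
        if not np.all(np.isfinite(self.od_raw)):
            raise PlateValidationError(f"non-finite OD readings in well {self.well}")


@dataclass
class PlateMapEntry:
    well: str
    genotype: str = ""
    vector: str = ""
    treatment: str = ""
    concentration: float = 0.0
    conc_unit: str = ""
    replicate: int = 1
    role: str = "sample"
    is_reference_condition: bool = False
    is_empty_vector: bool = False

    def __post_init__(self) -> None:
        self.well = normalize_well(self.well)
        if self.role not in ("sample", "blank"):
            raise PlateValidationError(f"role must be sample or blank, got {self.role!r}")
        if self.role == "sample" and not self.genotype:
            raise PlateValidationError(f"sample well {self.well} has no genotype")
        if self.replicate < 1:
            raise PlateValidationError(f"replicate must be >= 1 in well {self.well}")


@dataclass
class PlateMap:
    """Per-well experimental design for one or more plates.

    Entries are keyed by ``(plate_id, well)``. Blanks (medium-only wells)
    carry ``role='blank'`` and need no genotype.
    """

    entries: dict[tuple[str, str], PlateMapEntry]
    warnings: list[str] = field(default_factory=list)

    def samples(self) -> list[tuple[tuple[str, str], PlateMapEntry]]:
        return [(k, e) for k, e in sorted(self.entries.items()) if e.role == "sample"]

    def blanks(self) -> list[tuple[tuple[str, str], PlateMapEntry]]:
        return [(k, e) for k, e in sorted(self.entries.items()) if e.role == "blank"]

    def validate(self) -> None:
        plates = {pid for pid, _ in self.entries}
        for pid in plates:
            if not any(k[0] == pid and e.role == "blank" for k, e in self.entries.items()):
                msg = f"plate {pid} has no blank wells"
                if msg not in self.warnings:
                    self.warnings.append(msg)
        # at most one reference condition per genotype x treatment series
        ref: dict[tuple[str, str], float] = {}
        for _, e in self.entries.items():
            if e.role != "sample" or not e.is_reference_condition:
                continue
            key = (e.genotype, e.treatment)
            if key in ref and ref[key] != e.concentration:
                raise PlateValidationError(
                    f"conflicting reference concentrations for {e.genotype}/{e.treatment}: "
                    f"{ref[key]} vs {e.concentration}"
                )
            ref[key] = e.concentration


@dataclass
class ResultRow:
    genotype: str
    treatment: str
    concentration: float
    replicate: int
    lag_lambda: float | None = None
    mu_max: float | None = None
    kappa: float | None = None
    phi_used: float | None = None
    auc: float | None = None
    delta_auc_vs_control: float | None = None
    rel_auc_vs_empty: float | None = None
    flags: str = ""


@dataclass
class ResultTable:
    rows: list[ResultRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append({c: getattr(r, c) for c in RESULT_COLUMNS})
        df = pd.DataFrame.from_records(recs, columns=RESULT_COLUMNS)
        return df


def read_plate_timeseries(path, dialect: str = "long") -> list[WellTimeSeries]:
    """Parse a plate-reader time-series CSV into per-well series.

    ``dialect='long'`` expects columns plate_id, well, time_min, od_raw;
    ``'wide'`` expects a time_min column plus one column per well (an
    optional plate_id column is honoured, defaulting to 'plate1').
    Times are sorted ascending per well; duplicate (well, time) rows and
    non-numeric readings are rejected.
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path)
    if dialect == "long":
        missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
        if missing:
            raise PlateFormatError(f"missing column(s) {missing} in {path}")
        bad = pd.to_numeric(df["od_raw"], errors="coerce").isna() & df["od_raw"].notna()
        if bad.any():
            raise PlateFormatError(
                f"non-numeric od_raw at row index {int(np.flatnonzero(bad)[0])} in {path}"
            )
        df["od_raw"] = pd.to_numeric(df["od_raw"])
        df["time_min"] = pd.to_numeric(df["time_min"])
        out = []
        for (pid, well), grp in df.groupby(["plate_id", "well"], sort=True):
            grp = grp.sort_values("time_min")
            times = grp["time_min"].to_numpy(dtype=float)
            if np.any(np.diff(times) == 0):
                raise PlateValidationError(f"duplicate time point for well {well} in {path}")
            out.append(WellTimeSeries(str(pid), str(well), times, grp["od_raw"].to_numpy(dtype=float)))
        return out

    if "time_min" not in df.columns:
        raise PlateFormatError(f"missing column(s) ['time_min'] in {path}")
    pid = "plate1"
    if "plate_id" in df.columns:
        ids = df["plate_id"].unique()
        if len(ids) > 1:
            raise PlateFormatError("wide dialect supports a single plate_id per file")
        pid = str(ids[0])
        df = df.drop(columns=["plate_id"])
    df = df.sort_values("time_min")
    times = pd.to_numeric(df["time_min"]).to_numpy(dtype=float)
    if np.any(np.diff(times) == 0):
        raise PlateValidationError(f"duplicate time point in {path}")
    out = []
    for col in df.columns:
        if col == "time_min":
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise PlateFormatError(f"non-numeric od_raw in column {col!r} of {path}")
        out.append(WellTimeSeries(pid, col, times, vals.to_numpy(dtype=float)))
    return out


def write_plate_timeseries(series: list[WellTimeSeries], path) -> None:
    """Write series in the canonical long dialect."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "plate_id": s.plate_id,
                    "well": s.well,
                    "time_min": s.times,
                    "od_raw": s.od_raw,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


_TRUE_SET = {"1", "true", "yes"}
_FALSE_SET = {"0", "false", "no", "", "nan"}


def _parse_bool(v) -> bool:
    s = str(v).strip().lower()
    if s in _TRUE_SET:
        return True
    if s in _FALSE_SET:
        return False
    raise PlateFormatError(f"cannot parse boolean value {v!r}")


def read_plate_map(path, plate_id: str | None = None) -> PlateMap:
    """Read a plate-map CSV.

    An optional ``plate_id`` column assigns wells to plates; otherwise all
    wells go to the ``plate_id`` argument (default ``'plate1'``). ``role``
    defaults to sample; booleans parse from 0/1/true/false. Missing blanks
    are recorded as a warning, not an error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in PLATE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"missing column(s) {missing} in {path}")
    default_pid = plate_id or "plate1"
    entries: dict[tuple[str, str], PlateMapEntry] = {}
    for _, row in df.iterrows():
        pid = str(row["plate_id"]) if "plate_id" in df.columns and row.get("plate_id") else default_pid
        entry = PlateMapEntry(
            well=row["well"],
            genotype=row["genotype"].strip(),
            vector=row["vector"].strip(),
            treatment=row["treatment"].strip(),
            concentration=float(row["concentration"]) if row["concentration"] != "" else 0.0,
            conc_unit=row["conc_unit"].strip(),
            replicate=int(row["replicate"]) if row["replicate"] != "" else 1,
            role=row["role"].strip() or "sample",
            is_reference_condition=_parse_bool(row["is_reference_condition"]),
            is_empty_vector=_parse_bool(row["is_empty_vector"]),
        )
        key = (pid, entry.well)
        if key in entries:
            raise PlateValidationError(f"well {entry.well} listed twice for plate {pid}")
        entries[key] = entry
    pm = PlateMap(entries)
    pm.validate()
    return pm


def write_plate_map(pm: PlateMap, path) -> None:
    recs = []
    for (pid, well), e in sorted(pm.entries.items()):
        recs.append(
            {
                "plate_id": pid,
                "well": well,
                "genotype": e.genotype,
                "vector": e.vector,
                "treatment": e.treatment,
                "concentration": e.concentration,
                "conc_unit": e.conc_unit,
                "replicate": e.replicate,
                "role": e.role,
                "is_reference_condition": int(e.is_reference_condition),
                "is_empty_vector": int(e.is_empty_vector),
            }
        )
    pd.DataFrame.from_records(recs, columns=["plate_id"] + PLATE_MAP_COLUMNS).to_csv(path, index=False)


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return ""
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def write_results(table: ResultTable, path) -> None:
    """Write the result table with fixed column order.

    Floats are serialized with 6 significant digits; missing values become
    empty fields (the accompanying ``flags`` text says why).
    """
    lines = [",".join(RESULT_COLUMNS)]
    for r in table.rows:
        lines.append(",".join(_fmt(getattr(r, c)) for c in RESULT_COLUMNS))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"missing column(s) {missing} in {path}")
    return df
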