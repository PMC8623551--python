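"""Reading and validating plate-reader exports and plate layouts.

The plate data format is the ubiquitous wide export of microplate readers:
one time column (minutes or hours) followed by one column per well
("A1".."P24" on a 384-well plate), readings at a fixed interval.  Layouts map
each used well to its role on the plate — phage-treated culture, untreated
growth control, phage sterility control, or medium blank — plus strain,
phage and replicate identity.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("phagerange")

ROWS_384 = "ABCDEFGHIJKLMNOP"
N_COLS_384 = 24

ROLES = ("treatment", "untreated_control", "sterility_control", "blank")

_WELL_RE = re.compile(r"^([A-P])0?([1-9]|1[0-9]|2[0-4])$")


@dataclass(frozen=True, order=True)
class WellCoordinate:
    """A well on a 384-well plate: row letter A-P, column 1-24."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROWS_384:
            raise ValueError(f"well row {self.row!r} outside A-P")
        if not 1 <= self.column <= N_COLS_384:
            raise ValueError(f"well column {self.column} outside 1-24")

    @classmethod
    def parse(cls, text: str) -> "WellCoordinate":
        m = _WELL_RE.match(str(text).strip().upper())
        if m is None:
            raise ValueError(f"{text!r} is not a well coordinate (A1..P24)")
        return cls(m.group(1), int(m.group(2)))

    def __str__(self) -> str:
        return f"{self.row}{self.column}"


@dataclass(frozen=True)
class WellSeries:
    """One well's OD600 time series; times in hours from analysis start."""

    well: WellCoordinate
    times: np.ndarray
    readings: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        readings = np.asarray(self.readings, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "readings", readings)
        if times.shape != readings.shape or times.ndim != 1:
            raise ValueError(f"well {self.well}: times/readings shape mismatch")
        if times.size and not np.all(np.diff(times) > 0):
            raise ValueError(f"well {self.well}: times not strictly increasing")
        if not np.all(np.isfinite(readings)):
            raise ValueError(f"well {self.well}: non-finite OD reading")
        if readings.size and readings.min() < 0:
            raise ValueError(f"well {self.well}: negative OD reading")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class LayoutEntry:
    role: str
    strain_id: str = ""
    phage_id: str = ""
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown well role {self.role!r}")


@dataclass
class PlateLayout:
    """Mapping of used wells to (role, strain, phage, replicate)."""

    entries: dict[WellCoordinate, LayoutEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        problems: list[str] = []
        triples: dict[tuple[str, str, int | None], WellCoordinate] = {}
        for well, e in self.entries.items():
            if e.role == "treatment":
                if not e.strain_id or not e.phage_id:
                    problems.append(f"{well}: treatment needs strain and phage")
                key = (e.strain_id, e.phage_id, e.replicate)
                if key in triples:
                    problems.append(
                        f"{well}: duplicate (strain, phage, replicate) with {triples[key]}"
                    )
                triples[key] = well
            elif e.role == "untreated_control":
                if not e.strain_id or e.phage_id:
                    problems.append(f"{well}: untreated control carries strain only")
            elif e.role == "sterility_control":
                if not e.phage_id or e.strain_id:
                    problems.append(f"{well}: sterility control carries phage only")
            elif e.role == "blank":
                if e.strain_id or e.phage_id:
                    problems.append(f"{well}: blank carries neither strain nor phage")
        if problems:
            raise ValueError("invalid plate layout:\n  " + "\n  ".join(problems))

    def wells(self, role: str | None = None) -> list[WellCoordinate]:
        if role is None:
            return sorted(self.entries)
        return sorted(w for w, e in self.entries.items() if e.role == role)

    @property
    def strains(self) -> list[str]:
        return sorted({e.strain_id for e in self.entries.values() if e.strain_id})

    @property
    def phages(self) -> list[str]:
        return sorted(
            {e.phage_id for e in self.entries.values() if e.phage_id and e.role == "treatment"}
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "well": str(w),
                "role": e.role,
                "strain": e.strain_id,
                "phage": e.phage_id,
                "replicate": "" if e.replicate is None else e.replicate,
            }
            for w, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["well", "role", "strain", "phage", "replicate"])


@dataclass
class ExperimentConfig:
    """Tunable assay and analysis parameters.

    threshold
        OD600 detection threshold marking early exponential phase (0.2).
    duration
        Analysis window in hours (24 for Salmonella/Pseudomonas panels,
        40 for Listeria).
    interval
        Minutes between consecutive readings (30).
    start_time
        Hours into the raw file at which analysis time zero sits.
    min_growth_rate
        Minimum rolling slope (OD/h) for a well to count as growing.
    slope_window
        Number of readings in the rolling-slope window.
    delay_minor / delay_major
        Detection-delay cutoffs (h) separating no-delay, D and D+ classes.
    endpoint_bounds
        Decreasing OD_max/control ratios splitting the endpoint-effect
        classes (N | N/L | N/L+ | N/L++).
    """

    threshold: float = 0.2
    duration: float = 24.0
    interval: float = 30.0
    start_time: float = 0.0
    min_growth_rate: float = 0.02
    slope_window: int = 3
    delay_minor: float = 1.0
    delay_major: float = 5.0
    endpoint_bounds: tuple[float, float, float] = (0.85, 0.70, 0.40)
    blank_correction: bool = False
    control_aggregate: str = "mean"  # or "median"
    classify_mode: str = "per_replicate"  # or "averaged"
    outlier_time_rule: bool = False
    conditions: str = ""

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.duration <= 0 or self.interval <= 0:
            raise ValueError("duration and interval must be positive")
        if not self.delay_minor < self.delay_major < self.duration:
            raise ValueError("need delay_minor < delay_major < duration")
        b = tuple(float(x) for x in self.endpoint_bounds)
        if len(b) != 3 or not (1 > b[0] > b[1] > b[2] > 0):
            raise ValueError("endpoint_bounds must be strictly decreasing in (0,1)")
        self.endpoint_bounds = b
        if self.control_aggregate not in ("mean", "median"):
            raise ValueError("control_aggregate must be 'mean' or 'median'")
        if self.classify_mode not in ("per_replicate", "averaged"):
            raise ValueError("classify_mode must be 'per_replicate' or 'averaged'")
        if self.slope_window < 2:
            raise ValueError("slope_window must be >= 2")

    @property
    def interval_hours(self) -> float:
        return self.interval / 60.0

    @property
    def n_readings(self) -> int:
        """Readings in [0, duration] at the configured interval."""
        return int(round(self.duration / self.interval_hours)) + 1

    def with_overrides(self, **kwargs) -> "ExperimentConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path}: expected a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"config file {path}: unknown keys {sorted(unknown)}")
        if "endpoint_bounds" in data:
            data["endpoint_bounds"] = tuple(data["endpoint_bounds"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["endpoint_bounds"] = list(self.endpoint_bounds)
        return d


# ---------------------------------------------------------------------------
# plate table I/O


def _detect_time_unit(header: str, values: np.ndarray, duration: float) -> str:
    h = header.strip().lower()
    if "min" in h:
        return "min"
    if re.search(r"\bh(r|rs|our|ours)?\b", h) or h in ("h", "hours", "time_h", "time (h)"):
        return "h"
    # fall back to magnitude: minute counts dwarf the duration in hours
    if values.size and float(np.nanmax(values)) > duration * 3:
        return "min"
    return "h"


def read_plate_table(
    source: str | Path | pd.DataFrame,
    config: ExperimentConfig,
) -> dict[WellCoordinate, WellSeries]:
    """Read a wide plate-reader export into per-well series.

    First column is time (minutes or hours, auto-detected from the header or
    magnitude); every other column header must be a well coordinate.  Times
    are converted to hours and shifted so ``config.start_time`` maps to 0;
    earlier rows are dropped.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        path = Path(source)
        if path.suffix.lower() in (".xlsx", ".xlsm"):
            df = pd.read_excel(path)
        else:
            sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
            df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 1:
        raise ValueError("plate table has no columns")

    time_header = str(df.columns[0])
    well_headers = [str(c) for c in df.columns[1:]]
    wells: list[WellCoordinate] = []
    seen: set[WellCoordinate] = set()
    for h in well_headers:
        w = WellCoordinate.parse(h)
        if w in seen:
            raise ValueError(f"duplicate well column {w}")
        seen.add(w)
        wells.append(w)

    if df.empty:
        logger.warning("plate table %s is empty (header only)", source)
        return {}

    raw_time = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy(dtype=float)
    if np.isnan(raw_time).any():
        row = int(np.flatnonzero(np.isnan(raw_time))[0])
        raise ValueError(f"non-numeric time value at data row {row}")
    bad = np.flatnonzero(np.diff(raw_time) <= 0)
    if bad.size:
        raise ValueError(f"time column not strictly increasing at data row {int(bad[0]) + 1}")

    unit = _detect_time_unit(time_header, raw_time, config.duration)
    times_h = raw_time / 60.0 if unit == "min" else raw_time
    times_h = times_h - config.start_time
    keep = times_h >= -1e-9
    times_h = times_h[keep]

    # soft check: reading cadence should match the configured interval
    if times_h.size >= 2:
        step = float(np.median(np.diff(times_h)))
        if not math.isclose(step, config.interval_hours, rel_tol=0.05, abs_tol=1e-6):
            logger.warning(
                "reading interval %.3f h differs from configured %.3f h",
                step,
                config.interval_hours,
            )

    out: dict[WellCoordinate, WellSeries] = {}
    for w, h in zip(wells, well_headers):
        col = pd.to_numeric(df[h], errors="coerce").to_numpy(dtype=float)[keep]
        if np.isnan(col).any():
            row = int(np.flatnonzero(np.isnan(col))[0])
            raise ValueError(f"non-numeric OD reading in well {w} at data row {row}")
        out[w] = WellSeries(w, times_h, col)
    return out


def write_plate_table(
    series: Mapping[WellCoordinate, WellSeries] | Iterable[WellSeries],
    path: str | Path,
    time_unit: str = "min",
) -> Path:
    """Write well series back to the wide CSV/TSV dialect read_plate_table reads."""
    if isinstance(series, Mapping):
        series_list = [series[w] for w in sorted(series)]
    else:
        series_list = sorted(series, key=lambda s: s.well)
    if not series_list:
        raise ValueError("nothing to write")
    times = series_list[0].times
    for s in series_list[1:]:
        if not np.allclose(s.times, times):
            raise ValueError("wells are not on a common time grid")
    if time_unit == "min":
        data = {"time_min": np.round(times * 60.0, 6)}
    elif time_unit == "h":
        data = {"time_h": times}
    else:
        raise ValueError("time_unit must be 'min' or 'h'")
    for s in series_list:
        data[str(s.well)] = s.readings
    df = pd.DataFrame(data)
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")
    return path


# ---------------------------------------------------------------------------
# layout I/O


def _layout_from_records(records: Iterable[Mapping]) -> PlateLayout:
    entries: dict[WellCoordinate, LayoutEntry] = {}
    for rec in records:
        well = WellCoordinate.parse(str(rec["well"]))
        if well in entries:
            raise ValueError(f"well {well} listed more than once in layout")
        rep = rec.get("replicate", "")
        rep = None if rep in ("", None) or (isinstance(rep, float) and math.isnan(rep)) else int(rep)
        entries[well] = LayoutEntry(
            role=str(rec["role"]).strip(),
            strain_id=str(rec.get("strain", "") or "").strip(),
            phage_id=str(rec.get("phage", "") or "").strip(),
            replicate=rep,
        )
    return PlateLayout(entries)


def _layout_from_row_shorthand(data: Mapping) -> PlateLayout:
    """Expand the row-structured shorthand: a role/phage per plate row, a strain per column."""
    strains = list(data["strains"])
    if len(strains) > N_COLS_384:
        raise ValueError("more strains than plate columns")
    entries: dict[WellCoordinate, LayoutEntry] = {}
    rep_counter: dict[tuple[str, str], int] = {}
    for row_spec in data["rows"]:
        row = str(row_spec["row"]).strip().upper()
        role = str(row_spec["role"]).strip()
        phage = str(row_spec.get("phage", "") or "").strip()
        for col, strain in enumerate(strains, start=1):
            well = WellCoordinate(row, col)
            if well in entries:
                raise ValueError(f"well {well} assigned twice by row shorthand")
            if role == "treatment":
                key = (strain, phage)
                rep_counter[key] = rep_counter.get(key, 0) + 1
                entries[well] = LayoutEntry(role, strain, phage, rep_counter[key])
            elif role == "untreated_control":
                rep = row_spec.get("replicate")
                entries[well] = LayoutEntry(role, strain_id=strain, replicate=rep)
            elif role == "sterility_control":
                entries[well] = LayoutEntry(role, phage_id=phage)
            elif role == "blank":
                entries[well] = LayoutEntry(role)
            else:
                raise ValueError(f"unknown role {role!r} in row shorthand")
    for rec in data.get("extra_wells", []):
        well = WellCoordinate.parse(str(rec["well"]))
        if well in entries:
            raise ValueError(f"well {well} assigned twice")
        entries[well] = LayoutEntry(
            role=str(rec["role"]),
            strain_id=str(rec.get("strain", "") or ""),
            phage_id=str(rec.get("phage", "") or ""),
        )
    return PlateLayout(entries)


def read_layout(source: str | Path) -> PlateLayout:
    """Read a plate layout from YAML (long form or row shorthand) or TSV/CSV long form."""
    path = Path(source)
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        if isinstance(data, dict) and "rows" in data and "strains" in data:
            return _layout_from_row_shorthand(data)
        if isinstance(data, dict) and "wells" in data:
            return _layout_from_records(data["wells"])
        if isinstance(data, list):
            return _layout_from_records(data)
        raise ValueError(f"layout file {path}: unrecognized YAML structure")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"well", "role"}
    if not required <= set(df.columns):
        raise ValueError(f"layout file {path}: need columns {sorted(required)}")
    return _layout_from_records(df.to_dict("records"))


def write_layout(layout: PlateLayout, path: str | Path) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    layout.to_frame().to_csv(path, sep=sep, index=False)
    return path


def validate_plate(
    layout: PlateLayout,
    series: Mapping[WellCoordinate, WellSeries],
) -> dict[str, list[str]]:
    """Cross-check layout against data wells.

    Layout wells missing from the data are fatal (the caller aborts on a
    non-empty ``missing``); data wells absent from the layout are merely
    reported and ignored downstream.
    """
    layout_wells = set(layout.entries)
    data_wells = set(series)
    missing = sorted(str(w) for w in layout_wells - data_wells)
    unused = sorted(str(w) for w in data_wells - layout_wells)
    if unused:
        logger.warning("ignoring %d data wells absent from layout: %s", len(unused), unused[:8])
    return {"missing": missing, "unused": unused}
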