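"""Growth-inhibition designation of phage-treated wells.

Each phage-strain replicate is compared with the strain's untreated control
and assigned one of seven designations:

=========  =======================================================
C          complete inhibition — never reaches the detection threshold
D+         detection delayed by >= 5 h (up to the remaining window)
D          detection delayed by 1-5 h
N/L        endpoint OD_max 70-85 % of control, delay < 1 h
N/L+       endpoint OD_max 40-70 % of control, delay < 1 h
N/L++      endpoint OD_max <= 40 % of control, delay < 1 h
N          no effect
=========  =======================================================

Delay intervals are left-closed ([1, 5), [5, ...)); endpoint ratio bins are
right-closed ((0.40, 0.70], ...), with <= 0.40 for the deepest class.  A
sample detecting exactly at the end of the window is D+ (it did reach the
threshold, so "never reaches" is false).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .kinetics import CurveSummary
from .plate_io import ExperimentConfig, PlateLayout, WellCoordinate, WellSeries


class Designation(enum.Enum):
    """Growth-inhibition designation, ordered strongest (C) to weakest (N)."""

    C = "C"
    D_plus = "D+"
    D = "D"
    NL_plusplus = "N/L++"
    NL_plus = "N/L+"
    NL = "N/L"
    N = "N"

    @property
    def strength(self) -> int:
        """Rank for consensus tie-breaking: higher is more inhibitory."""
        order = ["N", "N/L", "N/L+", "N/L++", "D", "D+", "C"]
        return order.index(self.value)

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class ControlSummary:
    """Aggregated untreated-control behaviour for one strain."""

    strain_id: str
    detection_time: float | None
    od_max: float
    n_replicates: int
    qc_pass: bool


@dataclass
class ReplicateResult:
    """Classification outcome for one treated well."""

    well: WellCoordinate
    strain_id: str
    phage_id: str
    replicate: int | None
    detection_time: float | None
    od_max: float
    od_mean: float
    designation: Designation | None
    outlier: bool = False
    exclusion_reason: str = ""

    @property
    def excluded(self) -> bool:
        return self.designation is None


@dataclass
class PairResult:
    """Consensus over the technical replicates of one phage-strain pair."""

    strain_id: str
    phage_id: str
    designation: Designation | None
    detection_time: float | None
    od_max: float | None
    od_max_ratio: float | None
    replicates: list[ReplicateResult] = field(default_factory=list)
    not_evaluable_reason: str = ""

    @property
    def evaluable(self) -> bool:
        return self.designation is not None


def summarize_control(
    replicates: Sequence[CurveSummary],
    strain_id: str,
    config: ExperimentConfig,
) -> ControlSummary:
    """Aggregate a strain's untreated-control replicates.

    Only replicates that both reach the detection threshold and pass the
    growth-trend gate contribute; if none do the strain fails QC and all of
    its treatments become not-evaluable downstream.
    """
    if not replicates:
        raise ValueError(f"strain {strain_id}: no untreated-control replicates")
    usable = [r for r in replicates if r.detection_time is not None and r.trend]
    agg = np.median if config.control_aggregate == "median" else np.mean
    if not usable:
        return ControlSummary(
            strain_id=strain_id,
            detection_time=None,
            od_max=float(agg([r.od_max for r in replicates])),
            n_replicates=0,
            qc_pass=False,
        )
    det = float(agg([r.detection_time for r in usable]))
    qc = det < config.duration
    return ControlSummary(
        strain_id=strain_id,
        detection_time=det if qc else None,
        od_max=float(agg([r.od_max for r in usable])),
        n_replicates=len(usable),
        qc_pass=qc,
    )


def classify_replicate(
    sample: CurveSummary,
    control: ControlSummary,
    config: ExperimentConfig,
) -> Designation:
    """Designate one treated curve against its strain's control."""
    if not control.qc_pass or control.detection_time is None:
        raise ValueError(
            f"strain {control.strain_id}: control failed QC; sample must be excluded,"
            " not designated"
        )
    if sample.detection_time is None:
        return Designation.C
    delay = sample.detection_time - control.detection_time
    if delay >= config.delay_major:
        return Designation.D_plus
    if delay >= config.delay_minor:
        return Designation.D
    hi, mid, lo = config.endpoint_bounds
    ratio = sample.od_max / control.od_max if control.od_max > 0 else np.inf
    if ratio <= lo:
        return Designation.NL_plusplus
    if ratio <= mid:
        return Designation.NL_plus
    if ratio <= hi:
        return Designation.NL
    return Designation.N


def _consensus(designations: Sequence[Designation]) -> Designation:
    """Modal designation; ties resolved toward the weaker (less inhibitory)."""
    counts: dict[Designation, int] = {}
    for d in designations:
        counts[d] = counts.get(d, 0) + 1
    top = max(counts.values())
    modal = [d for d, c in counts.items() if c == top]
    return min(modal, key=lambda d: d.strength)


def _flag_outliers(results: Sequence[ReplicateResult], config: ExperimentConfig) -> None:
    """Majority-designation outlier rule, plus an optional detection-time screen.

    A replicate is an outlier when >= 3 replicates exist and a strict
    majority of the OTHERS share a designation different from its own.
    """
    included = [r for r in results if not r.excluded]
    if len(included) >= 3:
        for r in included:
            others = [o.designation for o in included if o is not r]
            counts: dict[Designation, int] = {}
            for d in others:
                counts[d] = counts.get(d, 0) + 1
            for d, c in counts.items():
                if d != r.designation and c * 2 > len(others):
                    r.outlier = True
                    break
    if config.outlier_time_rule:
        times = [r.detection_time for r in included if r.detection_time is not None]
        if len(times) >= 3:
            med = float(np.median(times))
            tol = 2.0 * config.interval_hours
            for r in included:
                if r.detection_time is not None and abs(r.detection_time - med) > tol:
                    r.outlier = True


def aggregate_replicates(
    results: Sequence[ReplicateResult],
    config: ExperimentConfig,
    control: ControlSummary | None = None,
) -> PairResult:
    """Consensus designation and replicate means for one phage-strain pair."""
    if not results:
        raise ValueError("no replicates to aggregate")
    strain = results[0].strain_id
    phage = results[0].phage_id
    included = [r for r in results if not r.excluded]
    if not included:
        reason = results[0].exclusion_reason or "all replicates excluded"
        return PairResult(
            strain_id=strain,
            phage_id=phage,
            designation=None,
            detection_time=None,
            od_max=None,
            od_max_ratio=None,
            replicates=list(results),
            not_evaluable_reason=reason,
        )
    _flag_outliers(results, config)
    kept = [r for r in included if not r.outlier] or included
    consensus = _consensus([r.designation for r in kept])
    det_times = [r.detection_time for r in kept if r.detection_time is not None]
    od_max = float(np.mean([r.od_max for r in kept]))
    ratio = None
    if control is not None and control.od_max > 0:
        ratio = od_max / control.od_max
    return PairResult(
        strain_id=strain,
        phage_id=phage,
        designation=consensus,
        detection_time=float(np.mean(det_times)) if det_times else None,
        od_max=od_max,
        od_max_ratio=ratio,
        replicates=list(results),
    )


def qc_plate(
    layout: PlateLayout,
    series: Mapping[WellCoordinate, WellSeries],
    summaries: Mapping[WellCoordinate, CurveSummary],
    controls: Mapping[str, ControlSummary],
    config: ExperimentConfig,
    blank_range_limit: float = 0.05,
) -> list[dict]:
    """Plate-level QC flags; flags never drop data silently.

    - sterility-control wells reaching the detection threshold suggest
      contamination of that phage stock;
    - blank wells with an OD range beyond ``blank_range_limit`` suggest
      medium contamination;
    - strains whose untreated control fails QC are not evaluable.
    """
    flags: list[dict] = []
    for well in layout.wells("sterility_control"):
        if well not in summaries:
            continue
        if summaries[well].detection_time is not None:
            flags.append(
                {
                    "check": "sterility_contamination",
                    "well": str(well),
                    "subject": layout.entries[well].phage_id,
                    "detail": f"sterility well reached OD {config.threshold:g}",
                }
            )
    for well in layout.wells("blank"):
        if well not in series:
            continue
        r = series[well].readings
        span = float(r.max() - r.min())
        if span > blank_range_limit:
            flags.append(
                {
                    "check": "blank_drift",
                    "well": str(well),
                    "subject": "",
                    "detail": f"blank OD range {span:.3f} exceeds {blank_range_limit:g}",
                }
            )
    for strain, ctrl in sorted(controls.items()):
        if not ctrl.qc_pass:
            flags.append(
                {
                    "check": "control_no_growth",
                    "well": "",
                    "subject": strain,
                    "detail": "untreated control never reached threshold with a growth trend;"
                    " strain not evaluable",
                }
            )
    return flags
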