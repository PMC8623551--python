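"""End-to-end plate analysis: curves in, host-range profiles out."""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping

from .classify import (
    ControlSummary,
    Designation,
    PairResult,
    ReplicateResult,
    aggregate_replicates,
    classify_replicate,
    qc_plate,
    summarize_control,
)
from .hostrange import HostRangeProfile, InhibitionScore, build_profile, t_actual, t_max
from .kinetics import CurveSummary, blank_correct, mean_series, summarize_curve
from .plate_io import (
    ExperimentConfig,
    PlateLayout,
    WellCoordinate,
    WellSeries,
    validate_plate,
)


@dataclass
class AnalysisResult:
    """All per-well, per-pair and per-phage results of one plate analysis."""

    layout: PlateLayout
    config: ExperimentConfig
    summaries: dict[WellCoordinate, CurveSummary]
    controls: dict[str, ControlSummary]
    replicates: list[ReplicateResult]
    pairs: list[PairResult]
    profiles: dict[str, HostRangeProfile]
    qc_flags: list[dict] = field(default_factory=list)


def _clip_window(series: WellSeries, duration: float) -> WellSeries:
    keep = series.times <= duration + 1e-9
    if keep.all():
        return series
    return WellSeries(series.well, series.times[keep], series.readings[keep])


def analyze(
    series: Mapping[WellCoordinate, WellSeries],
    layout: PlateLayout,
    config: ExperimentConfig,
) -> AnalysisResult:
    """Run the full analysis on one plate.

    Raises if wells named in the layout are missing from the data, or if a
    strain appears in treatments without any untreated-control wells.
    Strains whose controls fail QC (no threshold crossing with a growth
    trend) are carried through as not-evaluable, never dropped.
    """
    report = validate_plate(layout, series)
    if report["missing"]:
        raise ValueError(f"layout wells missing from plate data: {report['missing']}")

    series = {w: _clip_window(series[w], config.duration) for w in layout.entries}

    if config.blank_correction:
        blanks = [series[w] for w in layout.wells("blank")]
        if blanks:
            series = {
                w: blank_correct(s, blanks) if layout.entries[w].role != "blank" else s
                for w, s in series.items()
            }

    summaries = {
        w: summarize_curve(
            series[w], config.threshold, config.min_growth_rate, config.slope_window
        )
        for w in layout.entries
    }

    # untreated controls, grouped by strain
    control_wells: dict[str, list[WellCoordinate]] = defaultdict(list)
    for w in layout.wells("untreated_control"):
        control_wells[layout.entries[w].strain_id].append(w)

    treatment_strains = {
        e.strain_id for e in layout.entries.values() if e.role == "treatment"
    }
    orphans = sorted(treatment_strains - set(control_wells))
    if orphans:
        raise ValueError(f"strains treated without untreated controls: {orphans}")

    controls = {
        strain: summarize_control([summaries[w] for w in wells], strain, config)
        for strain, wells in control_wells.items()
    }

    # classify every treated well
    replicates: list[ReplicateResult] = []
    pair_wells: dict[tuple[str, str], list[WellCoordinate]] = defaultdict(list)
    for w in layout.wells("treatment"):
        e = layout.entries[w]
        s = summaries[w]
        ctrl = controls[e.strain_id]
        if ctrl.qc_pass:
            designation = classify_replicate(s, ctrl, config)
            reason = ""
        else:
            designation = None
            reason = "control failed QC"
        replicates.append(
            ReplicateResult(
                well=w,
                strain_id=e.strain_id,
                phage_id=e.phage_id,
                replicate=e.replicate,
                detection_time=s.detection_time,
                od_max=s.od_max,
                od_mean=s.od_mean,
                designation=designation,
                exclusion_reason=reason,
            )
        )
        pair_wells[(e.strain_id, e.phage_id)].append(w)

    by_pair: dict[tuple[str, str], list[ReplicateResult]] = defaultdict(list)
    for r in replicates:
        by_pair[(r.strain_id, r.phage_id)].append(r)

    pairs: list[PairResult] = []
    for key in sorted(by_pair):
        strain, _phage = key
        ctrl = controls[strain]
        pair = aggregate_replicates(by_pair[key], config, control=ctrl)
        if config.classify_mode == "averaged" and pair.evaluable:
            avg = mean_series([series[w] for w in sorted(pair_wells[key])])
            avg_summary = summarize_curve(
                avg, config.threshold, config.min_growth_rate, config.slope_window
            )
            pair.designation = classify_replicate(avg_summary, ctrl, config)
            pair.detection_time = avg_summary.detection_time
        pairs.append(pair)

    profiles = _host_range_profiles(pairs, controls, layout, config)
    flags = qc_plate(layout, series, summaries, controls, config)
    return AnalysisResult(
        layout=layout,
        config=config,
        summaries=summaries,
        controls=controls,
        replicates=replicates,
        pairs=pairs,
        profiles=profiles,
        qc_flags=flags,
    )


def _host_range_profiles(
    pairs: list[PairResult],
    controls: Mapping[str, ControlSummary],
    layout: PlateLayout,
    config: ExperimentConfig,
) -> dict[str, HostRangeProfile]:
    """Inhibition scores and HRi per phage over the declared panel.

    The declared panel is every strain on the plate; not-evaluable pairs
    contribute 0 to the sum while HR_max stays at the panel size.  A
    consensus of complete inhibition scores exactly 1 even if an outlying
    replicate detected growth.
    """
    panel = layout.strains
    hr_max = len(panel)
    by_phage: dict[str, dict[str, InhibitionScore | None]] = defaultdict(dict)
    for pair in pairs:
        ctrl = controls[pair.strain_id]
        if not pair.evaluable or not ctrl.qc_pass:
            by_phage[pair.phage_id][pair.strain_id] = None
            continue
        tmax = t_max(ctrl.detection_time, config.duration)
        if tmax <= 0:
            by_phage[pair.phage_id][pair.strain_id] = None
            continue
        if pair.designation is Designation.C:
            tact = tmax
        else:
            tact = t_actual(pair.detection_time, ctrl.detection_time, tmax)
        by_phage[pair.phage_id][pair.strain_id] = InhibitionScore(
            strain_id=pair.strain_id,
            phage_id=pair.phage_id,
            t_actual=tact,
            t_max=tmax,
        )
    return {
        phage: build_profile(phage, scores, hr_max=hr_max, conditions=config.conditions)
        for phage, scores in sorted(by_phage.items())
    }
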