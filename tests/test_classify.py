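"""Designation rules, control aggregation, replicate consensus and QC."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagerange import (
    Designation,
    ControlSummary,
    ExperimentConfig,
    aggregate_replicates,
    classify_replicate,
    qc_plate,
    summarize_control,
)
from phagerange.classify import ReplicateResult, _consensus
from phagerange.kinetics import CurveSummary, summarize_curve
from phagerange.plate_io import LayoutEntry, PlateLayout, WellCoordinate
from conftest import make_series

STRENGTH_ORDER = [
    Designation.N,
    Designation.NL,
    Designation.NL_plus,
    Designation.NL_plusplus,
    Designation.D,
    Designation.D_plus,
    Designation.C,
]


def summary(detection_time, od_max=1.0, od_mean=0.5, trend=True):
    return CurveSummary(detection_time, od_max, od_mean, trend, np.array([]))


def control(det=8.0, od_max=1.0, qc=True):
    return ControlSummary("S1", det if qc else None, od_max, 3, qc)


class TestClassifyReplicate:
    @pytest.mark.parametrize(
        "det, od_max, expected",
        [
            (None, 0.05, Designation.C),  # never reaches threshold
            (14.0, 1.0, Designation.D_plus),  # delay 6 h
            (10.5, 1.0, Designation.D),  # delay 2.5 h
            (8.5, 0.60, Designation.NL_plus),  # delay 0.5 h, 40-70 %
            (8.5, 0.90, Designation.N),  # above all endpoint bounds
            (8.5, 0.80, Designation.NL),  # 70-85 %
            (8.5, 0.30, Designation.NL_plusplus),  # <= 40 %
            (7.0, 1.0, Designation.N),  # detects before control
        ],
    )
    def test_rule_table(self, config, det, od_max, expected):
        assert classify_replicate(summary(det, od_max), control(), config) is expected

    @pytest.mark.parametrize(
        "det, od_max, expected",
        [
            (9.0, 1.0, Designation.D),  # delay exactly 1 h -> D (left closed)
            (13.0, 1.0, Designation.D_plus),  # delay exactly 5 h -> D+
            (8.0, 0.40, Designation.NL_plusplus),  # ratio exactly 0.40
            (8.0, 0.70, Designation.NL_plus),  # ratio exactly 0.70
            (8.0, 0.85, Designation.NL),  # ratio exactly 0.85
            (24.0, 1.0, Designation.D_plus),  # detects at the final reading
        ],
    )
    def test_boundary_inclusivity(self, config, det, od_max, expected):
        assert classify_replicate(summary(det, od_max), control(), config) is expected

    def test_failed_control_is_exclusion_not_designation(self, config):
        with pytest.raises(ValueError, match="excluded"):
            classify_replicate(summary(10.0), control(qc=False), config)

    @settings(derandomize=True, max_examples=500)
    @given(
        det=st.one_of(
            st.none(),
            st.floats(0.0, 24.0),
            st.sampled_from([8.0, 9.0, 13.0]),  # exact 0/1/5 h delays
        ),
        od_max=st.one_of(
            st.floats(0.0, 1.5),
            st.sampled_from([0.40, 0.70, 0.85]),  # exact bin edges
        ),
    )
    def test_partition_totality(self, det, od_max):
        """Every valid sample gets exactly one designation."""
        d = classify_replicate(summary(det, od_max), control(), ExperimentConfig())
        assert isinstance(d, Designation)

    @settings(derandomize=True, max_examples=200)
    @given(
        det=st.floats(0.0, 23.0),
        later=st.floats(0.0, 1.0),
        od_max=st.floats(0.05, 1.5),
    )
    def test_later_detection_never_weakens(self, det, later, od_max):
        cfg = ExperimentConfig()
        a = classify_replicate(summary(det, od_max), control(), cfg)
        b = classify_replicate(summary(det + later, od_max), control(), cfg)
        assert b.strength >= a.strength

    def test_strength_order(self):
        assert sorted(Designation, key=lambda d: d.strength) == STRENGTH_ORDER


class TestSummarizeControl:
    def _curve(self, det, trend=True, od_max=1.0):
        return CurveSummary(det, od_max, 0.5, trend, np.array([]))

    def test_mean_of_detecting_replicates(self, config):
        cs = summarize_control(
            [self._curve(7.5), self._curve(8.0), self._curve(8.5)], "S1", config
        )
        assert cs.detection_time == pytest.approx(8.0)
        assert cs.qc_pass and cs.n_replicates == 3

    def test_no_detection_fails_qc(self, config):
        cs = summarize_control([self._curve(None), self._curve(None)], "S1", config)
        assert not cs.qc_pass and cs.detection_time is None

    def test_flat_replicate_filtered(self, config):
        cs = summarize_control(
            [self._curve(7.0), self._curve(9.0), self._curve(2.0, trend=False)],
            "S1",
            config,
        )
        assert cs.detection_time == pytest.approx(8.0)
        assert cs.n_replicates == 2

    def test_median_aggregation_option(self):
        cfg = ExperimentConfig(control_aggregate="median")
        cs = summarize_control(
            [self._curve(7.0), self._curve(8.0), self._curve(20.0)], "S1", cfg
        )
        assert cs.detection_time == pytest.approx(8.0)

    def test_zero_replicates_is_an_error(self, config):
        with pytest.raises(ValueError, match="S1"):
            summarize_control([], "S1", config)


def _rep(designation, det=8.0, od_max=1.0, rep=1):
    return ReplicateResult(
        well=WellCoordinate("A", rep),
        strain_id="S1",
        phage_id="P1",
        replicate=rep,
        detection_time=det,
        od_max=od_max,
        od_mean=0.5,
        designation=designation,
    )


def oracle_consensus(designations):
    """Brute-force mode with ties to the weakest, via exhaustive counting."""
    counts = {d: designations.count(d) for d in set(designations)}
    top = max(counts.values())
    modal = [d for d, c in counts.items() if c == top]
    return min(modal, key=lambda d: STRENGTH_ORDER.index(d))


class TestAggregateReplicates:
    def test_unanimous(self, config):
        pair = aggregate_replicates(
            [_rep(Designation.C, None, 0.05, r) for r in (1, 2, 3)], config
        )
        assert pair.designation is Designation.C
        assert not any(r.outlier for r in pair.replicates)

    def test_majority_flags_outlier(self, config):
        reps = [
            _rep(Designation.C, None, 0.05, 1),
            _rep(Designation.C, None, 0.05, 2),
            _rep(Designation.N, 8.0, 1.0, 3),
        ]
        pair = aggregate_replicates(reps, config)
        assert pair.designation is Designation.C
        assert [r.outlier for r in reps] == [False, False, True]

    def test_all_distinct_consensus_is_weakest(self, config):
        reps = [
            _rep(Designation.C, None, 0.05, 1),
            _rep(Designation.D, 10.0, 1.0, 2),
            _rep(Designation.N, 8.0, 1.0, 3),
        ]
        pair = aggregate_replicates(reps, config)
        assert pair.designation is Designation.N
        assert not any(r.outlier for r in reps)

    def test_consensus_matches_oracle_on_all_triplets(self, config):
        """Exhaustive check of the tie rule over every 3-designation multiset."""
        for trio in itertools.combinations_with_replacement(Designation, 3):
            reps = [_rep(d, 8.0, 1.0, i + 1) for i, d in enumerate(trio)]
            pair = aggregate_replicates(reps, config)
            kept = [r.designation for r in reps if not r.outlier]
            assert pair.designation is oracle_consensus(kept or list(trio))
            assert _consensus(list(trio)) is oracle_consensus(list(trio))

    def test_all_excluded_marks_not_evaluable(self, config):
        reps = [_rep(None, 8.0, 1.0, r) for r in (1, 2, 3)]
        for r in reps:
            r.exclusion_reason = "control failed QC"
        pair = aggregate_replicates(reps, config)
        assert not pair.evaluable
        assert "control" in pair.not_evaluable_reason

    def test_optional_detection_time_screen(self):
        cfg = ExperimentConfig(outlier_time_rule=True)
        reps = [
            _rep(Designation.N, 8.0, 1.0, 1),
            _rep(Designation.N, 8.0, 1.0, 2),
            _rep(Designation.N, 12.0, 1.0, 3),  # > 2 intervals from median
        ]
        aggregate_replicates(reps, cfg)
        assert [r.outlier for r in reps] == [False, False, True]


class TestQcPlate:
    def _setup(self, sterility_readings, blank_readings, control_det=8.0):
        layout = PlateLayout(
            {
                WellCoordinate("A", 1): LayoutEntry("sterility_control", phage_id="P1"),
                WellCoordinate("A", 2): LayoutEntry("blank"),
            }
        )
        cfg = ExperimentConfig()
        series = {
            WellCoordinate("A", 1): make_series(sterility_readings, well="A1"),
            WellCoordinate("A", 2): make_series(blank_readings, well="A2"),
        }
        summaries = {
            w: summarize_curve(s, cfg.threshold, cfg.min_growth_rate, cfg.slope_window)
            for w, s in series.items()
        }
        controls = {
            "S1": ControlSummary("S1", control_det, 1.0, 3, control_det is not None)
        }
        return layout, series, summaries, controls, cfg

    def test_clean_plate_has_no_flags(self):
        args = self._setup([0.05] * 10, [0.05] * 10)
        assert qc_plate(*args) == []

    def test_contaminated_sterility_well_flags_phage(self):
        args = self._setup([0.05, 0.1, 0.4, 0.4], [0.05] * 4)
        flags = qc_plate(*args)
        assert [f["check"] for f in flags] == ["sterility_contamination"]
        assert flags[0]["subject"] == "P1"

    def test_drifting_blank_flagged(self):
        args = self._setup([0.05] * 4, [0.05, 0.05, 0.05, 0.12])
        assert [f["check"] for f in qc_plate(*args)] == ["blank_drift"]

    def test_non_growing_control_listed(self):
        args = self._setup([0.05] * 4, [0.05] * 4, control_det=None)
        flags = qc_plate(*args)
        assert [f["check"] for f in flags] == ["control_no_growth"]
        assert flags[0]["subject"] == "S1"
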