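"""Two-boundary classification, interval mapping, institutional pooling."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cusumlearn import (
    classify,
    classify_outcomes,
    cusum_trajectory,
    pool_institutional,
    segment_intervals,
)
from cusumlearn.classify import (
    INCONCLUSIVE,
    NONPROFICIENT,
    PROFICIENT,
    StateSegment,
    attempt_case_map,
    chronological_order,
    label_blocks,
)
from cusumlearn.cusum import Trajectory

from conftest import oracle_state_changes, signals_from_segments


class TestSignals:
    def test_proficient_after_38_consecutive_successes(self, constants):
        """First n with n*s >= 2*H0 is 38; 37 successes stay inconclusive."""
        segs = classify_outcomes([0] * 38, constants)
        assert [(s.state, s.start_attempt, s.end_attempt) for s in segs] == [
            (INCONCLUSIVE, 1, 37), (PROFICIENT, 38, 38),
        ]
        assert segs[1].signal_attempt == 38
        only = classify_outcomes([0] * 37, constants)
        assert [s.state for s in only] == [INCONCLUSIVE]

    def test_nonproficient_after_7_consecutive_failures(self, constants):
        """First n with n*(1-s) >= 2*H1 is 7."""
        segs = classify_outcomes([1] * 7, constants)
        assert [(s.state, s.signal_attempt) for s in segs] == [
            (INCONCLUSIVE, None), (NONPROFICIENT, 7),
        ]
        assert [s.state for s in classify_outcomes([1] * 6, constants)] == [INCONCLUSIVE]

    def test_alternating_sequence_signals_nonproficient(self, constants):
        """S,F,S,F,... is a 50% failure rate; the chart drifts up 1-2s per
        pair and crosses the unacceptable threshold at attempt 16
        (value verified against the brute-force oracle)."""
        outcomes = [0, 1] * 10
        assert oracle_state_changes(outcomes, constants) == [(16, NONPROFICIENT)]
        segs = classify_outcomes(outcomes, constants)
        assert signals_from_segments(segs) == [(16, NONPROFICIENT)]

    def test_empty_sequence_yields_no_segments(self, constants):
        assert classify_outcomes([], constants) == []

    def test_no_signal_possible_at_first_attempt(self, constants):
        """max(s, 1-s) < 2*H for the default design, so attempt 1 is
        always inconclusive."""
        assert max(constants.s, constants.failure_increment) < 2 * min(
            constants.H0, constants.H1
        )
        for outcome in (0, 1):
            assert [s.state for s in classify_outcomes([outcome], constants)] == [INCONCLUSIVE]

    def test_segments_partition_attempts(self, constants):
        rng = np.random.default_rng(5)
        outcomes = (rng.random(300) < 0.3).astype(int)
        segs = classify_outcomes(outcomes, constants)
        assert segs[0].start_attempt == 1
        assert segs[-1].end_attempt == 300
        for prev, nxt in zip(segs, segs[1:]):
            assert nxt.start_attempt == prev.end_attempt + 1
            assert nxt.state != prev.state

    def test_step_mismatch_rejected(self, constants):
        traj = cusum_trajectory([0, 1, 0], constants)
        bad = Trajectory(values=traj.values * 1.01, outcomes=traj.outcomes)
        with pytest.raises(ValueError, match="step sizes"):
            classify(bad, constants)


class TestOracleEquivalence:
    def test_exhaustive_short_sequences(self, constants):
        """classify() agrees with a full-rescan oracle on every outcome
        sequence of length 8."""
        for outcomes in product((0, 1), repeat=8):
            expected = oracle_state_changes(list(outcomes), constants)
            got = signals_from_segments(classify_outcomes(outcomes, constants))
            assert got == expected, outcomes

    def test_random_long_sequences(self, constants):
        rng = np.random.default_rng(11)
        for p in (0.1, 0.3, 0.6):
            for _ in range(60):
                outcomes = (rng.random(80) < p).astype(int).tolist()
                assert signals_from_segments(
                    classify_outcomes(outcomes, constants)
                ) == oracle_state_changes(outcomes, constants)

    @given(
        outcomes=st.lists(st.integers(0, 1), min_size=1, max_size=60),
        last=st.integers(0, 1),
    )
    @settings(max_examples=150, deadline=None)
    def test_monotonicity_of_appended_outcome(self, outcomes, last, constants):
        """Appending a success never triggers nonproficient at that attempt;
        appending a failure never triggers proficient."""
        segs = classify_outcomes(outcomes + [last], constants)
        n = len(outcomes) + 1
        new_signals = [s for s in segs if s.signal_attempt == n]
        if last == 0:
            assert all(s.state != NONPROFICIENT for s in new_signals)
        else:
            assert all(s.state != PROFICIENT for s in new_signals)


class TestIntervals:
    def test_boundary_closed_by_signal_case(self, constants):
        """With two nodes per case, a proficient signal at attempt 10 lies
        in case 5, which closes the learning interval; case 6 opens
        proficiency."""
        segs = [
            StateSegment(INCONCLUSIVE, 1, 9),
            StateSegment(PROFICIENT, 10, 20, signal_attempt=10, changepoint_attempt=2),
        ]
        a2c = [(k // 2) + 1 for k in range(20)]  # 1,1,2,2,...,10,10
        intervals = segment_intervals(segs, a2c)
        assert [(iv.label, iv.start_case, iv.end_case) for iv in intervals] == [
            ("learning", 1, 5), ("proficiency", 6, 10),
        ]

    def test_single_proficient_segment_spans_all_cases(self, constants):
        segs = [
            StateSegment(INCONCLUSIVE, 1, 37),
            StateSegment(PROFICIENT, 38, 60, signal_attempt=38, changepoint_attempt=1),
        ]
        intervals = segment_intervals(segs, list(range(1, 61)))
        assert [iv.label for iv in intervals] == ["learning", "proficiency"]
        assert intervals[-1].end_case == 60

    def test_four_block_structure(self):
        """inconclusive -> proficient -> nonproficient -> proficient maps to
        learning / proficiency / worsening / proficiency."""
        segs = [
            StateSegment(INCONCLUSIVE, 1, 40),
            StateSegment(PROFICIENT, 41, 100, 41, 20),
            StateSegment(NONPROFICIENT, 101, 140, 101, 95),
            StateSegment(PROFICIENT, 141, 200, 141, 138),
        ]
        a2c = list(range(1, 201))
        intervals = segment_intervals(segs, a2c)
        assert [iv.label for iv in intervals] == [
            "learning", "proficiency", "worsening", "proficiency",
        ]
        # partition with no gaps
        assert intervals[0].start_case == 1
        for prev, nxt in zip(intervals, intervals[1:]):
            assert nxt.start_case == prev.end_case + 1
        assert intervals[-1].end_case == 200

    def test_nonproficient_before_proficiency_merges_into_learning(self):
        segs = [
            StateSegment(INCONCLUSIVE, 1, 6),
            StateSegment(NONPROFICIENT, 7, 50, 7, 1),
            StateSegment(PROFICIENT, 51, 80, 51, 45),
        ]
        blocks = label_blocks(segs)
        assert [b[0] for b in blocks] == ["learning", "proficiency"]

    def test_short_case_map_rejected(self):
        segs = [StateSegment(INCONCLUSIVE, 1, 10)]
        with pytest.raises(ValueError, match="covers"):
            segment_intervals(segs, [1, 1, 2])


def _records_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["operator_id", "case_id", "node_order", "date_order", "outcome"],
    ).assign(attending_assist=0, cytopathologist=0, midazolam_mg=5.0, fentanyl_ug=100.0)


class TestPooling:
    def test_pooled_chart_merges_operators_chronologically(self, constants):
        records = _records_frame(
            [
                ("A", "A-1", 1, 1, 1),
                ("B", "B-1", 1, 2, 0),
                ("A", "A-2", 1, 3, 0),
                ("B", "B-1", 2, 4, 1),
            ]
        )
        traj = pool_institutional(records, constants)
        np.testing.assert_array_equal(traj.outcomes, [1, 0, 0, 1])
        assert len(traj.values) == 5

    def test_filtering_reproduces_per_operator_charts(self, constants, replica_records):
        ordered = chronological_order(replica_records)
        pooled = pool_institutional(ordered, constants)
        assert len(pooled.values) == len(ordered) + 1
        for op, group in ordered.groupby("operator_id", sort=False):
            sub = cusum_trajectory(group.sort_values("date_order")["outcome"].to_numpy(), constants)
            mask = (ordered["operator_id"] == op).to_numpy()
            np.testing.assert_array_equal(sub.outcomes, pooled.outcomes[mask])

    def test_unorderable_ties_rejected(self, constants):
        records = _records_frame(
            [("A", "A-1", 1, 1, 0), ("A", "A-1", 1, 1, 1)]
        )
        with pytest.raises(ValueError, match="ties"):
            pool_institutional(records, constants)

    def test_attempt_case_map_is_nondecreasing(self, replica_records):
        a2c = attempt_case_map(replica_records)
        assert a2c[0] == 1
        assert np.all(np.diff(a2c) >= 0)
        assert a2c[-1] == replica_records["case_id"].nunique()
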