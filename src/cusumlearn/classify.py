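"""Two-boundary proficiency classification and interval segmentation.

The decision rule is extremum-referenced: starting from the last signal
(or the chart origin), a *proficient* signal fires at the first attempt
where the chart has fallen two decision intervals (``2*H0``) below its
running maximum, and a *nonproficient* signal at the first attempt where
it has risen ``2*H1`` above its running minimum.  After a signal both
running extrema reset at the signalling value, so a repeated signal
requires a fresh two-interval excursion.  The state persists until the
opposite signal; attempts before the first signal are *inconclusive*.

Extremum-referencing makes the rule translation-invariant: a rule based
on a fixed lattice of boundary lines would depend on the arbitrary chart
start value, whereas an excursion from the running extremum does not.
The running extremum attempt doubles as a change-point estimate — the
chart turns where the underlying failure rate changed, while the signal
itself lags by the excursion length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cusum import FAILURE, ScoreConstants, Trajectory, cusum_trajectory, encode_outcomes

INCONCLUSIVE = "inconclusive"
PROFICIENT = "proficient"
NONPROFICIENT = "nonproficient"

LEARNING = "learning"
PROFICIENCY = "proficiency"
WORSENING = "worsening"

_STEP_ATOL = 1e-9


@dataclass(frozen=True)
class StateSegment:
    """A maximal run of attempts sharing a proficiency state.

    ``signal_attempt`` is the attempt at which the state was declared
    (None for the initial inconclusive segment); ``changepoint_attempt``
    is the attempt of the referenced extremum at signal time, the
    chart-based estimate of where performance actually changed.
    """

    state: str
    start_attempt: int
    end_attempt: int
    signal_attempt: Optional[int] = None
    changepoint_attempt: Optional[int] = None


@dataclass(frozen=True)
class IntervalLabel:
    """A chronological case interval: learning / proficiency / worsening."""

    label: str
    start_case: int
    end_case: int


def _validate_steps(trajectory: Trajectory, constants: ScoreConstants) -> None:
    diffs = np.diff(trajectory.values)
    expected = np.where(
        trajectory.outcomes == FAILURE, constants.failure_increment, -constants.s
    )
    if len(diffs) and np.max(np.abs(diffs - expected)) > _STEP_ATOL:
        raise ValueError(
            "trajectory step sizes do not match the supplied constants"
        )


def classify(trajectory: Trajectory, constants: ScoreConstants) -> list[StateSegment]:
    """Partition a trajectory's attempts into proficiency state segments.

    Returns an ordered list of :class:`StateSegment` covering attempts
    ``1..n`` with no gaps; consecutive segments have different states.
    An empty trajectory yields an empty list.
    """
    _validate_steps(trajectory, constants)
    n = trajectory.n_attempts
    if n == 0:
        return []
    two_h0 = 2.0 * constants.H0
    two_h1 = 2.0 * constants.H1
    step_max = max(constants.s, constants.failure_increment)
    if step_max >= min(two_h0, two_h1):
        raise ValueError(
            "a single attempt could cross a decision threshold; "
            "the two-boundary rule is not meaningful for these constants"
        )

    values = trajectory.values
    segments: list[StateSegment] = []
    state = INCONCLUSIVE
    seg_start = 1
    seg_signal: Optional[int] = None
    seg_change: Optional[int] = None
    ref_max = ref_min = values[0]
    argmax = argmin = 0

    for k in range(1, n + 1):
        c = values[k]
        if c > ref_max:
            ref_max, argmax = c, k
        if c < ref_min:
            ref_min, argmin = c, k
        prof = ref_max - c >= two_h0 - _STEP_ATOL
        nonprof = c - ref_min >= two_h1 - _STEP_ATOL
        if prof and nonprof:  # impossible when step_max < min(2H0, 2H1)
            raise AssertionError("both thresholds crossed at one attempt")
        if not (prof or nonprof):
            continue
        new_state = PROFICIENT if prof else NONPROFICIENT
        changepoint = argmax if prof else argmin
        if new_state != state:
            if seg_start <= k - 1:
                segments.append(
                    StateSegment(state, seg_start, k - 1, seg_signal, seg_change)
                )
            state, seg_start = new_state, k
            seg_signal, seg_change = k, changepoint
        # any signal (including a same-state one) resets the excursion
        ref_max = ref_min = c
        argmax = argmin = k

    segments.append(StateSegment(state, seg_start, n, seg_signal, seg_change))
    return segments


def classify_outcomes(outcomes, constants: ScoreConstants) -> list[StateSegment]:
    """Convenience wrapper: chart an outcome sequence, then classify it."""
    return classify(cusum_trajectory(outcomes, constants), constants)


def label_blocks(segments: Sequence[StateSegment]) -> list[tuple]:
    """Merge state segments into labelled blocks.

    Returns ``[(label, signal_attempt, changepoint_attempt), ...]`` where
    labels follow the interval semantics: inconclusive/nonproficient
    before proficiency is first attained = learning, proficient =
    proficiency, nonproficient afterwards = worsening.  Consecutive
    segments sharing a label merge (keeping the first segment's signal
    and change-point attempts).
    """
    seen_proficiency = False
    blocks: list[tuple] = []
    for seg in segments:
        if seg.state == PROFICIENT:
            label = PROFICIENCY
            seen_proficiency = True
        elif seg.state == NONPROFICIENT:
            label = WORSENING if seen_proficiency else LEARNING
        else:
            label = LEARNING
        if blocks and blocks[-1][0] == label:
            continue
        blocks.append((label, seg.signal_attempt, seg.changepoint_attempt))
    return blocks


def segment_intervals(
    segments: Sequence[StateSegment], attempt_to_case: Sequence[int]
) -> list[IntervalLabel]:
    """Map state segments to chronological case intervals.

    ``attempt_to_case`` maps 1-based attempt ``k`` to its 1-based case
    index via ``attempt_to_case[k-1]``; it must be nondecreasing and
    cover every attempt (several attempts may share one case).

    Labels: spans before proficiency is first attained (inconclusive or
    nonproficient) are *learning*; proficient spans are *proficiency*;
    a nonproficient span after proficiency was attained is *worsening*.
    The case containing a signalling attempt closes the preceding
    interval; the next case opens the new one.
    """
    if not segments:
        return []
    a2c = np.asarray(attempt_to_case, dtype=int)
    last_attempt = max(seg.end_attempt for seg in segments)
    if len(a2c) < last_attempt:
        raise ValueError(
            f"attempt_to_case covers {len(a2c)} attempts but segments "
            f"extend to attempt {last_attempt}"
        )
    if len(a2c) > 1 and np.any(np.diff(a2c) < 0):
        raise ValueError("attempt_to_case must be nondecreasing")

    blocks = label_blocks(segments)

    last_case = int(a2c[last_attempt - 1])
    intervals: list[IntervalLabel] = []
    start_case = 1
    for i, (label, _, _) in enumerate(blocks):
        if i + 1 < len(blocks):
            next_signal = blocks[i + 1][1]
            end_case = int(a2c[next_signal - 1])
        else:
            end_case = last_case
        if end_case >= start_case:
            intervals.append(IntervalLabel(label, start_case, end_case))
            start_case = end_case + 1
        # a signal landing in an already-closed case yields an empty
        # interval, which is dropped
    return intervals


def pool_institutional(records: pd.DataFrame, constants: ScoreConstants) -> Trajectory:
    """Pool all operators' attempts into one institutional chart.

    ``records`` follows the cohort schema (see :mod:`cusumlearn.io`):
    one row per sampled node with ``date_order``, ``case_id``,
    ``node_order`` and ``outcome``.  Attempts are merged across
    operators in chronological order — one running sum, not per-operator
    restarts.  Per-operator charts are obtained by filtering ``records``
    before calling :func:`cusumlearn.cusum.cusum_trajectory`.
    """
    ordered = chronological_order(records)
    return cusum_trajectory(ordered["outcome"].to_numpy(), constants)


def chronological_order(records: pd.DataFrame) -> pd.DataFrame:
    """Sort cohort records by (date_order, case_id, node_order); reject ties."""
    key_cols = ["date_order", "case_id", "node_order"]
    for col in key_cols + ["outcome"]:
        if col not in records.columns:
            raise ValueError(f"records are missing required column {col!r}")
    if records.duplicated(subset=key_cols).any():
        dup = records[records.duplicated(subset=key_cols, keep=False)]
        raise ValueError(
            "records contain unorderable ties (same date_order, case_id, "
            f"node_order): {dup[key_cols].head().to_dict('records')}"
        )
    out = records.sort_values(key_cols, kind="mergesort").reset_index(drop=True)
    out["outcome"] = encode_outcomes(out["outcome"])
    return out


def case_rank_map(records: pd.DataFrame) -> pd.Series:
    """Chronological 1-based case rank for each case_id, by first appearance."""
    ordered = chronological_order(records)
    first_seen = ordered.drop_duplicates("case_id")["case_id"]
    return pd.Series(
        np.arange(1, len(first_seen) + 1), index=first_seen.to_numpy(), name="case_rank"
    )


def attempt_case_map(records: pd.DataFrame) -> np.ndarray:
    """1-based chronological case index of each pooled attempt, in order."""
    ordered = chronological_order(records)
    ranks = case_rank_map(records)
    return ordered["case_id"].map(ranks).to_numpy()
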