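import numpy as np
import pytest

from cusumlearn import (
    CusumParams,
    derive_constants,
    generate_cohort,
    replica_scenario,
)


@pytest.fixture(scope="session")
def design():
    """The default sequential design: p0=0.1, p1=0.2, alpha=beta=0.1."""
    return CusumParams(p0=0.1, p1=0.2, alpha=0.1, beta=0.1)


@pytest.fixture(scope="session")
def constants(design):
    return derive_constants(design)


@pytest.fixture(scope="session")
def replica_records():
    """The packaged 222-node synthetic replica cohort."""
    return generate_cohort(replica_scenario())


def oracle_signals(outcomes, constants, threshold_multiple=2.0):
    """Brute-force re-scan classifier used as an independent oracle.

    Recomputes the running extrema from the last reset at *every* step
    by a full window scan, instead of maintaining them incrementally.
    Returns the list of (attempt, state) signals.
    """
    values = [0.0]
    for o in outcomes:
        values.append(values[-1] + (constants.failure_increment if o else -constants.s))
    reset = 0
    signals = []
    for k in range(1, len(values)):
        window = values[reset:k + 1]
        prof = max(window) - values[k] >= threshold_multiple * constants.H0 - 1e-9
        nonprof = values[k] - min(window) >= threshold_multiple * constants.H1 - 1e-9
        if prof or nonprof:
            signals.append((k, "proficient" if prof else "nonproficient"))
            reset = k
    return signals


def signals_from_segments(segments):
    """State-change signals (attempt, state) from classify() segments.

    classify() merges same-state re-signals into one segment, so this is
    compared against :func:`oracle_state_changes`, not raw oracle signals.
    """
    return [(s.signal_attempt, s.state) for s in segments if s.signal_attempt is not None]


def oracle_state_changes(outcomes, constants):
    """State-change signals from the oracle (drop same-state re-signals)."""
    out = []
    state = "inconclusive"
    for attempt, new_state in oracle_signals(outcomes, constants):
        if new_state != state:
            out.append((attempt, new_state))
            state = new_state
    return out
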