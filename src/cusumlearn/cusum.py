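"""Bernoulli CUSUM scoring for binary procedural outcomes.

The chart monitors a sequence of attempt-level successes and failures
against a designated acceptable failure rate ``p0`` and an unacceptable
rate ``p1``.  Scores derive from the sequential probability ratio test:
each failure moves the chart up by ``1 - s`` and each success moves it
down by ``s``, where ``s`` is chosen so the chart drifts downward while
the true failure probability is below ``s`` and upward above it
(``p0 < s < p1`` for any valid design).

All quantities are kept at full floating precision; rounding to two
decimals is presentation only (see :meth:`ScoreConstants.rounded`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np

#: Integer outcome codes used throughout the package.
SUCCESS = 0
FAILURE = 1

_OUTCOME_TOKENS = {
    "0": SUCCESS, "s": SUCCESS, "success": SUCCESS,
    "1": FAILURE, "f": FAILURE, "failure": FAILURE, "fail": FAILURE,
}


@dataclass(frozen=True)
class CusumParams:
    """Design quadruple of the sequential test.

    Parameters
    ----------
    p0 : float
        Acceptable failure rate of the monitored procedure.
    p1 : float
        Unacceptable failure rate; must exceed ``p0``.
    alpha : float
        Type 1 error — probability of falsely flagging an operator
        as nonproficient.
    beta : float
        Type 2 error — probability of falsely flagging an operator
        as proficient.
    """

    p0: float = 0.1
    p1: float = 0.2
    alpha: float = 0.1
    beta: float = 0.1

    def __post_init__(self) -> None:
        for name in ("p0", "p1", "alpha", "beta"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v!r} must lie strictly in (0, 1)")
        if not self.p0 < self.p1:
            raise ValueError(
                f"p0={self.p0} must be < p1={self.p1}: otherwise the test "
                "has no discriminating power"
            )
        if self.alpha + self.beta >= 1.0:
            raise ValueError(
                f"alpha + beta = {self.alpha + self.beta} must be < 1 for the "
                "decision intervals to be positive"
            )


@dataclass(frozen=True)
class ScoreConstants:
    """Derived scoring constants and decision intervals.

    ``P`` and ``Q`` are the log-likelihood-ratio increments for a failure
    and a success; ``s = Q/(P+Q)`` is the per-success decrement of the
    chart and ``1 - s`` the per-failure increment.  ``H0`` and ``H1`` are
    the acceptable and unacceptable decision intervals: the classifier
    signals on cumulative excursions of two decision intervals
    (see :mod:`cusumlearn.classify`).
    """

    P: float
    Q: float
    s: float
    failure_increment: float
    a: float
    b: float
    H0: float
    H1: float

    def rounded(self, ndigits: int = 2) -> dict:
        """Presentation-layer rounding (the internal values stay exact)."""
        return {k: round(v, ndigits) for k, v in asdict(self).items()}

    def to_dict(self) -> dict:
        return asdict(self)


def derive_constants(params: CusumParams) -> ScoreConstants:
    """Derive CUSUM scoring constants from the design parameters.

    ``P = ln(p1/p0)``, ``Q = ln((1-p0)/(1-p1))``, ``s = Q/(P+Q)``,
    ``a = ln((1-beta)/alpha)``, ``b = ln((1-alpha)/beta)``,
    ``H0 = b/(P+Q)``, ``H1 = a/(P+Q)``.  Natural logarithms throughout.

    With the default design (p0=0.1, p1=0.2, alpha=beta=0.1) this gives
    s = 0.1452, H0 = H1 = 2.71 (2 d.p.).
    """
    p0, p1 = params.p0, params.p1
    P = math.log(p1 / p0)
    Q = math.log((1.0 - p0) / (1.0 - p1))
    s = Q / (P + Q)
    a = math.log((1.0 - params.beta) / params.alpha)
    b = math.log((1.0 - params.alpha) / params.beta)
    return ScoreConstants(
        P=P, Q=Q, s=s, failure_increment=1.0 - s,
        a=a, b=b, H0=b / (P + Q), H1=a / (P + Q),
    )


def encode_outcomes(outcomes: Iterable) -> np.ndarray:
    """Normalise an outcome sequence to an int array (0=success, 1=failure).

    Accepts 0/1 integers, booleans (True=failure), or the string tokens
    ``S``/``F``, ``success``/``failure`` (case-insensitive).
    """
    coded = []
    for i, o in enumerate(outcomes):
        if isinstance(o, str):
            key = o.strip().lower()
            if key not in _OUTCOME_TOKENS:
                raise ValueError(f"unknown outcome token {o!r} at position {i}")
            coded.append(_OUTCOME_TOKENS[key])
        elif isinstance(o, (bool, np.bool_)):
            coded.append(int(o))
        else:
            v = int(o)
            if v not in (SUCCESS, FAILURE):
                raise ValueError(f"outcome {o!r} at position {i} is not 0/1")
            coded.append(v)
    return np.asarray(coded, dtype=np.int8)


@dataclass(frozen=True)
class Trajectory:
    """A CUSUM chart: values ``C_0..C_n`` over ``n`` binary outcomes.

    ``values[0] == 0`` and each step is ``+(1-s)`` for a failure or
    ``-s`` for a success.  The chart is unrestricted: no holding barrier
    at zero, so sustained success drives it arbitrarily negative.
    """

    values: np.ndarray
    outcomes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "outcomes", np.asarray(self.outcomes, dtype=np.int8))
        if len(self.values) != len(self.outcomes) + 1:
            raise ValueError("values must have length len(outcomes) + 1")
        if len(self.values) and self.values[0] != 0.0:
            raise ValueError("trajectory must start at C_0 = 0")

    @property
    def n_attempts(self) -> int:
        return len(self.outcomes)


def cusum_trajectory(outcomes: Iterable, constants: ScoreConstants) -> Trajectory:
    """Compute the CUSUM chart of an outcome sequence.

    ``C_0 = 0``; ``C_k = C_{k-1} + (1-s)`` for a failure, ``C_{k-1} - s``
    for a success.  An empty sequence yields the single start value.
    """
    coded = encode_outcomes(outcomes)
    steps = np.where(coded == FAILURE, constants.failure_increment, -constants.s)
    values = np.concatenate([[0.0], np.cumsum(steps)])
    return Trajectory(values=values, outcomes=coded)
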