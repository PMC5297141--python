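"""Synthetic cohorts with known ground truth, and Monte-Carlo operating
characteristics of the two-boundary decision rule.

The generator emulates a multi-operator procedural training cohort: each
operator works through chronological phases with a phase-specific
baseline failure probability; lymph-node sampling attempts are grouped
into cases (1-3 nodes per case); case-level suite covariates (assisting
attending, on-site cytopathologist, dichotomised sedative/opiate doses)
act on the per-attempt failure odds through a logistic link,

    logit(p_fail) = logit(p_phase) + sum_j x_j * log_odds_j .

Operators' case sequences are interleaved at random into one
institutional chronology.  Each operator consumes an independent
pseudo-random substream derived from the scenario seed, so adding an
operator does not perturb the others' draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .classify import (
    INCONCLUSIVE,
    LEARNING,
    NONPROFICIENT,
    PROFICIENCY,
    PROFICIENT,
    WORSENING,
    classify_outcomes,
    label_blocks,
)
from .cusum import CusumParams, Trajectory, cusum_trajectory, derive_constants

COVARIATE_NAMES = ("attending_assist", "cytopathologist", "high_midazolam", "high_fentanyl")

# dose draws: the dichotomous covariate decides which band the raw dose
# falls in; bands straddle the default thresholds (10 mg, 300 ug)
_MIDAZOLAM_BANDS = {0: (2.0, 8.0), 1: (10.0, 14.0)}
_FENTANYL_BANDS = {0: (50.0, 280.0), 1: (300.0, 500.0)}


@dataclass(frozen=True)
class Phase:
    """A run of attempts with a common baseline failure probability."""

    n_attempts: int
    p_fail: float


@dataclass(frozen=True)
class CovariateEffect:
    """Case-level prevalence and log-odds effect on per-attempt failure."""

    prevalence: float
    log_odds: float = 0.0


@dataclass(frozen=True)
class OperatorScenario:
    operator_id: str
    phases: tuple
    n_cases: Optional[int] = None  # exact case count; None = draw from nodes_per_case

    @property
    def n_attempts(self) -> int:
        return sum(ph.n_attempts for ph in self.phases)


@dataclass(frozen=True)
class SimulationScenario:
    """Full cohort recipe: operators, covariate model, case sizes, seed."""

    operators: tuple
    covariates: dict
    nodes_per_case: dict = field(default_factory=lambda: {1: 0.5, 2: 0.35, 3: 0.15})
    seed: int = 0

    def validate(self) -> None:
        if not self.operators:
            raise ValueError("scenario has no operators")
        any_effect = any(cv.log_odds != 0.0 for cv in self.covariates.values())
        for op in self.operators:
            if not op.phases:
                raise ValueError(f"operator {op.operator_id!r} has no phases")
            for ph in op.phases:
                if ph.n_attempts <= 0:
                    raise ValueError("phase n_attempts must be positive")
                lo, hi = (0.0, 1.0)
                if any_effect and not (lo < ph.p_fail < hi):
                    raise ValueError(
                        "phase p_fail must lie strictly in (0,1) when covariate "
                        "effects are nonzero (logistic link)"
                    )
                if not (lo <= ph.p_fail <= hi):
                    raise ValueError("phase p_fail must lie in [0,1]")
            if op.n_cases is not None:
                if not (op.n_cases <= op.n_attempts <= 3 * op.n_cases):
                    raise ValueError(
                        f"operator {op.operator_id!r}: n_cases={op.n_cases} cannot "
                        f"hold {op.n_attempts} attempts at 1-3 nodes per case"
                    )
        for name, cv in self.covariates.items():
            if not (0.0 <= cv.prevalence <= 1.0):
                raise ValueError(f"covariate {name!r} prevalence outside [0,1]")
        weights = np.array([self.nodes_per_case.get(k, 0.0) for k in (1, 2, 3)], dtype=float)
        if weights.sum() <= 0 or (weights < 0).any():
            raise ValueError("nodes_per_case must be a distribution over {1,2,3}")


def _case_sizes(op: OperatorScenario, scenario: SimulationScenario, rng) -> np.ndarray:
    """Partition an operator's attempts into case sizes of 1-3 nodes."""
    total = op.n_attempts
    weights = np.array([scenario.nodes_per_case.get(k, 0.0) for k in (1, 2, 3)], dtype=float)
    weights = weights / weights.sum()
    if op.n_cases is not None:
        sizes = np.ones(op.n_cases, dtype=int)
        extra = total - op.n_cases
        while extra > 0:
            open_cases = np.flatnonzero(sizes < 3)
            pick = rng.choice(open_cases)
            sizes[pick] += 1
            extra -= 1
        return sizes
    sizes = []
    remaining = total
    while remaining > 0:
        k = int(rng.choice([1, 2, 3], p=weights))
        sizes.append(min(k, remaining))
        remaining -= sizes[-1]
    return np.asarray(sizes, dtype=int)


def generate_cohort(scenario: SimulationScenario, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate one synthetic cohort as a tidy records table.

    Returns one row per sampled node with the cohort schema columns
    (see :mod:`cusumlearn.io`): operator_id, case_id, node_order,
    date_order, outcome (1 = failure), attending_assist,
    cytopathologist, midazolam_mg, fentanyl_ug.  Fully reproducible
    from the scenario seed (``seed`` overrides it).
    """
    scenario.validate()
    base_seed = scenario.seed if seed is None else seed
    cov_names = list(scenario.covariates.keys())

    per_op_cases = []  # list (per operator) of case dicts in operator order
    for idx, op in enumerate(scenario.operators):
        rng = np.random.default_rng([base_seed, 1000 + idx])
        sizes = _case_sizes(op, scenario, rng)
        # baseline failure probability of each attempt, phase by phase
        p_base = np.concatenate([np.full(ph.n_attempts, ph.p_fail) for ph in op.phases])
        # case-level covariates
        cov_draws = {
            name: rng.random(len(sizes)) < scenario.covariates[name].prevalence
            for name in cov_names
        }
        mid_high = cov_draws.get("high_midazolam", np.zeros(len(sizes), dtype=bool))
        fent_high = cov_draws.get("high_fentanyl", np.zeros(len(sizes), dtype=bool))
        midazolam = np.where(
            mid_high,
            rng.uniform(*_MIDAZOLAM_BANDS[1], len(sizes)),
            rng.uniform(*_MIDAZOLAM_BANDS[0], len(sizes)),
        )
        fentanyl = np.where(
            fent_high,
            rng.uniform(*_FENTANYL_BANDS[1], len(sizes)),
            rng.uniform(*_FENTANYL_BANDS[0], len(sizes)),
        )
        cases = []
        attempt = 0
        for c, size in enumerate(sizes):
            shift = sum(
                scenario.covariates[name].log_odds * float(cov_draws[name][c])
                for name in cov_names
            )
            p = expit(logit(np.clip(p_base[attempt:attempt + size], 1e-12, 1 - 1e-12)) + shift) \
                if shift != 0.0 else p_base[attempt:attempt + size]
            outcomes = (rng.random(size) < p).astype(int)
            cases.append(
                {
                    "operator_id": op.operator_id,
                    "case_seq": c + 1,
                    "outcomes": outcomes,
                    "covs": {name: int(cov_draws[name][c]) for name in cov_names},
                    "midazolam_mg": round(float(midazolam[c]), 1),
                    "fentanyl_ug": round(float(fentanyl[c]), 0),
                }
            )
            attempt += size
        per_op_cases.append(cases)

    # interleave operators' case sequences into one institutional chronology
    rng_merge = np.random.default_rng([base_seed, 999983])
    remaining = [len(cases) for cases in per_op_cases]
    cursors = [0] * len(per_op_cases)
    rows = []
    date_order = 0
    while sum(remaining) > 0:
        probs = np.asarray(remaining, dtype=float) / sum(remaining)
        pick = int(rng_merge.choice(len(per_op_cases), p=probs))
        case = per_op_cases[pick][cursors[pick]]
        cursors[pick] += 1
        remaining[pick] -= 1
        case_id = f"{case['operator_id']}-{case['case_seq']:03d}"
        for node_order, outcome in enumerate(case["outcomes"], start=1):
            date_order += 1
            rows.append(
                {
                    "operator_id": case["operator_id"],
                    "case_id": case_id,
                    "node_order": node_order,
                    "date_order": date_order,
                    "outcome": int(outcome),
                    "attending_assist": case["covs"].get("attending_assist", 0),
                    "cytopathologist": case["covs"].get("cytopathologist", 0),
                    "midazolam_mg": case["midazolam_mg"],
                    "fentanyl_ug": case["fentanyl_ug"],
                }
            )
    return pd.DataFrame(rows)


def replica_scenario(seed: Optional[int] = None) -> SimulationScenario:
    """The packaged study-replica scenario (3 operators, 222 nodes, 131 cases).

    Loaded from the packaged config ``data/replica_scenario.json``; it is
    synthetic — a structural stand-in for the study's chart-review data,
    with a four-phase institutional failure-rate profile
    (learning / proficient / worsening / proficient) shared across
    operators and illustrative covariate settings.
    """
    text = resources.files("cusumlearn.data").joinpath("replica_scenario.json").read_text()
    return scenario_from_dict(json.loads(text), seed=seed)


def four_phase_scenario(seed: int = 0) -> SimulationScenario:
    """Single-operator four-phase scenario used for segmentation recovery.

    Phases: learning p=0.35 for 30 attempts, proficient 0.08 for 60,
    worsening 0.30 for 40, proficient 0.08 for 70 (true phase changes
    after attempts 30, 90 and 130).  No covariate effects, so the phase
    probabilities are exact.
    """
    return SimulationScenario(
        operators=(
            OperatorScenario(
                operator_id="institution",
                phases=(Phase(30, 0.35), Phase(60, 0.08), Phase(40, 0.30), Phase(70, 0.08)),
            ),
        ),
        covariates={name: CovariateEffect(prevalence=0.3, log_odds=0.0) for name in COVARIATE_NAMES},
        seed=seed,
    )


def scenario_from_dict(d: dict, seed: Optional[int] = None) -> SimulationScenario:
    """Build a scenario from a plain-dict config (the JSON dialect)."""
    operators = tuple(
        OperatorScenario(
            operator_id=op["operator_id"],
            phases=tuple(Phase(int(n), float(p)) for n, p in op["phases"]),
            n_cases=op.get("n_cases"),
        )
        for op in d["operators"]
    )
    covariates = {
        name: CovariateEffect(float(cv["prevalence"]), float(cv.get("log_odds", 0.0)))
        for name, cv in d.get("covariates", {}).items()
    }
    nodes_per_case = {int(k): float(v) for k, v in d.get("nodes_per_case", {1: 0.5, 2: 0.35, 3: 0.15}).items()}
    return SimulationScenario(
        operators=operators,
        covariates=covariates,
        nodes_per_case=nodes_per_case,
        seed=int(d.get("seed", 0)) if seed is None else seed,
    )


def scenario_to_dict(scenario: SimulationScenario) -> dict:
    return {
        "seed": scenario.seed,
        "nodes_per_case": {str(k): v for k, v in scenario.nodes_per_case.items()},
        "operators": [
            {
                "operator_id": op.operator_id,
                "n_cases": op.n_cases,
                "phases": [[ph.n_attempts, ph.p_fail] for ph in op.phases],
            }
            for op in scenario.operators
        ],
        "covariates": {name: asdict(cv) for name, cv in scenario.covariates.items()},
    }


@dataclass(frozen=True)
class RecoveryResult:
    """Outcome of the four-phase segmentation-recovery experiment."""

    fraction_recovered: float     # four intervals AND boundaries within tolerance
    fraction_four_intervals: float  # label sequence matched, tolerance ignored
    n_reps: int
    tol_attempts: int

    def to_dict(self) -> dict:
        return asdict(self)


_FOUR_PHASE_LABELS = [LEARNING, PROFICIENCY, WORSENING, PROFICIENCY]


def simulate_segmentation_recovery(
    params: CusumParams,
    phases: Sequence = None,
    n_reps: int = 200,
    seed: int = 0,
    tol_attempts: int = 15,
) -> RecoveryResult:
    """How often does the classifier recover a known four-phase profile?

    Each replicate draws an outcome sequence from the phase profile
    (default: the :func:`four_phase_scenario` phases), classifies it,
    and checks (a) that the labelled blocks read
    learning / proficiency / worsening / proficiency and (b) that each
    detected boundary — the change-point (extremum) attempt of the
    signalling block — lies within ``tol_attempts`` of the true phase
    change.  Signals themselves lag the phase changes by the excursion
    length; the change-point estimate is the chart's turning point.
    """
    if phases is None:
        phases = four_phase_scenario().operators[0].phases
    phases = [Phase(int(ph[0]), float(ph[1])) if not isinstance(ph, Phase) else ph
              for ph in phases]
    truth = np.cumsum([ph.n_attempts for ph in phases])[:-1]
    const = derive_constants(params)
    n_structure = 0
    n_recovered = 0
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        outcomes = np.concatenate(
            [(rng.random(ph.n_attempts) < ph.p_fail).astype(int) for ph in phases]
        )
        blocks = label_blocks(classify_outcomes(outcomes, const))
        if [b[0] for b in blocks] != _FOUR_PHASE_LABELS:
            continue
        n_structure += 1
        boundaries = [b[2] for b in blocks[1:]]  # change-point attempts
        if all(abs(b - t) <= tol_attempts for b, t in zip(boundaries, truth)):
            n_recovered += 1
    return RecoveryResult(
        fraction_recovered=n_recovered / n_reps,
        fraction_four_intervals=n_structure / n_reps,
        n_reps=n_reps,
        tol_attempts=tol_attempts,
    )


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo estimates of the decision rule's error behaviour."""

    p_flag_nonproficient: float
    p_flag_proficient: float
    se_nonproficient: float
    se_proficient: float
    mean_run_length_to_signal: float  # NaN when no replicate signals
    n_reps: int
    horizon: int

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_operating_characteristics(
    params: CusumParams,
    p_true: float,
    horizon: int,
    n_reps: int,
    seed: int,
) -> OperatingCharacteristics:
    """Estimate flag probabilities and run length by direct simulation.

    Each replicate draws ``horizon`` i.i.d. outcomes at failure
    probability ``p_true``, applies the two-boundary classifier
    (including post-signal extremum resets), and records whether each
    signal type ever fires and the attempt of the first signal.
    """
    if horizon < 1 or n_reps < 1:
        raise ValueError("horizon and n_reps must be >= 1")
    if not (0.0 <= p_true <= 1.0):
        raise ValueError("p_true must lie in [0,1]")
    const = derive_constants(params)
    two_h0, two_h1 = 2.0 * const.H0, 2.0 * const.H1
    atol = 1e-9

    rng = np.random.default_rng(seed)
    c = np.zeros(n_reps)
    ref_max = np.zeros(n_reps)
    ref_min = np.zeros(n_reps)
    ever_prof = np.zeros(n_reps, dtype=bool)
    ever_nonprof = np.zeros(n_reps, dtype=bool)
    first_signal = np.zeros(n_reps, dtype=int)  # 0 = no signal yet

    for t in range(1, horizon + 1):
        fail = rng.random(n_reps) < p_true
        c = c + np.where(fail, const.failure_increment, -const.s)
        np.maximum(ref_max, c, out=ref_max)
        np.minimum(ref_min, c, out=ref_min)
        prof = ref_max - c >= two_h0 - atol
        nonprof = c - ref_min >= two_h1 - atol
        signal = prof | nonprof
        ever_prof |= prof
        ever_nonprof |= nonprof
        first_signal = np.where((first_signal == 0) & signal, t, first_signal)
        if signal.any():  # reset excursion references at the signalling value
            ref_max = np.where(signal, c, ref_max)
            ref_min = np.where(signal, c, ref_min)

    p_np = float(ever_nonprof.mean())
    p_p = float(ever_prof.mean())
    signalled = first_signal > 0
    mean_rl = float(first_signal[signalled].mean()) if signalled.any() else float("nan")
    return OperatingCharacteristics(
        p_flag_nonproficient=p_np,
        p_flag_proficient=p_p,
        se_nonproficient=float(np.sqrt(p_np * (1 - p_np) / n_reps)),
        se_proficient=float(np.sqrt(p_p * (1 - p_p) / n_reps)),
        mean_run_length_to_signal=mean_rl,
        n_reps=n_reps,
        horizon=horizon,
    )
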