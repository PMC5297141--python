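"""Learning-environment analysis: worsening-interval logistic regression.

Contrasts per-attempt environmental covariates between the worsening
interval and all other chronological intervals with a multivariable
logistic model.  The outcome is membership of the worsening interval;
covariates are the suite conditions recorded per case: an additional
assisting attending, an on-site cytopathologist (rapid on-site
evaluation), and dichotomised sedative/opiate doses (midazolam >= 10 mg,
fentanyl >= 300 ug by default; thresholds are configurable and the >= is
inclusive).

The unit of analysis defaults to the sampled node.  Covariates are
case-level, so within-case rows are correlated; no clustering adjustment
is applied and downstream reports carry a caveat to that effect.

Maximum-likelihood fitting is delegated to statsmodels; a hand-rolled
Firth (Jeffreys-prior penalized) fit is provided for separated data,
where the ML estimate diverges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .classify import IntervalLabel, WORSENING, chronological_order, case_rank_map

logger = logging.getLogger(__name__)

WALD_ML = "wald_ml"
FIRTH = "firth"

DEFAULT_MIDAZOLAM_MG = 10.0
DEFAULT_FENTANYL_UG = 300.0

#: model covariates in report order
MODEL_COVARIATES = ("attending_assist", "cytopathologist", "high_midazolam", "high_fentanyl")

# |log-odds| beyond this is treated as a diverged ML estimate
_DIVERGENCE_BOUND = 12.0


@dataclass(frozen=True)
class DoseThresholds:
    midazolam_mg: float = DEFAULT_MIDAZOLAM_MG
    fentanyl_ug: float = DEFAULT_FENTANYL_UG


@dataclass(frozen=True)
class RegressionResult:
    """Per-covariate result of the interval-contrast logistic model."""

    covariate: str
    estimate: float          # log-odds
    odds_ratio: float
    ci_low: float            # 95% CI on the odds-ratio scale
    ci_high: float
    p_value: float           # 2-tailed Wald
    method: str              # wald_ml | firth
    n_rows: int
    separation_flag: bool

    def to_dict(self) -> dict:
        return asdict(self)


def build_analysis_frame(
    records: pd.DataFrame,
    intervals: Sequence[IntervalLabel],
    thresholds: DoseThresholds = DoseThresholds(),
    unit: str = "node",
) -> pd.DataFrame:
    """Assemble the regression frame from cohort records and intervals.

    One row per sampled node (``unit="node"``, default) or per case
    (``unit="case"``).  ``outcome_nonproficient`` is 1 iff the row's
    case lies in a worsening interval; doses are dichotomised at the
    configured thresholds (inclusive >=).  Rows with a missing model
    covariate are dropped complete-case; the count is logged and stored
    in ``frame.attrs["n_dropped"]``.
    """
    if unit not in ("node", "case"):
        raise ValueError(f"unit must be 'node' or 'case', got {unit!r}")
    ordered = chronological_order(records)
    ranks = case_rank_map(records)
    case_rank = ordered["case_id"].map(ranks)

    covered = np.zeros(len(ordered), dtype=bool)
    worsening = np.zeros(len(ordered), dtype=bool)
    for iv in intervals:
        in_iv = (case_rank >= iv.start_case) & (case_rank <= iv.end_case)
        covered |= in_iv
        if iv.label == WORSENING:
            worsening |= in_iv
    if not covered.all():
        missing = sorted(case_rank[~covered].unique())
        raise ValueError(f"cases with chronological rank {missing} are not covered by any interval")

    frame = pd.DataFrame(
        {
            "unit_id": ordered["case_id"],
            "outcome_nonproficient": worsening.astype(int),
            "attending_assist": pd.to_numeric(ordered["attending_assist"], errors="coerce"),
            "cytopathologist": pd.to_numeric(ordered["cytopathologist"], errors="coerce"),
            "high_midazolam": (
                pd.to_numeric(ordered["midazolam_mg"], errors="coerce")
                >= thresholds.midazolam_mg
            ).where(ordered["midazolam_mg"].notna()),
            "high_fentanyl": (
                pd.to_numeric(ordered["fentanyl_ug"], errors="coerce")
                >= thresholds.fentanyl_ug
            ).where(ordered["fentanyl_ug"].notna()),
        }
    )
    if unit == "case":
        frame = frame.groupby("unit_id", sort=False, as_index=False).first()

    n_before = len(frame)
    frame = frame.dropna(subset=list(MODEL_COVARIATES)).reset_index(drop=True)
    n_dropped = n_before - len(frame)
    if n_dropped:
        logger.info("dropped %d rows with missing model covariates", n_dropped)
    for col in MODEL_COVARIATES:
        frame[col] = frame[col].astype(int)
    frame.attrs["n_dropped"] = n_dropped
    frame.attrs["unit"] = unit
    return frame


def _check_design(X: pd.DataFrame) -> None:
    """Reject collinear covariate pairs and constant columns, by name."""
    for col in X.columns:
        if X[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} is constant in the frame")
    for a, b in combinations(X.columns, 2):
        r = np.corrcoef(X[a], X[b])[0, 1]
        if abs(r) > 1.0 - 1e-10:
            raise ValueError(f"covariates {a!r} and {b!r} are collinear")
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ValueError("design matrix is rank-deficient")


def _perfect_prediction_flags(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> dict:
    """Per-covariate flag: a binary covariate level perfectly predicts y."""
    flags = {}
    for j, name in enumerate(names):
        col = X[:, j]
        flag = False
        levels = np.unique(col)
        if len(levels) <= 2:
            for lev in levels:
                ys = y[col == lev]
                if len(ys) and (ys.min() == ys.max()):
                    flag = True
        flags[name] = flag
    return flags


def _firth_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Jeffreys-prior penalized logistic fit (Firth correction).

    Newton iterations on the penalized score
    ``U*(b) = X' (y - p + h (1/2 - p))`` where ``h`` is the diagonal of
    the weighted hat matrix; step-halving on the penalized log-likelihood.
    Returns (coefficients, standard errors from the observed penalized
    information).
    """
    n, k = X.shape
    beta = np.zeros(k)

    def penalized_ll(b):
        eta = X @ b
        p = expit(eta)
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        W = p * (1.0 - p)
        info = X.T @ (X * W[:, None])
        sign, logdet = np.linalg.slogdet(info)
        return ll + 0.5 * logdet

    ll_old = penalized_ll(beta)
    for _ in range(max_iter):
        p = expit(X @ beta)
        W = p * (1.0 - p)
        XW = X * W[:, None]
        info = X.T @ XW
        info_inv = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        U = X.T @ (y - p + h * (0.5 - p))
        delta = info_inv @ U
        step = 1.0
        for _ in range(25):  # step-halve until the penalized LL improves
            cand = beta + step * delta
            ll_new = penalized_ll(cand)
            if ll_new >= ll_old - 1e-12:
                break
            step *= 0.5
        beta = beta + step * delta
        if np.max(np.abs(step * delta)) < tol:
            ll_old = ll_new
            break
        ll_old = ll_new

    p = expit(X @ beta)
    W = p * (1.0 - p)
    info = X.T @ (X * W[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    return beta, se


def fit_logistic(
    frame: pd.DataFrame,
    covariates: Optional[Sequence[str]] = None,
    outcome: str = "outcome_nonproficient",
    method: str = WALD_ML,
) -> list[RegressionResult]:
    """Fit the multivariable logistic model and report per-covariate results.

    All covariates enter jointly with an intercept.  Confidence
    intervals are Wald intervals on the log-odds scale, exponentiated;
    p-values are 2-tailed Wald.  With ``method="firth"`` the
    Jeffreys-penalized fit is used, which yields finite estimates under
    separation; with ``method="wald_ml"`` separation is reported via
    ``separation_flag`` on the affected covariates.
    """
    if method not in (WALD_ML, FIRTH):
        raise ValueError(f"unknown method {method!r}")
    if covariates is None:
        covariates = [c for c in MODEL_COVARIATES if c in frame.columns]
    if not covariates:
        raise ValueError("frame has no model covariates")
    y = frame[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError(
            f"degenerate outcome: {outcome!r} is constant "
            f"({'all ' + str(int(y[0])) if len(y) else 'empty frame'})"
        )
    Xdf = frame[list(covariates)]
    _check_design(Xdf)
    X = np.column_stack([np.ones(len(Xdf)), Xdf.to_numpy(dtype=float)])
    names = list(covariates)
    n_rows = len(frame)

    perfect = _perfect_prediction_flags(X[:, 1:], y, names)

    method_used = method
    if method == FIRTH:
        beta, se = _firth_fit(X, y)
        diverged = {name: False for name in names}
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200, warn_convergence=False)
            beta, se = np.asarray(fit.params), np.asarray(fit.bse)
            if not np.all(np.isfinite(beta)) or not np.all(np.isfinite(se)):
                raise np.linalg.LinAlgError("non-finite ML estimates")
            diverged = {
                name: (abs(beta[j + 1]) > _DIVERGENCE_BOUND)
                or not fit.mle_retvals["converged"]
                for j, name in enumerate(names)
            }
        except (np.linalg.LinAlgError, PerfectSeparationError):
            # the ML estimate diverges under separation; report the
            # penalized fit instead, flagged
            logger.warning(
                "ML fit failed (separation); falling back to the Firth "
                "penalized fit"
            )
            beta, se = _firth_fit(X, y)
            method_used = FIRTH
            diverged = {name: True for name in names}

    z = stats.norm.ppf(0.975)
    results = []
    for j, name in enumerate(names):
        b, s_ = beta[j + 1], se[j + 1]
        pval = 2.0 * stats.norm.sf(abs(b) / s_) if s_ > 0 else np.nan
        results.append(
            RegressionResult(
                covariate=name,
                estimate=float(b),
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(b - z * s_)),
                ci_high=float(np.exp(b + z * s_)),
                p_value=float(pval),
                method=method_used,
                n_rows=n_rows,
                separation_flag=bool(perfect[name] or diverged[name]),
            )
        )
    return results


def results_frame(results: Sequence[RegressionResult]) -> pd.DataFrame:
    """Tabulate regression results, one row per covariate."""
    return pd.DataFrame([r.to_dict() for r in results])
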