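"""Cohort CSV schema and readers/writers.

The interchange format is a UTF-8 CSV with a header row, one row per
sampled node:

======================  =======================================================
column                  meaning
======================  =======================================================
operator_id             operator identifier (string)
case_id                 case/procedure identifier (string; unique per case)
node_order              1-based node order within the case
date_order              integer chronological rank of the attempt; alternatively
                        a ``date`` column with ISO-8601 dates may be supplied
                        and is converted to a rank (ties broken by case_id,
                        node_order)
outcome                 1/``F``/``failure`` = failure, 0/``S``/``success`` =
                        success (failure = specimen without lymphocytes,
                        granulomas or malignant cells)
attending_assist        1 if an additional attending assisted, else 0
cytopathologist         1 if an on-site cytopathologist was present, else 0
midazolam_mg            midazolam dose in mg (may be empty)
fentanyl_ug             fentanyl dose in ug (may be empty)
======================  =======================================================
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cusum import encode_outcomes

COHORT_COLUMNS = [
    "operator_id",
    "case_id",
    "node_order",
    "date_order",
    "outcome",
    "attending_assist",
    "cytopathologist",
    "midazolam_mg",
    "fentanyl_ug",
]

_REQUIRED = ["operator_id", "case_id", "node_order", "outcome"]


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; errors name the offending row."""
    df = pd.read_csv(path, dtype={"operator_id": str, "case_id": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if "date_order" not in df.columns:
        if "date" not in df.columns:
            raise ValueError(f"{path}: needs a date_order or ISO-8601 date column")
        dates = pd.to_datetime(df["date"], format="ISO8601")
        order = df.assign(_d=dates).sort_values(
            ["_d", "case_id", "node_order"], kind="mergesort"
        ).index
        rank = pd.Series(np.arange(1, len(df) + 1), index=order)
        df["date_order"] = rank.sort_index().to_numpy()
    try:
        df["outcome"] = encode_outcomes(df["outcome"])
    except ValueError as exc:
        # re-raise with the CSV row number (header = row 1)
        msg = str(exc)
        if "position" in msg:
            pos = int(msg.rsplit(" ", 1)[1])
            raise ValueError(f"{path}: row {pos + 2}: {msg}") from exc
        raise
    for col in ("midazolam_mg", "fentanyl_ug"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        else:
            df[col] = np.nan
    for col in ("attending_assist", "cytopathologist"):
        if col not in df.columns:
            df[col] = np.nan
    return df[COHORT_COLUMNS + [c for c in df.columns if c not in COHORT_COLUMNS]]


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table in the documented column order."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[COHORT_COLUMNS].to_csv(path, index=False)
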