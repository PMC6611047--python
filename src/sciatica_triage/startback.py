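"""STarT Back tool scoring and prognostic risk classification.

The 9-item screening questionnaire stratifies patients by risk of
persistent back-pain-related disability.  Items 1-8 are agree/disagree
statements scored 0/1; item 9 is a five-level bothersomeness rating scored
1 for "very much" or "extremely".  Items 5-9 form the psychological
subscale.  Classification: total score <= 3 is low risk; otherwise a
psychological subscore >= 4 is high risk; everything else is medium risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import STARTBACK_ITEM9_LEVELS

__all__ = [
    "StartBackError",
    "StartBackResult",
    "RISK_LEVELS",
    "PSYCH_ITEMS",
    "dichotomize_item9",
    "classify_risk",
    "score_startback",
    "score_cohort",
]

RISK_LEVELS = ("low", "medium", "high")

# Positional indices (1-based) of the five psychological-construct items in
# the published tool layout: fear, anxiety, catastrophising, depression and
# the overall bothersomeness rating.
PSYCH_ITEMS = (5, 6, 7, 8, 9)

# Item-9 responses scored as 1.
_ITEM9_POSITIVE = frozenset({"very much", "extremely"})


class StartBackError(ValueError):
    """Scoring refused (incomplete or invalid item set)."""


@dataclass(frozen=True)
class StartBackResult:
    total_score: int
    psych_score: int
    risk_class: str


def dichotomize_item9(response: str) -> int:
    """Score the five-level bothersomeness item (1 iff very much/extremely)."""
    if response not in STARTBACK_ITEM9_LEVELS:
        raise StartBackError(
            f"invalid item 9 response {response!r}; expected one of "
            f"{STARTBACK_ITEM9_LEVELS}"
        )
    return int(response in _ITEM9_POSITIVE)


def classify_risk(total_score: int, psych_score: int) -> str:
    """Map (total, psychological) scores to low/medium/high risk.

    The total-score rule takes precedence: a total of 3 or less is always
    low risk.  Because the psychological items are a subset of the total,
    psych >= 4 forces total >= 4, so the rules never truly conflict.
    """
    if total_score <= 3:
        return "low"
    if psych_score >= 4:
        return "high"
    return "medium"


def score_startback(
    items_1_to_8: Sequence[int | None], item_9: str | None
) -> StartBackResult:
    """Score one complete 9-item response set.

    Raises :class:`StartBackError` naming the first missing item; no
    imputation of partially completed tools is attempted.
    """
    if len(items_1_to_8) != 8:
        raise StartBackError(f"expected 8 binary items, got {len(items_1_to_8)}")
    vals = []
    for i, v in enumerate(items_1_to_8, start=1):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA:
            raise StartBackError(f"item {i} missing; scoring refused")
        if v not in (0, 1):
            raise StartBackError(f"item {i} must be 0/1, got {v!r}")
        vals.append(int(v))
    if item_9 is None or item_9 is pd.NA:
        raise StartBackError("item 9 missing; scoring refused")
    vals.append(dichotomize_item9(item_9))

    total = sum(vals)
    psych = sum(vals[i - 1] for i in PSYCH_ITEMS)
    return StartBackResult(total, psych, classify_risk(total, psych))


def score_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Append ``startback_total``, ``startback_psych`` and ``startback_risk``.

    Vectorised over the cohort table; rows with any missing item get NA in
    all three derived columns (complete-case scoring, consistent with
    :func:`score_startback` refusing partial tools).
    """
    item_cols = [f"startback_{i}" for i in range(1, 9)]
    items = df[item_cols].astype("Int64")
    item9 = df["startback_9"].astype("string")
    item9_score = item9.map(
        {lvl: dichotomize_item9(lvl) for lvl in STARTBACK_ITEM9_LEVELS}
    ).astype("Int64")
    bad = item9.notna() & item9_score.isna()
    if bad.any():
        row = df.index[bad.to_numpy()][0]
        raise StartBackError(f"invalid item 9 response in row {row}")

    complete = items.notna().all(axis=1) & item9_score.notna()
    total = items.sum(axis=1) + item9_score
    psych = items[[f"startback_{i}" for i in PSYCH_ITEMS if i <= 8]].sum(axis=1) + item9_score
    total = total.where(complete)
    psych = psych.where(complete)

    risk = pd.Series(pd.NA, index=df.index, dtype="string")
    t = total.to_numpy(dtype="float", na_value=np.nan)
    p = psych.to_numpy(dtype="float", na_value=np.nan)
    ok = ~np.isnan(t)
    risk_vals = np.where(t <= 3, "low", np.where(p >= 4, "high", "medium"))
    risk[ok] = risk_vals[ok]

    out = df.copy()
    out["startback_total"] = total.astype("Int64")
    out["startback_psych"] = psych.astype("Int64")
    out["startback_risk"] = risk
    return out
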