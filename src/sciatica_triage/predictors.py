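"""Eligibility filtering and derivation of the analysis variables.

Derives the four clinical characteristics used by the allocation
algorithm:

* impact      — pain interferes with work/home activities (work-interference
                NRS > 6 for those in work, else a 'yes' on the RMDQ
                jobs-around-the-house item),
* leg pain    — current leg pain intensity NRS > 6,
* sensory     — sensory deficit (reduced or lost sensation on pin-prick),
* below knee  — pain radiating below the knee,

plus the sciatica bothersomeness composite (sum of four 0-6 items) and the
five candidate-factor domain blocks used by the association analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import RMDQ_HOUSE_ITEM

__all__ = [
    "ClinicalCharacteristics",
    "ExclusionReport",
    "BlockSpec",
    "DEFAULT_BLOCKS",
    "CONFIDENCE_THRESHOLD",
    "filter_eligible",
    "derive_characteristics",
    "derive_cohort_characteristics",
    "bothersomeness_composite",
    "add_composite",
]

CONFIDENCE_THRESHOLD = 70  # minimum diagnostic confidence (%), inclusive

CHARACTERISTIC_COLUMNS = ("c_impact", "c_leg_pain", "c_sensory", "c_below_knee")


@dataclass(frozen=True)
class ClinicalCharacteristics:
    """The four binary referral characteristics; ``None`` = indeterminate."""

    c_impact: bool | None
    c_leg_pain: bool | None
    c_sensory: bool | None
    c_below_knee: bool | None

    @property
    def flags(self) -> tuple[bool | None, ...]:
        return (self.c_impact, self.c_leg_pain, self.c_sensory, self.c_below_knee)

    @property
    def determinate(self) -> bool:
        return all(f is not None for f in self.flags)

    @property
    def count(self) -> int:
        """Number of characteristics present; requires all four determinate."""
        if not self.determinate:
            raise ValueError("count undefined: indeterminate characteristic present")
        return sum(bool(f) for f in self.flags)

    @property
    def count_min(self) -> int:
        return sum(f is True for f in self.flags)

    @property
    def count_max(self) -> int:
        return sum(f is not False for f in self.flags)


@dataclass
class ExclusionReport:
    n_total: int
    n_retained: int
    n_below_threshold: int
    n_confidence_missing: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.n_total} records: {self.n_retained} eligible, "
            f"{self.n_below_threshold} below {CONFIDENCE_THRESHOLD}% confidence, "
            f"{self.n_confidence_missing} with confidence missing"
        )


@dataclass(frozen=True)
class BlockSpec:
    """One candidate-factor domain for the block-wise association analysis."""

    block_id: int
    label: str
    variables: tuple[str, ...]


# The five candidate-factor domains.  Variables name cohort columns
# (including derived ones: c_impact, both_composite).
DEFAULT_BLOCKS: tuple[BlockSpec, ...] = (
    BlockSpec(1, "impact of condition", ("c_impact",)),
    BlockSpec(
        2,
        "pain levels/symptoms",
        (
            "back_pain_usual",
            "leg_pain_usual",
            "back_pain_current",
            "leg_pain_current",
            "both_leg_pain",
            "both_paraesthesia",
            "both_weakness",
            "both_sitting",
            "both_composite",
        ),
    ),
    BlockSpec(3, "psychological perceptions", ("pain_self_efficacy", "illness_identity")),
    BlockSpec(
        4,
        "symptom behaviour and presentation",
        ("leg_worse_than_back", "tingling_numbness", "cough_sneeze_positive"),
    ),
    BlockSpec(
        5,
        "clinical examination findings",
        ("myotomal_weakness", "reflex_status", "pinprick_sensation", "neural_tension_positive"),
    ),
)


def _check_blocks(blocks: Sequence[BlockSpec]) -> None:
    seen: dict[str, int] = {}
    for b in blocks:
        for v in b.variables:
            if v in seen:
                raise ValueError(f"variable {v!r} appears in blocks {seen[v]} and {b.block_id}")
            seen[v] = b.block_id


_check_blocks(DEFAULT_BLOCKS)


def filter_eligible(df: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Retain records with diagnostic confidence >= 70% (inclusive bound).

    Records with missing confidence are excluded and counted separately.
    """
    conf = df["diagnostic_confidence"]
    missing = conf.isna()
    eligible = conf.notna() & (conf >= CONFIDENCE_THRESHOLD)
    report = ExclusionReport(
        n_total=len(df),
        n_retained=int(eligible.sum()),
        n_below_threshold=int((~eligible & ~missing).sum()),
        n_confidence_missing=int(missing.sum()),
    )
    return df.loc[eligible].copy(), report


def _impact_flag(
    in_work, work_interference, rmdq_house
) -> bool | None:
    """Impact characteristic for one patient; ``None`` if indeterminate.

    In work: work-interference NRS > 6; a patient in work with the NRS
    missing falls back to the RMDQ house item.  Not in work: the RMDQ item.
    """
    if in_work is True:
        if work_interference is not None:
            return bool(work_interference > 6)
        return None if rmdq_house is None else bool(rmdq_house)
    if in_work is False:
        return None if rmdq_house is None else bool(rmdq_house)
    return None


def derive_characteristics(record: pd.Series | dict) -> ClinicalCharacteristics:
    """Derive the four clinical characteristics for one patient record.

    Pure function of the record; a missing input makes the corresponding
    flag ``None`` (indeterminate), flagging the record for complete-case
    exclusion downstream.
    """
    def get(name):
        v = record.get(name) if isinstance(record, dict) else record.get(name, pd.NA)
        if v is None or v is pd.NA or (isinstance(v, float) and np.isnan(v)):
            return None
        return v

    leg = get("leg_pain_current")
    pin = get("pinprick_sensation")
    return ClinicalCharacteristics(
        c_impact=_impact_flag(
            None if get("in_work") is None else bool(get("in_work")),
            get("work_interference"),
            get(RMDQ_HOUSE_ITEM),
        ),
        c_leg_pain=None if leg is None else bool(leg > 6),
        c_sensory=None if pin is None else bool(pin in ("reduced", "loss")),
        c_below_knee=None if get("pain_below_knee") is None else bool(get("pain_below_knee")),
    )


def derive_cohort_characteristics(df: pd.DataFrame) -> pd.DataFrame:
    """Append c_impact, c_leg_pain, c_sensory, c_below_knee and char_count.

    Vectorised equivalent of :func:`derive_characteristics` row by row.
    ``char_count`` is NA whenever any flag is indeterminate.
    """
    out = df.copy()

    in_work = df["in_work"].astype("boolean")
    wi = df["work_interference"].astype("Int64")
    house = df[RMDQ_HOUSE_ITEM].astype("boolean")

    wi_flag = (wi > 6).astype("boolean")
    impact = pd.Series(pd.NA, index=df.index, dtype="boolean")
    use_wi = (in_work == True) & wi.notna()  # noqa: E712 - boolean-dtype mask
    impact[use_wi] = wi_flag[use_wi]
    use_house = (in_work.notna() & ~use_wi.fillna(False)) & house.notna()
    impact[use_house] = house[use_house]

    out["c_impact"] = impact
    out["c_leg_pain"] = (df["leg_pain_current"] > 6).astype("boolean").where(
        df["leg_pain_current"].notna()
    )
    out["c_sensory"] = (
        df["pinprick_sensation"].isin(["reduced", "loss"]).astype("boolean")
    ).where(df["pinprick_sensation"].notna())
    out["c_below_knee"] = df["pain_below_knee"].astype("boolean")

    flags = out[list(CHARACTERISTIC_COLUMNS)]
    count = flags.sum(axis=1).astype("Int64")
    out["char_count"] = count.where(flags.notna().all(axis=1))
    return out


def bothersomeness_composite(items: Sequence[int]) -> int:
    """Sum of the four sciatica bothersomeness items (each 0-6; total 0-24)."""
    names = ("leg pain", "paraesthesia", "weakness", "pain while sitting")
    if len(items) != 4:
        raise ValueError(f"expected 4 items, got {len(items)}")
    total = 0
    for name, v in zip(names, items):
        if not (0 <= int(v) <= 6):
            raise ValueError(f"bothersomeness item {name!r} out of range [0, 6]: {v!r}")
        total += int(v)
    return total


def add_composite(df: pd.DataFrame) -> pd.DataFrame:
    """Append ``both_composite`` (NA when any of the four items is missing)."""
    cols = ["both_leg_pain", "both_paraesthesia", "both_weakness", "both_sitting"]
    out = df.copy()
    total = df[cols].sum(axis=1).astype("Int64")
    out["both_composite"] = total.where(df[cols].notna().all(axis=1))
    return out
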