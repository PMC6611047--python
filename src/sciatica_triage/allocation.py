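"""The 3-group subgrouping algorithm and scenario evaluation.

Allocation rule (matched care pathways):

* group 1 — low prognostic risk, irrespective of clinical characteristics
  (brief self-management support);
* group 3 — high risk with >= 3 of the four clinical characteristics, or
  medium risk with all four (fast-track referral to imaging and spinal
  specialist opinion);
* group 2 — everyone else (physiotherapist-led care).

Scenario evaluation treats a fast-track rule as a predicate over (risk
class, characteristic count), builds the predicted-vs-observed-referral
confusion table, and reports sensitivity, specificity, predictive values
(Clopper-Pearson exact 95% CIs) and the fraction of the sample
fast-tracked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .association import TwoByTwoTable
from .predictors import CHARACTERISTIC_COLUMNS, ClinicalCharacteristics
from .startback import RISK_LEVELS

__all__ = [
    "AllocationError",
    "ScenarioRule",
    "SCENARIOS",
    "ClassificationMetrics",
    "allocate",
    "allocate_cohort",
    "evaluate_rule",
    "metrics_from_confusion",
    "group_summary",
]


class AllocationError(ValueError):
    """Allocation refused (indeterminate characteristic could change the group)."""


def _forced_group(risk_class: str, count_min: int, count_max: int) -> int | None:
    """Group if it is decided for every count in [count_min, count_max], else None."""
    if risk_class == "low":
        return 1
    if risk_class == "high":
        if count_min >= 3:
            return 3
        if count_max < 3:
            return 2
        return None
    if risk_class == "medium":
        if count_min == 4:
            return 3
        if count_max < 4:
            return 2
        return None
    raise ValueError(f"unknown risk class {risk_class!r}")


def allocate(risk_class: str, characteristics: ClinicalCharacteristics | int) -> int:
    """Allocate one patient to group 1, 2 or 3.

    ``characteristics`` may be a :class:`ClinicalCharacteristics` (possibly
    with indeterminate flags) or a plain count 0-4.  With indeterminate
    flags the allocation proceeds only when every possible count yields
    the same group (e.g. low risk is always group 1); otherwise
    :class:`AllocationError` is raised.
    """
    if risk_class not in RISK_LEVELS:
        raise ValueError(f"unknown risk class {risk_class!r}")
    if isinstance(characteristics, ClinicalCharacteristics):
        cmin, cmax = characteristics.count_min, characteristics.count_max
    else:
        count = int(characteristics)
        if not 0 <= count <= 4:
            raise ValueError(f"characteristic count must be in 0..4, got {count}")
        cmin = cmax = count
    group = _forced_group(risk_class, cmin, cmax)
    if group is None:
        raise AllocationError(
            f"indeterminate characteristics (count in [{cmin}, {cmax}]) "
            f"could change the group at {risk_class} risk"
        )
    return group


def allocate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Append a ``group`` column (Int64; NA where allocation is refused).

    Requires ``startback_risk`` and the four characteristic flags (from
    :func:`sciatica_triage.predictors.derive_cohort_characteristics`).
    """
    flags = df[list(CHARACTERISTIC_COLUMNS)]
    cmin = flags.fillna(False).sum(axis=1).to_numpy(dtype=float)
    cmax = flags.fillna(True).sum(axis=1).to_numpy(dtype=float)
    risk = df["startback_risk"].astype("string")

    group = np.full(len(df), np.nan)
    low = (risk == "low").to_numpy(dtype=bool)
    med = (risk == "medium").to_numpy(dtype=bool)
    high = (risk == "high").to_numpy(dtype=bool)
    group[low] = 1
    group[high & (cmin >= 3)] = 3
    group[high & (cmax < 3)] = 2
    group[med & (cmin == 4)] = 3
    group[med & (cmax < 4)] = 2

    out = df.copy()
    out["group"] = pd.Series(group, index=df.index).astype("Int64")
    return out


@dataclass(frozen=True)
class ScenarioRule:
    """A fast-track predicate over (risk class, characteristic count).

    ``min_count`` applies to every risk class; ``per_class_min`` maps a
    risk class to the minimum count required for that class (classes not
    listed are never fast-tracked).  With ``low_risk_excluded`` low-risk
    patients are never fast-tracked but remain in all denominators.
    """

    rule_id: str
    min_count: int | None = None
    per_class_min: dict[str, int] | None = None
    low_risk_excluded: bool = False

    def __post_init__(self):
        if (self.min_count is None) == (self.per_class_min is None):
            raise ValueError("specify exactly one of min_count / per_class_min")

    def fast_track(self, risk_class: str, count: int) -> bool:
        if risk_class not in RISK_LEVELS:
            raise ValueError(f"unknown risk class {risk_class!r}")
        if not 0 <= count <= 4:
            raise ValueError(f"characteristic count must be in 0..4, got {count}")
        if self.low_risk_excluded and risk_class == "low":
            return False
        if self.min_count is not None:
            return count >= self.min_count
        need = self.per_class_min.get(risk_class)
        return need is not None and count >= need


# the three published candidate rules
SCENARIOS: tuple[ScenarioRule, ...] = (
    ScenarioRule("scenario_1", min_count=3),
    ScenarioRule("scenario_2", min_count=4),
    ScenarioRule(
        "scenario_3",
        per_class_min={"high": 3, "medium": 4},
        low_risk_excluded=True,
    ),
)


def _exact_ci(k: int, n: int) -> tuple[float, float]:
    # Clopper-Pearson: reproduces the reference tables' printed intervals
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    return float(lo) * 100, float(hi) * 100


@dataclass
class ClassificationMetrics:
    """Diagnostic metrics (percent scale) for a fast-track rule."""

    confusion: TwoByTwoTable  # a=TP, b=FP, c=FN, d=TN
    n: int = field(init=False)
    sensitivity: float | None = field(init=False)
    specificity: float | None = field(init=False)
    ppv: float | None = field(init=False)
    npv: float | None = field(init=False)
    fraction_fast_tracked: float = field(init=False)
    sensitivity_ci: tuple[float, float] | None = field(init=False, default=None)
    specificity_ci: tuple[float, float] | None = field(init=False, default=None)
    ppv_ci: tuple[float, float] | None = field(init=False, default=None)
    npv_ci: tuple[float, float] | None = field(init=False, default=None)

    def __post_init__(self):
        tp, fp, fn, tn = (
            self.confusion.a,
            self.confusion.b,
            self.confusion.c,
            self.confusion.d,
        )
        self.n = tp + fp + fn + tn
        if self.n == 0:
            raise ValueError("empty confusion table")

        def ratio(k, d):
            return None if d == 0 else 100 * k / d

        self.sensitivity = ratio(tp, tp + fn)
        self.specificity = ratio(tn, fp + tn)
        self.ppv = ratio(tp, tp + fp)
        self.npv = ratio(tn, fn + tn)
        self.fraction_fast_tracked = 100 * (tp + fp) / self.n
        if self.sensitivity is not None:
            self.sensitivity_ci = _exact_ci(tp, tp + fn)
        if self.specificity is not None:
            self.specificity_ci = _exact_ci(tn, fp + tn)
        if self.ppv is not None:
            self.ppv_ci = _exact_ci(tp, tp + fp)
        if self.npv is not None:
            self.npv_ci = _exact_ci(tn, fn + tn)

    def to_dict(self) -> dict:
        c = self.confusion
        return {
            "confusion": {"tp": c.a, "fp": c.b, "fn": c.c, "tn": c.d},
            "n": self.n,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": self.sensitivity_ci,
            "specificity": self.specificity,
            "specificity_ci": self.specificity_ci,
            "ppv": self.ppv,
            "ppv_ci": self.ppv_ci,
            "npv": self.npv,
            "npv_ci": self.npv_ci,
            "fraction_fast_tracked": self.fraction_fast_tracked,
        }

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        def fmt(v, ci):
            if v is None:
                return "undefined"
            return f"{v:.0f}% ({ci[0]:.0f}-{ci[1]:.0f})"

        return (
            f"sensitivity {fmt(self.sensitivity, self.sensitivity_ci)}, "
            f"specificity {fmt(self.specificity, self.specificity_ci)}, "
            f"PPV {fmt(self.ppv, self.ppv_ci)}, NPV {fmt(self.npv, self.npv_ci)}, "
            f"fast-tracked {self.fraction_fast_tracked:.0f}%"
        )


def metrics_from_confusion(table: TwoByTwoTable) -> ClassificationMetrics:
    """Classification metrics from an existing TP/FP/FN/TN table."""
    return ClassificationMetrics(table)


def evaluate_rule(rule: ScenarioRule, df: pd.DataFrame) -> ClassificationMetrics:
    """Evaluate a fast-track rule against observed referral.

    Complete-case on the rule inputs (risk class, characteristic count)
    and the outcome; excluded rows are simply not analysed.  Low-risk
    patients under a ``low_risk_excluded`` rule stay in the denominators.
    """
    needed = ["startback_risk", "char_count", "referred"]
    data = df.dropna(subset=needed)
    risk = data["startback_risk"].astype(str).to_numpy()
    count = data["char_count"].to_numpy(dtype=int)
    referred = data["referred"].to_numpy(dtype=bool)
    fast = np.array(
        [rule.fast_track(r, c) for r, c in zip(risk, count)], dtype=bool
    )
    table = TwoByTwoTable(
        a=int((fast & referred).sum()),
        b=int((fast & ~referred).sum()),
        c=int((~fast & referred).sum()),
        d=int((~fast & ~referred).sum()),
    )
    return ClassificationMetrics(table)


# Table-4-style descriptive variables: (column, kind)
SUMMARY_VARIABLES: tuple[tuple[str, str], ...] = (
    ("age", "continuous"),
    ("sex", "categorical"),
    ("back_pain_current", "continuous"),
    ("leg_pain_current", "continuous"),
    ("leg_worse_than_back", "binary"),
    ("pain_below_knee", "binary"),
    ("duration_category", "categorical"),
    ("pain_self_efficacy", "continuous"),
    ("myotomal_weakness", "binary"),
    ("c_sensory", "binary"),
    ("neural_tension_positive", "binary"),
)


def group_summary(
    df: pd.DataFrame,
    variables: tuple[tuple[str, str], ...] = SUMMARY_VARIABLES,
) -> pd.DataFrame:
    """Per-group descriptive table (mean/SD or count/percentage).

    Complete-case per variable; empty groups appear with n = 0 and blank
    statistics.  Returns a tidy frame with one row per (group, variable,
    level) and columns ``statistic`` / ``value``.
    """
    rows = []
    for g in (1, 2, 3):
        sub = df[df["group"] == g]
        rows.append({"group": g, "variable": "n", "level": "", "statistic": "count",
                     "value": float(len(sub))})
        for var, kind in variables:
            if var not in df.columns:
                continue
            col = sub[var].dropna()
            if len(col) == 0:
                rows.append({"group": g, "variable": var, "level": "",
                             "statistic": "mean" if kind == "continuous" else "percent",
                             "value": np.nan})
                continue
            if kind == "continuous":
                vals = col.to_numpy(dtype=float)
                rows.append({"group": g, "variable": var, "level": "",
                             "statistic": "mean", "value": float(vals.mean())})
                rows.append({"group": g, "variable": var, "level": "",
                             "statistic": "sd",
                             "value": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan})
            elif kind == "binary":
                k = int(col.astype(bool).sum())
                rows.append({"group": g, "variable": var, "level": "yes",
                             "statistic": "count", "value": float(k)})
                rows.append({"group": g, "variable": var, "level": "yes",
                             "statistic": "percent", "value": 100 * k / len(col)})
            else:
                for level, k in col.astype(str).value_counts().items():
                    rows.append({"group": g, "variable": var, "level": level,
                                 "statistic": "count", "value": float(k)})
                    rows.append({"group": g, "variable": var, "level": level,
                                 "statistic": "percent", "value": 100 * k / len(col)})
    return pd.DataFrame(rows)
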