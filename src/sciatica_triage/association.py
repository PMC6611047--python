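"""Factors associated with specialist referral.

Implements the three-stage, block-wise logistic-regression procedure used
to identify referral-associated factors:

1. univariable logistic regression of referral on every candidate factor
   within each of the five domains (blocks);
2. a collinearity screen within each block (type-appropriate pairwise
   correlations, one variable of each pair with |r| > 0.7 dropped, then
   variance inflation factors with VIF > 5 flagged), followed by a
   within-block multivariable model whose significant terms progress;
3. an overall multivariable model over the block survivors with backward
   elimination of the least significant variable until all remaining
   terms have p < 0.05.

Also provides classical 2x2 odds-ratio analysis with Wald confidence
intervals, matching a univariable logistic fit exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, spearmanr
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .predictors import BlockSpec, DEFAULT_BLOCKS

__all__ = [
    "TwoByTwoTable",
    "OddsRatioResult",
    "SelectionTrace",
    "odds_ratio_2x2",
    "collinearity_screen",
    "blockwise_selection",
    "fit_logistic",
]

ALPHA = 0.05  # strict: p exactly 0.05 counts as not significant
CORRELATION_THRESHOLD = 0.7
VIF_THRESHOLD = 5.0

# ordinal columns get Spearman correlations in the collinearity screen
ORDINAL_COLUMNS = {"illness_identity", "duration_category", "reflex_status"}

# categorical factors entered as treatment-coded dummies (reference first)
FACTOR_LEVELS = {
    "pinprick_sensation": ("normal", "reduced", "loss"),
    "reflex_status": ("normal", "slightly reduced", "absent", "significantly reduced"),
    "duration_category": ("<6 weeks", "6 weeks-3 months", ">3 months"),
}


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposure x outcome counts: a/b exposed with/without outcome, c/d unexposed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    continuity_corrected: bool = False

    def __post_init__(self):
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI must bracket the odds ratio")


def odds_ratio_2x2(table: TwoByTwoTable, *, conf_level: float = 0.95) -> OddsRatioResult:
    """Unadjusted odds ratio with Wald CI from a 2x2 table.

    OR = (a*d)/(b*c); CI = exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).
    A zero cell (with all margins positive) triggers the Haldane-Anscombe
    correction of +0.5 to every cell, flagged in the result.  A zero row
    or column leaves the OR undefined and raises ``ValueError``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("odds ratio undefined: a margin of the 2x2 table is zero")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(0.5 + conf_level / 2)
    p = 2 * norm.sf(abs(log_or) / se)
    return OddsRatioResult(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p_value=float(p),
        continuity_corrected=corrected,
    )


# ----------------------------------------------------------------------
# design-matrix encoding
# ----------------------------------------------------------------------


def encode_terms(df: pd.DataFrame, variables: list[str]) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Encode model variables as a float design matrix (no constant).

    Categorical factors become treatment-coded dummy columns against their
    first level.  Returns (matrix, column names, variable -> column-index map).
    """
    mats, names, spans = [], [], {}
    for var in variables:
        col = df[var]
        if var in FACTOR_LEVELS:
            levels = FACTOR_LEVELS[var]
            idx = []
            for lvl in levels[1:]:
                mats.append((col.astype(str) == lvl).to_numpy(dtype=float))
                names.append(f"{var}[{lvl}]")
                idx.append(len(names) - 1)
            spans[var] = idx
        else:
            mats.append(col.to_numpy(dtype=float))
            names.append(var)
            spans[var] = [len(names) - 1]
    X = np.column_stack(mats) if mats else np.empty((len(df), 0))
    return X, names, spans


@dataclass
class LogisticFit:
    """Plain logistic-regression result on an encoded design."""

    params: np.ndarray  # includes intercept at position 0
    bse: np.ndarray
    term_names: list[str]
    llf: float
    converged: bool
    n: int

    def wald_p(self) -> np.ndarray:
        z = self.params / self.bse
        return 2 * norm.sf(np.abs(z))

    def odds_ratios(self, conf_level: float = 0.95) -> pd.DataFrame:
        z = norm.ppf(0.5 + conf_level / 2)
        with np.errstate(over="ignore"):  # wide CIs may overflow to inf
            lo = np.exp(self.params - z * self.bse)
            hi = np.exp(self.params + z * self.bse)
        return pd.DataFrame(
            {
                "odds_ratio": np.exp(self.params),
                "ci_low": lo,
                "ci_high": hi,
                "p_value": self.wald_p(),
            },
            index=["intercept"] + self.term_names,
        )


class SeparationError(RuntimeError):
    """Non-finite logistic estimate (complete or quasi-complete separation)."""


def fit_logistic(y: np.ndarray, X: np.ndarray, term_names: list[str] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic fit with an intercept.

    Raises :class:`SeparationError` when the estimate is non-finite or the
    optimiser fails to converge (separation or single-class outcome).
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise SeparationError("outcome has a single class")
    Xc = sm.add_constant(np.asarray(X, dtype=float), has_constant="add")
    try:
        with warnings.catch_warnings():
            # non-convergence is detected below and raised as SeparationError
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(str(exc)) from exc
    params, bse = np.asarray(res.params), np.asarray(res.bse)
    if (
        not res.mle_retvals.get("converged", True)
        or not np.all(np.isfinite(params))
        or not np.all(np.isfinite(bse))
        or np.max(np.abs(params)) > 50
    ):
        raise SeparationError("non-finite or diverging estimate")
    names = term_names or [f"x{i}" for i in range(1, Xc.shape[1])]
    return LogisticFit(params, bse, list(names), float(res.llf), True, len(y))


def _term_pvalue(fit: "LogisticFit", cols: list[int]) -> float:
    """Significance of one model variable from its Wald p-values.

    A categorical factor spanning several dummy columns counts as
    significant when *any* of its levels is (minimum Wald p): the factor
    is kept as a whole whenever one level shows an effect, mirroring how
    regression output with a significant level and non-significant
    siblings is read in practice.
    """
    p = fit.wald_p()
    return float(min(p[j + 1] for j in cols))  # +1 skips the intercept


# ----------------------------------------------------------------------
# collinearity screen
# ----------------------------------------------------------------------


def _pair_correlation(x: pd.Series, y: pd.Series, x_ordinal: bool, y_ordinal: bool) -> float:
    """Type-appropriate pairwise correlation on complete cases.

    Spearman when either variable is ordinal; otherwise Pearson (which is
    the point-biserial coefficient when one variable is binary 0/1).
    """
    ok = x.notna() & y.notna()
    xv, yv = x[ok].to_numpy(dtype=float), y[ok].to_numpy(dtype=float)
    if xv.std() == 0 or yv.std() == 0:
        return float("nan")
    if x_ordinal or y_ordinal:
        return float(spearmanr(xv, yv).statistic)
    return float(np.corrcoef(xv, yv)[0, 1])


def _ordinal_codes(df: pd.DataFrame, var: str) -> pd.Series:
    if var in FACTOR_LEVELS:
        mapping = {lvl: i for i, lvl in enumerate(FACTOR_LEVELS[var])}
        return df[var].astype(str).map(mapping).astype("Float64")
    return df[var].astype("Float64")


def collinearity_screen(
    df: pd.DataFrame,
    variables: list[str],
    *,
    forced: list[str] | None = None,
    threshold: float = CORRELATION_THRESHOLD,
    vif_threshold: float = VIF_THRESHOLD,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Drop collinear variables within a block.

    For every pair with |r| > ``threshold`` one variable is dropped (never
    a ``forced`` survivor, which mirrors a clinical override; otherwise
    the later variable in block order).  Survivors with VIF >
    ``vif_threshold`` are then dropped as well.  Returns
    ``(retained, [(variable, reason), ...])``.
    """
    forced = list(forced or [])
    dropped: list[tuple[str, str]] = []
    coded = {v: _ordinal_codes(df, v) for v in variables}

    active = []
    for v in variables:
        vals = coded[v].dropna()
        if len(vals) == 0 or float(vals.std()) == 0.0:
            dropped.append((v, "zero variance"))
        else:
            active.append(v)

    # rank by protectedness then block order so forced survivors win ties
    def _priority(v: str) -> tuple[int, int]:
        return (0 if v in forced else 1, variables.index(v))

    i = 0
    while i < len(active):
        j = i + 1
        while j < len(active):
            vi, vj = active[i], active[j]
            r = _pair_correlation(
                coded[vi], coded[vj], vi in ORDINAL_COLUMNS, vj in ORDINAL_COLUMNS
            )
            if abs(r) > threshold:
                loser = max(vi, vj, key=_priority)
                dropped.append((loser, f"|r|={abs(r):.3f}>{threshold} with "
                                       f"{vi if loser == vj else vj}"))
                if loser == vi:
                    active.pop(i)
                    j = i + 1
                    continue
                active.pop(j)
                continue
            j += 1
        i += 1

    if len(active) >= 2:
        sub = pd.DataFrame({v: coded[v] for v in active}).dropna()
        X = sm.add_constant(sub.to_numpy(dtype=float), has_constant="add")
        vifs = {v: variance_inflation_factor(X, k + 1) for k, v in enumerate(active)}
        for v, vif in vifs.items():
            if vif > vif_threshold and v not in forced:
                active.remove(v)
                dropped.append((v, f"VIF={vif:.2f}>{vif_threshold}"))
    return active, dropped


# ----------------------------------------------------------------------
# block-wise selection
# ----------------------------------------------------------------------


@dataclass
class SelectionTrace:
    """Full audit trail of the three-stage selection procedure."""

    univariable: dict[str, pd.DataFrame] = field(default_factory=dict)
    univariable_p: dict[str, float] = field(default_factory=dict)
    collinearity_dropped: list[tuple[int, str, str]] = field(default_factory=list)
    block_survivors: dict[int, list[str]] = field(default_factory=dict)
    stage3_entered: list[str] = field(default_factory=list)
    stage3_dropped: list[tuple[str, float]] = field(default_factory=list)
    separation_flagged: list[tuple[str, str]] = field(default_factory=list)
    final_model: pd.DataFrame | None = None
    final_variables: list[str] = field(default_factory=list)
    disposition: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "univariable_p": self.univariable_p,
            "collinearity_dropped": [
                {"block": b, "variable": v, "reason": r}
                for b, v, r in self.collinearity_dropped
            ],
            "block_survivors": {str(k): v for k, v in self.block_survivors.items()},
            "stage3_entered": self.stage3_entered,
            "stage3_dropped": [{"variable": v, "p": p} for v, p in self.stage3_dropped],
            "separation_flagged": [
                {"variable": v, "reason": r} for v, r in self.separation_flagged
            ],
            "final_variables": self.final_variables,
            "final_model": None
            if self.final_model is None
            else self.final_model.round(6).to_dict("index"),
            "disposition": self.disposition,
        }

    def report(self) -> str:
        """Human-readable selection report (association-table layout)."""
        lines = ["Block-wise selection of factors associated with referral", ""]
        for var, tab in self.univariable.items():
            row = tab.iloc[1]
            lines.append(
                f"  {var:28s} OR {row.odds_ratio:5.2f} "
                f"({row.ci_low:.2f}, {row.ci_high:.2f})  p={self.univariable_p[var]:.4f}"
                f"  -> {self.disposition[var]}"
            )
        if self.final_model is not None:
            lines += ["", "Final multivariable model:"]
            for name, row in self.final_model.iloc[1:].iterrows():
                lines.append(
                    f"  {name:28s} OR {row.odds_ratio:5.2f} "
                    f"({row.ci_low:.2f}, {row.ci_high:.2f})  p={row.p_value:.4f}"
                )
        return "\n".join(lines)


def _complete_cases(df: pd.DataFrame, variables: list[str], outcome: str) -> pd.DataFrame:
    return df.dropna(subset=[*variables, outcome])


def blockwise_selection(
    df: pd.DataFrame,
    blocks: tuple[BlockSpec, ...] = DEFAULT_BLOCKS,
    *,
    outcome: str = "referred",
    forced_survivors: dict[int, list[str]] | None = None,
    alpha: float = ALPHA,
) -> SelectionTrace:
    """Run the three-stage block-wise selection; deterministic given data.

    ``forced_survivors`` maps block id to variables that must survive the
    collinearity screen (the clinical-override mechanism by which a single
    representative of a highly correlated block is chosen).
    """
    if forced_survivors is None:
        forced_survivors = {2: ["leg_pain_current"]}
    trace = SelectionTrace(block_survivors={})
    stage3_candidates: list[str] = []

    for block in blocks:
        # stage 1: univariable fits
        for var in block.variables:
            sub = _complete_cases(df, [var], outcome)
            y = sub[outcome].to_numpy(dtype=float)
            X, names, spans = encode_terms(sub, [var])
            try:
                fit = fit_logistic(y, X, names)
                p = _term_pvalue(fit, spans[var])
            except SeparationError as exc:
                trace.separation_flagged.append((var, str(exc)))
                trace.disposition[var] = "flagged: separation in univariable fit"
                continue
            trace.univariable[var] = fit.odds_ratios()
            trace.univariable_p[var] = float(p)
            trace.disposition[var] = "univariable only"

        # stage 2: collinearity screen, then within-block multivariable
        candidates = [v for v in block.variables if v in trace.univariable]
        retained, dropped = collinearity_screen(
            df, candidates, forced=forced_survivors.get(block.block_id)
        )
        for v, reason in dropped:
            trace.collinearity_dropped.append((block.block_id, v, reason))
            trace.disposition[v] = f"dropped in collinearity screen ({reason})"

        survivors: list[str] = []
        if len(retained) == 1:
            # single-variable block: stage 2 is the univariable result
            var = retained[0]
            if trace.univariable_p[var] < alpha:
                survivors.append(var)
            else:
                trace.disposition[var] = (
                    f"not significant (p={trace.univariable_p[var]:.3f})"
                )
        elif retained:
            sub = _complete_cases(df, retained, outcome)
            y = sub[outcome].to_numpy(dtype=float)
            X, names, spans = encode_terms(sub, retained)
            try:
                block_fit = fit_logistic(y, X, names)
                for var in retained:
                    p = _term_pvalue(block_fit, spans[var])
                    if p < alpha:
                        survivors.append(var)
                    else:
                        trace.disposition[var] = (
                            f"not significant within block {block.block_id} (p={p:.3f})"
                        )
            except SeparationError as exc:
                for var in retained:
                    trace.separation_flagged.append((var, str(exc)))
                    trace.disposition[var] = "flagged: separation in block model"
        trace.block_survivors[block.block_id] = survivors
        stage3_candidates.extend(survivors)

    # stage 3: overall model with backward elimination at alpha
    trace.stage3_entered = list(stage3_candidates)
    current = list(stage3_candidates)
    final_fit = None
    while current:
        sub = _complete_cases(df, current, outcome)
        y = sub[outcome].to_numpy(dtype=float)
        X, names, spans = encode_terms(sub, current)
        try:
            final_fit = fit_logistic(y, X, names)
        except SeparationError as exc:
            # drop the variable causing the failure conservatively: flag all
            trace.separation_flagged.append((";".join(current), str(exc)))
            break
        pvals = {var: _term_pvalue(final_fit, spans[var]) for var in current}
        worst, worst_p = max(pvals.items(), key=lambda kv: kv[1])
        if worst_p >= alpha:
            current.remove(worst)
            trace.stage3_dropped.append((worst, float(worst_p)))
            trace.disposition[worst] = f"dropped from overall model (p={worst_p:.3f})"
            final_fit = None
        else:
            for var in current:
                trace.disposition[var] = "retained in final model"
            break

    if final_fit is not None and current:
        trace.final_model = final_fit.odds_ratios()
        trace.final_variables = list(current)
    return trace
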