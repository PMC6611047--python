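"""Internal validation of the referral model.

Discrimination is summarised by the area under the ROC curve (the
probability that a randomly chosen referred patient scores higher than a
randomly chosen non-referred patient, ties counted 1/2), with a DeLong
95% CI.  Optimism in apparent performance is estimated by the enhanced
bootstrap: refit the model in each resample, compare its AUC on the
resample (training performance) with its AUC on the original cohort (test
performance), and subtract the mean difference from the apparent AUC.
Calibration is summarised by the calibration slope, the coefficient from
a logistic regression of the outcome on the model's linear predictor
(identically 1 on the development data for a maximum-likelihood fit).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from .association import SeparationError, encode_terms, fit_logistic

__all__ = [
    "ValidationReport",
    "auc",
    "delong_ci",
    "calibration_slope",
    "bootstrap_optimism",
]

# the final referral model: impact characteristic, current leg pain
# intensity (continuous NRS, per-unit OR) and pin-prick sensation
# (3-level factor, "normal" reference)
DEFAULT_MODEL_VARIABLES = ["c_impact", "leg_pain_current", "pinprick_sensation"]


def _check_scores_outcomes(scores, outcomes):
    scores = np.asarray(scores, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if scores.shape != outcomes.shape:
        raise ValueError("scores and outcomes must have the same length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not set(np.unique(outcomes)) <= {0.0, 1.0}:
        raise ValueError("outcomes must be binary 0/1")
    if outcomes.min() == outcomes.max():
        raise ValueError("AUC undefined: outcome has a single class")
    return scores, outcomes


def auc(scores, outcomes) -> float:
    """Concordance-probability AUC (ties counted 0.5)."""
    scores, outcomes = _check_scores_outcomes(scores, outcomes)
    return float(roc_auc_score(outcomes, scores))


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks as used by the DeLong covariance estimator."""
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1)
        i = j
    out = np.empty(n)
    out[order] = t + 1
    return out


def delong_ci(scores, outcomes, conf_level: float = 0.95) -> tuple[float, float, float]:
    """AUC with DeLong variance-based CI: (auc, lower, upper)."""
    scores, outcomes = _check_scores_outcomes(scores, outcomes)
    pos = scores[outcomes == 1]
    neg = scores[outcomes == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    a = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (tz[:m] - tx) / n  # structural components over cases
    v10 = 1.0 - (tz[m:] - ty) / m  # over non-cases
    var = np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n
    se = float(np.sqrt(var))
    z = norm.ppf(0.5 + conf_level / 2)
    return float(a), max(0.0, float(a - z * se)), min(1.0, float(a + z * se))


def calibration_slope(linear_predictor, outcomes, conf_level: float = 0.95):
    """Slope (with Wald CI) of a logistic refit of outcome on the linear predictor.

    The predictor must be on the log-odds scale.  Returns
    ``(slope, ci_low, ci_high)``.  A maximum-likelihood model evaluated on
    its own development data has slope exactly 1.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if lp.std() == 0:
        raise ValueError("calibration slope undefined: zero-variance predictor")
    fit = fit_logistic(y, lp[:, None], ["linear_predictor"])
    z = norm.ppf(0.5 + conf_level / 2)
    slope, se = float(fit.params[1]), float(fit.bse[1])
    return slope, slope - z * se, slope + z * se


@dataclass
class ValidationReport:
    """Apparent and optimism-corrected discrimination plus calibration."""

    apparent_auc: float
    apparent_auc_ci: tuple[float, float]
    bootstrap_mean_auc: float
    bootstrap_mean_auc_ci: tuple[float, float]
    optimism: float
    corrected_auc: float
    calibration_slope: float
    calibration_slope_ci: tuple[float, float]
    n_replicates: int
    n_discarded: int
    seed: int
    negative_optimism: bool = dc_field(init=False)

    def __post_init__(self):
        self.negative_optimism = self.optimism < 0

    def to_dict(self) -> dict:
        return {
            "apparent_auc": self.apparent_auc,
            "apparent_auc_ci": list(self.apparent_auc_ci),
            "bootstrap_mean_auc": self.bootstrap_mean_auc,
            "bootstrap_mean_auc_ci": list(self.bootstrap_mean_auc_ci),
            "optimism": self.optimism,
            "corrected_auc": self.corrected_auc,
            "calibration_slope": self.calibration_slope,
            "calibration_slope_ci": list(self.calibration_slope_ci),
            "n_replicates": self.n_replicates,
            "n_discarded": self.n_discarded,
            "seed": self.seed,
            "negative_optimism": self.negative_optimism,
        }

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.apparent_auc_ci
        blo, bhi = self.bootstrap_mean_auc_ci
        clo, chi = self.calibration_slope_ci
        return (
            f"apparent AUC {self.apparent_auc:.3f} ({lo:.3f}, {hi:.3f}); "
            f"bootstrap mean {self.bootstrap_mean_auc:.3f} ({blo:.3f}, {bhi:.3f}); "
            f"optimism {self.optimism:.3f}; corrected AUC {self.corrected_auc:.3f}; "
            f"calibration slope {self.calibration_slope:.2f} ({clo:.2f}, {chi:.2f})"
        )


def bootstrap_optimism(
    df: pd.DataFrame,
    model_variables: list[str] | None = None,
    *,
    outcome: str = "referred",
    n_replicates: int = 500,
    seed: int = 0,
) -> ValidationReport:
    """Enhanced-bootstrap internal validation of a fixed model specification.

    Each replicate resamples patients with replacement, refits the model,
    and contributes (training AUC - test-on-original AUC) to the optimism
    estimate; ``corrected = apparent - mean(optimism)``.  Replicates with
    a single-class outcome or separation are discarded and counted; a
    warning is raised if more than 10% are discarded.
    """
    model_variables = model_variables or DEFAULT_MODEL_VARIABLES
    data = df.dropna(subset=[*model_variables, outcome]).reset_index(drop=True)
    y = data[outcome].to_numpy(dtype=float)
    X, names, _ = encode_terms(data, model_variables)

    apparent_fit = fit_logistic(y, X, names)
    lp = apparent_fit.params[0] + X @ apparent_fit.params[1:]
    apparent, lo, hi = delong_ci(lp, y)
    slope, slo, shi = calibration_slope(lp, y)

    rng = np.random.default_rng(seed)
    n = len(data)
    train_aucs, optimisms = [], []
    n_discarded = 0
    for _ in range(n_replicates):
        idx = rng.integers(0, n, size=n)
        yb, Xb = y[idx], X[idx]
        try:
            fit = fit_logistic(yb, Xb, names)
        except SeparationError:
            n_discarded += 1
            continue
        lp_train = fit.params[0] + Xb @ fit.params[1:]
        lp_test = fit.params[0] + X @ fit.params[1:]
        train = auc(lp_train, yb)
        test = auc(lp_test, y)
        train_aucs.append(train)
        optimisms.append(train - test)

    if n_discarded > 0.1 * n_replicates:
        import warnings

        warnings.warn(
            f"{n_discarded}/{n_replicates} bootstrap replicates discarded",
            RuntimeWarning,
            stacklevel=2,
        )

    train_aucs = np.asarray(train_aucs)
    optimism = float(np.mean(optimisms))
    mean_boot = float(train_aucs.mean())
    se_boot = float(train_aucs.std(ddof=1) / np.sqrt(len(train_aucs)))
    return ValidationReport(
        apparent_auc=apparent,
        apparent_auc_ci=(lo, hi),
        bootstrap_mean_auc=mean_boot,
        bootstrap_mean_auc_ci=(mean_boot - 1.96 * se_boot, mean_boot + 1.96 * se_boot),
        optimism=optimism,
        corrected_auc=apparent - optimism,
        calibration_slope=slope,
        calibration_slope_ci=(slo, shi),
        n_replicates=n_replicates,
        n_discarded=n_discarded,
        seed=seed,
    )
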