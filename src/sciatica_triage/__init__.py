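"""Subgrouping primary-care sciatica patients for matched care pathways.

End-to-end machinery for developing and evaluating a 3-group triage
algorithm on (synthetic) primary-care sciatica cohorts: cohort
simulation, STarT Back risk scoring, derivation of the four clinical
referral characteristics, block-wise logistic selection of
referral-associated factors, bootstrap internal validation, and
scenario-based evaluation of fast-track rules.
"""

from .allocation import (
    SCENARIOS,
    ClassificationMetrics,
    ScenarioRule,
    allocate,
    allocate_cohort,
    evaluate_rule,
    group_summary,
    metrics_from_confusion,
)
from .association import (
    OddsRatioResult,
    SelectionTrace,
    TwoByTwoTable,
    blockwise_selection,
    collinearity_screen,
    odds_ratio_2x2,
)
from .cohort import (
    GeneratorConfig,
    MarginalTargets,
    ReferralModel,
    generate_cohort,
    generate_eligible_cohort,
)
from .predictors import (
    BlockSpec,
    ClinicalCharacteristics,
    DEFAULT_BLOCKS,
    add_composite,
    bothersomeness_composite,
    derive_characteristics,
    derive_cohort_characteristics,
    filter_eligible,
)
from .schema import LoadReport, SchemaError, read_cohort, write_cohort
from .startback import StartBackResult, classify_risk, score_cohort, score_startback
from .validation import (
    ValidationReport,
    auc,
    bootstrap_optimism,
    calibration_slope,
    delong_ci,
)

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]


def prepare_cohort(df):
    """Score and derive all analysis columns on a cohort table.

    Convenience pipeline: STarT Back scores, bothersomeness composite and
    the four clinical characteristics with their count.
    """
    df = score_cohort(df)
    df = add_composite(df)
    return derive_cohort_characteristics(df)
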