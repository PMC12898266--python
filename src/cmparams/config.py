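"""Shared constants: parameter names, attribute sets and default targets.

The 13 per-CM parameters are grouped into seven clinical attributes.
Column names in all tabular output are ``<CM><Parameter>`` (for example
``SBPValue1`` or ``A1cNumClust``).
"""

from __future__ import annotations

from typing import Dict, Mapping, Tuple

from .timeline import CM_NAMES, TargetSpec

#: Attribute -> parameter names, in reporting/entry order.  The order of
#: attributes (current metabolic control, chronicity, disease burden,
#: refractoriness, tendency to relapse, lability, temporal trends) is
#: also the default entry order for the set-wise stepwise model.
ATTRIBUTES: Dict[str, Tuple[str, ...]] = {
    "current_control": ("Value1",),
    "chronicity": ("FUDaysNotAtGoal", "NumNotAtGoal"),
    "disease_burden": ("AbnAUC", "TimeWtAvg"),
    "refractoriness": ("TimeNotAtGoal", "CtNotAtGoal", "MaxClustDays"),
    "relapse": ("NumClust",),
    "lability": ("CoeffVar", "MeanValDiff"),
    "trends": ("NetChange", "Lag3Dev"),
}

#: The 13 parameter names in attribute order.
PARAMETER_NAMES: Tuple[str, ...] = tuple(p for ps in ATTRIBUTES.values() for p in ps)

#: Baseline covariate column names in the design matrix.
COVARIATE_NAMES: Tuple[str, ...] = (
    "age", "charl_2yr", "charl_ever", "elix_2yr", "elix_ever",
)

OUTCOME_NAME = "death60"


def candidate_columns(cms: Tuple[str, ...] = CM_NAMES) -> Tuple[str, ...]:
    """CM-major candidate predictor names: 13 per CM, attribute order within CM."""
    return tuple(f"{cm}{p}" for cm in cms for p in PARAMETER_NAMES)


#: Documentation defaults for treatment targets, all overridable.  Units:
#: SBP/DBP mmHg, O2Sat %, BMI kg/m^2, eGFR mL/min/1.73m^2, Alb g/dL
#: (interpreted as serum albumin, see docs/methods.md), HCT %, ALT U/L,
#: A1c %, HDL/LDL mg/dL.
DEFAULT_TARGETS: Mapping[str, TargetSpec] = {
    "SBP": TargetSpec("SBP", high=140.0),
    "DBP": TargetSpec("DBP", high=90.0),
    "O2Sat": TargetSpec("O2Sat", low=95.0),
    "BMI": TargetSpec("BMI", high=30.0),
    "eGFR": TargetSpec("eGFR", low=60.0),
    "Alb": TargetSpec("Alb", low=3.5),
    "HCT": TargetSpec("HCT", low=38.0, high=52.0),
    "ALT": TargetSpec("ALT", high=40.0),
    "A1c": TargetSpec("A1c", high=7.0),
    "HDL": TargetSpec("HDL", low=40.0),
    "LDL": TargetSpec("LDL", high=130.0),
}
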