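"""Unmet primary-care need (UMN) as an additive visit-equivalent term.

UMN is deliberately a subjective, locally elicited quantity. The default
concretization here is a weighted linear composite of three proxies —
low-urgency emergency-department visits, hospitalizations for ambulatory care
sensitive conditions (ACSC), and a survey-reported unmet share of resident
needs — scaled by a consultation-elicited multiplier. Any alternative
estimator mapping the same inputs to a per-neighbourhood UMN series can be
plugged in instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import pandas as pd

REQUIRED_COLUMNS = ("low_urgency_ed", "acsc", "survey_share", "consultation_adjustment")


@dataclass(frozen=True)
class UnmetNeedWeights:
    """Visit-equivalent weights for the three unmet-need proxies."""

    ed: float = 1.0       # avoidable primary-care visits per low-urgency ED visit
    acsc: float = 5.0     # visits that could have averted one ACSC hospitalization
    survey: float = 1.0   # weight on the survey-reported unmet share of V_RES

    def __post_init__(self) -> None:
        if min(self.ed, self.acsc, self.survey) < 0:
            raise ValueError("unmet-need weights must be non-negative")


@dataclass
class UnmetNeedEstimate:
    """Per-neighbourhood UMN in visits/year, with its component breakdown."""

    umn: pd.Series
    components: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.umn < 0).any():
            raise ValueError("UMN must be non-negative")


def validate_unmet_inputs(inputs: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in inputs.columns]
    if missing:
        raise ValueError(f"unmet-need inputs missing columns {missing}")
    if (inputs["low_urgency_ed"] < 0).any() or (inputs["acsc"] < 0).any():
        raise ValueError("ED and ACSC counts must be non-negative")
    if ((inputs["survey_share"] < 0) | (inputs["survey_share"] > 1)).any():
        raise ValueError("survey_share must lie in [0, 1]")
    if (inputs["consultation_adjustment"] < 0).any():
        raise ValueError("consultation_adjustment must be >= 0")
    return inputs


def compute_umn(
    inputs: pd.DataFrame,
    needs: pd.Series,
    weights: UnmetNeedWeights = UnmetNeedWeights(),
    estimator: Callable[[pd.DataFrame, pd.Series], pd.Series] | None = None,
) -> UnmetNeedEstimate:
    """UMN_x = adj_x * (w_ed*ED_x + w_acsc*ACSC_x + w_survey*share_x*V_RES_x).

    The survey term scales resident needs (the unmet share of needed visits),
    so every component is in visit units. Setting a neighbourhood's
    consultation adjustment to 0 removes its UMN entirely — a scenario lever.
    A custom ``estimator`` replaces the composite wholesale.
    """
    validate_unmet_inputs(inputs)
    inputs = inputs.reindex(needs.index)
    if inputs.isna().any().any():
        raise ValueError("unmet-need inputs do not cover every neighbourhood")
    if estimator is not None:
        umn = estimator(inputs, needs).clip(lower=0.0)
        comp = pd.DataFrame({"custom": umn})
        return UnmetNeedEstimate(umn.rename("umn"), comp)
    adj = inputs["consultation_adjustment"]
    comp = pd.DataFrame(
        {
            "ed_component": adj * weights.ed * inputs["low_urgency_ed"],
            "acsc_component": adj * weights.acsc * inputs["acsc"],
            "survey_component": adj * weights.survey * inputs["survey_share"] * needs,
        }
    )
    umn = comp.sum(axis=1).clip(lower=0.0).rename("umn")
    return UnmetNeedEstimate(umn, comp)
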