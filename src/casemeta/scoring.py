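"""Strong/weak confirmatory scoring of case-report outcomes.

A benefit outcome counts as modified under the *strong* confirmatory
method only when the case report both mentions the improvement and backs
it up (evaluation method described, or a quantitative measure given);
under the *weak* method a mere mention suffices.  Harm outcomes under
the dose-change criterion (infusion-related reactions) count only when
the event forced a therapy dose change, identically under both methods;
documented-event harm outcomes (antibody development) follow the same
rule shape as benefits.

The denominator of every per-outcome proportion is the number of cases
in the analysis set, not the number of cases reporting the outcome:
unreported outcomes are conservatively treated as not modified.
"""

from __future__ import annotations

from enum import Enum

from .data_model import (
    CaseDataset,
    Direction,
    HarmCriterion,
    OutcomeObservation,
    OutcomeSpec,
)

__all__ = ["ScoringMethod", "is_positive", "count_positives", "count_all_positives"]


class ScoringMethod(str, Enum):
    STRONG = "strong"
    WEAK = "weak"


def is_positive(
    obs: OutcomeObservation, outcome: OutcomeSpec, method: ScoringMethod
) -> bool:
    """Whether one observation counts as an outcome modification."""
    if obs.outcome_id != outcome.outcome_id:
        raise ValueError(
            f"observation of {obs.outcome_id!r} scored against outcome "
            f"{outcome.outcome_id!r}"
        )
    if (
        outcome.direction is Direction.HARM
        and outcome.harm_criterion is HarmCriterion.DOSE_CHANGE
    ):
        return obs.irr_dose_change
    if method is ScoringMethod.STRONG:
        return obs.improvement_mentioned and (
            obs.method_described or obs.quantitative_measure
        )
    return obs.improvement_mentioned


def count_positives(
    ds: CaseDataset, outcome: OutcomeSpec, method: ScoringMethod
) -> tuple[int, int]:
    """(k, n): positive cases for ``outcome`` over all cases in ``ds``."""
    if outcome.outcome_id not in {o.outcome_id for o in ds.outcomes}:
        raise ValueError(f"outcome {outcome.outcome_id!r} not configured in dataset")
    n = ds.n_cases
    k = sum(
        is_positive(case.observation(outcome.outcome_id), outcome, method)
        for case in ds.cases
    )
    return k, n


def count_all_positives(
    ds: CaseDataset, method: ScoringMethod
) -> dict[str, tuple[int, int]]:
    """Per-outcome (k, n) for every configured outcome, in configured order."""
    return {o.outcome_id: count_positives(ds, o, method) for o in ds.outcomes}
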