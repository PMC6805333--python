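"""Synthetic case-report corpora and operating characteristics.

The generator makes explicit the statistical structure the pipeline
assumes about published single-case narratives: each case independently
improves on each outcome with that outcome's true modification
probability; an improvement is documented at the strong level
(evaluation method or quantitative measure recorded) with some
probability, else only mentioned; outcomes that did not improve are
reported (as unchanged) with some probability, else omitted entirely.
Publication bias enters as the probability that a case with nothing
positive to report never appears in the corpus at all -- the mechanism
by which observed positive proportions exceed true modification rates.

Outcome improvements are independent across outcomes by default; an
optional shared per-case severity factor (logit-normal) induces
positive dependence when enabled.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .data_model import (
    CaseDataset,
    CaseReport,
    Direction,
    HarmCriterion,
    OutcomeObservation,
    OutcomeSpec,
    PublicationType,
    SoeGrade,
)
from .evidence import ClassificationConfig, classify_evidence
from .scoring import ScoringMethod, count_all_positives

__all__ = [
    "OutcomeModel",
    "SimulationScenario",
    "OperatingCharacteristics",
    "generate_corpus",
    "operating_characteristics",
]


@dataclass(frozen=True)
class OutcomeModel:
    """Per-outcome response and reporting model."""

    true_modification_prob: float
    prob_strong_documentation_given_improvement: float = 0.7
    prob_reported_given_no_improvement: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "true_modification_prob",
            "prob_strong_documentation_given_improvement",
            "prob_reported_given_no_improvement",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class SimulationScenario:
    """Corpus size, per-outcome models, and the publication process."""

    n_cases: int
    outcome_models: Mapping[str, OutcomeModel]
    publication_bias: float = 0.0
    congress_fraction: float = 0.0
    case_severity_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")
        if not 0.0 <= self.publication_bias <= 1.0:
            raise ValueError("publication_bias must lie in [0, 1]")
        if not 0.0 <= self.congress_fraction <= 1.0:
            raise ValueError("congress_fraction must lie in [0, 1]")
        if self.case_severity_sd < 0:
            raise ValueError("case_severity_sd must be non-negative")


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Per-outcome fraction of replicates classified acceptable evidence."""

    rejection_rate: Mapping[str, float]
    replicates: int
    scenario: SimulationScenario
    config: ClassificationConfig
    method: ScoringMethod


def _default_outcomes(ids: Sequence[str]) -> tuple[OutcomeSpec, ...]:
    return tuple(
        OutcomeSpec(
            outcome_id=oid,
            label=oid,
            direction=Direction.BENEFIT,
            soe_grade=SoeGrade.INSUFFICIENT,
        )
        for oid in ids
    )


def generate_corpus(
    scenario: SimulationScenario,
    outcomes: Optional[Sequence[OutcomeSpec]] = None,
) -> CaseDataset:
    """Draw one synthetic corpus; identical scenario+seed => identical corpus."""
    if outcomes is None:
        outcomes = _default_outcomes(list(scenario.outcome_models))
    models = scenario.outcome_models
    for o in outcomes:
        if o.outcome_id not in models:
            raise ValueError(f"no outcome model for {o.outcome_id!r}")

    rng = np.random.default_rng(scenario.seed)
    n_out = len(outcomes)
    probs = np.array([models[o.outcome_id].true_modification_prob for o in outcomes])
    doc = np.array(
        [models[o.outcome_id].prob_strong_documentation_given_improvement for o in outcomes]
    )
    rep = np.array(
        [models[o.outcome_id].prob_reported_given_no_improvement for o in outcomes]
    )

    if scenario.case_severity_sd > 0:
        sev = rng.normal(0.0, scenario.case_severity_sd, size=scenario.n_cases)
        with np.errstate(divide="ignore"):
            logit = np.log(probs / (1 - probs))
        imp_prob = 1 / (1 + np.exp(-(logit[None, :] + sev[:, None])))
        imp_prob = np.where(probs[None, :] == 0, 0.0, imp_prob)
        imp_prob = np.where(probs[None, :] == 1, 1.0, imp_prob)
    else:
        imp_prob = np.broadcast_to(probs, (scenario.n_cases, n_out))

    improved = rng.random((scenario.n_cases, n_out)) < imp_prob
    documented = rng.random((scenario.n_cases, n_out)) < doc
    reported_neg = rng.random((scenario.n_cases, n_out)) < rep
    dropped = rng.random(scenario.n_cases) < scenario.publication_bias
    congress = rng.random(scenario.n_cases) < scenario.congress_fraction

    base_date = _dt.date(2010, 1, 1)
    cases = []
    for i in range(scenario.n_cases):
        observations: dict[str, OutcomeObservation] = {}
        any_positive = False
        for j, outcome in enumerate(outcomes):
            oid = outcome.outcome_id
            if improved[i, j]:
                any_positive = True
                if (
                    outcome.direction is Direction.HARM
                    and outcome.harm_criterion is HarmCriterion.DOSE_CHANGE
                ):
                    observations[oid] = OutcomeObservation(
                        outcome_id=oid,
                        reported=True,
                        improvement_mentioned=True,
                        irr_dose_change=True,
                    )
                elif documented[i, j]:
                    observations[oid] = OutcomeObservation(
                        outcome_id=oid,
                        reported=True,
                        improvement_mentioned=True,
                        quantitative_measure=True,
                    )
                else:
                    observations[oid] = OutcomeObservation(
                        outcome_id=oid, reported=True, improvement_mentioned=True
                    )
            elif reported_neg[i, j]:
                observations[oid] = OutcomeObservation(outcome_id=oid, reported=True)
        if not any_positive and dropped[i]:
            continue
        cases.append(
            CaseReport(
                case_id=f"s{i + 1:04d}",
                publication_id=f"sp{i + 1:04d}",
                publication_date=base_date + _dt.timedelta(days=int(i % 2000)),
                publication_type=(
                    PublicationType.CONGRESS_COMMUNICATION
                    if congress[i]
                    else PublicationType.ARTICLE
                ),
                observations=observations,
            )
        )
    return CaseDataset(
        cases=tuple(cases),
        outcomes=tuple(outcomes),
        provenance=f"synthetic corpus (seed={scenario.seed})",
    )


def operating_characteristics(
    scenario: SimulationScenario,
    cfg: ClassificationConfig = ClassificationConfig(),
    replicates: int = 1000,
    seed: int = 0,
    method: ScoringMethod = ScoringMethod.STRONG,
    outcomes: Optional[Sequence[OutcomeSpec]] = None,
) -> OperatingCharacteristics:
    """Monte-Carlo rejection rates of the full classification procedure.

    One independent child seed per replicate is derived from ``seed`` via
    :class:`numpy.random.SeedSequence`, so replicate r is reproducible
    regardless of the total replicate count.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    children = np.random.SeedSequence(seed).spawn(replicates)
    ids = list(scenario.outcome_models)
    hits = {oid: 0 for oid in ids}
    for child in children:
        child_seed = int(child.generate_state(1)[0] % (2**31))
        corpus = generate_corpus(replace(scenario, seed=child_seed), outcomes)
        if corpus.n_cases == 0:
            continue
        rows = classify_evidence(count_all_positives(corpus, method), cfg)
        for row in rows:
            if row.acceptable:
                hits[row.outcome_id] += 1
    return OperatingCharacteristics(
        rejection_rate={oid: hits[oid] / replicates for oid in ids},
        replicates=replicates,
        scenario=scenario,
        config=cfg,
        method=method,
    )
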