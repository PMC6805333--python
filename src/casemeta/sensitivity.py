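"""Sensitivity analyses: one full pipeline run per scenario.

Three axes are swept: scoring method (strong vs weak confirmatory),
analysis set (primary, all cases, excluding gold-standard-overlap
publications, excluding congress communications), and the futility
boundary p0 of the binomial null (1, 5, 10, 15, 20%).  Each scenario is
evaluated independently; the FDR adjustment applies within a scenario
only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .concordance import (
    AgreementResult,
    ConfusionTable,
    ValidityResult,
    confusion_from_classification,
    spearman_midrank,
    validity_indices,
)
from .data_model import AnalysisSetSpec, CaseDataset, apply_analysis_set
from .evidence import ClassificationConfig, EvidenceRow, classify_evidence
from .scoring import ScoringMethod, count_all_positives

__all__ = ["SweepResult", "run_scenario", "boundary_sweep", "DEFAULT_BOUNDARIES"]

DEFAULT_BOUNDARIES = [0.01, 0.05, 0.10, 0.15, 0.20]


@dataclass(frozen=True)
class SweepResult:
    """One scenario's evidence table plus concordance summaries."""

    label: str
    n_cases: int
    n_publications: int
    evidence: tuple[EvidenceRow, ...]
    confusion: ConfusionTable
    validity: ValidityResult
    agreement: AgreementResult

    @property
    def acceptable_ids(self) -> set[str]:
        return {r.outcome_id for r in self.evidence if r.acceptable}


def run_scenario(
    ds: CaseDataset,
    set_spec: AnalysisSetSpec,
    method: ScoringMethod = ScoringMethod.STRONG,
    cfg: ClassificationConfig = ClassificationConfig(),
    label: str | None = None,
) -> SweepResult:
    """Filter -> score -> classify -> concord, for one scenario."""
    sub = apply_analysis_set(ds, set_spec)
    counts = count_all_positives(sub, method)
    rows = classify_evidence(counts, cfg)
    confusion = confusion_from_classification(rows, sub.outcomes)
    validity = validity_indices(confusion)
    agreement = spearman_midrank(
        [counts[o.outcome_id][0] for o in sub.outcomes],
        [o.soe_score for o in sub.outcomes],
    )
    return SweepResult(
        label=label or f"{set_spec.name}/{method.value}/p0={cfg.p0:g}",
        n_cases=sub.n_cases,
        n_publications=sub.n_publications,
        evidence=tuple(rows),
        confusion=confusion,
        validity=validity,
        agreement=agreement,
    )


def boundary_sweep(
    ds: CaseDataset,
    set_spec: AnalysisSetSpec,
    method: ScoringMethod = ScoringMethod.STRONG,
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES,
    cfg: ClassificationConfig = ClassificationConfig(),
) -> list[SweepResult]:
    """One scenario per futility boundary p0."""
    if len(boundaries) == 0:
        raise ValueError("empty boundary list")
    for b in boundaries:
        if not 0.0 < b < 1.0:
            raise ValueError(f"futility boundary must lie in (0, 1), got {b}")
    return [
        run_scenario(
            ds,
            set_spec,
            method,
            replace(cfg, p0=b),
            label=f"{set_spec.name}/{method.value}/p0={b:g}",
        )
        for b in boundaries
    ]
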