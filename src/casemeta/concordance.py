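"""Concordance between case-report evidence classification and SOE grades.

The case-report pipeline labels each outcome acceptable/unacceptable
evidence; the gold standard labels the same outcome by its clinical
strength-of-evidence grade, dichotomized as moderate-to-high (positive)
vs low-to-insufficient (negative).  Agreement is summarized two ways:

* a 2x2 confusion table with sensitivity, specificity, predictive
  values and accuracy, each with an exact Clopper-Pearson interval;
* tie-corrected Spearman correlation between the per-outcome positive
  counts and the ordinal SOE scores (midranks + product-moment), with a
  Fisher-z confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .data_model import OutcomeSpec
from .evidence import EvidenceRow

__all__ = [
    "ConfusionTable",
    "IndexEstimate",
    "ValidityResult",
    "AgreementResult",
    "confusion_from_classification",
    "clopper_pearson_interval",
    "validity_indices",
    "midrank",
    "spearman_midrank",
    "fisher_z_interval",
    "percent",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 agreement; positive = acceptable evidence / moderate-to-high SOE."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion cells must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class IndexEstimate:
    """A proportion with its exact 95% (or other) CI; may be undefined."""

    value: Optional[float]
    ci: Optional[tuple[float, float]]

    @property
    def defined(self) -> bool:
        return self.value is not None


@dataclass(frozen=True)
class ValidityResult:
    sensitivity: IndexEstimate
    specificity: IndexEstimate
    ppv: IndexEstimate
    npv: IndexEstimate
    accuracy: IndexEstimate


@dataclass(frozen=True)
class AgreementResult:
    """Tie-corrected Spearman rho with Fisher-z CI over n paired outcomes."""

    rho: Optional[float]
    ci: Optional[tuple[float, float]]
    n: int


def confusion_from_classification(
    rows: Sequence[EvidenceRow], outcomes: Sequence[OutcomeSpec]
) -> ConfusionTable:
    """Cross the evidence groups against the dichotomized SOE grades."""
    grade = {o.outcome_id: o.soe_grade for o in outcomes}
    tp = fp = fn = tn = 0
    for row in rows:
        if row.outcome_id not in grade:
            raise ValueError(f"no gold SOE grade for outcome {row.outcome_id!r}")
        gold_pos = grade[row.outcome_id].is_acceptable
        if row.acceptable and gold_pos:
            tp += 1
        elif row.acceptable and not gold_pos:
            fp += 1
        elif not row.acceptable and gold_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def clopper_pearson_interval(
    successes: int, trials: int, confidence: float = 0.95
) -> Optional[tuple[float, float]]:
    """Exact two-sided binomial CI; None when trials == 0 (undefined)."""
    if trials == 0:
        return None
    if not 0 <= successes <= trials:
        raise ValueError(f"require 0 <= successes <= trials, got {successes}/{trials}")
    lo, hi = proportion_confint(successes, trials, alpha=1 - confidence, method="beta")
    return (float(lo), float(hi))


def _estimate(successes: int, trials: int, confidence: float) -> IndexEstimate:
    if trials == 0:
        return IndexEstimate(value=None, ci=None)
    return IndexEstimate(
        value=successes / trials,
        ci=clopper_pearson_interval(successes, trials, confidence),
    )


def validity_indices(ct: ConfusionTable, confidence: float = 0.95) -> ValidityResult:
    """Se, Sp, PPV, NPV and accuracy with exact CIs; empty margins undefined."""
    if ct.total == 0:
        raise ValueError("confusion table is empty")
    return ValidityResult(
        sensitivity=_estimate(ct.tp, ct.tp + ct.fn, confidence),
        specificity=_estimate(ct.tn, ct.tn + ct.fp, confidence),
        ppv=_estimate(ct.tp, ct.tp + ct.fp, confidence),
        npv=_estimate(ct.tn, ct.tn + ct.fn, confidence),
        accuracy=_estimate(ct.tp + ct.tn, ct.total, confidence),
    )


def midrank(values: Sequence[float]) -> list[float]:
    """Midranks: tied values share the mean of the ranks they span."""
    if len(values) == 0:
        raise ValueError("empty value list")
    return [float(r) for r in stats.rankdata(values, method="average")]


def spearman_midrank(x: Sequence[float], y: Sequence[float]) -> AgreementResult:
    """Tie-corrected Spearman: product-moment correlation of midranks."""
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 2:
        raise ValueError("need at least two paired observations")
    rx = np.asarray(midrank(x))
    ry = np.asarray(midrank(y))
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return AgreementResult(rho=None, ci=None, n=len(x))
    rho = float(np.corrcoef(rx, ry)[0, 1])
    ci = None
    if abs(rho) < 1.0 and len(x) > 3:
        ci = fisher_z_interval(rho, len(x))
    return AgreementResult(rho=rho, ci=ci, n=len(x))


def fisher_z_interval(
    rho: float, n: int, confidence: float = 0.95
) -> Optional[tuple[float, float]]:
    """CI for a correlation via atanh transform with SE 1/sqrt(n-3)."""
    if n <= 3 or abs(rho) >= 1.0:
        return None
    z = math.atanh(rho)
    half = stats.norm.ppf(1 - (1 - confidence) / 2) / math.sqrt(n - 3)
    return (math.tanh(z - half), math.tanh(z + half))


def percent(fraction: float) -> int:
    """Whole-percent display, rounding halves away from zero."""
    return int(math.floor(abs(fraction) * 100 + 0.5)) * (1 if fraction >= 0 else -1)
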