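"""Exact binomial futility testing and FDR evidence classification.

Each outcome's positive-case count k out of n is tested one-sided
against the futility boundary p0 (default 5%): p = P(X >= k) for
X ~ Binomial(n, p0).  Multiplicity over the nr outcomes is handled with
Benjamini-Hochberg critical values c_r = r/nr * q at FDR level q
(default 10%).  Ranks are dense over the sorted p-values with ties
assigned the minimum (most conservative) rank of their group.

Two classification rules are provided:

* ``per_rank`` (default): an outcome is *acceptable evidence* iff its own
  p-value is at or below its own critical value.
* ``step_up``: the orthodox BH step-up -- find the largest sorted
  position i with p_(i) <= i/nr * q and accept everything up to it.

The two coincide on monotone configurations (including every dataset
analyzed here) but can diverge in general, which is why both are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EvidenceGroup",
    "ClassificationRule",
    "ClassificationConfig",
    "EvidenceRow",
    "binomial_upper_tail_p",
    "fdr_critical_values",
    "assign_ranks",
    "classify_evidence",
    "format_p_value",
]


class EvidenceGroup(str, Enum):
    ACCEPTABLE = "acceptable"
    UNACCEPTABLE = "unacceptable"


class ClassificationRule(str, Enum):
    PER_RANK = "per_rank"
    STEP_UP = "step_up"


@dataclass(frozen=True)
class ClassificationConfig:
    """Null boundary p0, FDR level q, and the classification rule."""

    p0: float = 0.05
    q: float = 0.10
    rule: ClassificationRule = ClassificationRule.PER_RANK

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ValueError(f"p0 must lie in (0, 1), got {self.p0}")
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"q must lie in (0, 1), got {self.q}")


@dataclass(frozen=True)
class EvidenceRow:
    """One outcome's row of the evidence table."""

    outcome_id: str
    k: int
    n: int
    p_value: float
    rank: int
    critical_value: float
    group: EvidenceGroup

    @property
    def acceptable(self) -> bool:
        return self.group is EvidenceGroup.ACCEPTABLE


def binomial_upper_tail_p(k: int, n: int, p0: float) -> float:
    """Exact one-sided binomial p-value P(X >= k), X ~ Binomial(n, p0)."""
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def fdr_critical_values(nr: int, q: float) -> list[float]:
    """Benjamini-Hochberg critical values r/nr * q for ranks 1..nr."""
    if nr < 1:
        raise ValueError(f"need at least one outcome, got nr={nr}")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    return [r / nr * q for r in range(1, nr + 1)]


def assign_ranks(p_values: Sequence[float]) -> list[int]:
    """Dense minimum ranks of p-values, ascending; ties share one rank.

    Tied p-values (identical counts) all receive the smallest rank of
    their group and the next distinct p-value continues one above it, so
    ties are resolved in the direction of smaller critical values --
    conservative for declaring an outcome modified.
    """
    if len(p_values) == 0:
        raise ValueError("empty p-value list")
    return [int(r) for r in stats.rankdata(p_values, method="dense")]


def classify_evidence(
    counts: Mapping[str, tuple[int, int]],
    cfg: ClassificationConfig = ClassificationConfig(),
) -> list[EvidenceRow]:
    """Classify every outcome as acceptable/unacceptable evidence.

    ``counts`` maps outcome_id -> (k, n); all outcomes must share the
    same denominator n (one analysis set).  Rows are returned sorted by
    rank, then outcome_id.
    """
    if not counts:
        raise ValueError("no outcomes to classify")
    ns = {n for _, n in counts.values()}
    if len(ns) != 1:
        raise ValueError(f"inconsistent denominators across outcomes: {sorted(ns)}")

    ids = list(counts)
    nr = len(ids)
    ks = [counts[i][0] for i in ids]
    n = ns.pop()
    pvals = [binomial_upper_tail_p(k, n, cfg.p0) for k in ks]
    ranks = assign_ranks(pvals)
    grid = fdr_critical_values(nr, cfg.q)
    crit = [grid[r - 1] for r in ranks]

    if cfg.rule is ClassificationRule.PER_RANK:
        accepted = [p <= c for p, c in zip(pvals, crit)]
    else:
        accepted = _step_up_accept(pvals, cfg.q)

    rows = [
        EvidenceRow(
            outcome_id=ids[i],
            k=ks[i],
            n=n,
            p_value=pvals[i],
            rank=ranks[i],
            critical_value=crit[i],
            group=EvidenceGroup.ACCEPTABLE if accepted[i] else EvidenceGroup.UNACCEPTABLE,
        )
        for i in range(nr)
    ]
    rows.sort(key=lambda r: (r.rank, r.outcome_id))
    return rows


def _step_up_accept(pvals: Sequence[float], q: float) -> list[bool]:
    """Standard BH step-up over sorted positions 1..nr."""
    nr = len(pvals)
    order = np.argsort(pvals, kind="stable")
    threshold = -1.0
    for pos in range(nr, 0, -1):
        p = pvals[order[pos - 1]]
        if p <= pos / nr * q:
            threshold = p
            break
    return [p <= threshold for p in pvals]


def format_p_value(p: float) -> str:
    """Display convention: '< 0.0001' below 1e-4, '1' at one, else 3 dp."""
    if p < 0.0001:
        return "< 0.0001"
    if p == 1.0:
        return "1"
    return f"{p:.3f}"
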