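"""Exact binomial futility test, FDR critical values, ranks, classification."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from statsmodels.stats.multitest import multipletests

from casemeta import (
    ClassificationConfig,
    ClassificationRule,
    assign_ranks,
    binomial_upper_tail_p,
    classify_evidence,
    fdr_critical_values,
)
from casemeta.evidence import format_p_value

OUTCOME_IDS = [
    "ugags", "liver", "antibodies", "6mwt", "jrom", "growth",
    "irr", "pulmonary", "cardiac", "qol", "sleep",
]
STRONG_COUNTS = [20, 8, 6, 4, 4, 3, 2, 1, 0, 0, 0]
WEAK_COUNTS = [20, 13, 6, 15, 5, 5, 2, 4, 0, 8, 1]


def exact_tail(k: int, n: int, p0: Fraction) -> Fraction:
    """Independent oracle: exact rational summation of the binomial mass."""
    return sum(
        Fraction(math.comb(n, i)) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1)
    )


def test_binomial_tail_matches_exact_summation_up_to_n_60():
    p0 = Fraction(1, 20)
    for n in range(0, 61):
        for k in range(0, n + 1):
            exact = float(exact_tail(k, n, p0))
            assert abs(binomial_upper_tail_p(k, n, 0.05) - exact) < 1e-12


@pytest.mark.parametrize(
    "k, n, expected",
    [(6, 44, 0.022), (0, 44, 1.0), (2, 44, 0.653), (8, 44, 0.001), (4, 44, 0.177)],
)
def test_binomial_tail_reference_values(k, n, expected):
    assert round(binomial_upper_tail_p(k, n, 0.05), 3) == expected


def test_binomial_tail_boundaries_and_monotonicity():
    assert binomial_upper_tail_p(0, 10, 0.3) == 1.0
    assert binomial_upper_tail_p(10, 10, 0.3) == pytest.approx(0.3**10, rel=1e-12)
    ps = [binomial_upper_tail_p(k, 30, 0.05) for k in range(31)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


@pytest.mark.parametrize("k, n", [(5, 4), (-1, 4), (1, -1)])
def test_binomial_tail_domain_errors(k, n):
    with pytest.raises(ValueError):
        binomial_upper_tail_p(k, n, 0.05)


def test_fdr_critical_values_grid():
    grid = fdr_critical_values(11, 0.10)
    assert grid[:3] == pytest.approx([0.00909090909, 0.01818181818, 0.02727272727])
    assert grid[-1] == pytest.approx(0.10)
    assert all(a < b for a, b in zip(grid, grid[1:]))
    assert fdr_critical_values(1, 0.10) == [0.10]
    assert fdr_critical_values(4, 0.05) == pytest.approx([0.0125, 0.025, 0.0375, 0.05])
    with pytest.raises(ValueError):
        fdr_critical_values(0, 0.1)


def test_assign_ranks_dense_minimum_tie_rule():
    pvals = [binomial_upper_tail_p(k, 44, 0.05) for k in STRONG_COUNTS]
    assert assign_ranks(pvals) == [1, 2, 3, 4, 4, 5, 6, 7, 8, 8, 8]
    assert assign_ranks([0.3, 0.1, 0.2]) == [3, 1, 2]
    assert assign_ranks([0.5] * 5) == [1] * 5


def _classify(counts, n=44, **cfg):
    return classify_evidence(
        {oid: (k, n) for oid, k in zip(OUTCOME_IDS, counts)},
        ClassificationConfig(**cfg) if cfg else ClassificationConfig(),
    )


def acceptable_ids(rows):
    return {r.outcome_id for r in rows if r.acceptable}


def test_strong_classification_groups():
    rows = _classify(STRONG_COUNTS)
    assert acceptable_ids(rows) == {"ugags", "liver", "antibodies"}
    by_id = {r.outcome_id: r for r in rows}
    assert by_id["antibodies"].critical_value == pytest.approx(3 / 11 * 0.1)
    assert by_id["6mwt"].rank == by_id["jrom"].rank == 4


def test_weak_classification_groups():
    rows = _classify(WEAK_COUNTS)
    assert acceptable_ids(rows) == {"ugags", "liver", "antibodies", "6mwt", "qol"}


def test_per_rank_and_step_up_agree_on_corpus_counts():
    for counts in (STRONG_COUNTS, WEAK_COUNTS):
        per_rank = _classify(counts)
        step_up = _classify(counts, rule=ClassificationRule.STEP_UP)
        assert acceptable_ids(per_rank) == acceptable_ids(step_up)


def test_tie_rank_policy_does_not_change_groups_on_corpus_counts():
    """Minimum, mean, or maximum ranks for ties classify identically here."""
    from scipy import stats

    for counts in (STRONG_COUNTS, WEAK_COUNTS):
        pvals = [binomial_upper_tail_p(k, 44, 0.05) for k in counts]
        reference = {
            oid
            for oid, p, r in zip(OUTCOME_IDS, pvals, assign_ranks(pvals))
            if p <= r / 11 * 0.1
        }
        for method in ("average", "max"):
            ranks = stats.rankdata(pvals, method=method)
            alt = {
                oid
                for oid, p, r in zip(OUTCOME_IDS, pvals, ranks)
                if p <= r / 11 * 0.1
            }
            assert alt == reference


@given(
    st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=30),
    st.floats(min_value=0.01, max_value=0.3),
)
def test_step_up_matches_statsmodels_bh(pvals, q):
    """The optional step-up rule is the orthodox Benjamini-Hochberg."""
    from casemeta.evidence import _step_up_accept

    expected = multipletests(pvals, alpha=q, method="fdr_bh")[0]
    assert _step_up_accept(pvals, q) == list(expected)


def test_step_up_can_accept_above_own_rank_threshold():
    """Divergence case: BH accepts a p above its own critical value."""
    counts = {"a": (0.030, 1), "b": (0.032, 2), "c": (0.049, 3)}
    # p=(0.030, 0.032, 0.049), q=0.15, m=3: criticals 0.05, 0.10, 0.15
    pvals = [0.030, 0.032, 0.049]
    from casemeta.evidence import _step_up_accept

    assert _step_up_accept(pvals, 0.15) == [True, True, True]


def test_inconsistent_denominator_rejected():
    with pytest.raises(ValueError):
        classify_evidence({"a": (1, 10), "b": (2, 12)})


def test_single_null_outcome_is_unacceptable():
    (row,) = classify_evidence({"only": (0, 44)})
    assert row.p_value == 1.0
    assert not row.acceptable


def test_p_value_monotone_in_null_boundary():
    for k in (0, 2, 6, 20):
        ps = [binomial_upper_tail_p(k, 44, p0) for p0 in (0.01, 0.05, 0.1, 0.2, 0.5)]
        assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))


def test_p_value_display_convention():
    assert format_p_value(binomial_upper_tail_p(20, 44, 0.05)) == "< 0.0001"
    assert format_p_value(binomial_upper_tail_p(6, 44, 0.05)) == "0.022"
    assert format_p_value(1.0) == "1"
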