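"""2x2 validity indices with exact CIs and tie-corrected Spearman agreement."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from casemeta import (
    ClassificationConfig,
    ConfusionTable,
    classify_evidence,
    clopper_pearson_interval,
    confusion_from_classification,
    fisher_z_interval,
    midrank,
    spearman_midrank,
    validity_indices,
)
from casemeta.concordance import percent

STRONG_COUNTS = [20, 8, 6, 4, 4, 3, 2, 1, 0, 0, 0]
WEAK_COUNTS = [20, 13, 6, 15, 5, 5, 2, 4, 0, 8, 1]
SOE_SCORES = [3, 3, 3, 2, 1, 2, 2, 2, 1, 1, 1]


def _rows(counts, outcomes):
    ids = [o.outcome_id for o in outcomes]
    return classify_evidence(
        {oid: (k, 44) for oid, k in zip(ids, counts)}, ClassificationConfig()
    )


def test_confusion_strong_method(outcomes):
    ct = confusion_from_classification(_rows(STRONG_COUNTS, outcomes), outcomes)
    assert (ct.tp, ct.fp, ct.fn, ct.tn) == (3, 0, 0, 8)


def test_confusion_weak_method(outcomes):
    ct = confusion_from_classification(_rows(WEAK_COUNTS, outcomes), outcomes)
    assert (ct.tp, ct.fp, ct.fn, ct.tn) == (3, 2, 0, 6)


def test_confusion_empty_rows(outcomes):
    ct = confusion_from_classification([], outcomes)
    assert ct.total == 0


def test_confusion_missing_gold_grade(outcomes):
    rows = _rows(STRONG_COUNTS, outcomes)
    with pytest.raises(ValueError, match="ugags"):
        confusion_from_classification(rows, outcomes[1:])


@pytest.mark.parametrize(
    "successes, trials, lo, hi",
    [(3, 3, 0.292, 1.0), (8, 8, 0.631, 1.0), (0, 10, 0.0, 0.308)],
)
def test_clopper_pearson_reference_bounds(successes, trials, lo, hi):
    got = clopper_pearson_interval(successes, trials, 0.95)
    assert got == pytest.approx((lo, hi), abs=5e-4)


def test_clopper_pearson_degenerate_closed_forms():
    lo, hi = clopper_pearson_interval(3, 3, 0.95)
    assert lo == pytest.approx(0.025 ** (1 / 3), abs=1e-10) and hi == 1.0
    lo, hi = clopper_pearson_interval(0, 7, 0.95)
    assert lo == 0.0 and hi == pytest.approx(1 - 0.025 ** (1 / 7), abs=1e-10)
    assert clopper_pearson_interval(0, 5, 0.95)[0] == 0.0


def test_clopper_pearson_undefined_for_zero_trials():
    assert clopper_pearson_interval(0, 0) is None


@given(st.integers(0, 30), st.integers(1, 30))
def test_clopper_pearson_intervals_nest(successes, trials):
    successes = min(successes, trials)
    narrow = clopper_pearson_interval(successes, trials, 0.95)
    wide = clopper_pearson_interval(successes, trials, 0.99)
    assert wide[0] <= narrow[0] and narrow[1] <= wide[1]


def test_validity_indices_all_perfect():
    v = validity_indices(ConfusionTable(tp=3, fp=0, fn=0, tn=8))
    for est in (v.sensitivity, v.specificity, v.ppv, v.npv, v.accuracy):
        assert est.value == 1.0
    assert v.sensitivity.ci == pytest.approx((0.292, 1.0), abs=5e-4)
    assert v.specificity.ci == pytest.approx((0.631, 1.0), abs=5e-4)


def test_validity_indices_congress_exclusion_row():
    v = validity_indices(ConfusionTable(tp=2, fp=0, fn=1, tn=8))
    assert percent(v.accuracy.value) == 91
    assert percent(v.sensitivity.value) == 67
    assert percent(v.specificity.value) == 100
    assert percent(v.ppv.value) == 100
    assert percent(v.npv.value) == 89


def test_validity_indices_undefined_on_empty_margin():
    v = validity_indices(ConfusionTable(tp=0, fp=0, fn=0, tn=5))
    assert not v.sensitivity.defined and not v.ppv.defined
    assert v.specificity.value == v.npv.value == v.accuracy.value == 1.0
    with pytest.raises(ValueError):
        validity_indices(ConfusionTable())


def test_midrank_assignment():
    assert midrank([0, 0, 0, 1]) == [2, 2, 2, 4]
    assert midrank(STRONG_COUNTS) == [11, 10, 9, 7.5, 7.5, 6, 5, 4, 2, 2, 2]
    assert midrank([3, 1, 2]) == [3, 1, 2]
    assert sum(midrank(WEAK_COUNTS)) == 11 * 12 / 2


def test_spearman_reproduces_published_agreement():
    res = spearman_midrank(STRONG_COUNTS, SOE_SCORES)
    assert round(res.rho, 2) == 0.82
    assert res.ci == pytest.approx((0.43, 0.95), abs=5e-3)
    assert res.n == 11


def test_spearman_identity_and_reversal():
    x = [5.0, 3.0, 1.0, 4.0, 2.0]
    assert spearman_midrank(x, x).rho == pytest.approx(1.0)
    assert spearman_midrank(x, [-v for v in x]).rho == pytest.approx(-1.0)


def test_spearman_undefined_on_constant_input():
    res = spearman_midrank([1, 1, 1], [1, 2, 3])
    assert res.rho is None and res.ci is None


@given(st.lists(st.integers(0, 30), min_size=4, max_size=15))
def test_spearman_matches_scipy(xs):
    ys = SOE_SCORES[: len(xs)] + [1] * max(0, len(xs) - len(SOE_SCORES))
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        return
    expected = stats.spearmanr(xs, ys).statistic
    assert spearman_midrank(xs, ys).rho == pytest.approx(expected, abs=1e-12)


@given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=12))
def test_spearman_invariant_to_monotone_transform(xs):
    ys = list(range(len(xs)))
    if len(set(xs)) == 1:
        return
    base = spearman_midrank(xs, ys).rho
    transformed = spearman_midrank([x**3 + 2 * x for x in xs], ys).rho
    assert transformed == pytest.approx(base, abs=1e-12)


def test_spearman_no_tie_shortcut_formula_agrees():
    """With no ties, midrank Spearman equals 1 - 6*sum(d^2)/(n(n^2-1))."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = 9
        x = rng.permutation(n).tolist()
        y = rng.permutation(n).tolist()
        d2 = sum((rx - ry) ** 2 for rx, ry in zip(midrank(x), midrank(y)))
        shortcut = 1 - 6 * d2 / (n * (n**2 - 1))
        assert spearman_midrank(x, y).rho == pytest.approx(shortcut, abs=1e-12)


def test_fisher_z_reference_interval():
    rho = spearman_midrank(STRONG_COUNTS, SOE_SCORES).rho
    lo, hi = fisher_z_interval(rho, 11, 0.95)
    assert round(lo, 2) == 0.43 and round(hi, 2) == 0.95


def test_fisher_z_symmetry_and_interior():
    lo, hi = fisher_z_interval(0.0, 100, 0.95)
    assert lo == pytest.approx(-hi)
    lo, hi = fisher_z_interval(0.9, 5, 0.95)
    assert -1 < lo < 0.9 < hi < 1


def test_fisher_z_undefined_cases():
    assert fisher_z_interval(1.0, 11) is None
    assert fisher_z_interval(0.5, 3) is None


def test_percent_rounds_half_away_from_zero():
    assert percent(10 / 11) == 91
    assert percent(2 / 3) == 67
    assert percent(8 / 9) == 89
    assert percent(0.605) == 61
    assert percent(0.5) == 50
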