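"""Diagnostic statistics: cross-tabs, exact CIs, McNemar, AUC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stonect import (
    ConfusionMatrix2x2,
    StoneLabel,
    ValidationError,
    cross_tabulate,
    diagnostic_metrics,
    exact_binomial_ci,
    mcnemar_between,
    mcnemar_exact,
    roc_auc,
    round_percent,
)

UA, NON, MIX = StoneLabel.UA, StoneLabel.NON_UA, StoneLabel.MIXED


def labels_from_counts(tp, fn, fp, tn):
    preds = [UA] * tp + [NON] * fn + [UA] * fp + [NON] * tn
    refs = [UA] * (tp + fn) + [NON] * (fp + tn)
    return preds, refs


# --------------------------------------------------------------- cross-tabs
def test_identity_predictions_have_no_errors():
    preds = [UA, NON, NON, UA]
    cm = cross_tabulate(preds, preds)
    assert (cm.fp, cm.fn) == (0, 0) and cm.total == 4


def test_published_knn_cross_tab_counts():
    preds, refs = labels_from_counts(37, 0, 3, 103)
    cm = cross_tabulate(preds, refs)
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (37, 0, 3, 103)


def test_mixed_references_excluded_before_counting():
    preds = [UA, NON, UA]
    refs = [UA, MIX, NON]
    cm = cross_tabulate(preds, refs)
    assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 0, 1, 0)


def test_mixed_prediction_is_a_contract_violation():
    with pytest.raises(ValidationError):
        cross_tabulate([MIX], [UA])


def test_cross_tab_matches_counting_oracle(rng):
    for _ in range(20):
        preds = [[UA, NON][rng.integers(2)] for _ in range(50)]
        refs = [[UA, NON, MIX][rng.integers(3)] for _ in range(50)]
        cm = cross_tabulate(preds, refs)
        tp = sum(p is UA and r is UA for p, r in zip(preds, refs))
        fn = sum(p is NON and r is UA for p, r in zip(preds, refs))
        fp = sum(p is UA and r is NON for p, r in zip(preds, refs))
        tn = sum(p is NON and r is NON for p, r in zip(preds, refs))
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (tp, fn, fp, tn)


# ------------------------------------------------------------------ metrics
@pytest.mark.parametrize(
    "counts, expected",
    [
        ((37, 0, 3, 103), (100, 97, 98)),  # published kNN cross-tab
        ((35, 2, 2, 104), (95, 98, 97)),  # published rigid-cutoff cross-tab
        ((34, 3, 6, 100), (92, 94, 94)),  # published maxHU cross-tab
    ],
)
def test_published_metric_points(counts, expected):
    r = diagnostic_metrics(ConfusionMatrix2x2(*counts))
    assert (r.sensitivity.percent, r.specificity.percent, r.accuracy.percent) == expected


def test_all_correct_matrix_scores_100():
    r = diagnostic_metrics(ConfusionMatrix2x2(10, 0, 0, 20))
    assert (r.sensitivity.percent, r.specificity.percent, r.accuracy.percent) == (100, 100, 100)


def test_zero_denominator_flagged_not_dropped():
    r = diagnostic_metrics(ConfusionMatrix2x2(0, 0, 2, 8))
    assert not r.sensitivity.defined
    with pytest.raises(ValidationError):
        _ = r.sensitivity.percent
    assert r.specificity.defined


def test_point_estimate_inside_its_ci():
    r = diagnostic_metrics(ConfusionMatrix2x2(35, 2, 2, 104))
    for p in (r.sensitivity, r.specificity, r.accuracy):
        assert p.ci_low <= p.value <= p.ci_high
        assert 0.0 <= p.ci_low <= p.ci_high <= 1.0


# ---------------------------------------------------------------- exact CIs
@pytest.mark.parametrize(
    "k, n, expected",
    [(37, 37, (91, 100)), (103, 106, (92, 99)), (140, 143, (94, 100))],
)
def test_printed_interval_examples(k, n, expected):
    lo, hi = exact_binomial_ci(k, n)
    assert (round_percent(lo), round_percent(hi)) == expected


def test_degenerate_bounds():
    assert exact_binomial_ci(5, 5)[1] == 1.0
    assert exact_binomial_ci(0, 12)[0] == 0.0


def test_matches_statsmodels_beta_interval(rng):
    from statsmodels.stats.proportion import proportion_confint

    for _ in range(25):
        n = int(rng.integers(1, 200))
        k = int(rng.integers(0, n + 1))
        lo, hi = exact_binomial_ci(k, n)
        slo, shi = proportion_confint(k, n, alpha=0.05, method="beta")
        assert np.isclose(lo, slo, atol=1e-10) and np.isclose(hi, shi, atol=1e-10)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(k=st.integers(0, 30), extra=st.integers(0, 50))
def test_interval_widens_with_confidence(k, extra):
    n = k + extra + 1
    lo95, hi95 = exact_binomial_ci(k, n, 0.95)
    lo99, hi99 = exact_binomial_ci(k, n, 0.99)
    assert lo99 <= lo95 and hi99 >= hi95


def test_exact_interval_coverage_is_conservative(rng):
    """Over 10,000 simulated binomial draws the 95% interval covers the true
    p at least 95% of the time (exact intervals are conservative)."""
    p_true, n = 0.3, 40
    cis = [exact_binomial_ci(k, n) for k in range(n + 1)]
    draws = rng.binomial(n, p_true, size=10_000)
    covered = np.mean([cis[k][0] <= p_true <= cis[k][1] for k in draws])
    assert covered >= 0.95


def test_invalid_counts_rejected():
    with pytest.raises(ValidationError):
        exact_binomial_ci(5, 4)
    with pytest.raises(ValidationError):
        exact_binomial_ci(-1, 4)


# ------------------------------------------------------------------ McNemar
def test_mcnemar_no_discordance_is_one():
    assert mcnemar_exact(0, 0) == 1.0


def test_mcnemar_single_discordant_pair_capped_at_one():
    assert mcnemar_exact(1, 0) == 1.0


def test_mcnemar_9_3_equals_binomial_tail():
    assert np.isclose(mcnemar_exact(9, 3), 598 / 4096)


def test_mcnemar_matches_pmf_summation_oracle():
    for b in range(0, 13):
        for c in range(0, 13):
            n = b + c
            if n == 0:
                continue
            m = min(b, c)
            oracle = min(1.0, 2 * sum(stats.binom.pmf(i, n, 0.5) for i in range(m + 1)))
            assert np.isclose(mcnemar_exact(b, c), oracle, atol=1e-12)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(b=st.integers(0, 25), c=st.integers(0, 25))
def test_mcnemar_symmetric(b, c):
    assert mcnemar_exact(b, c) == mcnemar_exact(c, b)


def test_mcnemar_matches_statsmodels_exact():
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

    for b, c in [(9, 3), (5, 5), (12, 1), (2, 7)]:
        table = [[0, b], [c, 0]]
        assert np.isclose(mcnemar_exact(b, c), sm_mcnemar(table, exact=True).pvalue)


def test_mcnemar_variants_ordering():
    assert mcnemar_exact(9, 3, "midp") <= mcnemar_exact(9, 3, "exact")
    assert 0.0 <= mcnemar_exact(9, 3, "chi2_cc") <= 1.0


def test_mcnemar_between_counts_discordant_correctness():
    refs = [UA, UA, NON, NON, MIX]
    pa = [UA, NON, NON, UA, UA]  # right, wrong, right, wrong
    pb = [UA, UA, UA, UA, NON]  # right, right, wrong, wrong
    b, c, p = mcnemar_between(pa, pb, refs)
    assert (b, c) == (1, 1) and p == 1.0


# ---------------------------------------------------------------------- AUC
def test_perfectly_separated_scores():
    refs = [UA] * 5 + [NON] * 5
    scores = [1.0] * 5 + [0.0] * 5
    assert roc_auc(scores, refs) == 1.0


def test_constant_scores_give_half():
    refs = [UA] * 4 + [NON] * 6
    assert roc_auc([0.5] * 10, refs) == 0.5


def test_auc_matches_all_pairs_mann_whitney(rng):
    refs = [UA if rng.random() < 0.4 else NON for _ in range(30)]
    if UA not in refs:
        refs[0] = UA
    if NON not in refs:
        refs[-1] = NON
    scores = rng.normal(size=30).round(1)  # rounding forces some ties
    pos = [s for s, r in zip(scores, refs) if r is UA]
    neg = [s for s, r in zip(scores, refs) if r is NON]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    assert np.isclose(roc_auc(scores, refs), wins / (len(pos) * len(neg)))


def test_auc_invariant_under_monotone_transform(rng):
    refs = [UA] * 10 + [NON] * 20
    scores = rng.normal(size=30)
    a = roc_auc(scores, refs)
    assert np.isclose(a, roc_auc(np.exp(2 * scores), refs))


def test_auc_orientation_flip():
    refs = [UA] * 5 + [NON] * 5
    max_hu = np.r_[np.full(5, 400.0), np.full(5, 1300.0)]
    assert roc_auc(-max_hu, refs) == 1.0
    assert roc_auc(max_hu, refs, higher_is_ua=False) == 1.0


def test_auc_single_class_rejected():
    with pytest.raises(ValidationError):
        roc_auc([0.1, 0.2], [UA, UA])
    with pytest.raises(ValidationError):
        roc_auc([0.1, 0.2], [UA, MIX])  # MIXED excluded first
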