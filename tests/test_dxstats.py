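import numpy as np
import pytest
from scipy import stats
from statsmodels.sandbox.stats.multicomp import multipletests
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from deploycal.dxstats import (
    ConfusionCounts,
    PairedTable,
    holm,
    mcnemar_chi2,
    mcnemar_exact,
    mcnemar_test,
    metrics_from_counts,
    relative_pv_test,
    round_half_up_pct,
)
from deploycal.errors import DegenerateInputError, DomainError


def test_metrics_reproduce_patient_level_pirads3_row():
    m = metrics_from_counts(ConfusionCounts(tp=106, fn=2, tn=25, fp=126))
    assert m.sensitivity.render() == "98% (106/108)"
    assert m.specificity.render() == "17% (25/151)"
    assert m.ppv.render() == "46% (106/232)"
    assert m.npv.render() == "93% (25/27)"


def test_perfect_classifier_all_100():
    m = metrics_from_counts(ConfusionCounts(tp=10, fn=0, tn=10, fp=0))
    assert all(x.pct == 100 for x in (m.sensitivity, m.specificity, m.ppv, m.npv))


def test_sextant_conjunction_npv():
    assert round_half_up_pct(1151, 1267) == 91


def test_zero_denominator_yields_undefined_not_zero():
    m = metrics_from_counts(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
    assert m.sensitivity is None
    assert m.specificity is not None


def test_half_up_rounding():
    assert round_half_up_pct(1, 8) == 13  # 12.5 rounds up
    assert round_half_up_pct(119, 309) == 39  # 38.51...


def test_clopper_pearson_interval_brackets_the_estimate():
    m = metrics_from_counts(ConfusionCounts(tp=106, fn=2, tn=25, fp=126))
    lo, hi = m.sensitivity.ci95
    assert lo < 106 / 108 < hi
    # exact CP endpoints via the beta quantiles
    assert lo == pytest.approx(stats.beta.ppf(0.025, 106, 3))
    assert hi == pytest.approx(stats.beta.ppf(0.975, 107, 2))


# -- McNemar ------------------------------------------------------------------


def test_mcnemar_no_discordance():
    assert mcnemar_test(0, 0) == 1.0


def test_mcnemar_exact_small_example():
    # 2*P(X <= 2 | n=10, p=0.5)
    assert mcnemar_test(2, 8) == pytest.approx(0.109375)


def test_mcnemar_chi2_closed_form():
    expected = stats.chi2.sf((abs(40 - 60) - 1) ** 2 / 100, df=1)
    assert mcnemar_test(40, 60) == pytest.approx(expected)


def test_mcnemar_exact_equals_binomial_enumeration_up_to_25():
    for n in range(0, 26):
        for b in range(0, n + 1):
            c = n - b
            if n == 0:
                expected = 1.0
            else:
                k = min(b, c)
                tail = sum(stats.binom.pmf(i, n, 0.5) for i in range(k + 1))
                expected = min(1.0, 2 * tail)
            assert mcnemar_exact(b, c) == pytest.approx(expected, abs=1e-12)
            assert mcnemar_test(b, c) == pytest.approx(expected, abs=1e-12)


def test_mcnemar_chi2_matches_statsmodels():
    for b, c in ((40, 60), (30, 31), (100, 70)):
        table = [[0, b], [c, 0]]
        expected = sm_mcnemar(table, exact=False, correction=True).pvalue
        assert mcnemar_chi2(b, c) == pytest.approx(float(expected))


def test_exact_and_chi2_agree_asymptotically():
    # b + c = 200 with b/c near 1
    assert abs(mcnemar_exact(95, 105) - mcnemar_chi2(95, 105)) < 0.01


# -- relative predictive values ----------------------------------------------


def reconstructed_patient_table():
    """Conjunction (A) vs radiologist >=4 alone (B): 145 A+ (91 sPC) nested in
    154 B+ (91 sPC); 105 men both-negative (17 sPC); 259 total, 108 sPC."""
    counts = np.zeros((2, 2, 2), dtype=int)
    counts[1, 1, 1] = 91
    counts[1, 1, 0] = 54
    counts[0, 1, 1] = 0
    counts[0, 1, 0] = 9
    counts[0, 0, 1] = 17
    counts[0, 0, 0] = 88
    return PairedTable(counts)


def test_identical_tests_give_unit_ratio_and_p_one():
    counts = np.zeros((2, 2, 2), dtype=int)
    counts[1, 1, 1] = 30
    counts[1, 1, 0] = 20
    counts[0, 0, 1] = 5
    counts[0, 0, 0] = 45
    res = relative_pv_test(PairedTable(counts))
    assert res.rppv == pytest.approx(1.0)
    assert res.p_ppv == 1.0
    assert res.rnpv == pytest.approx(1.0)
    assert res.p_npv == 1.0


def test_reconstructed_patient_table_values():
    t = reconstructed_patient_table()
    res = relative_pv_test(t)
    assert res.rppv == pytest.approx((91 / 145) / (91 / 154))
    assert res.p_ppv <= 0.03
    m = metrics_from_counts(t.margin("a"))
    assert m.ppv.render() == "63% (91/145)"
    assert m.npv.render() == "85% (97/114)"
    mb = metrics_from_counts(t.margin("b"))
    assert mb.ppv.render() == "59% (91/154)"
    assert mb.npv.render() == "84% (88/105)"


def test_swapping_tests_inverts_ratios_and_preserves_p():
    t = reconstructed_patient_table()
    res = relative_pv_test(t)
    swapped = relative_pv_test(t.swapped())
    assert swapped.rppv == pytest.approx(1.0 / res.rppv)
    assert swapped.rnpv == pytest.approx(1.0 / res.rnpv)
    assert swapped.p_ppv == pytest.approx(res.p_ppv)
    assert swapped.p_npv == pytest.approx(res.p_npv)


def test_degenerate_margin_is_named():
    counts = np.zeros((2, 2, 2), dtype=int)
    counts[0, 1, 1] = 5
    counts[0, 1, 0] = 5
    counts[0, 0, 0] = 10
    with pytest.raises(DegenerateInputError, match="test A"):
        relative_pv_test(PairedTable(counts))


def bootstrap_p(table, reps=20000, seed=0):
    """Oracle: nonparametric bootstrap SE of log rPPV/log rNPV -> Wald p."""
    rng = np.random.default_rng(seed)
    n = table.counts.ravel()
    N = n.sum()
    draws = rng.multinomial(N, n / N, size=reps).reshape(reps, 2, 2, 2)

    def log_ratio(c, idx):
        s1, s2, s3, s4 = idx
        x1 = c[(slice(None),) + s1].reshape(reps, -1).sum(axis=1).astype(float)
        x2 = c[(slice(None),) + s2].reshape(reps, -1).sum(axis=1).astype(float)
        x3 = c[(slice(None),) + s3].reshape(reps, -1).sum(axis=1).astype(float)
        x4 = c[(slice(None),) + s4].reshape(reps, -1).sum(axis=1).astype(float)
        ok = (x1 > 0) & (x2 > 0) & (x3 > 0) & (x4 > 0)
        return np.log(x1[ok]) - np.log(x2[ok]) - np.log(x3[ok]) + np.log(x4[ok])

    ax = np.index_exp
    out = {}
    for name, idx in (
        ("ppv", (ax[1, :, 1], ax[1, :, :], ax[:, 1, 1], ax[:, 1, :])),
        ("npv", (ax[0, :, 0], ax[0, :, :], ax[:, 0, 0], ax[:, 0, :])),
    ):
        g_star = log_ratio(draws, idx)
        nn = table.counts
        x = [float(nn[s].sum()) for s in idx]
        g_hat = np.log(x[0]) - np.log(x[1]) - np.log(x[2]) + np.log(x[3])
        se = g_star.std(ddof=1)
        out[name] = 2 * stats.norm.sf(abs(g_hat) / se)
    return out


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_relative_pv_p_matches_bootstrap_oracle(seed):
    rng = np.random.default_rng(seed)
    while True:  # draw a random small table with all margins non-degenerate
        counts = rng.integers(1, 11, size=(2, 2, 2))
        t = PairedTable(counts)
        n = t.counts
        if min(n[1].sum(), n[:, 1].sum(), n[1, :, 1].sum(), n[:, 1, 1].sum(),
               n[0].sum(), n[:, 0].sum(), n[0, :, 0].sum(), n[:, 0, 0].sum()) > 0:
            break
    res = relative_pv_test(t)
    oracle = bootstrap_p(t, reps=20000, seed=seed)
    # at table totals near 50 the delta-method and bootstrap standard errors
    # of log rPPV differ by a higher-order term, not just Monte-Carlo noise
    assert res.p_ppv == pytest.approx(oracle["ppv"], abs=0.1)
    assert res.p_npv == pytest.approx(oracle["npv"], abs=0.1)


def test_relative_pv_se_converges_to_bootstrap_on_larger_tables():
    rng = np.random.default_rng(10)
    counts = rng.integers(20, 60, size=(2, 2, 2))
    t = PairedTable(counts)
    res = relative_pv_test(t)
    oracle = bootstrap_p(t, reps=20000, seed=10)
    assert res.p_ppv == pytest.approx(oracle["ppv"], abs=0.02)
    assert res.p_npv == pytest.approx(oracle["npv"], abs=0.02)


# -- Holm ---------------------------------------------------------------------


def test_holm_single_p_unchanged():
    assert holm([0.2]) == pytest.approx([0.2])


def test_holm_hand_computed_example():
    np.testing.assert_allclose(holm([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])


def test_holm_dominates_raw_and_is_permutation_equivariant():
    rng = np.random.default_rng(4)
    p = rng.random(8)
    adj = holm(p)
    assert (adj >= p).all()
    order = rng.permutation(8)
    np.testing.assert_allclose(holm(p[order]), adj[order])


def test_holm_matches_statsmodels():
    rng = np.random.default_rng(5)
    for _ in range(5):
        p = rng.random(6)
        expected = multipletests(p, method="holm")[1]
        np.testing.assert_allclose(holm(p), expected)


def test_holm_rejects_out_of_range():
    with pytest.raises(DomainError):
        holm([0.5, 1.2])
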