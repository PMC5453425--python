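import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from infodyn.errors import ParameterError
from infodyn.stats import (
    aggregate_by_recording,
    binomial_aggregate,
    icc,
    lmm_compare,
    perm_anova_2way,
    perm_ttest_ind,
    spearman_restricted_perm,
    surrogate_test,
)


class TestSurrogateTest:
    def test_coupled_epochs_significant(self, rng):
        # per-epoch lag-5 coupling, destroyed by epoch shuffling
        src = rng.normal(size=(30, 120))
        tgt = rng.normal(size=(30, 120))
        tgt[:, 5:] += 0.8 * src[:, :-5]

        def estimator(s, t):
            return float(np.mean(s[:, :-5] * t[:, 5:]))

        res = surrogate_test(src, tgt, estimator, n_surrogates=99, seed=1)
        assert res.p < 0.05
        assert res.observed > res.null_values.max()

    def test_single_epoch_errors(self, rng):
        with pytest.raises(ParameterError):
            surrogate_test(
                rng.normal(size=(1, 50)), rng.normal(size=(1, 50)),
                lambda s, t: 0.0, n_surrogates=10,
            )

    def test_p_never_zero_and_reproducible(self, rng):
        src = rng.normal(size=(5, 50))
        tgt = rng.normal(size=(5, 50))
        est = lambda s, t: float(np.sum(s * t))
        r1 = surrogate_test(src, tgt, est, n_surrogates=50, seed=3)
        r2 = surrogate_test(src, tgt, est, n_surrogates=50, seed=3)
        assert r1.p > 0
        assert r1.p == r2.p
        np.testing.assert_array_equal(r1.null_values, r2.null_values)


class TestBinomialAggregate:
    def test_zero_significant(self):
        assert binomial_aggregate(0, 5) == 1.0

    def test_all_significant_closed_form(self):
        assert binomial_aggregate(5, 5) == pytest.approx(0.05**5, rel=1e-9)

    def test_two_of_eight_oracle(self):
        # independent oracle: exact upper-tail sum of the binomial pmf
        expected = sum(
            sstats.binom.pmf(k, 8, 0.05) for k in range(2, 9)
        )
        assert binomial_aggregate(2, 8) == pytest.approx(expected, rel=1e-9)
        assert binomial_aggregate(2, 8) == pytest.approx(0.0572, abs=5e-4)

    def test_monotone_in_n_significant(self):
        ps = [binomial_aggregate(k, 10) for k in range(11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_out_of_range(self):
        with pytest.raises(ParameterError):
            binomial_aggregate(6, 5)


def _make_table(rng, n_per_cell=6, effect_a=0.0, effect_b=0.0, interaction=0.0):
    rows = []
    for ia, la in enumerate(["a0", "a1", "a2"]):
        for ib, lb in enumerate(["b0", "b1"]):
            mu = effect_a * ia + effect_b * ib + interaction * ia * (2 * ib - 1)
            for _ in range(n_per_cell):
                rows.append((rng.normal(mu, 1.0), la, lb))
    vals, fa, fb = zip(*rows)
    return np.array(vals), list(fa), list(fb)


class TestPermAnova:
    def test_injected_main_effect_a(self, rng):
        vals, fa, fb = _make_table(rng, effect_a=2.0)
        res = perm_anova_2way(vals, fa, fb, n_perm=300, seed=0)
        assert res.p_main_A < 0.05
        assert res.p_main_B > 0.01  # no B effect injected

    def test_injected_interaction(self, rng):
        vals, fa, fb = _make_table(rng, interaction=2.0)
        res = perm_anova_2way(vals, fa, fb, n_perm=300, seed=0)
        assert res.p_interaction < 0.05

    def test_empty_cell_errors(self, rng):
        vals = rng.normal(size=4)
        with pytest.raises(ParameterError):
            perm_anova_2way(vals, ["a", "a", "b", "b"], ["x", "x", "x", "x"],
                            n_perm=10)

    def test_f_matches_parametric_oracle_balanced(self, rng):
        # balanced design: Type II F equals the classical two-way ANOVA F
        vals, fa, fb = _make_table(rng, effect_a=1.0, effect_b=0.5)
        res = perm_anova_2way(vals, fa, fb, n_perm=10, seed=0)
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = pd.DataFrame({"y": vals, "A": fa, "B": fb})
        tab = sm.stats.anova_lm(ols("y ~ C(A) * C(B)", df).fit(), typ=2)
        assert res.F_main_A == pytest.approx(tab.loc["C(A)", "F"], rel=1e-6)
        assert res.F_main_B == pytest.approx(tab.loc["C(B)", "F"], rel=1e-6)
        assert res.F_interaction == pytest.approx(tab.loc["C(A):C(B)", "F"], rel=1e-6)

    def test_reproducible(self, rng):
        vals, fa, fb = _make_table(rng)
        r1 = perm_anova_2way(vals, fa, fb, n_perm=50, seed=9)
        r2 = perm_anova_2way(vals, fa, fb, n_perm=50, seed=9)
        assert r1.as_dict() == r2.as_dict()


class TestAggregate:
    def test_median_robust(self):
        tab = pd.DataFrame(
            {"session_id": ["s"] * 3, "value": [1.0, 2.0, 100.0], "measure": "TE_SPO"}
        )
        out = aggregate_by_recording(tab)
        assert out["value"].iloc[0] == 2.0

    def test_single_epoch(self):
        tab = pd.DataFrame({"session_id": ["s"], "value": [7.0]})
        assert aggregate_by_recording(tab)["value"].iloc[0] == 7.0

    def test_preserves_recording_count(self, rng):
        tab = pd.DataFrame(
            {
                "session_id": np.repeat([f"s{i}" for i in range(5)], 4),
                "value": rng.normal(size=20),
            }
        )
        assert len(aggregate_by_recording(tab)) == 5


def _lmm_table(rng, n_rec=8, n_epoch=20, beta_d=0.0, beta_a=0.0, re_sd=0.5, noise=1.0):
    rows = []
    conds = ["c0.0", "c0.5", "c1.0"]
    for j in range(n_rec):
        gamma = rng.normal(0, re_sd)
        cond = conds[j % 3]
        a_effect = beta_a * conds.index(cond)
        for i in range(n_epoch):
            d = 1 if i % 2 == 0 else -1
            rows.append(
                {
                    "session_id": f"r{j}",
                    "condition": cond,
                    "direction_or_site": "fwd" if d == 1 else "rev",
                    "value": gamma + a_effect + beta_d * d + rng.normal(0, noise),
                }
            )
    return pd.DataFrame(rows)


class TestLmm:
    def test_injected_direction_effect_detected(self, rng):
        tab = _lmm_table(rng, beta_d=0.5)
        cmp_tab = lmm_compare(tab).set_index("model")
        row = cmp_tab.loc["fm_d"]
        assert row["p"] < 0.05
        assert row["bic"] < row["bic_baseline"]

    def test_no_effect_not_significant(self, rng):
        ps = [
            lmm_compare(_lmm_table(np.random.default_rng(s))).set_index("model")
            .loc["fm_d", "p"]
            for s in range(5)
        ]
        assert min(ps) > 0.001  # no systematic spurious effect

    def test_interaction_tested_against_additive(self, rng):
        tab = _lmm_table(rng, beta_d=0.3, beta_a=0.5)
        cmp_tab = lmm_compare(tab).set_index("model")
        assert cmp_tab.loc["fm_axb", "baseline"] == "fm_ab"
        assert cmp_tab.loc["fm_axb", "df"] == 2  # two condition contrasts x direction

    def test_bic_formula(self, rng):
        tab = _lmm_table(rng)
        cmp_tab = lmm_compare(tab).set_index("model")
        row = cmp_tab.loc["fm_d"]
        n = len(tab)
        k = 4  # intercept + direction + random-intercept var + residual var
        assert row["bic"] == pytest.approx(-2 * row["llf"] + k * np.log(n), rel=1e-9)


class TestIcc:
    def test_zero_between_recording_variance(self, rng):
        tab = _lmm_table(rng, re_sd=0.0)
        assert icc(tab) < 0.05

    def test_disjoint_constants_near_one(self, rng):
        tab = _lmm_table(rng, re_sd=3.0, noise=0.05)
        assert icc(tab) > 0.95

    def test_equal_variances_near_half(self):
        rng = np.random.default_rng(42)
        tab = _lmm_table(rng, n_rec=30, n_epoch=30, re_sd=1.0, noise=1.0)
        assert icc(tab) == pytest.approx(0.5, abs=0.12)

    def test_needs_replication(self):
        tab = pd.DataFrame({"session_id": ["a", "b"], "value": [1.0, 2.0]})
        with pytest.raises(ParameterError):
            icc(tab)


class TestSpearmanRestricted:
    def test_identity_correlation(self, rng):
        x = rng.normal(size=40)
        ids = np.repeat([0, 1, 2, 3], 10)
        rho, p = spearman_restricted_perm(x, x, ids, n_perm=200, seed=0)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 201)

    def test_between_recording_confound_not_significant(self, rng):
        # x and y share only recording-level means; no within-recording link
        ids = np.repeat(np.arange(4), 15)
        means = np.array([0.0, 2.0, 4.0, 6.0])
        x = means[ids] + rng.normal(0, 0.5, size=60)
        y = means[ids] + rng.normal(0, 0.5, size=60)
        rho, p = spearman_restricted_perm(x, y, ids, n_perm=300, seed=0)
        assert rho > 0.5  # pooled correlation looks strong...
        assert p > 0.05   # ...but the restricted test sees through it

    def test_misaligned(self, rng):
        with pytest.raises(ParameterError):
            spearman_restricted_perm(rng.normal(size=5), rng.normal(size=6),
                                     np.zeros(5), n_perm=10)


class TestPermTtest:
    def test_clear_difference(self, rng):
        a = rng.normal(2.0, 1.0, 50)
        b = rng.normal(0.0, 1.0, 50)
        t, p = perm_ttest_ind(a, b, n_perm=500, seed=0)
        assert t > 0 and p < 0.01

    def test_no_difference(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        _, p = perm_ttest_ind(a, b, n_perm=200, seed=0)
        assert p > 0.01
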