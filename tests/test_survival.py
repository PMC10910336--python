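"""Cox regression, concordance, time-dependent ROC and Kaplan-Meier."""

import numpy as np
import pytest

from pfradiomics.survival import (c_index_ci, compare_models_permutation,
                                  concordance_index, cox_fit,
                                  cox_score_at_null, km_estimate,
                                  mann_whitney_auc, td_auc, td_roc)


def _two_group_exponential(n=400, hr=2.0, seed=0, censor=3.0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0, n) / np.exp(np.log(hr) * x)
    c = rng.uniform(0, censor, n)
    return x[:, None], np.minimum(t, c), (t <= c).astype(float)


class TestCox:
    def test_score_at_null_matches_closed_form(self):
        X, t, e = _two_group_exponential(n=80, seed=1)
        grad = cox_score_at_null(X, t, e)
        # closed form: events in group 1 minus group-1's share of each
        # risk set, summed over events
        x = X[:, 0]
        expected = 0.0
        for i in np.flatnonzero(e > 0):
            risk = t >= t[i]
            expected += x[i] - x[risk].sum() / risk.sum()
        assert np.isclose(grad[0], expected, atol=1e-10)

    def test_agrees_with_lifelines_on_fixture(self):
        import pandas as pd
        from lifelines import CoxPHFitter
        X, t, e = _two_group_exponential(n=150, seed=2)
        rng = np.random.default_rng(3)
        X = np.column_stack([X[:, 0], rng.normal(0, 1, 150)])
        fit = cox_fit(X, t, e, names=["grp", "z"])
        df = pd.DataFrame({"grp": X[:, 0], "z": X[:, 1], "t": t, "e": e})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        # distinct event times -> Efron and Breslow coincide
        np.testing.assert_allclose(fit.beta,
                                   cph.params_[["grp", "z"]].to_numpy(),
                                   atol=1e-6)
        np.testing.assert_allclose(
            fit.se, cph.standard_errors_[["grp", "z"]].to_numpy(), atol=1e-6)

    def test_loglik_not_worse_than_null(self):
        X, t, e = _two_group_exponential(n=200, seed=4)
        fit = cox_fit(X, t, e)
        # likelihood at the optimum must beat beta = 0
        from pfradiomics.survival import _cox_loglik_grad_hess
        order = np.argsort(-t)
        ll0, _, _ = _cox_loglik_grad_hess(X[order], t[order], e[order],
                                          np.zeros(1))
        assert fit.loglik >= ll0

    def test_degenerate_inputs_error(self):
        X, t, e = _two_group_exponential(n=50, seed=5)
        with pytest.raises(ValueError):
            cox_fit(X, t, np.zeros_like(e))
        with pytest.raises(ValueError):
            cox_fit(np.ones_like(X), t, e)

    def test_hr_recovery_single_replicate(self):
        X, t, e = _two_group_exponential(n=4000, hr=2.0, seed=6)
        fit = cox_fit(X, t, e)
        assert abs(fit.beta[0] - np.log(2.0)) < 0.15
        lo, hi = fit.ci[:, 0]
        assert lo < fit.hr[0] < hi


class TestConcordance:
    def test_perfect_ranking_no_censoring(self):
        t = np.arange(1.0, 21.0)
        score = -t
        assert concordance_index(score, t, np.ones(20)) == 1.0

    def test_uninformative_score_near_half(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(1, 4000)
        s = rng.normal(0, 1, 4000)
        assert abs(concordance_index(s, t, np.ones(4000)) - 0.5) < 0.03

    def test_matches_brute_force_pairs(self, censored_fixture50):
        s, t, e = censored_fixture50
        conc = ties = comp = 0
        for i in range(50):
            for j in range(50):
                if e[i] and t[i] < t[j]:
                    comp += 1
                    if s[i] > s[j]:
                        conc += 1
                    elif s[i] == s[j]:
                        ties += 1
        expected = (conc + 0.5 * ties) / comp
        assert concordance_index(s, t, e) == expected

    def test_negation_flips_c_index(self, censored_fixture50):
        s, t, e = censored_fixture50
        assert np.isclose(concordance_index(s, t, e),
                          1.0 - concordance_index(-s, t, e), atol=1e-12)

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(ValueError):
            concordance_index([1.0, 2.0], [5.0, 5.0], [1, 1])


class TestBootstrapCI:
    def test_perfect_score_degenerate_ci(self):
        t = np.arange(1.0, 31.0)
        lo, hi = c_index_ci(-t, t, np.ones(30), n_boot=100, seed=0)
        assert lo == 1.0 and hi == 1.0

    def test_ci_contains_point_estimate(self, censored_fixture50):
        s, t, e = censored_fixture50
        c = concordance_index(s, t, e)
        lo, hi = c_index_ci(s, t, e, n_boot=400, seed=1)
        assert lo <= c <= hi

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(8)
        widths = {}
        for n in (100, 400, 1600):
            risk = rng.normal(0, 1, n)
            t = rng.exponential(1, n) / np.exp(0.7 * risk)
            lo, hi = c_index_ci(risk, t, np.ones(n), n_boot=300, seed=2)
            widths[n] = hi - lo
        assert widths[400] < widths[100]
        assert widths[1600] < widths[400]


class TestPermutationComparison:
    def test_identical_models_give_moderate_p(self, censored_fixture50):
        s, t, e = censored_fixture50
        p = compare_models_permutation(s, s.copy(), t, e, n_perm=200, seed=0)
        assert 0.2 <= p <= 1.0

    def test_clearly_better_model_is_significant(self):
        rng = np.random.default_rng(9)
        n = 300
        risk = rng.normal(0, 1, n)
        t = rng.exponential(1, n) / np.exp(1.5 * risk)
        e = np.ones(n)
        p = compare_models_permutation(risk, rng.normal(0, 1, n), t, e,
                                       n_perm=1000, seed=1)
        assert p <= 0.01

    def test_p_respects_add_one_bound(self, censored_fixture50):
        s, t, e = censored_fixture50
        p = compare_models_permutation(s, -s, t, e, n_perm=99, seed=2)
        assert 1.0 / 100 <= p <= 1.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            compare_models_permutation([1.0], [1.0, 2.0], [1.0], [1])


class TestTdRoc:
    def test_reduces_to_binary_auc_without_censoring(self):
        rng = np.random.default_rng(10)
        t = rng.uniform(1, 50, 200)
        e = rng.integers(0, 2, 200)
        # horizon beyond every observed time, all subjects uncensored cases
        # or event-free controls
        s = rng.normal(0, 1, 200)
        t2 = np.where(e == 1, t, 100.0)
        auc = td_auc(s, t2, e, 60.0)
        case = e == 1
        assert np.isclose(auc, mann_whitney_auc(s[case], s[~case]))

    def test_perfect_separation_gives_one(self):
        t = np.r_[np.full(10, 10.0), np.full(10, 90.0)]
        e = np.r_[np.ones(10), np.zeros(10)]
        s = np.r_[np.full(10, 5.0), np.full(10, 1.0)]
        assert td_auc(s, t, e, 30.0) == 1.0

    def test_matches_exhaustive_pair_count(self):
        rng = np.random.default_rng(11)
        n = 40
        t = rng.uniform(0, 100, n)
        e = rng.integers(0, 2, n)
        s = rng.normal(0, 1, n)
        horizon = 50.0
        roc, auc, info = td_roc(s, t, e, horizon)
        case = (e == 1) & (t <= horizon)
        ctrl = t > horizon
        num = comp = 0.0
        for i in np.flatnonzero(case):
            for j in np.flatnonzero(ctrl):
                comp += 1
                num += (s[i] > s[j]) + 0.5 * (s[i] == s[j])
        assert auc == num / comp
        assert info["n_excluded_censored"] == int(((~case) & (~ctrl)).sum())

    def test_roc_curve_monotone(self, censored_fixture50):
        s, t, e = censored_fixture50
        roc, auc, _ = td_roc(s, t, e, 30.0)
        assert np.all(np.diff(roc[:, 0]) >= 0)
        assert np.all(np.diff(roc[:, 1]) >= 0)
        assert 0.0 <= auc <= 1.0

    def test_no_cases_errors(self):
        with pytest.raises(ValueError):
            td_roc([1.0, 2.0], [90.0, 95.0], [0, 0], 30.0)


class TestKaplanMeier:
    def test_all_events_closed_form(self):
        curves = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        km = curves[0]
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_hand_product_limit_with_censoring(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])[0]
        np.testing.assert_allclose(km.times, [1.0, 3.0])
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])
        assert km.at(1.5) == pytest.approx(2 / 3)
        assert km.at(0.5) == 1.0

    def test_no_events_flat_curve(self):
        km = km_estimate([5.0, 6.0], [0, 0])[0]
        assert km.times.size == 0
        assert km.at(100.0) == 1.0

    def test_all_event_km_equals_empirical_survival(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(10, 200)
        km = km_estimate(t, np.ones(200))[0]
        for q in (5.0, 10.0, 20.0):
            assert np.isclose(km.at(q), np.mean(t > q), atol=1e-12)

    def test_groups_and_empty_group_error(self):
        curves = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1],
                             ["a", "a", "b", "b"])
        assert set(curves) == {"a", "b"}
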