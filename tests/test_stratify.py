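"""Risk-score fusion, Youden thresholds, progression classes, confusion."""

import numpy as np
import pandas as pd
import pytest

from pfradiomics import stratify
from pfradiomics.stratify import (FAST, HIGH, INDET, LOW, MEDIUM, NON, SLOW,
                                  RiskStrata, classify, confusion_and_ppv,
                                  fit_risk_score, optimize_thresholds,
                                  progression_labels, youden_best_cutpoint)


def test_progression_label_boundaries():
    t = np.array([30.0, 30.1, 84.0, 84.0, 90.0, 50.0, 85.0])
    e = np.array([1, 1, 1, 0, 0, 0, 1])
    lab = progression_labels(t, e)
    assert list(lab) == [FAST, SLOW, SLOW, NON, NON, INDET, NON]


def _cohort_table(n, rng, radscore_signal=True):
    s = rng.uniform(0, 1, n)
    klg = np.clip(np.round(s * 4 + rng.normal(0, 0.8, n)), 0, 4)
    lam = np.exp(-6.5 + 1.8 * s + 0.4 * klg)
    t = rng.exponential(1, n) / lam
    c = rng.uniform(60, 100, n)
    df = pd.DataFrame({
        "age": rng.uniform(50, 79, n),
        "gender": rng.integers(0, 2, n).astype(float),
        "bmi": rng.normal(30, 5, n),
        "klg": klg,
        "pfoa": (s > 0.7).astype(float),
        "kr_event": (t <= c).astype(int),
        "kr_time_months": np.minimum(t, c),
    })
    rs = s + rng.normal(0, 0.3, n) if radscore_signal \
        else rng.normal(0, 1, n)
    return df, rs


class TestFitRiskScore:
    def test_planted_radscore_is_retained(self):
        # generator study conditions; RadScore proxied by severity + noise
        from pfradiomics import synthdata
        retained = 0
        for seed in range(5):
            cfg = synthdata.SimulationConfig(n_subjects=1000, seed=500 + seed)
            df, s = synthdata.simulate_table(cfg)
            rng = np.random.default_rng(900 + seed)
            rs = s + rng.normal(0, 0.25, len(s))
            model = fit_risk_score(df, rs)
            retained += "radscore" in model.retained
        assert retained >= 4

    def test_fallback_to_radscore_klg_when_nothing_significant(self):
        rng = np.random.default_rng(20)
        df, rs = _cohort_table(300, rng, radscore_signal=False)
        model = fit_risk_score(df, rs, p_threshold=1e-12)
        assert model.fallback_used
        assert model.retained == ["radscore", "klg"]

    def test_linear_predictor_uses_training_standardization(self):
        rng = np.random.default_rng(21)
        df, rs = _cohort_table(500, rng)
        model = fit_risk_score(df, rs)
        df2 = df.copy()
        df2["radscore"] = rs
        lp = model.linear_predictor(df2)
        assert lp.shape == (500,)
        assert np.all(np.isfinite(lp))


class TestThresholds:
    def test_separated_clusters_thresholds_fall_between(self):
        scores = np.r_[np.random.default_rng(0).normal(0, 0.1, 30),
                       np.random.default_rng(1).normal(2, 0.1, 30),
                       np.random.default_rng(2).normal(4, 0.1, 30)]
        labels = np.array([NON] * 30 + [SLOW] * 30 + [FAST] * 30,
                          dtype=object)
        strata = optimize_thresholds(scores, labels)
        assert 0.5 < strata.t_low < 1.5
        assert 2.5 < strata.t_high < 3.5

    def test_youden_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(0, 1, 120)
        positive = rng.random(120) < 0.4
        uniq = np.sort(np.unique(scores))
        candidates = (uniq[:-1] + uniq[1:]) / 2
        cut, j = youden_best_cutpoint(scores, positive, candidates)
        best_j, best_cut = -np.inf, None
        for c in candidates:
            pred = scores >= c
            sens = (pred & positive).sum() / positive.sum()
            spec = ((~pred) & (~positive)).sum() / (~positive).sum()
            if sens + spec - 1 > best_j + 1e-12:
                best_j, best_cut = sens + spec - 1, c
        assert cut == best_cut
        assert np.isclose(j, best_j)

    def test_monotone_transform_preserves_assignments(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(0, 1, 90)
        labels = np.array([NON] * 40 + [SLOW] * 30 + [FAST] * 20,
                          dtype=object)
        rng.shuffle(labels)
        strata1 = optimize_thresholds(scores, labels)
        warped = np.exp(scores)
        strata2 = optimize_thresholds(warped, labels)
        np.testing.assert_array_equal(classify(scores, strata1),
                                      classify(warped, strata2))

    def test_missing_class_errors(self):
        with pytest.raises(ValueError, match="fast"):
            optimize_thresholds(np.arange(10.0),
                                np.array([NON] * 5 + [SLOW] * 5, dtype=object))


class TestClassify:
    def test_boundary_rules(self):
        strata = RiskStrata(1.0, 2.0)
        out = classify(np.array([0.5, 1.0, 1.5, 2.0, 3.0]), strata)
        assert list(out) == [LOW, MEDIUM, MEDIUM, HIGH, HIGH]

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(5)
        out = classify(rng.normal(0, 1, 250), RiskStrata(-0.5, 0.5))
        assert sum((out == c).sum() for c in (LOW, MEDIUM, HIGH)) == 250


class TestConfusion:
    def test_perfect_classifier_is_diagonal(self):
        labels = np.array([NON] * 10 + [SLOW] * 6 + [FAST] * 4, dtype=object)
        pred = np.array([LOW] * 10 + [MEDIUM] * 6 + [HIGH] * 4, dtype=object)
        out = confusion_and_ppv(pred, labels)
        np.testing.assert_array_equal(out["matrix"],
                                      np.diag([10, 6, 4]))
        assert out["ppv_high_any_progression"] == 1.0
        assert out["ppv_high_fast_progression"] == 1.0

    def test_no_high_predictions_gives_unavailable_ppv(self):
        labels = np.array([NON, SLOW, FAST], dtype=object)
        pred = np.array([LOW, LOW, LOW], dtype=object)
        out = confusion_and_ppv(pred, labels)
        assert out["ppv_high_any_progression"] is None
        assert out["matrix"].sum() == 3

    def test_indeterminate_excluded_and_counted(self):
        labels = np.array([NON, INDET, FAST, INDET], dtype=object)
        pred = np.array([LOW, LOW, HIGH, HIGH], dtype=object)
        out = confusion_and_ppv(pred, labels)
        assert out["n_indeterminate_excluded"] == 2
        assert out["matrix"].sum() == 2


def test_refit_on_retained_preserves_full_model_ranking():
    # when the dropped covariates are pure noise, the reduced model's risk
    # ordering matches the full model's almost exactly
    from pfradiomics import synthdata
    from pfradiomics.survival import cox_fit
    cfg = synthdata.SimulationConfig(n_subjects=1200, seed=77)
    df, s = synthdata.simulate_table(cfg)
    rng = np.random.default_rng(78)
    rs = s + rng.normal(0, 0.25, len(s))
    model = fit_risk_score(df, rs)
    dfx = df.copy()
    dfx["radscore"] = rs
    dfx["gender"] = (dfx["gender"] == "male").astype(float)
    reduced = model.linear_predictor(dfx)
    full_cols = ["radscore", "age", "gender", "bmi", "klg"]
    z = (rs - rs.mean()) / rs.std()
    X = np.column_stack([z] + [dfx[c].to_numpy(float) for c in full_cols[1:]])
    full = cox_fit(X, df.kr_time_months.to_numpy(),
                   df.kr_event.to_numpy(), names=full_cols)
    lp_full = X @ full.beta
    rho = np.corrcoef(np.argsort(np.argsort(reduced)),
                      np.argsort(np.argsort(lp_full)))[0, 1]
    assert rho > 0.95
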