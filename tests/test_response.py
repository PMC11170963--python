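import numpy as np
import pandas as pd
import pytest

from microshift.response import (
    arm_response_dataset,
    count_significant_features,
    elasticnet_variance_explained,
    gee_longitudinal,
    partial_spearman_screen,
    percent_change,
    responder_logistic,
    stratify_responders,
)


class TestPercentChange:
    def test_examples(self):
        assert percent_change(8.0, 6.0) == pytest.approx(-25.0)
        assert percent_change(5.0, 5.0) == 0.0
        # cohort-mean HbA1c 8.20 -> 6.36 corresponds to a -22.44% change
        assert percent_change(8.20, 6.36) == pytest.approx(-22.44, abs=0.01)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestStratifyResponders:
    def test_even_split(self):
        resp = pd.Series([-30.0, -20, -10, 0], index=list("abcd"))
        cls = stratify_responders(resp)
        assert set(cls[cls == "HR"].index) == {"a", "b"}
        assert set(cls[cls == "LR"].index) == {"c", "d"}

    def test_odd_n_median_subject_goes_low(self):
        resp = pd.Series([-40.0, -30, -20, -10, 0], index=list("abcde"))
        cls = stratify_responders(resp)
        assert (cls == "HR").sum() == 2 and (cls == "LR").sum() == 3
        assert cls["c"] == "LR"

    def test_duplicate_median_values_deterministic(self):
        resp = pd.Series([-10.0, -5, -5, 0], index=list("abcd"))
        cls = stratify_responders(resp)
        assert cls["b"] == "LR" and cls["c"] == "LR"
        assert (cls == "HR").sum() + (cls == "LR").sum() == 4

    def test_order_invariance(self, rng):
        resp = pd.Series(rng.normal(0, 10, 20), index=[f"s{i}" for i in range(20)])
        shuffled = resp.sample(frac=1, random_state=1)
        a, b = stratify_responders(resp), stratify_responders(shuffled)
        assert (a.sort_index() == b.sort_index()).all()

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            stratify_responders(pd.Series([1.0, 1.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            stratify_responders(pd.Series([1.0, 2.0, 3.0]))


class TestPartialSpearman:
    def test_monotone_signal_detected(self):
        r = np.random.default_rng(2)
        f = r.standard_normal(200)
        resp = pd.Series(np.exp(f) + 0.1 * r.standard_normal(200))
        cov = pd.DataFrame({"a": r.standard_normal(200), "b": r.standard_normal(200)})
        out = partial_spearman_screen(pd.DataFrame({"f": f}), resp, cov)
        assert out.loc[0, "partial_rho"] >= 0.95
        assert bool(out.loc[0, "significant"])

    def test_full_mediation_leaves_no_association(self):
        r = np.random.default_rng(0)
        c = r.standard_normal(500)
        feats = pd.DataFrame({"f": 2 * c + 0.5 * r.standard_normal(500)})
        resp = pd.Series(3 * c + 0.5 * r.standard_normal(500))
        out = partial_spearman_screen(feats, resp, pd.DataFrame({"c": c}))
        assert abs(out.loc[0, "partial_rho"]) < 0.1
        assert not bool(out.loc[0, "significant"])

    def test_null_features_rarely_flagged(self):
        flagged = 0
        for s in range(40):
            r = np.random.default_rng(1000 + s)
            feats = pd.DataFrame({"f": r.standard_normal(80)})
            resp = pd.Series(r.standard_normal(80))
            out = partial_spearman_screen(feats, resp)
            flagged += int(out.loc[0, "significant"])
        assert flagged / 40 <= 0.05

    def test_constant_feature_excluded(self):
        r = np.random.default_rng(1)
        feats = pd.DataFrame({"f": np.ones(30), "g": r.standard_normal(30)})
        out = partial_spearman_screen(feats, pd.Series(r.standard_normal(30)))
        assert bool(out.set_index("feature_id").loc["f", "excluded"])

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        r = np.random.default_rng(5)
        c = r.standard_normal(120)
        x = c + r.standard_normal(120)
        y = 0.5 * c + r.standard_normal(120)
        ours = partial_spearman_screen(pd.DataFrame({"x": x}), pd.Series(y),
                                       pd.DataFrame({"c": c}))
        theirs = pg.partial_corr(pd.DataFrame({"x": x, "y": y, "c": c}),
                                 x="x", y="y", covar="c", method="spearman")
        assert ours.loc[0, "partial_rho"] == pytest.approx(theirs["r"].iloc[0], abs=1e-9)
        assert ours.loc[0, "p"] == pytest.approx(theirs["p_val"].iloc[0], abs=1e-9)

    def test_count_significant(self):
        df = pd.DataFrame({"feature_id": list("abc"),
                           "significant": [True, False, True]})
        assert count_significant_features(df) == 2
        assert count_significant_features(df.iloc[:0]) == 0


class TestElasticNet:
    def test_response_equal_to_one_feature(self):
        r = np.random.default_rng(0)
        X = r.standard_normal((50, 10))
        feats = pd.DataFrame(X, columns=[f"f{i}" for i in range(10)])
        res = elasticnet_variance_explained(feats, pd.Series(X[:, 0]), seed=0)
        assert "f0" in res.selected_features
        assert res.r_squared >= 0.99

    def test_pure_noise_low_r2(self):
        r = np.random.default_rng(1)
        feats = pd.DataFrame(r.standard_normal((200, 50)),
                             columns=[f"f{i}" for i in range(50)])
        res = elasticnet_variance_explained(feats, pd.Series(r.standard_normal(200)), seed=0)
        assert res.r_squared <= 0.1

    def test_fold_count_validated(self):
        r = np.random.default_rng(2)
        feats = pd.DataFrame(r.standard_normal((25, 5)))
        with pytest.raises(ValueError, match="cv_folds"):
            elasticnet_variance_explained(feats, pd.Series(r.standard_normal(25)),
                                          cv_folds=30, seed=0)

    def test_deterministic_given_seed(self):
        r = np.random.default_rng(3)
        X = r.standard_normal((60, 20))
        y = pd.Series(X[:, 0] + 0.5 * r.standard_normal(60))
        feats = pd.DataFrame(X, columns=[f"f{i}" for i in range(20)])
        a = elasticnet_variance_explained(feats, y, seed=7)
        b = elasticnet_variance_explained(feats, y, seed=7)
        assert a.selected_features == b.selected_features
        assert a.r_squared == b.r_squared


class TestResponderLogistic:
    def test_two_by_two_collapse_cross_product(self):
        x = pd.Series([1.0] * 10 + [0.0] * 5 + [1.0] * 5 + [0.0] * 10, name="b")
        cls = pd.Series(["HR"] * 15 + ["LR"] * 15, index=x.index)
        res = responder_logistic(x, cls, standardize=False)
        assert res.odds_ratio == pytest.approx(4.0, abs=1e-6)  # (10*10)/(5*5)
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    def test_perfect_separation_flagged(self):
        x = pd.Series(np.r_[np.ones(10), np.zeros(10)], name="s")
        cls = pd.Series(["HR"] * 10 + ["LR"] * 10, index=x.index)
        assert responder_logistic(x, cls).separated

    def test_null_feature_ci_covers_one(self):
        r = np.random.default_rng(0)
        x = pd.Series(r.standard_normal(80), name="f")
        cls = stratify_responders(pd.Series(r.standard_normal(80)))
        res = responder_logistic(x, cls)
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_degenerate_inputs_rejected(self):
        cls = pd.Series(["HR"] * 5 + ["LR"] * 5)
        with pytest.raises(ValueError, match="variance"):
            responder_logistic(pd.Series(np.ones(10)), cls)
        with pytest.raises(ValueError, match="non-empty"):
            responder_logistic(pd.Series(np.arange(10.0)), pd.Series(["HR"] * 10))


class TestGee:
    def test_singleton_clusters_reduce_to_ols(self):
        import statsmodels.api as sm

        r = np.random.default_rng(3)
        x = pd.Series(r.standard_normal(50), name="f")
        y = pd.Series(2 * x.to_numpy() + r.standard_normal(50))
        subjects = pd.Series([f"s{i}" for i in range(50)], index=x.index)
        gee = gee_longitudinal(x, y, subjects)
        ols = sm.OLS(y.to_numpy(), sm.add_constant(x.to_numpy())).fit()
        assert gee.coefficient == pytest.approx(ols.params[1], abs=1e-6)

    def test_planted_within_subject_association_sign(self):
        recovered = 0
        for s in range(20):
            r = np.random.default_rng(500 + s)
            n_subj, n_t = 30, 3
            subj = np.repeat([f"s{i}" for i in range(n_subj)], n_t)
            x = r.standard_normal(n_subj * n_t)
            subj_int = np.repeat(r.standard_normal(n_subj), n_t)
            y = subj_int - 0.8 * x + 0.5 * r.standard_normal(n_subj * n_t)
            res = gee_longitudinal(pd.Series(x, name="f"), pd.Series(y), pd.Series(subj))
            recovered += int(res.coefficient < 0)
        assert recovered / 20 >= 0.95

    def test_zero_variance_feature_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            gee_longitudinal(pd.Series(np.ones(10), name="f"),
                             pd.Series(np.arange(10.0)),
                             pd.Series([f"s{i}" for i in range(10)]))


class TestArmResponseDataset:
    def test_assembles_baseline_features_and_percent_change(self):
        from microshift.synthetic import SyntheticConfig, ArmEffect, simulate_cohort

        cfg = SyntheticConfig(n_subjects=24, n_species=30, seed=0,
                              arm_effects={"drug": ArmEffect(0.1, 1.0)})
        species, _, meta, _ = simulate_cohort(cfg)
        feats, resp, cov, dropped = arm_response_dataset(species, meta, "drug",
                                                         "hba1c", 90)
        assert len(feats) == len(resp) == len(cov) == 24 - dropped
        assert set(cov.columns) == {"age", "sex", "bmi", "baseline_hba1c"}
        subj = resp.index[0]
        pre = meta.clinical_value(subj, "hba1c", 0)
        post = meta.clinical_value(subj, "hba1c", 90)
        assert resp[subj] == pytest.approx(percent_change(pre, post))
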