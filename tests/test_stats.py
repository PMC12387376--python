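"""Statistical stage: test selection, logistic fits, ROC/DeLong."""

import numpy as np
import pandas as pd
import pytest

from respcomplex.stats import (
    adjusted_logistic,
    combined_model,
    compare_groups,
    roc_analysis,
    univariate_logistic,
)


def _expit(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestCompareGroups:
    def test_normal_groups_use_t_test_with_power(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "x": np.concatenate(
                    [rng.normal(0, 1, 50), rng.normal(1, 1, 50)]
                ),
                "pc_label": [0] * 50 + [1] * 50,
            }
        )
        res = compare_groups(df, "x")
        assert res.test == "t"
        assert res.p_value < 1e-3

    def test_skewed_groups_use_mann_whitney(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "x": rng.lognormal(0, 1.5, 120),
                "pc_label": [0] * 60 + [1] * 60,
            }
        )
        assert compare_groups(df, "x").test == "mann-whitney"

    def test_sparse_2x2_table_uses_fisher(self):
        df = pd.DataFrame(
            {
                "x": ["yes"] * 3 + ["no"] * 12 + ["no"] * 15,
                "pc_label": [0] * 15 + [1] * 15,
            }
        )
        assert compare_groups(df, "x").test == "fisher"

    def test_null_type_i_error_calibrated(self):
        rejections = 0
        n_rep = 300
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            df = pd.DataFrame(
                {
                    "x": rng.standard_normal(40),
                    "pc_label": [0] * 20 + [1] * 20,
                }
            )
            rejections += compare_groups(df, "x").p_value < 0.05
        assert 0.015 <= rejections / n_rep <= 0.10

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "pc_label": [0, 0, 0]})
        with pytest.raises(ValueError):
            compare_groups(df, "x")


class TestLogistic:
    def test_null_variable_ci_contains_one(self):
        rng = np.random.default_rng(2)
        n = 3000
        df = pd.DataFrame(
            {"x": rng.standard_normal(n), "pc_label": rng.integers(0, 2, n)}
        )
        res = univariate_logistic(df, "x")
        assert res.ci_low < 1.0 < res.ci_high

    def test_known_slope_recovered_within_ten_percent(self):
        rng = np.random.default_rng(3)
        n = 2000
        x = rng.standard_normal(n)
        y = rng.uniform(size=n) < _expit(-0.2 + 0.7 * x)
        df = pd.DataFrame({"x": x, "pc_label": y.astype(int)})
        res = univariate_logistic(df, "x")
        assert res.coef == pytest.approx(0.7, rel=0.10)
        assert res.ci_low < np.exp(0.7) < res.ci_high

    def test_wald_ci_coverage_near_nominal(self):
        hits = 0
        n_rep = 120
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            x = rng.standard_normal(800)
            y = rng.uniform(size=800) < _expit(0.5 * x)
            df = pd.DataFrame({"x": x, "pc_label": y.astype(int)})
            res = univariate_logistic(df, "x")
            hits += res.ci_low <= np.exp(0.5) <= res.ci_high
        assert 0.88 <= hits / n_rep <= 1.0

    def test_perfect_separation_flagged(self):
        df = pd.DataFrame(
            {"x": np.arange(20.0), "pc_label": [0] * 10 + [1] * 10}
        )
        res = univariate_logistic(df, "x")
        assert any("separation" in f or "non_converged" in f for f in res.flags)

    def test_invalid_model_id_rejected(self):
        df = pd.DataFrame(
            {
                "x": np.arange(10.0),
                "age": 60.0,
                "sex": "male",
                "pc_label": [0, 1] * 5,
            }
        )
        with pytest.raises(ValueError, match="model_id"):
            adjusted_logistic(df, "x", 6)

    def test_independent_covariates_leave_or_unchanged(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.standard_normal(n)
        y = rng.uniform(size=n) < _expit(0.6 * x)
        df = pd.DataFrame(
            {
                "x": x,
                "age": rng.normal(60, 10, n),
                "sex": rng.choice(["male", "female"], n),
                "pc_label": y.astype(int),
            }
        )
        unadj = univariate_logistic(df, "x")
        adj = adjusted_logistic(df, "x", 1)
        assert adj.coef == pytest.approx(unadj.coef, abs=0.1)

    def test_confounder_adjustment_attenuates_toward_direct_effect(self):
        # z drives both x and the outcome; adjusting for z should pull the
        # x coefficient from the confounded value toward its direct effect
        rng = np.random.default_rng(5)
        n = 4000
        z = rng.standard_normal(n)
        x = z + rng.standard_normal(n)
        direct = 0.3
        y = rng.uniform(size=n) < _expit(direct * x + 1.0 * z)
        df = pd.DataFrame(
            {
                "x": x,
                "age": z,  # confounder enters via the model-1 covariate slot
                "sex": "male",
                "pc_label": y.astype(int),
            }
        )
        unadj = univariate_logistic(df, "x").coef
        adj = adjusted_logistic(df, "x", 1).coef
        assert unadj > adj
        assert adj == pytest.approx(direct, abs=0.12)


class TestCombinedModel:
    def _cohort(self, n, seed, signal=True):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "dbp": rng.normal(75, 12, n),
                "log_ntprobnp": rng.normal(3.7, 0.4, n),
                "nyha_iv": rng.integers(0, 2, n).astype(float),
                "mean_TE_ratio": rng.normal(58, 3, n),
                "RA_area_1_5": rng.normal(3.5, 1.3, n),
                "RA_area_6_20": rng.normal(10, 4, n),
            }
        )
        if signal:
            z = (
                -0.05 * (df["dbp"] - 75)
                + 0.8 * (df["log_ntprobnp"] - 3.7)
                + 0.25 * (df["mean_TE_ratio"] - 58)
                + 0.6 * (df["RA_area_1_5"] - 3.5)
            )
        else:
            z = pd.Series(np.zeros(n))
        df["pc_label"] = (rng.uniform(size=n) < _expit(z.to_numpy())).astype(int)
        return df

    def test_in_sample_auc_dominates_single_terms(self):
        df = self._cohort(60, seed=6)
        results, probs = combined_model(df)
        combined_auc = roc_analysis(probs, df["pc_label"]).auc
        for term in ["dbp", "log_ntprobnp", "mean_TE_ratio", "RA_area_1_5"]:
            single = roc_analysis(df[term], df["pc_label"]).auc
            assert combined_auc >= max(single, 1 - single) - 1e-9

    def test_pure_noise_model_near_half_out_of_sample(self):
        train = self._cohort(500, seed=7, signal=False)
        test = self._cohort(500, seed=8, signal=False)
        import statsmodels.api as sm

        results, _ = combined_model(train)
        # score the held-out replicate with the fitted coefficients
        coefs = {r.term: r.coef for r in results}
        z = sum(coefs[t] * test[t] for t in coefs)
        auc = roc_analysis(z, test["pc_label"]).auc
        assert abs(auc - 0.5) < 0.1

    def test_duplicated_predictor_flagged(self):
        df = self._cohort(80, seed=9)
        df["dup"] = df["RA_area_1_5"]
        results, _ = combined_model(df, terms=["RA_area_1_5", "dup"])
        assert any(
            "rank_deficient" in r.flags or "separation" in "".join(r.flags)
            for r in results
        )


class TestROC:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 4], [0, 0, 1, 1])
        assert res.auc == pytest.approx(1.0)
        assert res.sensitivity_pct == pytest.approx(100.0)
        assert res.specificity_pct == pytest.approx(100.0)

    def test_all_tied_scores_give_half(self):
        assert roc_analysis([5, 5, 5, 5], [0, 1, 0, 1]).auc == pytest.approx(0.5)

    def test_interleaved_example_matches_pair_counting(self):
        res = roc_analysis([1, 2, 3, 4, 5, 6], [0, 1, 0, 1, 0, 1])
        assert res.auc == pytest.approx(6 / 9)

    def test_auc_equals_exhaustive_pair_statistic(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            n = int(rng.integers(8, 40))
            scores = np.round(rng.standard_normal(n), 1)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert roc_analysis(scores, labels).auc == pytest.approx(expected)

    def test_label_flip_antisymmetry(self):
        rng = np.random.default_rng(11)
        scores = rng.standard_normal(50)
        labels = rng.integers(0, 2, 50)
        a = roc_analysis(scores, labels).auc
        b = roc_analysis(scores, 1 - labels).auc
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            roc_analysis([1, 2, 3], [1, 1, 1])

    def test_delong_interval_behaves(self):
        rng = np.random.default_rng(12)
        scores = np.concatenate([rng.normal(0, 1, 60), rng.normal(1.5, 1, 60)])
        labels = np.array([0] * 60 + [1] * 60)
        res = roc_analysis(scores, labels)
        assert res.ci_low < res.auc < res.ci_high
        assert res.p_value < 0.001  # clearly better than chance
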