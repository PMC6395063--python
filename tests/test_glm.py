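"""Regression recipes, group tests, permutation correction, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from entroscope import glm, synthetic


class TestBuildDesign:
    def test_glm4_columns(self, small_subject_data):
        sub = small_subject_data
        X = glm.build_design("GLM4", sub["labeled"], sub["beliefs"])
        bias_cols = [c for c in X.columns if c.startswith("bias_run")]
        assert len(bias_cols) == 4
        assert "entropy" in X.columns

    def test_glm8_includes_global_mean(self, small_subject_data):
        sub = small_subject_data
        n = len(sub["trials"])
        rng = np.random.default_rng(0)
        X = glm.build_design(
            "GLM8", sub["labeled"], sub["beliefs"],
            extra_series={"signal": rng.standard_normal(n),
                          "global_mean": rng.standard_normal(n)},
        )
        assert "global_mean" in X.columns and "signal" in X.columns

    def test_glm2_transition_indicators(self, small_subject_data):
        sub = small_subject_data
        X = glm.build_design("GLM2", sub["labeled"], sub["beliefs"])
        for col in ("reward", "switch_next", "last_exploit", "first_exploit"):
            assert set(np.unique(X[col])) <= {0.0, 1.0}
        # a last-exploit trial is followed by an explore trial in the same run
        lab = sub["labeled"]
        idx = np.where(X["last_exploit"].to_numpy() == 1)[0]
        assert (lab["phase"].to_numpy()[idx] == "exploit").all()
        assert (lab["phase"].to_numpy()[idx + 1] == "explore").all()

    def test_unknown_recipe_rejected(self, small_subject_data):
        with pytest.raises(ValueError, match="unknown recipe"):
            glm.build_design("GLM9", small_subject_data["labeled"], None)

    def test_rank_deficiency_detected(self, small_subject_data):
        sub = small_subject_data
        beliefs = sub["beliefs"].copy()
        beliefs["entropy"] = 1.0  # constant, collinear with the bias columns
        with pytest.raises(ValueError, match="rank deficient"):
            glm.build_design("GLM4", sub["labeled"], beliefs)


class TestFitOLS:
    def test_noiseless_line_recovered_exactly(self):
        x = np.arange(10, dtype=float)
        X = pd.DataFrame({"bias": np.ones(10), "x": x})
        fit = glm.fit_ols(X, 1.0 + 2.0 * x)
        np.testing.assert_allclose(fit["beta"], [1.0, 2.0], atol=1e-10)

    def test_five_point_fixture_matches_closed_form(self):
        """Classical SE formulas on a tiny fixture agree with the fit."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 3.9, 6.2, 7.8, 10.1])
        X = pd.DataFrame({"bias": np.ones(5), "x": x})
        fit = glm.fit_ols(X, y).set_index("regressor")
        # closed-form simple regression
        b1 = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        b0 = y.mean() - b1 * x.mean()
        resid = y - b0 - b1 * x
        s2 = (resid**2).sum() / 3
        se1 = np.sqrt(s2 / ((x - x.mean()) ** 2).sum())
        assert fit.loc["x", "beta"] == pytest.approx(b1, abs=1e-12)
        assert fit.loc["x", "se"] == pytest.approx(se1, abs=1e-12)
        assert fit.loc["x", "t"] == pytest.approx(b1 / se1, abs=1e-9)

    def test_underdetermined_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((3, 4)))
        with pytest.raises(ValueError):
            glm.fit_ols(X, np.zeros(3))


class TestGroupTTest:
    def test_zero_betas(self):
        res = glm.group_ttest(np.zeros(10))
        assert res.t == 0.0 and res.p == 1.0 and res.df == 9

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            glm.group_ttest(np.array([1.0]))

    def test_power_matches_noncentral_t_prediction(self):
        """Empirical one-sample power over 2000 simulated cohorts matches the
        noncentral-t closed form within Monte-Carlo error."""
        rng = np.random.default_rng(6)
        n, mu = 19, 0.5
        n_sim = 2000
        betas = rng.normal(mu, 1.0, size=(n_sim, n))
        tvals = betas.mean(axis=1) / (betas.std(axis=1, ddof=1) / np.sqrt(n))
        tcrit = stats.t.ppf(0.975, n - 1)
        empirical = np.mean(np.abs(tvals) > tcrit)
        ncp = mu * np.sqrt(n)
        predicted = (1 - stats.nct.cdf(tcrit, n - 1, ncp)) + stats.nct.cdf(-tcrit, n - 1, ncp)
        assert abs(empirical - predicted) < 3 * np.sqrt(predicted * (1 - predicted) / n_sim)


class TestSampleSize:
    def test_monotonicity(self):
        assert glm.sample_size_t(0.5) >= glm.sample_size_t(1.0) >= glm.sample_size_t(2.0)
        assert glm.sample_size_t(0.89, power=0.9) >= glm.sample_size_t(0.89, power=0.8)

    def test_cross_checked_against_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower

        for d in (0.6, 0.89, 1.3):
            ours = glm.sample_size_t(d)
            ref = TTestIndPower().solve_power(effect_size=d, alpha=0.05, power=0.8,
                                              alternative="larger")
            assert ours == int(np.ceil(ref))

    def test_invalid_inputs(self):
        for bad in (dict(d=-1), dict(d=0.5, alpha=0.0), dict(d=0.5, power=0.3)):
            with pytest.raises(ValueError):
                glm.sample_size_t(**bad)


class TestMedianSplit:
    @staticmethod
    def subject(rng, slope=0.0, n=120):
        dpup_inc = rng.standard_normal(n)
        rs = np.cumsum(slope * dpup_inc + rng.standard_normal(n) * 0.5)
        pup = np.cumsum(dpup_inc)
        return {
            "rs": rs, "pupil_baseline": pup,
            "entropy": rng.standard_normal(n) * 0.01 + 1.0,
            "run": np.zeros(n, int), "outcome": np.zeros(n, int),
            "core_exploit": np.ones(n, bool),
        }

    def test_negative_coupling_detected(self):
        rng = np.random.default_rng(8)
        cohort = [self.subject(rng, slope=-0.8) for _ in range(12)]
        res = glm.median_split_contrast(cohort)
        assert res.mean < 0 and res.p < 0.05

    def test_null_centred(self):
        rng = np.random.default_rng(9)
        tvals = [glm.median_split_contrast([self.subject(rng) for _ in range(8)]).t
                 for _ in range(40)]
        assert abs(np.mean(tvals)) < 0.5

    def test_constant_pupil_rejected(self):
        rng = np.random.default_rng(10)
        sub = self.subject(rng)
        sub["pupil_baseline"] = np.ones(120)
        with pytest.raises(ValueError, match="identical"):
            glm.median_split_contrast([sub])

    def test_median_tie_goes_to_lower_half(self):
        """Odd trial counts put the median-valued trial in the lower half."""
        rng = np.random.default_rng(11)
        sub = self.subject(rng, slope=-1.0, n=121)
        res = glm.median_split_contrast([sub, self.subject(rng, slope=-1.0, n=121)])
        assert np.isfinite(res.mean)


class TestClusterMass:
    def test_no_suprathreshold_voxels_empty_result(self):
        rng = np.random.default_rng(12)
        vols = rng.standard_normal((10, 6, 6, 6)) * 0.01
        res = glm.cluster_mass_correction(vols, n_perm=50, rng=rng)
        assert res["clusters"] == []

    def test_planted_cluster_survives(self):
        rng = np.random.default_rng(13)
        vols = rng.standard_normal((19, 10, 10, 10))
        vols[:, 3:7, 3:7, 3:7] += 1.5
        res = glm.cluster_mass_correction(vols, n_perm=200, rng=rng)
        surviving = [c for c in res["clusters"] if c["survives"]]
        assert len(surviving) >= 1
        assert max(c["size"] for c in surviving) >= 30

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            glm.cluster_mass_correction(np.zeros((4, 5, 5, 5)), n_perm=10)


class TestUnivariateCouplings:
    def test_glm7_recovers_entropy_change_coupling(self, small_subject_data):
        """Planted signal = b * dEntropy is recovered within 2 SE (GLM7)."""
        sub = small_subject_data
        rng = np.random.default_rng(14)
        run = sub["trials"]["run"].to_numpy()
        b_true = 1.3
        sig = synthetic.generate_univariate_signal(sub["beliefs"], b_true, 0.3, rng, run=run)
        X = glm.build_design("GLM7", sub["labeled"], sub["beliefs"])
        fit = glm.fit_ols(X, sig).set_index("regressor")
        assert abs(fit.loc["delta_entropy", "beta"] - b_true) < 2 * fit.loc["delta_entropy", "se"]

    def test_glm8_global_mean_absorbs_shared_variation(self, small_subject_data):
        """A global arousal component present in both the voxel signal and the
        pupil change loads on the global-mean column, leaving the specific
        signal -> pupil coupling estimable."""
        sub = small_subject_data
        rng = np.random.default_rng(15)
        n = len(sub["trials"])
        global_arousal = rng.standard_normal(n)
        specific = rng.standard_normal(n)
        signal = specific + global_arousal
        dpup = 0.8 * specific + 1.5 * global_arousal + rng.standard_normal(n) * 0.2
        X = glm.build_design(
            "GLM8", sub["labeled"], sub["beliefs"],
            extra_series={"signal": signal, "global_mean": global_arousal},
        )
        fit = glm.fit_ols(X, dpup).set_index("regressor")
        assert abs(fit.loc["signal", "beta"] - 0.8) < 2 * fit.loc["signal", "se"]
        assert fit.loc["global_mean", "t"] > 5


class TestDeltaCoupling:
    @staticmethod
    def null_subject(rng, n=200):
        return {
            "rs": rng.standard_normal(n),
            "pupil_baseline": rng.standard_normal(n),
            "entropy": rng.standard_normal(n) * 0.2 + 1.0,
            "run": np.zeros(n, int),
            "outcome": rng.integers(0, 2, n),
            "core_exploit": np.ones(n, bool),
        }

    def test_too_few_trials_excludes_subject(self):
        rng = np.random.default_rng(16)
        subs = [self.null_subject(rng) for _ in range(4)]
        tiny = self.null_subject(rng, n=6)
        res = glm.delta_coupling_regression(subs + [tiny])
        assert res["excluded_subjects"] == [4]

    def test_null_rejection_rate_near_nominal(self):
        """No planted coupling: the unrewarded-split group test rejects at
        about the nominal 5% over simulated null cohorts."""
        rng = np.random.default_rng(17)
        n_cohorts, rej = 300, 0
        for _ in range(n_cohorts):
            cohort = [self.null_subject(rng, n=120) for _ in range(10)]
            res = glm.delta_coupling_regression(cohort)
            rej += res["unrewarded"].p < 0.05
        rate = rej / n_cohorts
        se = np.sqrt(0.05 * 0.95 / n_cohorts)
        assert rate < 0.05 + 4 * se
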