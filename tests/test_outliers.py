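import numpy as np
import pandas as pd
import pytest

from fieldhtp.outliers import (
    ModelError,
    ModelSpec,
    attitude_filter,
    fit_trait_model,
    plot_means,
    remove_outliers,
    studentized_deleted_residuals,
)
from oracles import loo_studentized_residuals


def _one_way(groups, values):
    return pd.DataFrame({"plot_id": groups, "value": values})


class TestFit:
    def test_single_factor_fits_plot_means(self):
        rng = np.random.default_rng(0)
        df = _one_way(np.repeat(["a", "b", "c"], 10), rng.normal(30, 1, 30))
        fit = fit_trait_model(df, ModelSpec())
        expected = df.groupby("plot_id")["value"].transform("mean").to_numpy()
        assert np.allclose(fit.fitted, expected)
        assert fit.p == 3

    def test_balanced_two_plot_coefficients(self):
        df = _one_way(["a", "a", "b", "b"], [1.0, 3.0, 10.0, 14.0])
        fit = fit_trait_model(df, ModelSpec())
        # cell-means coding: parameters are the plot means
        assert sorted(np.round(fit.params, 9)) == [2.0, 12.0]

    def test_duplication_invariance(self):
        rng = np.random.default_rng(1)
        df = _one_way(np.repeat(["a", "b"], 6), rng.normal(0, 1, 12))
        doubled = pd.concat([df, df], ignore_index=True)
        f1 = fit_trait_model(df, ModelSpec())
        f2 = fit_trait_model(doubled, ModelSpec())
        assert np.allclose(np.sort(f1.params), np.sort(f2.params))

    def test_leverage_sums_to_p(self):
        rng = np.random.default_rng(2)
        for k, n in [(2, 8), (5, 40), (10, 55)]:
            df = _one_way(np.repeat([f"p{i}" for i in range(k)], n // k),
                          rng.normal(0, 1, (n // k) * k))
            fit = fit_trait_model(df, ModelSpec())
            assert fit.leverage.sum() == pytest.approx(fit.p, abs=1e-9)
            assert ((fit.leverage >= 0) & (fit.leverage <= 1)).all()

    def test_two_factor_model_with_alias_warning(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "plot_id": np.repeat(["a", "b", "c", "d"], 6),
            "treatment": np.repeat(["WW", "WW", "WL", "WL"], 6),  # nested in plot
            "value": rng.normal(0, 1, 24),
        })
        with pytest.warns(UserWarning, match="aliased"):
            fit = fit_trait_model(df, ModelSpec(factors=["plot_id", "treatment"]))
        assert fit.p == 4  # treatment adds no rank beyond the plot cells

    def test_saturated_model_fatal(self):
        df = _one_way(["a", "b"], [1.0, 2.0])
        with pytest.raises(ModelError, match="degrees of freedom"):
            fit_trait_model(df, ModelSpec())


class TestStudentizedDeletedResiduals:
    def test_zero_residual_gives_zero_t(self):
        df = _one_way(np.repeat(["a", "b"], 5),
                      [2.0] * 4 + [3.0] + [7.0] * 5)
        fit = fit_trait_model(df, ModelSpec())
        t = studentized_deleted_residuals(fit)
        assert t[5] == pytest.approx(0.0)  # exactly on its plot mean

    def test_distant_value_has_largest_t(self):
        df = _one_way(["a"] * 21, [5.0] * 20 + [50.0])
        fit = fit_trait_model(df, ModelSpec())
        t = studentized_deleted_residuals(fit)
        assert np.nanargmax(np.abs(t)) == 20

    @pytest.mark.parametrize("seed,k,n", [(0, 1, 12), (1, 3, 24), (2, 5, 50),
                                          (3, 2, 9), (4, 4, 44)])
    def test_matches_leave_one_out_refit_oracle(self, seed, k, n):
        """The no-refit shortcut equals explicit LOO refitting to 1e-8."""
        rng = np.random.default_rng(seed)
        groups = [f"p{i % k}" for i in range(n)]
        df = _one_way(groups, rng.normal(30, 1, n))
        df.loc[n - 1, "value"] += 8  # make sure a real outlier is present
        fit = fit_trait_model(df, ModelSpec())
        t = studentized_deleted_residuals(fit)
        t_oracle = loo_studentized_residuals(df, "value", ["plot_id"])
        assert np.nanmax(np.abs(t - t_oracle)) < 1e-8

    def test_matches_statsmodels_external_studentization(self):
        import statsmodels.api as sm
        from statsmodels.stats.outliers_influence import OLSInfluence

        rng = np.random.default_rng(7)
        df = _one_way(np.repeat(["a", "b", "c"], 15), rng.normal(25, 2, 45))
        fit = fit_trait_model(df, ModelSpec())
        t = studentized_deleted_residuals(fit)
        X = pd.get_dummies(df["plot_id"], dtype=float).to_numpy()
        ref = OLSInfluence(sm.OLS(df["value"], X).fit()).resid_studentized_external
        assert np.nanmax(np.abs(t - ref)) < 1e-10


class TestRemoveOutliers:
    def test_fixed_point_when_clean(self):
        rng = np.random.default_rng(10)
        df = _one_way(np.repeat(["a", "b"], 30), rng.normal(30, 1, 60))
        spec = ModelSpec(tau=6.0)
        cleaned, diag, iters = remove_outliers(df, spec)
        assert len(cleaned) == len(df) and iters == 1
        assert (diag["iteration_removed"] == 0).all()

    def test_injected_shifts_removed(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            vals = rng.normal(30, 1, 100)
            vals[:5] += 15.0
            df = _one_way(["p"] * 100, vals)
            cleaned, diag, iters = remove_outliers(df, ModelSpec(tau=3.0))
            removed = set(diag.index[diag["iteration_removed"] > 0])
            if set(range(5)) <= removed and iters <= 3:
                hits += 1
        assert hits >= 95

    def test_infinite_tau_removes_nothing(self):
        rng = np.random.default_rng(3)
        df = _one_way(["p"] * 30, rng.normal(0, 1, 30))
        df.loc[0, "value"] = 100.0
        cleaned, _, _ = remove_outliers(df, ModelSpec(tau=1e12))
        assert len(cleaned) == len(df)

    def test_threshold_monotonicity_single_iteration(self):
        """The removal set at a smaller tau contains the set at a larger
        tau, judged on the same fit."""
        rng = np.random.default_rng(8)
        df = _one_way(["p"] * 50, rng.normal(0, 1, 50))
        fit = fit_trait_model(df, ModelSpec())
        t = np.abs(studentized_deleted_residuals(fit))
        s_small = set(np.flatnonzero(t > 1.0))
        s_large = set(np.flatnonzero(t > 2.0))
        assert s_large <= s_small

    def test_all_removed_is_fatal(self):
        df = _one_way(["a", "a", "a", "b", "b", "b"],
                      [0.0, 0.0, 50.0, 1.0, 1.0, 60.0])
        with pytest.raises(ModelError):
            # pathological threshold that eats everything
            remove_outliers(df, ModelSpec(tau=1e-9, max_iterations=50))


class TestAttitudeFilter:
    def _obs(self):
        return pd.DataFrame({"value": [1.0, 2.0, 3.0],
                             "pitch": [0.1, 9.0, 0.2],
                             "roll": [0.1, 0.0, -8.0]})

    def test_disabled_filter_is_identity(self):
        obs = self._obs()
        kept, removed = attitude_filter(obs)
        pd.testing.assert_frame_equal(kept, obs)
        assert len(removed) == 0

    def test_threshold_removal(self):
        kept, removed = attitude_filter(self._obs(), max_pitch=5.0, max_roll=5.0)
        assert len(kept) == 1 and len(removed) == 2

    def test_level_attitudes_keep_everything(self):
        obs = self._obs()
        obs["pitch"] = 0.0
        obs["roll"] = 0.0
        kept, _ = attitude_filter(obs, max_pitch=5.0, max_roll=5.0)
        assert len(kept) == 3

    def test_missing_attitude_warns_and_skips(self):
        obs = pd.DataFrame({"value": [1.0]})
        with pytest.warns(UserWarning, match="attitude"):
            kept, _ = attitude_filter(obs, max_pitch=5.0)
        assert len(kept) == 1


class TestPlotMeans:
    def test_identical_values(self):
        df = pd.DataFrame({"plot_id": ["a"] * 4, "trait": "height",
                           "value": [0.8] * 4})
        out = plot_means(df)
        assert out.iloc[0]["mean"] == 0.8 and out.iloc[0]["sd"] == 0.0
        assert out.iloc[0]["n"] == 4

    def test_empty_plot_reported_missing(self):
        df = pd.DataFrame({"plot_id": ["a"] * 3, "trait": "height",
                           "value": [1.0, 2.0, 3.0]})
        out = plot_means(df, plot_universe=["a", "b"])
        row_b = out[out["plot_id"] == "b"].iloc[0]
        assert row_b["n"] == 0 and np.isnan(row_b["mean"])

    def test_recovery_within_sampling_error(self, small_sim):
        """Plot means from clean simulated data sit within 4*sd/sqrt(n)
        of the per-plot truths."""
        gt = small_sim.ground_truth
        clean = gt[gt["corrupted"] == 0]
        means = plot_means(clean.rename(columns={"value": "value"}),
                           by=("plot_id", "trait"))
        truth = (clean.groupby(["plot_id", "trait"])["true_value"]
                 .first().reset_index())
        merged = means.merge(truth, on=["plot_id", "trait"])
        sd = clean.groupby(["plot_id", "trait"])["value"].std().reset_index()
        merged = merged.merge(sd.rename(columns={"value": "obs_sd"}),
                              on=["plot_id", "trait"])
        bound = 4 * merged["obs_sd"] / np.sqrt(merged["n"])
        ok = (merged["mean"] - merged["true_value"]).abs() <= bound
        assert ok.mean() >= 0.99
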