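"""The covariance-structure engine: implied moments, ML fit, indices, pruning."""

import numpy as np
import pandas as pd
import pytest

from gaitimpress.sem import (
    EXPECTED_DF,
    MODEL_NAMES,
    PUBLISHED_FIT,
    SemModel,
    SemSpec,
    TRUE_PARAMS,
    agfi_from_gfi,
    builtin_model,
    rmsea_from_stats,
    sample_covariance_dataset,
)
from tests.conftest import relative_error


class TestImpliedCovariance:
    def test_independent_variables_give_diagonal_sigma(self):
        spec = SemSpec(["a", "b"])
        sigma = spec.implied_covariance({"a~~a": 0.7, "b~~b": 1.3})
        np.testing.assert_allclose(sigma, np.diag([0.7, 1.3]))

    def test_one_factor_cross_covariance_is_loading_product(self):
        spec = SemSpec(["y1", "y2"])
        spec.add_latent("f", ["y1", "y2"])
        sigma = spec.implied_covariance(
            {"f=~y2": 0.8, "f~~f": 1.0, "y1~~y1": 0.5, "y2~~y2": 0.5}
        )
        assert np.isclose(sigma[0, 1], 0.8)

    def test_recursive_spec_matches_monte_carlo(self):
        """Sigma(theta) equals the empirical covariance of simulated data."""
        spec = SemSpec(["x", "m", "y"])
        spec.add_path("x", "m")
        spec.add_path("m", "y")
        spec.add_path("x", "y")
        theta = {"x~>m": 0.6, "m~>y": 0.5, "x~>y": -0.3,
                 "x~~x": 1.0, "m~~m": 0.8, "y~~y": 0.7}
        sigma = spec.implied_covariance(theta)
        n = 400_000
        data = sample_covariance_dataset(spec, theta, n=n, seed=4)
        S = np.cov(data.to_numpy(), rowvar=False)
        for i in range(3):
            for j in range(3):
                se = np.sqrt((sigma[i, i] * sigma[j, j] + sigma[i, j] ** 2) / n)
                assert abs(S[i, j] - sigma[i, j]) < 3 * se

    def test_singular_structural_system_rejected(self):
        spec = SemSpec(["a", "b"])
        spec.add_path("a", "b")
        spec.add_path("b", "a")
        with pytest.raises(ValueError, match="singular"):
            # loop product exactly 1 makes (I - A) singular
            spec.implied_covariance({"a~>b": 1.0, "b~>a": 1.0, "a~~a": 1.0, "b~~b": 1.0})


class TestMLFit:
    def test_self_consistency_recovers_parameters(self):
        """Fitting S = Sigma(theta0) returns theta0 with chi2 ~ 0."""
        spec = builtin_model("B1")
        theta0 = TRUE_PARAMS["B1"]
        sigma = spec.implied_covariance(theta0)
        res = SemModel(spec, sigma, nobs=2000).fit(n_starts=3, seed=0)
        assert res.converged
        assert res.chi_square < 1e-6
        for label, val in theta0.items():
            assert abs(res.params[label] - val) < 1e-4, label

    def test_saturated_model_has_zero_chi_square_and_df(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((500, 3))
        S = np.cov(X, rowvar=False)
        spec = SemSpec(["a", "b", "c"])
        spec.add_covariance("a", "b")
        spec.add_covariance("a", "c")
        spec.add_covariance("b", "c")
        res = SemModel(spec, S, nobs=500).fit(n_starts=2, seed=0)
        assert spec.df == 0
        assert res.chi_square < 1e-6
        np.testing.assert_allclose(res.implied_cov, S, atol=1e-5)

    def test_badly_misspecified_model_is_flagged_or_poor(self):
        """One-factor data forced into an orthogonal two-factor spec."""
        gen = SemSpec(["y1", "y2", "y3", "y4"])
        gen.add_latent("f", ["y1", "y2", "y3", "y4"])
        theta = {"f=~y2": 0.9, "f=~y3": 0.8, "f=~y4": 0.85, "f~~f": 1.0,
                 "y1~~y1": 0.4, "y2~~y2": 0.4, "y3~~y3": 0.4, "y4~~y4": 0.4}
        bad = SemSpec(["y1", "y2", "y3", "y4"])
        bad.add_latent("f1", ["y1", "y2"])
        bad.add_latent("f2", ["y3", "y4"])
        # no f1-f2 covariance: cross-block correlations cannot be explained
        for seed in range(3):
            data = sample_covariance_dataset(gen, theta, n=2000, seed=seed)
            res = SemModel.from_dataframe(bad, data).fit(n_starts=3, seed=seed)
            assert (not res.converged) or res.chi_square > 10 * bad.df

    def test_unidentified_spec_rejected(self):
        spec = SemSpec(["a", "b"])
        spec.add_path("a", "b")
        spec.add_path("b", "a")
        spec.add_covariance("a", "b")
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        with pytest.raises(ValueError, match="df"):
            SemModel(spec, S, nobs=100)

    def test_non_pd_sample_covariance_rejected(self):
        spec = SemSpec(["a", "b"])
        S = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive-definite"):
            SemModel(spec, S, nobs=100)


class TestStandardizedSolution:
    def test_unit_variance_covariance_is_correlation(self):
        spec = SemSpec(["a", "b"])
        spec.add_covariance("a", "b")
        S = np.array([[1.0, 0.44], [0.44, 1.0]])
        res = SemModel(spec, S, nobs=500).fit(n_starts=2, seed=0)
        std = res.standardized().set_index(["lhs", "rhs"])
        assert np.isclose(std.loc[("a", "b"), "standardized"], 0.44, atol=1e-3)

    def test_path_rescaled_by_source_and_target_sd(self):
        # y = b x with Var(x) = 4 and Var(y) = 1 -> standardized b' = 2b
        spec = SemSpec(["x", "y"])
        spec.add_path("x", "y")
        b = 0.35
        resid = 1.0 - b**2 * 4.0
        S = np.array([[4.0, b * 4.0], [b * 4.0, 1.0]])
        res = SemModel(spec, S, nobs=1000).fit(n_starts=2, seed=0)
        std = res.standardized().set_index(["lhs", "rhs"])
        assert np.isclose(std.loc[("x", "y"), "standardized"], 2 * b, atol=1e-3)
        assert resid > 0  # sanity of construction

    def test_standardized_invariant_to_observed_rescaling(self):
        spec = builtin_model("H1")
        data = sample_covariance_dataset(spec, TRUE_PARAMS["H1"], n=3000, seed=8)
        res1 = SemModel.from_dataframe(spec, data).fit(n_starts=3, seed=0)
        scaled = data.copy()
        scaled["backward_arm_swing"] *= 10.0
        res2 = SemModel.from_dataframe(builtin_model("H1"), scaled).fit(n_starts=3, seed=0)
        s1 = res1.standardized()
        s2 = res2.standardized()
        np.testing.assert_allclose(
            s1.standardized.to_numpy(), s2.standardized.to_numpy(), atol=2e-3
        )
        # chi-square is scale-free too
        assert relative_error(res2.chi_square, res1.chi_square, floor=1e-3) < 1e-2


class TestFitIndices:
    def test_perfect_fit_limits(self):
        spec = builtin_model("B1")
        sigma = spec.implied_covariance(TRUE_PARAMS["B1"])
        res = SemModel(spec, sigma, nobs=2037).fit(n_starts=3, seed=0)
        assert res.gfi > 0.9999
        assert res.cfi == 1.0
        assert res.rmsea < 1e-3

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_rmsea_closure_on_published_statistics(self, name):
        pub = PUBLISHED_FIT[name]
        val = rmsea_from_stats(pub["chi_square"], pub["df"], pub["nobs"])
        assert round(val, 3) == round(pub["rmsea"], 3)

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_agfi_closure_on_published_statistics(self, name):
        pub = PUBLISHED_FIT[name]
        val = agfi_from_gfi(pub["gfi"], pub["df"], pub["p_observed"])
        assert abs(val - pub["agfi"]) < 0.005

    def test_agfi_equals_gfi_for_null_df(self):
        # df = p(p+1)/2 makes the AGFI penalty factor exactly 1
        p = 4
        df = p * (p + 1) // 2
        gfi = 0.87
        assert np.isclose(agfi_from_gfi(gfi, df, p), gfi)

    def test_df_zero_reports_undefined_indices(self):
        rng = np.random.default_rng(1)
        S = np.cov(rng.standard_normal((200, 2)), rowvar=False)
        spec = SemSpec(["a", "b"])
        spec.add_covariance("a", "b")
        res = SemModel(spec, S, nobs=200).fit(n_starts=2, seed=0)
        assert np.isnan(res.agfi) and np.isnan(res.rmsea)


class TestPruning:
    def _fit_with_paths(self, weak_value):
        spec = SemSpec(["x", "z", "y", "w"])
        spec.add_path("x", "y")
        spec.add_path("z", "y")
        spec.add_path("z", "w")  # keeps z connected if z~>y is pruned
        theta = {"x~>y": 0.6, "z~>y": weak_value, "z~>w": 0.6,
                 "x~~x": 1.0, "z~~z": 1.0, "y~~y": 0.5, "w~~w": 0.5}
        sigma = spec.implied_covariance(theta)
        return SemModel(spec, sigma, nobs=5000).fit(n_starts=2, seed=0)

    def test_weak_path_removed(self):
        res = self._fit_with_paths(0.05)
        pruned, flagged = res.prune_paths(threshold=0.1)
        labels = [p.label for p in pruned.paths]
        assert "z~>y" not in labels and "x~>y" in labels and not flagged

    def test_boundary_coefficient_retained(self):
        # standardized value lands exactly near 0.1; strict < keeps ~0.1 paths
        res = self._fit_with_paths(0.2)
        std = res.standardized().set_index(["lhs", "rhs"])
        assert abs(std.loc[("z", "y"), "standardized"]) >= 0.1
        pruned, _ = res.prune_paths(threshold=0.1)
        assert len(pruned.paths) == 3

    def test_strong_model_unchanged(self):
        spec = builtin_model("B1")
        sigma = spec.implied_covariance(TRUE_PARAMS["B1"])
        res = SemModel(spec, sigma, nobs=2037).fit(n_starts=3, seed=0)
        pruned, _ = res.prune_paths(threshold=0.1)
        assert len(pruned.paths) == len(spec.paths)

    def test_pruning_never_orphans_an_observed_variable(self):
        spec = SemSpec(["x", "y"])
        spec.add_path("x", "y")
        theta = {"x~>y": 0.05, "x~~x": 1.0, "y~~y": 1.0}
        sigma = spec.implied_covariance(theta)
        res = SemModel(spec, sigma, nobs=4000).fit(n_starts=2, seed=0)
        pruned, flagged = res.prune_paths(threshold=0.1)
        assert len(pruned.paths) == 1 and flagged == ["x~>y"]


class TestBuiltinModels:
    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_specs_valid_identified_and_match_published_df(self, name):
        spec = builtin_model(name)
        assert spec.validate(expected_df=EXPECTED_DF[name]) == []
        assert spec.df >= 0

    def test_observed_variable_counts_match_error_terms(self):
        # E1..E5 for the silhouette models, E1..E7 / E1..E6 for the factor models
        assert len(builtin_model("B1").observed) == 5
        assert len(builtin_model("B2").observed) == 7
        assert len(builtin_model("H1").observed) == 5
        assert len(builtin_model("H2").observed) == 6

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            builtin_model("Z9")

    def test_spec_text_round_trip(self):
        spec = builtin_model("B2")
        back = SemSpec.from_text(spec.to_text())
        assert back.observed == spec.observed
        assert back.df == spec.df
        assert [p.label for p in back.free_parameters] == [
            p.label for p in spec.free_parameters
        ]
        sigma1 = spec.implied_covariance(TRUE_PARAMS["B2"])
        sigma2 = back.implied_covariance(TRUE_PARAMS["B2"])
        np.testing.assert_allclose(sigma1, sigma2)

    def test_recovery_smoke_single_model(self):
        """Short recovery check (the full 4x20 sweep runs in acceptance)."""
        spec = builtin_model("B1")
        theta0 = np.array([TRUE_PARAMS["B1"][p.label] for p in spec.free_parameters])
        errs = []
        for seed in range(3):
            data = sample_covariance_dataset(spec, TRUE_PARAMS["B1"], n=2000, seed=seed)
            res = SemModel.from_dataframe(spec, data).fit(n_starts=3, seed=seed)
            assert res.converged
            errs.append(np.mean(np.abs(res.params.to_numpy() - theta0)))
        assert np.mean(errs) < 0.06

    def test_summary_contains_indices_and_estimates(self):
        spec = builtin_model("B1")
        sigma = spec.implied_covariance(TRUE_PARAMS["B1"])
        res = SemModel(spec, sigma, nobs=2037).fit(n_starts=2, seed=0)
        text = res.summary()
        for token in ("chi2", "GFI", "AGFI", "CFI", "RMSEA", "SilhouetteT"):
            assert token in text
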