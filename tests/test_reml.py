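import itertools

import numpy as np
import pandas as pd
import pytest

import gsspatial as gs

from conftest import balanced_trial, grid_trial


def identity_spec(t, trait="y"):
    return gs.ModelSpec(trait, gs.GenomicKinship.identity(t.genotypes))


def matched_spatial_spec(t, family, param, dim=gs.PlotDimension(2.0, 1.0)):
    d = gs.distance_matrix(t, dim)
    return gs.ModelSpec(
        "y", gs.GenomicKinship.identity(t.genotypes),
        spatial=gs.spatial_correlation(d, family, param),
    )


class TestAgainstReferenceFits:
    def test_matches_lmer_on_balanced_design(self):
        """Variance components, intercept and restricted log-likelihood
        reproduce lme4::lmer (REML) on a frozen 15x3 balanced dataset."""
        t = balanced_trial(15, 3, seed=42)
        fit = gs.fit_reml(t, identity_spec(t))
        # lmer(y ~ 1 + (1|genotype), REML=TRUE) on the same data
        assert fit.varcomps["g"] == pytest.approx(1.0636175495, abs=1e-6)
        assert fit.varcomps["r"] == pytest.approx(0.3722779294, abs=1e-6)
        assert fit.restricted_loglik == pytest.approx(-58.4093847227, abs=1e-6)
        assert fit.mu_hat == pytest.approx(10.0672894429, abs=1e-6)

    def test_matches_anova_closed_form_on_balanced_design(self):
        g, reps = 20, 2
        t = balanced_trial(g, reps, seed=1, sigma_g=1.5, sigma_r=0.7)
        fit = gs.fit_reml(t, identity_spec(t))
        y = t.values("y").reshape(g, reps)
        msw = ((y - y.mean(1, keepdims=True)) ** 2).sum() / (g * (reps - 1))
        msb = reps * ((y.mean(1) - y.mean()) ** 2).sum() / (g - 1)
        assert fit.varcomps["r"] == pytest.approx(msw, rel=1e-6)
        assert fit.varcomps["g"] == pytest.approx((msb - msw) / reps, rel=1e-6)


class TestRestrictedLoglik:
    def test_single_component_closed_form(self):
        t = balanced_trial(10, 2, seed=3)
        y = t.values("y")
        n = len(y)
        s2 = 1.7
        rss = float(((y - y.mean()) ** 2).sum())
        expected = -0.5 * (
            (n - 1) * np.log(2 * np.pi * s2) + rss / s2 + np.log(n)
        )
        got = gs.restricted_loglik(t, identity_spec(t), {"g": 0.0, "r": s2})
        assert got == pytest.approx(expected, abs=1e-10)

    def test_scaling_y_scales_variance_optimum(self):
        t = balanced_trial(12, 2, seed=7)
        fit1 = gs.fit_reml(t, identity_spec(t))
        t2 = gs.TrialTable(t.data.assign(y=t.values("y") * 3.0), ["y"])
        fit2 = gs.fit_reml(t2, identity_spec(t2))
        assert fit2.varcomps["g"] == pytest.approx(9.0 * fit1.varcomps["g"], rel=1e-4)
        assert fit2.varcomps["r"] == pytest.approx(9.0 * fit1.varcomps["r"], rel=1e-4)

    def test_invariant_to_consistent_plot_permutation(self):
        t = grid_trial({f"G{i}": [float(i % 4) + 0.1 * i] for i in range(12)})
        spec = matched_spatial_spec(t, "gaussian", 3.0)
        vc = {"g": 0.8, "s": 0.5, "r": 0.4}
        ll = gs.restricted_loglik(t, spec, vc)
        perm = np.random.default_rng(0).permutation(t.n_plots)
        tp = gs.TrialTable(t.data.iloc[perm].reset_index(drop=True), ["y"])
        # same kernel object: rows are found by plot id, so consistent
        assert gs.restricted_loglik(tp, spec, vc) == pytest.approx(ll, abs=1e-9)

    def test_all_zero_components_rejected(self):
        t = balanced_trial(5, 2, seed=0)
        with pytest.raises(ValueError):
            gs.restricted_loglik(t, identity_spec(t), {"g": 0.0, "r": 0.0})


class TestFitBehavior:
    def test_constant_response_degenerates_cleanly(self):
        t = grid_trial({f"G{i}": [4.2] for i in range(8)})
        fit = gs.fit_reml(t, identity_spec(t))
        assert fit.converged
        assert fit.mu_hat == pytest.approx(4.2)
        assert fit.varcomps["g"] == 0.0 and fit.varcomps["r"] == 0.0

    def test_mixed_model_equation_identity(self):
        """mu + sum of effect BLUPs + residual reproduces y exactly."""
        lay = gs.default_layout(20, 2, 2, n_cols=5)
        sim = gs.simulate_trial(
            gs.SimulationConfig(0.5, 0.6, "gaussian", 4.0, seed=2), lay
        )
        t = sim.phenotypes
        spec = gs.ModelSpec(
            "y", gs.GenomicKinship.identity(t.genotypes),
            spatial=gs.spatial_correlation(
                gs.distance_matrix(t, gs.PlotDimension(2, 1)), "gaussian", 4.0),
            range_effect=True, column_effect=True,
        )
        fit = gs.fit_reml(t, spec)
        recon = (
            fit.mu_hat
            + fit.blup_g.loc[t.data["genotype"]].to_numpy()
            + fit.blup_s.loc[t.plot_ids].to_numpy()
            + fit.blup_ra.loc[t.data["range_idx"]].to_numpy()
            + fit.blup_cl.loc[t.data["col_idx"]].to_numpy()
            + fit.residuals
        )
        assert np.max(np.abs(recon - t.values("y"))) < 1e-8

    def test_variance_components_never_negative(self):
        for seed in range(5):
            lay = gs.default_layout(15, 2, 2, n_cols=5)
            sim = gs.simulate_trial(
                gs.SimulationConfig(0.4, 0.3, "power", 0.5, seed=seed), lay
            )
            fit = gs.fit_reml(sim.phenotypes,
                              matched_spatial_spec(sim.phenotypes, "power", 0.5))
            assert all(v >= 0.0 for v in fit.varcomps.values())

    def test_boundary_component_reported_as_zero(self):
        # no spatial signal at all: sigma2_s should pin at the boundary
        rng = np.random.default_rng(10)
        t = grid_trial({f"G{i}": [float(v)] for i, v in
                        enumerate(rng.normal(0, 0.01, 40))}, n_cols=8)
        t.data["y"] = rng.normal(0.0, 1.0, 40)
        fit = gs.fit_reml(t, matched_spatial_spec(t, "gaussian", 6.0))
        if fit.boundary["s"]:
            assert fit.varcomps["s"] == 0.0

    def test_small_instance_beats_grid_search(self):
        lay = gs.default_layout(12, 2, 2, n_cols=4)
        sim = gs.simulate_trial(
            gs.SimulationConfig(0.5, 0.5, "power", 0.5, seed=7), lay
        )
        spec = matched_spatial_spec(sim.phenotypes, "power", 0.5)
        fit = gs.fit_reml(sim.phenotypes, spec)
        grid = np.geomspace(0.02, 5.0, 12)
        best = max(
            gs.restricted_loglik(sim.phenotypes, spec,
                                 {"g": a, "s": b, "r": c})
            for a, b, c in itertools.product(grid, grid, grid)
        )
        assert fit.restricted_loglik >= best - 1e-4


class TestLRT:
    def _two_fits(self, seed=4, shift=0.0):
        lay = gs.default_layout(25, 3, 2, n_cols=6)
        sim = gs.simulate_trial(
            gs.SimulationConfig(0.4, 0.7, "gaussian", 5.0, seed=seed), lay
        )
        t = sim.phenotypes
        if shift:
            t = gs.TrialTable(t.data.assign(y=t.values("y") + shift), ["y"])
        base = gs.fit_reml(t, identity_spec(t))
        model = gs.fit_reml(t, matched_spatial_spec(t, "gaussian", 5.0))
        return model, base

    def test_identical_likelihoods_not_significant(self):
        model, base = self._two_fits()
        res = gs.lrt(base, base, extra_df=1)
        assert res.statistic == 0.0
        assert not res.significant
        assert res.p_value == 1.0

    def test_statistic_invariant_to_location_shift(self):
        m1, b1 = self._two_fits(shift=0.0)
        m2, b2 = self._two_fits(shift=100.0)
        s1 = gs.lrt(m1, b1, extra_df=1).statistic
        s2 = gs.lrt(m2, b2, extra_df=1).statistic
        assert s1 == pytest.approx(s2, abs=1e-5)

    def test_mismatched_n_is_error(self):
        model, base = self._two_fits()
        model.n_obs = base.n_obs + 1
        with pytest.raises(ValueError, match="different numbers"):
            gs.lrt(model, base, extra_df=1)

    def test_mixture_p_value_is_half_tail(self):
        from scipy.stats import chi2

        model, base = self._two_fits()
        res = gs.lrt(model, base, extra_df=1)
        assert res.p_value == pytest.approx(
            0.5 * chi2.sf(res.statistic, 1), rel=1e-12
        )


class TestCullisHeritability:
    def _balanced_fit(self):
        t = balanced_trial(20, 2, seed=1, sigma_g=1.5, sigma_r=0.7)
        return gs.fit_reml(t, identity_spec(t))

    def test_zero_pev_gives_one(self):
        fit = self._balanced_fit()
        fit._pev_g = np.zeros_like(fit.pev_g)
        assert gs.cullis_h2(fit) == pytest.approx(1.0)

    def test_pev_equal_to_genetic_variance_gives_zero(self):
        fit = self._balanced_fit()
        g = len(fit.blup_g)
        fit._pev_g = fit.varcomps["g"] * np.eye(g)
        assert gs.cullis_h2(fit) == pytest.approx(0.0, abs=1e-12)

    def test_matches_classical_line_mean_form_when_balanced(self):
        fit = self._balanced_fit()
        sg, sr = fit.varcomps["g"], fit.varcomps["r"]
        classical = 1.0 - 1.0 / (1.0 + 2 * sg / sr)
        assert gs.cullis_h2(fit) == pytest.approx(classical, abs=1e-6)

    def test_zero_genetic_variance_undefined(self):
        fit = self._balanced_fit()
        fit.varcomps["g"] = 0.0
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(gs.cullis_h2(fit))


class TestPredictHeldout:
    def test_base_model_prediction_is_mu_plus_blup(self):
        t = balanced_trial(12, 2, seed=9)
        genos = list(t.genotypes)
        train_mask = ~t.data["genotype"].isin(genos[:3]).to_numpy()
        kinship = gs.GenomicKinship.identity(t.genotypes)
        fit = gs.fit_reml(t.subset(train_mask), gs.ModelSpec("y", kinship))
        test = t.subset(~train_mask)
        pred = gs.predict_heldout(fit, test)
        expected = fit.mu_hat + fit.blup_g.loc[test.data["genotype"]].to_numpy()
        assert np.allclose(pred, expected)

    def test_unknown_genotype_is_hard_error(self):
        t = balanced_trial(8, 2, seed=9)
        kinship = gs.GenomicKinship.identity(t.genotypes)
        fit = gs.fit_reml(t, gs.ModelSpec("y", kinship))
        stranger = grid_trial({"ZZ1": [0.0], "ZZ2": [0.0]})
        with pytest.raises(KeyError, match="absent"):
            gs.predict_heldout(fit, stranger)

    def test_coincident_plot_spherical_kriging(self):
        """A test plot at the exact location of a training plot, with a
        spherical kernel too short to reach any other plot, inherits that
        training plot's spatial BLUP."""
        train = grid_trial(
            {"A": [1.0], "B": [2.5], "C": [0.3], "D": [1.8]}, n_cols=1
        )
        # plots sit on a transect at 0, 10, 20, 30 m; T0 coincides with P000
        ids = np.concatenate([train.plot_ids, ["T0"]])
        x = np.array([0.0, 10.0, 20.0, 30.0, 0.0])
        dist = gs.DistanceMatrix(np.abs(x[:, None] - x[None, :]), "isotropic", ids)
        kernel = gs.spatial_correlation(dist, "spherical", 5.0)
        kinship = gs.GenomicKinship.identity(np.array(list("ABCDE")))
        fit = gs.fit_reml(train, gs.ModelSpec("y", kinship, spatial=kernel))
        test = gs.TrialTable(pd.DataFrame([{
            "plot_id": "T0", "range_idx": 99, "col_idx": 99,
            "genotype": "E", "is_check": False, "y": np.nan,
        }, {
            "plot_id": "P001", "range_idx": 99, "col_idx": 98,
            "genotype": "A", "is_check": False, "y": np.nan,
        }]))
        pred = gs.predict_heldout(fit, test)
        # genotype E is unobserved and unrelated: g_hat = 0, so the
        # prediction minus mu is exactly the kriged spatial effect
        s_test = pred[0] - fit.mu_hat
        assert s_test == pytest.approx(fit.blup_s.loc["P000"], abs=1e-10)
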