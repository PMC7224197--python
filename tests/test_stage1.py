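"""Stage-1 aggregation, REML, BLUPs, de-regression and variability statistics."""

import numpy as np
import pandas as pd
import pytest

import rootpheno as rp
from rootpheno.stage1 import (
    aggregate_plots,
    deregress,
    fit_stage1,
    gcv,
    pcv,
    reml_fit,
    variability_stats,
)


def _toy_roots(values_by_plot):
    rows = []
    for plot, vals in values_by_plot.items():
        for i, v in enumerate(vals):
            rows.append(dict(plot_id=plot, particle_id=i, area=v))
    return pd.DataFrame(rows)


class TestAggregate:
    design = pd.DataFrame(
        {"plot_id": ["p1", "p2"], "clone_id": ["c1", "c2"],
         "location": ["L", "L"], "range": ["r1", "r1"], "NOHAV": [3, 4]}
    )

    def test_mean_and_sample_sd(self):
        table = aggregate_plots(_toy_roots({"p1": [10, 20, 30], "p2": [5]}),
                                self.design, traits=["area"])
        row = table.set_index("plot_id").loc["p1"]
        assert row["area_mean"] == 20.0
        assert row["area_sd"] == pytest.approx(10.0)

    def test_single_root_plot_has_no_sd(self):
        table = aggregate_plots(_toy_roots({"p1": [10, 20], "p2": [5]}),
                                self.design, traits=["area"])
        row = table.set_index("plot_id").loc["p2"]
        assert np.isnan(row["area_sd"])
        assert row["area_mean"] == 5.0

    def test_row_count_matches_plots_with_roots(self, trial_500):
        # every simulated plot contributes its phenotype row
        roots = _toy_roots({"p1": [1, 2], "p2": [3]})
        table = aggregate_plots(roots, self.design, traits=["area"])
        assert len(table) == 2

    def test_log_transform_drops_nonpositive(self, caplog):
        table = aggregate_plots(_toy_roots({"p1": [-1.0], "p2": [np.e]}),
                                self.design, traits=["area"], log_transform=True)
        t = table.set_index("plot_id")
        assert np.isnan(t.loc["p1", "area_mean"])
        assert t.loc["p2", "area_mean"] == pytest.approx(1.0)

    def test_unknown_plot_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            aggregate_plots(_toy_roots({"px": [1]}), self.design, traits=["area"])


def _dense_reml_ll(y, X, Z_list, sigma2, s2e):
    """Independent textbook restricted likelihood with an explicit V matrix."""
    n, p = X.shape
    V = s2e * np.eye(n)
    for s2, Z in zip(sigma2, Z_list):
        V += s2 * Z @ Z.T
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (
        np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1] + r @ Vi @ r
    )


class TestREML:
    def test_matches_profile_likelihood_grid_on_toy(self):
        rng = np.random.default_rng(0)
        n_clone, reps = 10, 3  # 30 plots
        Zc = np.kron(np.eye(n_clone), np.ones((reps, 1)))
        ranges = rng.integers(0, 5, size=n_clone * reps)
        Zr = np.zeros((n_clone * reps, 5))
        Zr[np.arange(n_clone * reps), ranges] = 1
        y = (
            Zc @ rng.normal(0, 1.0, n_clone)
            + Zr @ rng.normal(0, 0.7, 5)
            + rng.normal(0, 1.0, n_clone * reps)
        )
        X = np.ones((n_clone * reps, 1))
        sigma2, s2e, *_ = reml_fit(y, X, [Zc, Zr])

        grid_c = np.geomspace(0.02, 30.0, 21)
        grid_e = np.geomspace(0.1, 10.0, 17)
        best, best_ll = None, -np.inf
        for gc in grid_c:
            for gr in grid_c:
                for ge in grid_e:
                    ll = _dense_reml_ll(y, X, [Zc, Zr], [gc, gr], ge)
                    if ll > best_ll:
                        best_ll, best = ll, (gc, gr, ge)
        # the optimiser must beat the exhaustive grid ...
        ll_fit = _dense_reml_ll(y, X, [Zc, Zr], sigma2, s2e)
        assert ll_fit >= best_ll - 1e-9
        # ... and land within one grid step of the grid argmax
        step_c = grid_c[1] / grid_c[0]
        step_e = grid_e[1] / grid_e[0]
        for fitted, gridded, step in zip(
            (sigma2[0], sigma2[1], s2e), best, (step_c, step_c, step_e)
        ):
            assert gridded / step <= max(fitted, grid_c[0]) <= gridded * step

    def test_two_clone_blups_equal_shrinkage_formula(self):
        rng = np.random.default_rng(3)
        reps = 8
        y = np.concatenate([rng.normal(2.0, 1, reps), rng.normal(-1.0, 1, reps)])
        X = np.ones((2 * reps, 1))
        Zc = np.kron(np.eye(2), np.ones((reps, 1)))
        sigma2, s2e, beta, *_ = reml_fit(y, X, [Zc])
        from rootpheno.stage1 import _blups_and_pev

        (blup, _), = _blups_and_pev(y, X, [Zc], sigma2, s2e)
        grand = y.mean()
        shrink = reps * sigma2[0] / (reps * sigma2[0] + s2e)
        expect = shrink * (np.array([y[:reps].mean(), y[reps:].mean()]) - grand)
        np.testing.assert_allclose(blup, expect, rtol=1e-6)

    def test_translation_invariance(self, trial_500):
        vc1, est1 = fit_stage1(trial_500.phenotypes, "area", model=2)
        shifted = trial_500.phenotypes.copy()
        shifted["area"] += 500.0
        vc2, est2 = fit_stage1(shifted, "area", model=2)
        assert vc1.sigma2_clone == pytest.approx(vc2.sigma2_clone, rel=1e-3)
        assert vc1.sigma2_resid == pytest.approx(vc2.sigma2_resid, rel=1e-3)
        assert vc1.h2 == pytest.approx(vc2.h2, abs=1e-4)
        np.testing.assert_allclose(est1["egv"], est2["egv"], atol=1e-3)

    def test_cmd_covariate_absorbs_disease_signal(self, genotypes_500):
        from conftest import common_marker

        resid = {1: [], 2: []}
        h2 = {1: [], 2: []}
        for seed in range(3):
            # heritable severity: CMD tied to a resistance locus, so the
            # CMD-corrected model strips genuine clone-level signal
            params = rp.TrialParams(
                trait="area", h2_plot=0.3, sigma2_e=1.0, beta_cmd=-0.6,
                confound_qtl=common_marker(genotypes_500), cmd_confound_r=0.6,
            )
            sim = rp.simulate_trial(
                genotypes_500, params, rp.DesignSpec(plots_per_clone=2), seed=seed
            )
            for model in (1, 2):
                vc, _ = fit_stage1(sim.phenotypes, "area", model=model)
                resid[model].append(vc.sigma2_resid)
                h2[model].append(vc.h2)
        assert np.mean(resid[1]) <= np.mean(resid[2]) + 1e-6
        # correcting for a heritable covariate removes clone-level variance
        assert np.mean(h2[1]) <= np.mean(h2[2]) + 0.02

    def test_constant_covariate_dropped_with_warning(self, trial_500):
        tbl = trial_500.phenotypes.copy()
        tbl["CMD"] = 3
        with pytest.warns(UserWarning, match="CMD"):
            vc, _ = fit_stage1(tbl, "area", model=1)
        assert "CMD" not in vc.fixed_effects

    def test_degenerate_trait_rejected(self, trial_500):
        tbl = trial_500.phenotypes.copy()
        tbl["area"] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            fit_stage1(tbl, "area", model=2)


class TestDeregress:
    def test_definitional_division(self):
        est = pd.DataFrame(
            {"clone_id": ["a"], "egv": [2.0], "pev": [0.5], "reliability": [0.5]}
        )
        out = deregress(est)
        assert out["deregressed_egv"].iloc[0] == pytest.approx(4.0)

    def test_low_reliability_set_missing(self):
        est = pd.DataFrame(
            {"clone_id": ["a"], "egv": [2.0], "pev": [0.95], "reliability": [0.05]}
        )
        assert np.isnan(deregress(est, min_reliability=0.1)["deregressed_egv"]).all()

    def test_magnitude_exceeds_egv(self, trial_500):
        _, est = fit_stage1(trial_500.phenotypes, "area", model=2)
        out = deregress(est).dropna(subset=["deregressed_egv"])
        nz = out[out["egv"].abs() > 1e-9]
        assert (nz["deregressed_egv"].abs() >= nz["egv"].abs()).all()

    def test_adjustment_beats_raw_plot_means(self, genotypes_500):
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            params = rp.TrialParams(
                trait="area", h2_plot=0.3, sigma2_range=1.0, sigma2_e=1.0
            )
            sim = rp.simulate_trial(
                genotypes_500, params, rp.DesignSpec(plots_per_clone=2), seed=100 + seed
            )
            _, est = fit_stage1(sim.phenotypes, "area", model=2)
            dr = deregress(est).set_index("clone_id")["deregressed_egv"]
            raw = sim.phenotypes.groupby("clone_id")["area"].mean()
            truth = sim.true_genetic_values["area"]
            if dr.corr(truth) >= raw.corr(truth):
                wins += 1
        assert wins >= int(0.75 * n_seeds)


class TestVariability:
    @pytest.mark.parametrize(
        "var_g,mu,expected",
        [(293.464, 125.71, 13.63), (8.579, 27.58, 10.62)],
    )
    def test_gcv_matches_published_root_trait_values(self, var_g, mu, expected):
        assert round(gcv(var_g, mu), 2) == expected

    def test_null_variance_gives_zero_stats(self):
        from rootpheno.stage1 import VarianceComponents

        vc = VarianceComponents(
            trait="t", sigma2_clone=0.0, sigma2_range=0.1, sigma2_resid=1.0,
            fixed_effects={}, grand_mean=10.0, loglik=0.0, n_obs=10, model=2,
        )
        h2, g, p = variability_stats(vc)
        assert h2 == 0.0 and g == 0.0 and p > 0

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            gcv(1.0, 0.0)
        with pytest.raises(ValueError):
            pcv(1.0, -2.0)

    def test_pcv_at_least_gcv(self, trial_500):
        vc, _ = fit_stage1(trial_500.phenotypes, "area", model=2)
        h2, g, p = variability_stats(vc)
        assert p >= g
        assert 0 <= h2 <= 1
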