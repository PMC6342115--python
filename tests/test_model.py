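"""Joint posterior construction, the Laplace fitter, and prediction."""

import numpy as np
import pytest
import scipy.sparse as sp

from prefsdm import (
    ArgumentError,
    GridGeometry,
    MaternHyperparams,
    ModelSpec,
    Problem,
    ScenarioConfig,
    bin_point_pattern,
    build_rw2_precision,
    fit,
    joint_neg_log_posterior,
    make_scenario,
    poisson_cell_nll,
    predict_surface,
)
from prefsdm.model import CovariateSmoothSpec, PriorSpec


@pytest.fixture(scope="module")
def tiny_problem():
    """A 6x6 preferential problem small enough for dense finite differences."""
    cfg = ScenarioConfig(grid=GridGeometry(6, 6), hyper=MaternHyperparams(1.0, 1.5), n=12)
    sc = make_scenario(cfg, seed=8)
    prob = Problem(ModelSpec(preferential=True, pad_cells=2), sc.preferential)
    hyper = prob.coder.decode(prob.coder.initial())
    rng = np.random.default_rng(0)
    x = 0.3 * rng.standard_normal(prob.dim)
    return prob, hyper, x


class TestBinPointPattern:
    def test_counts_are_conserved(self):
        grid = GridGeometry(8, 8)
        rng = np.random.default_rng(1)
        cells = rng.integers(0, 64, size=37)
        counts, exposure = bin_point_pattern(cells, grid)
        assert counts.sum() == 37
        assert np.all(exposure == grid.cell_area)

    def test_empty_pattern_gives_zero_counts(self):
        counts, _ = bin_point_pattern([], GridGeometry(5, 5))
        assert counts.sum() == 0

    def test_single_point_is_an_indicator(self):
        counts, _ = bin_point_pattern([13], GridGeometry(5, 5))
        expected = np.zeros(25)
        expected[13] = 1
        assert np.array_equal(counts, expected)

    def test_out_of_window_rejected(self):
        with pytest.raises(ArgumentError):
            bin_point_pattern([99], GridGeometry(5, 5))


class TestJointNegLogPosterior:
    def test_value_is_sum_of_components(self, tiny_problem):
        prob, hyper, x = tiny_problem
        parts = prob.neg_log_posterior_components(x, hyper)
        val, _, _ = joint_neg_log_posterior(x, hyper, prob)
        assert val == pytest.approx(sum(parts.values()), rel=1e-12)
        assert set(parts) == {"mark", "point_process", "field", "priors"}

    def test_gradient_matches_finite_differences(self, tiny_problem):
        prob, hyper, x = tiny_problem
        val, g, _ = prob.neg_log_posterior(x, hyper)
        rng = np.random.default_rng(3)
        idx = rng.choice(prob.dim, size=25, replace=False)
        h = 1e-5
        for i in idx:
            e = np.zeros(prob.dim)
            e[i] = h
            fd = (prob.neg_log_posterior_value(x + e, hyper)
                  - prob.neg_log_posterior_value(x - e, hyper)) / (2 * h)
            assert fd == pytest.approx(g[i], rel=1e-4, abs=1e-7)

    def test_hessian_matches_finite_differences(self, tiny_problem):
        prob, hyper, x = tiny_problem
        _, _, H = prob.neg_log_posterior(x, hyper)
        H = H.toarray()
        rng = np.random.default_rng(4)
        idx = rng.choice(prob.dim, size=8, replace=False)
        h = 1e-5
        for i in idx:
            e = np.zeros(prob.dim)
            e[i] = h
            _, gp, _ = prob.neg_log_posterior(x + e, hyper)
            _, gm, _ = prob.neg_log_posterior(x - e, hyper)
            fd_row = (gp - gm) / (2 * h)
            assert np.allclose(fd_row, H[i], rtol=1e-4, atol=1e-6)

    def test_nonpreferential_value_ignores_point_pattern(self):
        cfg = ScenarioConfig(grid=GridGeometry(6, 6), hyper=MaternHyperparams(1.0, 1.5), n=12)
        sc = make_scenario(cfg, seed=8)
        spec = ModelSpec(preferential=False, pad_cells=2)
        prob_a = Problem(spec, sc.preferential)
        prob_b = Problem(spec, sc.preferential, pattern_cells=np.zeros(12, dtype=int))
        hyper = prob_a.coder.decode(prob_a.coder.initial())
        x = np.linspace(-0.2, 0.2, prob_a.dim)
        assert prob_a.neg_log_posterior_value(x, hyper) == prob_b.neg_log_posterior_value(x, hyper)

    def test_rejects_nonfinite_latent(self, tiny_problem):
        prob, hyper, x = tiny_problem
        bad = x.copy()
        bad[0] = np.nan
        with pytest.raises(ArgumentError):
            prob.neg_log_posterior(bad, hyper)

    def test_poisson_term_invariant_to_exposure_rescaling(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(1.0, size=50)
        log_exp = np.zeros(50)
        eta = rng.normal(0, 1, size=50)
        a = poisson_cell_nll(counts, log_exp, eta)
        b = poisson_cell_nll(counts, log_exp + np.log(2.0), eta - np.log(2.0))
        assert a == pytest.approx(b, rel=1e-12)


class TestRw2Precision:
    def test_null_space_and_scaling(self):
        m = 12
        R = build_rw2_precision(m).toarray()
        ones = np.ones(m)
        lin = np.arange(1.0, m + 1)
        assert np.allclose(R @ ones, 0.0, atol=1e-10)
        assert np.allclose(R @ lin, 0.0, atol=1e-9)
        quad = lin ** 2
        assert np.linalg.norm(R @ quad) > 1e-6
        evals = np.linalg.eigvalsh(R)
        assert np.sum(evals > 1e-9) == m - 2
        marg = np.diag(np.linalg.pinv(R))
        assert np.exp(np.mean(np.log(marg))) == pytest.approx(1.0, rel=1e-8)

    def test_too_few_knots_rejected(self):
        with pytest.raises(ArgumentError):
            build_rw2_precision(2)


class TestFit:
    def test_nonpreferential_fit_ignores_pattern_perturbation(self, small_scenario):
        spec = ModelSpec(preferential=False)
        a = fit(spec, small_scenario.preferential, outer_maxfev=40, hyper_se=False)
        b = fit(
            spec,
            small_scenario.preferential,
            pattern_cells=np.zeros(len(small_scenario.preferential), dtype=int),
            outer_maxfev=40,
            hyper_se=False,
        )
        assert np.array_equal(a.x_mode, b.x_mode)
        assert a.hyper_mode == b.hyper_mode

    def test_fit_rejects_empty_sample(self, small_scenario):
        import copy

        empty = copy.copy(small_scenario.preferential)
        empty.cells = np.empty(0, dtype=int)
        empty.marks = np.empty(0)
        with pytest.raises(ArgumentError):
            fit(ModelSpec(preferential=True), empty)

    def test_fit_rejects_nonpositive_gamma_marks(self, small_scenario):
        import copy

        bad = copy.copy(small_scenario.preferential)
        bad.marks = bad.marks.copy()
        bad.marks[0] = -1.0
        with pytest.raises(ArgumentError):
            fit(ModelSpec(preferential=True), bad)

    def test_preferential_spec_requires_sharing(self):
        with pytest.raises(ArgumentError):
            ModelSpec(preferential=True, share_spatial=False)

    def test_gaussian_family_fit_runs(self):
        cfg = ScenarioConfig(
            grid=GridGeometry(12, 12),
            hyper=MaternHyperparams(1.0, 2.4),
            n=30,
            family="gaussian",
            noise_sd=0.3,
        )
        sc = make_scenario(cfg, seed=5)
        fr = fit(ModelSpec(mark_family="gaussian", preferential=True),
                 sc.preferential, outer_maxfev=60, hyper_se=False)
        assert fr.converged
        assert fr.hyper_mode["dispersion"] == pytest.approx(0.3, abs=0.3)

    def test_covariate_smooth_fit_runs(self):
        cfg = ScenarioConfig(grid=GridGeometry(12, 12), hyper=MaternHyperparams(1.0, 2.4), n=40)
        sc = make_scenario(cfg, seed=6)
        sample = sc.preferential
        raster = sc.field.grid.cell_centers()[:, 0]  # "depth" = x coordinate
        sample.covariate = raster[sample.cells]
        spec = ModelSpec(
            preferential=False,
            covariate_smooth=CovariateSmoothSpec(n_knots=8),
        )
        fr = fit(spec, sample, covariate_raster=raster, outer_maxfev=60, hyper_se=False)
        assert fr.converged
        assert fr.smooth is not None
        assert fr.smooth.values.shape == (8,)
        mean, _ = predict_surface(fr, covariate_raster=raster)
        assert np.all(mean.values > 0)

    def test_grid_integration_summaries(self):
        cfg = ScenarioConfig(grid=GridGeometry(10, 10), hyper=MaternHyperparams(1.0, 2.0), n=25)
        sc = make_scenario(cfg, seed=9)
        fr = fit(
            ModelSpec(preferential=False, pad_cells=3),
            sc.preferential,
            outer_maxfev=40,
            integrate_grid=True,
        )
        assert fr.hyper_summary is not None
        ranges = fr.hyper_summary.set_index("parameter")
        assert ranges.loc["range", "sd"] > 0
        # weighted mean should sit near the mode
        assert ranges.loc["range", "mean"] == pytest.approx(fr.hyper_mode["range"], rel=1.0)


class TestAlphaRecovery:
    def test_alpha_interval_covers_truth(self):
        """Simulation-based calibration of the sharing scale on scaled replicates.

        Data are generated with sampling probability proportional to
        exp(field), i.e. a sharing scale of 1; the equal-tailed 95% interval
        should cover 1 in at least 80% of fits, and the posterior modes for
        range and field sd should concentrate near the generating values.
        """
        cfg = ScenarioConfig(grid=GridGeometry(32, 32), hyper=MaternHyperparams(1.0, 6.4), n=100)
        covered = 0
        total = 0
        ranges, sds = [], []
        for rep in range(30):
            sc = make_scenario(cfg, seed=3000 + rep)
            fr = fit(ModelSpec(preferential=True), sc.preferential, outer_maxfev=80)
            if not fr.converged:
                continue
            total += 1
            lo, hi = fr.hyper_interval("alpha")
            if lo <= 1.0 <= hi:
                covered += 1
            ranges.append(fr.hyper_mode["range"])
            sds.append(fr.hyper_mode["sd"])
        assert total >= 25
        assert covered / total >= 0.80
        assert 0.5 * 6.4 <= np.median(ranges) <= 2.0 * 6.4
        assert 0.5 <= np.median(sds) <= 2.0


class TestPredictSurface:
    def test_positive_means_under_log_link(self, small_pref_fit):
        mean, sd = predict_surface(small_pref_fit)
        assert np.all(mean.values > 0)
        assert np.all(sd.values >= 0)

    def test_predictions_track_observed_marks(self, small_pref_fit, small_scenario):
        from scipy.stats import spearmanr

        mean, _ = predict_surface(small_pref_fit)
        rho, _ = spearmanr(
            mean.values[small_scenario.preferential.cells], small_scenario.preferential.marks
        )
        assert rho > 0

    def test_zero_variance_posterior_reduces_to_exp_mode(self, small_pref_fit, monkeypatch):
        monkeypatch.setattr(
            type(small_pref_fit), "latent_var", lambda self, S: np.zeros(S.shape[0])
        )
        mean, sd = predict_surface(small_pref_fit)
        prob = small_pref_fit._problem
        eta = (
            small_pref_fit.x_mode[prob.interior]
            + small_pref_fit.x_mode[prob.i_b_mark]
        )
        assert np.allclose(mean.values, np.exp(eta))
        assert np.allclose(sd.values, 0.0)

    def test_unconverged_fit_rejected(self, small_pref_fit):
        import copy

        from prefsdm import ConvergenceError

        broken = copy.copy(small_pref_fit)
        broken.converged = False
        with pytest.raises(ConvergenceError):
            predict_surface(broken)
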