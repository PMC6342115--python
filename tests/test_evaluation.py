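"""Scoring (DIC, LCPO, MAE) and the study runner."""

import math

import numpy as np
import pytest

from prefsdm import (
    ArgumentError,
    ConvergenceError,
    GridGeometry,
    LatentField,
    MaternHyperparams,
    ModelSpec,
    ScenarioConfig,
    StudyConfig,
    compute_dic,
    compute_lcpo,
    compute_mae,
    fit,
    make_scenario,
    run_simulation_study,
    summarize_study,
)
from prefsdm.likelihoods import GaussianLikelihood


class _ConjugatePosterior:
    """Exact normal-normal posterior exposing the scoring protocol.

    y_i ~ N(theta, s^2) with known s, theta ~ N(0, v0): the posterior of
    theta (and hence of eta_i = theta) is Gaussian in closed form, so DIC
    has a closed-form value to compare against.
    """

    converged = True

    def __init__(self, y, s, v0):
        self.y = np.asarray(y, dtype=float)
        n = self.y.size
        self.post_var = 1.0 / (n / s ** 2 + 1.0 / v0)
        self.post_mean = self.post_var * self.y.sum() / s ** 2
        self.obs_likelihood = GaussianLikelihood(sd=s)

    @property
    def eta_obs_mean(self):
        return np.full(self.y.size, self.post_mean)

    def sample_eta_obs(self, n_draws, rng):
        theta = self.post_mean + math.sqrt(self.post_var) * rng.standard_normal(n_draws)
        return np.repeat(theta[:, None], self.y.size, axis=1)

    def closed_form_dic(self):
        n = self.y.size
        s2 = self.obs_likelihood.sd ** 2
        const = n * math.log(2 * math.pi * s2)
        dhat = const + np.sum((self.y - self.post_mean) ** 2) / s2
        p_d = n * self.post_var / s2
        dbar = dhat + p_d
        return dbar + p_d, dbar, p_d


class TestComputeDic:
    def test_identity_holds_exactly(self, small_pref_fit, small_scenario):
        res = compute_dic(small_pref_fit, small_scenario.preferential, seed=4)
        assert res.dic == res.dbar + res.pd

    def test_point_mass_posterior_has_zero_pd(self):
        post = _ConjugatePosterior(y=[1.0, 2.0, 0.5], s=1.0, v0=1.0)
        post.post_var = 0.0  # degenerate: no posterior spread
        res = compute_dic(post, np.array([1.0, 2.0, 0.5]), n_draws=500, seed=0)
        assert res.pd == pytest.approx(0.0, abs=1e-9)

    def test_matches_conjugate_closed_form(self):
        rng = np.random.default_rng(12)
        y = rng.normal(1.5, 0.7, size=25)
        post = _ConjugatePosterior(y, s=0.7, v0=4.0)
        res = compute_dic(post, y, n_draws=40_000, seed=1)
        dic, dbar, p_d = post.closed_form_dic()
        # MC error of Dbar scales like sqrt(2 pD) / sqrt(S)
        tol = 6 * math.sqrt(2 * p_d + 4 * p_d ** 2) / math.sqrt(40_000) + 0.05
        assert res.pd == pytest.approx(p_d, abs=tol)
        assert res.dic == pytest.approx(dic, abs=2 * tol)

    def test_unconverged_fit_rejected(self, small_pref_fit, small_scenario):
        import copy

        broken = copy.copy(small_pref_fit)
        broken.converged = False
        with pytest.raises(ConvergenceError):
            compute_dic(broken, small_scenario.preferential)


class TestComputeLcpo:
    def test_cpo_are_finite_densities(self, small_pref_fit, small_scenario):
        res = compute_lcpo(small_pref_fit, small_scenario.preferential)
        assert np.all(res.cpo > 0)
        assert np.all(np.isfinite(res.cpo))
        assert not res.flagged

    def test_approximate_agrees_with_exact_loo(self):
        cfg = ScenarioConfig(grid=GridGeometry(10, 10), hyper=MaternHyperparams(1.0, 2.0), n=20)
        sc = make_scenario(cfg, seed=21)
        fr = fit(ModelSpec(preferential=True, pad_cells=3), sc.preferential,
                 outer_maxfev=80, hyper_se=False)
        approx = compute_lcpo(fr, sc.preferential, method="approximate")
        exact = compute_lcpo(fr, sc.preferential, method="exact_loo")
        assert approx.lcpo == pytest.approx(exact.lcpo, rel=0.05)

    def test_structured_fit_beats_shuffled_fit(self):
        cfg = ScenarioConfig(grid=GridGeometry(16, 16), hyper=MaternHyperparams(1.0, 4.0), n=60)
        sc = make_scenario(cfg, seed=31)
        import copy

        structured = sc.preferential
        shuffled = copy.copy(structured)
        rng = np.random.default_rng(0)
        shuffled.marks = rng.permutation(structured.marks)
        spec = ModelSpec(preferential=False)
        fit_struct = fit(spec, structured, outer_maxfev=60, hyper_se=False)
        fit_noise = fit(spec, shuffled, outer_maxfev=60, hyper_se=False)
        l_struct = compute_lcpo(fit_struct, structured).lcpo
        l_noise = compute_lcpo(fit_noise, shuffled).lcpo
        assert l_struct < l_noise

    def test_needs_two_observations(self, small_pref_fit):
        class OneMark:
            marks = np.array([1.0])

        with pytest.raises(ArgumentError):
            compute_lcpo(small_pref_fit, OneMark())


class TestComputeMae:
    def test_identities(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=64)
        b = rng.normal(size=64)
        assert compute_mae(a, a) == 0.0
        assert compute_mae(a + 0.7, a) == pytest.approx(0.7, rel=1e-12)
        assert compute_mae(a, b) == compute_mae(b, a)
        assert compute_mae(a, b) >= 0.0

    def test_held_out_subset_flag(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=50), rng.normal(size=50)
        cells = np.array([3, 10, 41])
        assert compute_mae(a, b, cells=cells) == pytest.approx(
            np.mean(np.abs(a[cells] - b[cells]))
        )
        with pytest.raises(ArgumentError):
            compute_mae(a, b, cells=[60])

    def test_grid_mismatch_rejected(self):
        g1 = GridGeometry(4, 4)
        g2 = GridGeometry(4, 5)
        with pytest.raises(ArgumentError):
            compute_mae(
                LatentField(g1, np.zeros(16)), LatentField(g2, np.zeros(20))
            )


class TestSimulationStudy:
    def test_smoke_study_produces_full_table(self):
        cfg = StudyConfig(replicates=2, nx=12, ny=12, n=30, outer_maxfev=40, dic_draws=200)
        res = run_simulation_study(cfg, seed=5)
        assert len(res.table) == 2 * 2 * 2  # replicate x design x model
        assert set(res.table.design) == {"preferential", "uniform"}
        assert set(res.table.model) == {"preferential", "nonpreferential"}
        assert {"dic", "lcpo", "mae"} <= set(res.table.columns)
        assert len(res.summary) == 6

    def test_study_deterministic_given_seed(self):
        cfg = StudyConfig(replicates=2, nx=10, ny=10, n=20, outer_maxfev=30, dic_draws=100)
        a = run_simulation_study(cfg, seed=9)
        b = run_simulation_study(cfg, seed=9)
        pd_a = a.table.drop(columns=["seed"])
        pd_b = b.table.drop(columns=["seed"])
        assert pd_a.equals(pd_b)

    def test_summary_invariant_to_replicate_ordering(self):
        cfg = StudyConfig(replicates=2, nx=10, ny=10, n=20, outer_maxfev=30, dic_draws=100)
        res = run_simulation_study(cfg, seed=9)
        reordered = res.table.sort_values(["model", "replicate"], ascending=False)
        assert summarize_study(reordered).equals(res.summary)

    def test_rejects_single_replicate(self):
        with pytest.raises(ArgumentError):
            StudyConfig(replicates=1)
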