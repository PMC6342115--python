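"""Model scoring (DIC, LCPO, MAE) and the simulation study.

All three criteria are computed on the *mark* likelihood only, so the
joint preferential model and the mark-only baseline are directly
comparable; lower is better for each.

The study runner reproduces the simulation experiment: per replicate one
latent field, one preferential and one uniform sample, four fits
(2 designs x 2 models), and the three scores per fit, summarized as the
fraction of replicates in which the preferential model scores lower.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss

from .exceptions import ArgumentError, ConvergenceError
from .grids import GridGeometry, LatentField
from .model import ModelSpec, Problem, _newton, fit, predict_surface
from .random_fields import MaternHyperparams
from .sampling import ScenarioConfig, make_scenario, true_abundance_surface

logger = logging.getLogger(__name__)

_GH_NODES = 41


@dataclass(frozen=True)
class DicResult:
    dic: float
    dbar: float
    pd: float


def compute_dic(
    fit_result, data, n_draws: int = 1000, seed: int = 0, method: str = "auto"
) -> DicResult:
    """Deviance information criterion over the mark likelihood.

    Dbar is the posterior-mean deviance of the mark linear predictor under
    the Gaussian approximation at the hyperparameter mode; pD = Dbar -
    D(posterior mean); DIC = Dbar + pD.  When the likelihood family admits
    a closed-form Gaussian expectation (all built-in families do) the
    exact S -> infinity limit is used (``method='analytic'``); otherwise —
    or with ``method='mc'`` — Dbar averages over ``n_draws`` seeded draws.
    Accepts any object exposing ``eta_obs_mean``, ``obs_likelihood``,
    ``converged`` and either ``eta_obs_var`` or ``sample_eta_obs``.
    """
    if method not in ("auto", "analytic", "mc"):
        raise ArgumentError(f"unknown DIC method {method!r}")
    if not getattr(fit_result, "converged", False):
        raise ConvergenceError("DIC requires a converged fit")
    y = np.asarray(data.marks if hasattr(data, "marks") else data, dtype=float)
    lik = fit_result.obs_likelihood
    m = np.asarray(fit_result.eta_obs_mean, dtype=float)
    analytic = hasattr(lik, "expected_deviance") and hasattr(fit_result, "eta_obs_var")
    if method == "analytic" and not analytic:
        raise ArgumentError("analytic DIC unavailable for this posterior object")
    if method in ("auto", "analytic") and analytic:
        v = np.asarray(fit_result.eta_obs_var(), dtype=float)
        dbar = float(np.sum(lik.expected_deviance(y, m, v)))
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        draws = fit_result.sample_eta_obs(n_draws, rng)
        dev_draws = -2.0 * np.sum(lik.logpdf(y[None, :], draws), axis=1)
        dbar = float(np.mean(dev_draws))
    dhat = float(-2.0 * np.sum(lik.logpdf(y, m)))
    p_d = dbar - dhat
    return DicResult(dic=dbar + p_d, dbar=dbar, pd=p_d)


@dataclass
class LcpoResult:
    cpo: np.ndarray
    lcpo: float
    underflow: np.ndarray  # indices with numerically zero CPO

    @property
    def flagged(self) -> bool:
        return self.underflow.size > 0


def _log_mean_gh(logpdf_at, m, sd):
    """Vector of log E[exp(g(eta_i))], eta_i ~ N(m_i, sd_i^2), via Gauss-Hermite."""
    nodes, weights = hermegauss(_GH_NODES)
    logw = np.log(weights) - 0.5 * math.log(2.0 * math.pi)
    eta = m[:, None] + sd[:, None] * nodes[None, :]
    vals = logpdf_at(eta) + logw[None, :]
    from scipy.special import logsumexp

    return logsumexp(vals, axis=1)


def compute_lcpo(fit_result, data, method: str = "approximate") -> LcpoResult:
    """Leave-one-out conditional predictive ordinates and their summary.

    CPO_i is the predictive density of mark i given the remaining data;
    LCPO = -(1/n) sum log CPO_i (lower is better).  ``approximate``
    deflates the full-data Gaussian marginal of eta_i by observation i's
    local quadratic likelihood contribution (importance reweighting of
    the Gaussian approximation, as in standard nested-Laplace software)
    and integrates the predictive against the deflated marginal;
    ``exact_loo`` re-optimizes the latent field with observation i
    removed (hyperparameters held at the full-data mode) and integrates
    the 1-D predictive directly.  Both integrals use Gauss-Hermite
    quadrature, so results are deterministic.
    """
    if method not in ("approximate", "exact_loo"):
        raise ArgumentError(f"unknown LCPO method {method!r}")
    y = np.asarray(data.marks, dtype=float)
    n = y.size
    if n < 2:
        raise ArgumentError("LCPO needs at least two observations")
    lik = fit_result.obs_likelihood
    if method == "approximate":
        m = fit_result.eta_obs_mean
        v = fit_result.eta_obs_var()
        c = lik.d2_nll(y, m)  # likelihood curvature of obs i at the mode
        g = lik.d_nll(y, m)
        prec_loo = 1.0 / v - c
        ok = prec_loo > 0
        v_loo = np.where(ok, 1.0 / np.where(ok, prec_loo, 1.0), v)
        m_loo = np.where(ok, v_loo * (m / v - c * m + g), m)
        log_cpo = _log_mean_gh(lambda eta: lik.logpdf(y[:, None], eta), m_loo, np.sqrt(v_loo))
    else:
        problem = fit_result._problem
        hyper = fit_result._hyper
        log_cpo = np.zeros(n)
        for i in range(n):
            sub = _drop_mark(problem, i)
            inner = _newton(sub, hyper, np.asarray(fit_result.x_mode, dtype=float))
            a_i = problem.A_mark[i]
            m_i = float((a_i @ inner["x"])[0])
            col = inner["lu"].solve(a_i.toarray().ravel())
            v_i = max(float((a_i @ col)[0]), 0.0)
            log_cpo[i] = _log_mean_gh(
                lambda eta: lik.logpdf(y[i], eta), np.array([m_i]), np.array([math.sqrt(v_i)])
            )[0]
    cpo = np.exp(log_cpo)
    underflow = np.flatnonzero(~np.isfinite(log_cpo) | (cpo == 0.0))
    lcpo = float(-np.mean(log_cpo))
    if underflow.size:
        logger.warning("CPO underflow at observations %s; LCPO flagged", underflow.tolist())
    return LcpoResult(cpo=cpo, lcpo=lcpo, underflow=underflow)


def _drop_mark(problem: Problem, i: int) -> Problem:
    """A shallow problem copy with the i-th mark term removed (location kept)."""
    import copy

    sub = copy.copy(problem)
    data = copy.copy(problem.data)
    keep = np.ones(len(problem.data), dtype=bool)
    keep[i] = False
    data.cells = problem.data.cells[keep]
    data.marks = problem.data.marks[keep]
    sub.data = data
    sub.A_mark = problem.A_mark[keep]
    return sub


def compute_mae(predicted, truth, cells=None) -> float:
    """Mean absolute error between a predicted and a reference surface.

    By default the error averages over every grid cell (full-surface
    truth is available in simulations); ``cells`` restricts it to a
    held-out subset of flat cell indices.
    """
    p = predicted.values if isinstance(predicted, LatentField) else np.asarray(predicted, dtype=float)
    t = truth.values if isinstance(truth, LatentField) else np.asarray(truth, dtype=float)
    if isinstance(predicted, LatentField) and isinstance(truth, LatentField):
        if predicted.grid != truth.grid:
            raise ArgumentError("predicted and truth surfaces live on different grids")
    if p.shape != t.shape:
        raise ArgumentError(f"surface shapes differ: {p.shape} vs {t.shape}")
    if cells is not None:
        cells = np.asarray(cells, dtype=int)
        if cells.size == 0 or cells.min() < 0 or cells.max() >= p.size:
            raise ArgumentError("held-out cell indices outside the surface")
        p, t = p[cells], t[cells]
    return float(np.mean(np.abs(p - t)))


# ---------------------------------------------------------------------------
# the simulation study


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of the preferential-vs-baseline simulation study.

    The default is the desk-scale study: 30 replicates on a 32x32 grid
    with 100 sampling locations per design, preferentiality b=1 and gamma
    marks with shape 10.  ``paper_scale()`` gives the full experiment
    (100 replicates on a 100x100 grid), which is long-running.
    """

    replicates: int = 30
    nx: int = 32
    ny: int = 32
    range_: Optional[float] = None  # default: 20% of the window width
    sigma2: float = 1.0
    n: int = 100
    b: float = 1.0
    family: str = "gamma"
    shape: float = 10.0
    noise_sd: float = 0.1
    intercept: float = 0.0
    outer_maxfev: int = 100
    dic_draws: int = 1000

    def __post_init__(self):
        if self.replicates < 2:
            raise ArgumentError("need at least 2 replicates")

    @classmethod
    def paper_scale(cls) -> "StudyConfig":
        return cls(replicates=100, nx=100, ny=100)

    def scenario_config(self) -> ScenarioConfig:
        grid = GridGeometry(self.nx, self.ny)
        rng_ = self.range_ if self.range_ is not None else 0.2 * grid.width
        return ScenarioConfig(
            grid=grid,
            hyper=MaternHyperparams(sigma2=self.sigma2, range_=rng_),
            n=self.n,
            b=self.b,
            family=self.family,
            shape=self.shape,
            noise_sd=self.noise_sd,
            intercept=self.intercept,
        )


@dataclass
class StudyResult:
    """Per-replicate scores plus the preferential-better summary."""

    table: pd.DataFrame  # one row per replicate x design x model
    summary: pd.DataFrame  # per design x score: fraction preferential better
    n_failed: int
    config: StudyConfig
    seed: int

    def fraction_preferential_better(self, design: str, score: str) -> float:
        row = self.summary[(self.summary.design == design) & (self.summary.score == score)]
        return float(row["fraction_preferential_better"].iloc[0])


def score_fit(fit_result, data, truth_surface, dic_draws=1000, seed=0) -> dict:
    """DIC, LCPO and full-grid MAE for one converged fit."""
    dic = compute_dic(fit_result, data, n_draws=dic_draws, seed=seed)
    lcpo = compute_lcpo(fit_result, data, method="approximate")
    mean_surface, _ = predict_surface(fit_result)
    mae = compute_mae(mean_surface.values, truth_surface)
    return {"dic": dic.dic, "lcpo": lcpo.lcpo, "mae": mae}


def run_simulation_study(config: StudyConfig = StudyConfig(), seed: int = 0) -> StudyResult:
    """Run the full replicate x design x model comparison.

    Per replicate: one scenario, then preferential and non-preferential
    fits to both the preferential and the uniform sample.  Fit failures
    are logged, excluded from the summary fractions, and counted.
    Deterministic for a given master seed.
    """
    scen_cfg = config.scenario_config()
    pref_spec = ModelSpec(mark_family=config.family, preferential=True)
    nonpref_spec = ModelSpec(mark_family=config.family, preferential=False)
    rows = []
    n_failed = 0
    for r in range(config.replicates):
        rep_seed = int(np.random.SeedSequence(seed, spawn_key=(r,)).generate_state(1)[0] % (2**31))
        scenario = make_scenario(scen_cfg, seed=rep_seed)
        truth = true_abundance_surface(scenario)
        for design_name, sample in (
            ("preferential", scenario.preferential),
            ("uniform", scenario.uniform),
        ):
            for model_name, spec in (("preferential", pref_spec), ("nonpreferential", nonpref_spec)):
                row = {
                    "replicate": r,
                    "seed": rep_seed,
                    "design": design_name,
                    "model": model_name,
                    "converged": False,
                    "dic": np.nan,
                    "lcpo": np.nan,
                    "mae": np.nan,
                }
                try:
                    fr = fit(spec, sample, outer_maxfev=config.outer_maxfev, hyper_se=False)
                    scores = score_fit(
                        fr, sample, truth, dic_draws=config.dic_draws, seed=rep_seed
                    )
                    row.update(converged=True, **scores)
                except (ConvergenceError, ArgumentError) as exc:
                    n_failed += 1
                    logger.warning(
                        "fit failed (replicate %d, %s sample, %s model): %s",
                        r, design_name, model_name, exc,
                    )
                rows.append(row)
    table = pd.DataFrame(rows)
    summary = summarize_study(table)
    return StudyResult(table=table, summary=summary, n_failed=n_failed, config=config, seed=seed)


def summarize_study(table: pd.DataFrame) -> pd.DataFrame:
    """Fraction of replicates with a lower preferential-model score.

    Only replicates where both models converged enter a fraction; the
    result is invariant to replicate ordering.
    """
    rows = []
    for design in sorted(table.design.unique()):
        sub = table[table.design == design]
        pref = sub[sub.model == "preferential"].set_index("replicate")
        base = sub[sub.model == "nonpreferential"].set_index("replicate")
        both = pref.index.intersection(base.index)
        ok = both[(pref.loc[both, "converged"]) & (base.loc[both, "converged"])]
        for score in ("dic", "lcpo", "mae"):
            frac = float(np.mean(pref.loc[ok, score].values < base.loc[ok, score].values))
            rows.append(
                {
                    "design": design,
                    "score": score,
                    "fraction_preferential_better": frac,
                    "n_compared": int(len(ok)),
                    "n_excluded": int(len(both) - len(ok)),
                }
            )
    return pd.DataFrame(rows)
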