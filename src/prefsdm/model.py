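"""Joint preferential-sampling model and its Laplace-approximation fitter.

Two model families are fitted over the same latent machinery:

* **preferential** (joint): the sampling locations are a log-Gaussian Cox
  process whose log-intensity shares the latent Matérn field W of the mark
  (abundance) process, scaled by alpha:

      y_i   ~  family(mu_i, rho),   link(mu_i) = b' + W(s_i) [+ f(d_i)]
      N(cell j) ~ Poisson( |cell| * exp(b0 + alpha * W_j [+ alpha_d f(d_j)]) )

* **non-preferential** (baseline): the mark layer alone; the point pattern
  carries no information (an independent field in the two-field notation).

Inference is empirical-Bayes Laplace: an inner Newton optimization of the
latent vector at fixed hyperparameters (sparse Cholesky/LU solves), and an
outer derivative-free maximization of the Laplace-approximated log
marginal posterior of the hyperparameters (2 log kappa, log tau, log
dispersion, alpha, ...), optionally followed by a coarse-grid weighting
step for posterior-mean hyperparameter summaries.  The LGCP likelihood is
approximated on the lattice by per-cell Poisson counts with the cell area
as exposure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize

from .exceptions import ArgumentError, ConvergenceError
from .grids import GridGeometry, LatentField
from .likelihoods import make_likelihood
from .random_fields import (
    MaternHyperparams,
    SpdePrecision,
    _lattice_laplacian,
    build_spde_precision,
)
from .sampling import MarkedSample

INNER_TOL = 1e-8
INNER_MAXIT = 50


# ---------------------------------------------------------------------------
# specification objects


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the joint model.

    The spatial field prior acts on the internal coordinates
    (2 log kappa, log tau).  In the default ``gaussian`` style the two
    coordinates get independent normals whose means are set so that the
    prior-median range and prior-median standard deviation equal
    ``prior_median_range`` (default: half the study window, resolved at fit
    time) and ``prior_median_sd``.  The ``pc`` style uses penalized-
    complexity priors: P(range < r0) = p_r and P(sd > s0) = p_s.
    """

    fixed_effect_variance: float = 100.0
    spatial_style: str = "gaussian"  # "gaussian" | "pc"
    prior_median_range: Optional[float] = None
    prior_median_sd: float = 1.0
    sd_2logkappa: float = math.sqrt(10.0)
    sd_logtau: float = math.sqrt(10.0)
    pc_range: Optional[tuple[float, float]] = None  # (r0, p_r)
    pc_sigma: Optional[tuple[float, float]] = None  # (s0, p_s)
    alpha_prior_sd: float = 1.0
    obs_hyper_prior_mean: float = 0.0  # on the log scale of shape / sd
    obs_hyper_prior_sd: float = 10.0
    rw2_prior: tuple[float, float] = (4.0, 1e-4)  # LogGamma(a, b) on the RW2 precision

    def __post_init__(self):
        if self.spatial_style not in ("gaussian", "pc"):
            raise ArgumentError(f"unknown spatial prior style {self.spatial_style!r}")
        if self.spatial_style == "pc" and (self.pc_range is None or self.pc_sigma is None):
            raise ArgumentError("pc prior style requires pc_range and pc_sigma")
        if not self.fixed_effect_variance > 0:
            raise ArgumentError("fixed_effect_variance must be positive")


@dataclass(frozen=True)
class CovariateSmoothSpec:
    """A second-order random walk smooth over a binned covariate."""

    n_knots: int = 20

    def __post_init__(self):
        if self.n_knots < 3:
            raise ArgumentError("a RW2 smooth needs at least 3 knots")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of the model to fit."""

    mark_family: str = "gamma"
    preferential: bool = True
    share_spatial: bool = True
    share_covariate: bool = False
    covariate_smooth: Optional[CovariateSmoothSpec] = None
    priors: PriorSpec = PriorSpec()
    pad_cells: Optional[int] = None  # boundary extension; default 20% of the longer side

    def __post_init__(self):
        if self.mark_family not in ("gamma", "gaussian", "lognormal", "poisson"):
            raise ArgumentError(f"unknown mark family {self.mark_family!r}")
        if self.preferential and not (self.share_spatial or self.share_covariate):
            raise ArgumentError("a preferential model must share at least one component")
        if self.share_covariate and self.covariate_smooth is None:
            raise ArgumentError("share_covariate requires a covariate_smooth")
        if not self.preferential and (self.share_covariate):
            raise ArgumentError("share_covariate only makes sense for a preferential model")


@dataclass(frozen=True)
class HyperState:
    """Hyperparameters at one point of the outer optimization."""

    matern: MaternHyperparams
    likelihood: object  # family likelihood carrying the dispersion
    alpha: float = 1.0
    rho_d: float = 1.0
    alpha_d: float = 0.0


@dataclass
class CovariateSmooth:
    """Fitted RW2 smooth: knot locations, effect values, their sds, precision."""

    knots: np.ndarray
    values: np.ndarray
    sd: np.ndarray
    precision: float


# ---------------------------------------------------------------------------
# building blocks


def bin_point_pattern(locations, grid: GridGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Lattice approximation of a point pattern: per-cell counts + exposures."""
    cells = np.asarray(locations, dtype=int).ravel()
    if cells.size and (cells.min() < 0 or cells.max() >= grid.n_cells):
        raise ArgumentError("point-pattern location outside the grid")
    counts = np.bincount(cells, minlength=grid.n_cells).astype(float)
    exposure = np.full(grid.n_cells, grid.cell_area)
    return counts, exposure


def poisson_cell_nll(counts, log_exposure, eta):
    """Negative log-likelihood of independent Poisson cell counts.

    The cell intensity is exposure * exp(eta); the count-factorial constant
    is dropped.  Doubling the exposures while halving the intensities
    (eta -> eta - log 2, log_exposure -> log_exposure + log 2) leaves the
    value unchanged.
    """
    log_lam = np.asarray(log_exposure) + np.asarray(eta)
    return float(np.sum(np.exp(log_lam) - np.asarray(counts) * log_lam))


def build_rw2_precision(m: int) -> sp.csr_matrix:
    """Second-difference (RW2) structure matrix, scaled to generalized variance 1.

    Rank m-2 with null space spanned by the constant and linear vectors; the
    geometric mean of the marginal variances (diagonal of the pseudo-inverse)
    equals 1 after scaling.
    """
    if m < 3:
        raise ArgumentError(f"RW2 needs at least 3 knots, got {m}")
    e = np.ones(m - 2)
    D = sp.diags([e, -2.0 * e, e], [0, 1, 2], shape=(m - 2, m))
    R = (D.T @ D).toarray()
    marg = np.diag(np.linalg.pinv(R))
    g = float(np.exp(np.mean(np.log(marg))))
    return sp.csr_matrix(R * g)


def _bin_covariate(values: np.ndarray, n_knots: int) -> tuple[np.ndarray, np.ndarray]:
    """Assign covariate values to equal-width bins; returns (knots, bin index)."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ArgumentError("covariate values must be finite")
    lo, hi = v.min(), v.max()
    if hi <= lo:
        raise ArgumentError("covariate is constant; cannot build a smooth")
    edges = np.linspace(lo, hi, n_knots + 1)
    idx = np.clip(np.digitize(v, edges[1:-1]), 0, n_knots - 1)
    knots = 0.5 * (edges[:-1] + edges[1:])
    return knots, idx


# ---------------------------------------------------------------------------
# the assembled problem


class Problem:
    """Data + model spec assembled into a differentiable posterior.

    The latent vector is laid out as [W (extended grid), b_mark, (b_pp),
    (f knots)].  All design matrices are sparse and built once; only the
    sharing scales rescale the point-process design between hyperparameter
    evaluations.
    """

    def __init__(
        self,
        spec: ModelSpec,
        data: MarkedSample,
        grid: Optional[GridGeometry] = None,
        covariate_raster: Optional[np.ndarray] = None,
        pattern_cells: Optional[np.ndarray] = None,
    ):
        if len(data) == 0:
            raise ArgumentError("cannot fit a model to an empty sample")
        self.spec = spec
        self.data = data
        self.grid = grid or data.grid
        make_likelihood(spec.mark_family, 1.0).validate(data.marks)

        pad = spec.pad_cells
        if pad is None:
            pad = int(math.ceil(0.2 * max(self.grid.nx, self.grid.ny)))
        self.pad_cells = pad
        self.grid_ext = self.grid.expand(pad)
        self.interior = self.grid.interior_of(self.grid_ext, pad)
        self.n_field = self.grid_ext.n_cells

        # latent layout
        self.i_b_mark = self.n_field
        self.n_fixed = 2 if spec.preferential else 1
        self.i_b_pp = self.n_field + 1 if spec.preferential else None
        self.n_knots = spec.covariate_smooth.n_knots if spec.covariate_smooth else 0
        self.i_f = self.n_field + self.n_fixed
        self.dim = self.n_field + self.n_fixed + self.n_knots

        n = len(data)
        obs_cells_ext = self.interior[data.cells]

        # covariate smooth plumbing
        self.knots = None
        self._B_obs_idx = None
        self._cell_knot_idx = None
        if spec.covariate_smooth is not None:
            if data.covariate is None:
                raise ArgumentError("spec requests a covariate smooth but data has no covariate")
            self.knots, self._B_obs_idx = _bin_covariate(data.covariate, self.n_knots)
            # re-bin with the observation-derived edges so obs and raster share knots
            if covariate_raster is not None:
                raster = np.asarray(covariate_raster, dtype=float).ravel()
                if raster.size != self.grid.n_cells:
                    raise ArgumentError("covariate raster does not match the grid")
                centers = self.knots
                self._cell_knot_idx = np.argmin(
                    np.abs(raster[:, None] - centers[None, :]), axis=1
                )
            elif spec.share_covariate:
                raise ArgumentError("share_covariate requires a covariate raster over the grid")
            self._R_rw2 = build_rw2_precision(self.n_knots)

        # mark design: eta_mark = b_mark + W[cell] + f[bin]
        rows, cols, vals = [], [], []
        rows += list(range(n)) * 2
        cols += list(obs_cells_ext) + [self.i_b_mark] * n
        vals += [1.0] * (2 * n)
        if self._B_obs_idx is not None:
            rows += list(range(n))
            cols += list(self.i_f + self._B_obs_idx)
            vals += [1.0] * n
        self.A_mark = sp.csr_matrix((vals, (rows, cols)), shape=(n, self.dim))

        # point-process design pieces (combined with alpha / alpha_d per eval)
        if spec.preferential:
            if pattern_cells is None:
                pattern_cells = data.cells
            counts, exposure = bin_point_pattern(pattern_cells, self.grid)
            self.counts = counts
            self.log_exposure = np.log(exposure)
            ni = self.grid.n_cells
            if spec.share_spatial:
                self._P_w = sp.csr_matrix(
                    (np.ones(ni), (np.arange(ni), self.interior)), shape=(ni, self.dim)
                )
            else:
                self._P_w = sp.csr_matrix((ni, self.dim))
            self._P_b = sp.csr_matrix(
                (np.ones(ni), (np.arange(ni), np.full(ni, self.i_b_pp))), shape=(ni, self.dim)
            )
            if spec.share_covariate:
                self._P_f = sp.csr_matrix(
                    (np.ones(ni), (np.arange(ni), self.i_f + self._cell_knot_idx)),
                    shape=(ni, self.dim),
                )
            else:
                self._P_f = sp.csr_matrix((ni, self.dim))

        # soft level/slope priors that make the intrinsic RW2 block proper
        if self.n_knots:
            m = self.n_knots
            u1 = np.ones(m) / math.sqrt(m)
            t = np.arange(m, dtype=float)
            t -= t.mean()
            u2 = t / np.linalg.norm(t)
            self._f_constraint = (np.outer(u1, u1) + np.outer(u2, u2)) / spec.priors.fixed_effect_variance

        self._field_cache: tuple | None = None
        self.coder = _HyperCoder(spec, self.grid, data)

        # value-only field-prior fast path (no sparse construction per call)
        self._L_ext = _lattice_laplacian(self.grid_ext.nx, self.grid_ext.ny)
        mux = 2.0 * (1.0 - np.cos(np.pi * np.arange(self.grid_ext.nx) / self.grid_ext.nx))
        muy = 2.0 * (1.0 - np.cos(np.pi * np.arange(self.grid_ext.ny) / self.grid_ext.ny))
        self._lap_spectrum = (mux[None, :] + muy[:, None]).ravel()

    def _field_quad(self, w: np.ndarray, matern: MaternHyperparams) -> float:
        """0.5 * w' Q w through the square-root lattice operator."""
        h = self.grid.cell_size
        mw = (matern.kappa ** 2 * h ** 2) * w + self._L_ext @ w
        scale = matern.tau / h
        return 0.5 * float(scale ** 2 * (mw @ mw))

    def _field_logdet(self, matern: MaternHyperparams) -> float:
        h = self.grid.cell_size
        lam = matern.kappa ** 2 * h ** 2 + self._lap_spectrum
        return 2.0 * self.n_field * math.log(matern.tau / h) + 2.0 * float(
            np.sum(np.log(lam))
        )

    # -- pieces ------------------------------------------------------------

    def field_precision(self, hyper: HyperState) -> SpdePrecision:
        key = (hyper.matern.kappa, hyper.matern.tau)
        if self._field_cache is None or self._field_cache[0] != key:
            spde = build_spde_precision(self.grid, hyper.matern, pad_cells=self.pad_cells)
            self._field_cache = (key, spde)
        return self._field_cache[1]

    def _f_block_precision(self, hyper: HyperState) -> np.ndarray:
        return hyper.rho_d * self._R_rw2.toarray() + self._f_constraint

    def _A_pp(self, hyper: HyperState) -> sp.csr_matrix:
        A = hyper.alpha * self._P_w + self._P_b
        if self.spec.share_covariate:
            A = A + hyper.alpha_d * self._P_f
        return A.tocsr()

    def neg_log_posterior_components(self, x: np.ndarray, hyper: HyperState) -> dict:
        """The four additive pieces of the (unnormalized) negative log posterior."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dim,):
            raise ArgumentError(f"latent vector must have length {self.dim}")
        if not np.all(np.isfinite(x)):
            raise ArgumentError("latent vector contains non-finite values")
        w = x[: self.n_field]
        eta_m = self.A_mark @ x
        lik = hyper.likelihood
        lik.validate(self.data.marks)
        mark = float(lik.nll(self.data.marks, eta_m))
        pp = 0.0
        if self.spec.preferential:
            eta_p = np.full(self.grid.n_cells, x[self.i_b_pp])
            if self.spec.share_spatial:
                eta_p = eta_p + hyper.alpha * w[self.interior]
            if self.spec.share_covariate:
                eta_p = eta_p + hyper.alpha_d * x[self.i_f + self._cell_knot_idx]
            pp = poisson_cell_nll(self.counts, self.log_exposure, eta_p)
        field = self._field_quad(w, hyper.matern)
        priors = 0.5 * float(
            np.sum(x[self.n_field : self.n_field + self.n_fixed] ** 2)
        ) / self.spec.priors.fixed_effect_variance
        if self.n_knots:
            f = x[self.i_f :]
            priors += 0.5 * float(f @ (self._f_block_precision(hyper) @ f))
        return {"mark": mark, "point_process": pp, "field": field, "priors": priors}

    def neg_log_posterior_value(self, x: np.ndarray, hyper: HyperState) -> float:
        return float(sum(self.neg_log_posterior_components(x, hyper).values()))

    def neg_log_posterior(self, x: np.ndarray, hyper: HyperState):
        """Value, gradient and sparse Hessian of the joint negative log posterior."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.dim,):
            raise ArgumentError(f"latent vector must have length {self.dim}")
        if not np.all(np.isfinite(x)):
            raise ArgumentError("latent vector contains non-finite values")
        lik = hyper.likelihood
        y = self.data.marks
        lik.validate(y)
        eta_m = self.A_mark @ x
        val = float(lik.nll(y, eta_m))
        g = self.A_mark.T @ lik.d_nll(y, eta_m)
        H = (self.A_mark.T @ sp.diags(lik.d2_nll(y, eta_m)) @ self.A_mark).tocsr()
        if self.spec.preferential:
            A_p = self._A_pp(hyper)
            eta_p = self.log_exposure + A_p @ x
            lam = np.exp(eta_p)
            val += float(np.sum(lam - self.counts * (eta_p)))
            g = g + A_p.T @ (lam - self.counts)
            H = H + (A_p.T @ sp.diags(lam) @ A_p).tocsr()
        Qx = self.prior_precision(hyper)
        val += 0.5 * float(x @ (Qx @ x))
        g = g + Qx @ x
        H = H + Qx
        return val, np.asarray(g).ravel(), H.tocsc()

    def prior_precision(self, hyper: HyperState) -> sp.csr_matrix:
        key = (hyper.matern.kappa, hyper.matern.tau, hyper.rho_d)
        cached = getattr(self, "_qx_cache", None)
        if cached is not None and cached[0] == key:
            return cached[1]
        spde = self.field_precision(hyper)
        blocks = [spde.Q, sp.identity(self.n_fixed) / self.spec.priors.fixed_effect_variance]
        if self.n_knots:
            blocks.append(sp.csr_matrix(self._f_block_precision(hyper)))
        Qx = sp.block_diag(blocks, format="csr")
        self._qx_cache = (key, Qx)
        return Qx

    def prior_log_det(self, hyper: HyperState) -> float:
        val = self._field_logdet(hyper.matern) - self.n_fixed * math.log(
            self.spec.priors.fixed_effect_variance
        )
        if self.n_knots:
            sign, ld = np.linalg.slogdet(self._f_block_precision(hyper))
            val += float(ld)
        return val

    def log_joint_density(self, x: np.ndarray, theta: np.ndarray) -> float:
        """Unnormalized log posterior of (latent, hyper) — the MCMC target.

        Includes the Gaussian prior normalizing constant (which varies with
        the hyperparameters) and the hyperprior, so independent samplers can
        be run on exactly the surface the Laplace fitter approximates.
        """
        try:
            hyper = self.coder.decode(np.asarray(theta, dtype=float))
        except (ArgumentError, OverflowError):
            return -np.inf
        try:
            nlp = self.neg_log_posterior_value(x, hyper)
        except ArgumentError:
            return -np.inf
        return -nlp + 0.5 * self.prior_log_det(hyper) + self.coder.log_prior(np.asarray(theta))

    def initial_latent(self) -> np.ndarray:
        x0 = np.zeros(self.dim)
        y = self.data.marks
        lik_link = make_likelihood(self.spec.mark_family, 1.0).link
        if lik_link == "log":
            x0[self.i_b_mark] = math.log(max(float(np.mean(y)), 1e-8))
        else:
            x0[self.i_b_mark] = float(np.mean(y))
        if self.spec.preferential:
            area = self.grid.n_cells * self.grid.cell_area
            x0[self.i_b_pp] = math.log(len(self.data) / area)
        return x0


def joint_neg_log_posterior(latent, hyper: HyperState, problem: Problem):
    """Module-level alias: (value, gradient, sparse Hessian) of the joint NLP."""
    return problem.neg_log_posterior(latent, hyper)


# ---------------------------------------------------------------------------
# hyperparameter coding and priors


class _HyperCoder:
    """Maps between the unconstrained outer-optimization vector and HyperState.

    Coordinates, in order and conditional on the spec:
    2 log kappa, log tau, log dispersion (shape or sd; absent for poisson),
    alpha (natural scale), log rho_d, alpha_d (natural scale).
    """

    def __init__(self, spec: ModelSpec, grid: GridGeometry, data: MarkedSample):
        self.spec = spec
        self.grid = grid
        self.names = ["2logkappa", "logtau"]
        self.has_obs = spec.mark_family != "poisson"
        if self.has_obs:
            self.names.append("log_dispersion")
        self.has_alpha = spec.preferential and spec.share_spatial
        if self.has_alpha:
            self.names.append("alpha")
        self.has_rw2 = spec.covariate_smooth is not None
        if self.has_rw2:
            self.names.append("log_rho_d")
        self.has_alpha_d = spec.preferential and spec.share_covariate
        if self.has_alpha_d:
            self.names.append("alpha_d")
        self.dim = len(self.names)

        pri = spec.priors
        self.median_range = (
            pri.prior_median_range
            if pri.prior_median_range is not None
            else 0.5 * max(grid.width, grid.height)
        )
        self.median_sd = pri.prior_median_sd
        m0 = MaternHyperparams(sigma2=self.median_sd ** 2, range_=self.median_range)
        self.mu_2logkappa = 2.0 * math.log(m0.kappa)
        self.mu_logtau = math.log(m0.tau)
        self._data = data

    def decode(self, t: np.ndarray) -> HyperState:
        if not np.all(np.isfinite(t)):
            raise ArgumentError("non-finite hyperparameter vector")
        kappa = math.exp(0.5 * float(t[0]))
        tau = math.exp(float(t[1]))
        matern = MaternHyperparams.from_kappa_tau(kappa, tau)
        k = 2
        obs = None
        if self.has_obs:
            obs = math.exp(float(t[k]))
            k += 1
        lik = make_likelihood(self.spec.mark_family, obs)
        alpha = 1.0
        if self.has_alpha:
            alpha = float(t[k])
            k += 1
        rho_d = 1.0
        if self.has_rw2:
            rho_d = math.exp(float(t[k]))
            k += 1
        alpha_d = 0.0
        if self.has_alpha_d:
            alpha_d = float(t[k])
        return HyperState(matern=matern, likelihood=lik, alpha=alpha, rho_d=rho_d, alpha_d=alpha_d)

    def log_prior(self, t: np.ndarray) -> float:
        pri = self.spec.priors
        val = 0.0
        if pri.spatial_style == "gaussian":
            val += -0.5 * ((t[0] - self.mu_2logkappa) / pri.sd_2logkappa) ** 2
            val += -0.5 * ((t[1] - self.mu_logtau) / pri.sd_logtau) ** 2
        else:
            # penalized-complexity priors on (range, sd), with the Jacobian of
            # (range, sd) -> (2 log kappa, log tau)
            r = math.sqrt(8.0) * math.exp(-0.5 * t[0])
            s = math.exp(-0.5 * t[0] - t[1]) / (2.0 * math.sqrt(math.pi))
            r0, p_r = pri.pc_range
            s0, p_s = pri.pc_sigma
            lam_r = -math.log(p_r) * r0
            lam_s = -math.log(p_s) / s0
            val += math.log(lam_r) - 2.0 * math.log(r) - lam_r / r
            val += math.log(lam_s) - lam_s * s
            val += math.log(r * s / 2.0)
        k = 2
        if self.has_obs:
            val += -0.5 * ((t[k] - pri.obs_hyper_prior_mean) / pri.obs_hyper_prior_sd) ** 2
            k += 1
        if self.has_alpha:
            val += -0.5 * (t[k] / pri.alpha_prior_sd) ** 2
            k += 1
        if self.has_rw2:
            a, b = pri.rw2_prior
            val += a * t[k] - b * math.exp(t[k])
            k += 1
        if self.has_alpha_d:
            val += -0.5 * (t[k] / pri.alpha_prior_sd) ** 2
        return float(val)

    def initial(self) -> np.ndarray:
        """Documented, deterministic initial values for the outer search."""
        t0 = [self.mu_2logkappa, self.mu_logtau]
        y = self._data.marks
        if self.has_obs:
            if self.spec.mark_family == "gamma":
                v = float(np.var(y))
                mo = float(np.mean(y)) ** 2 / v if v > 0 else 10.0
                t0.append(math.log(min(max(mo, 0.1), 1000.0)))
            elif self.spec.mark_family == "lognormal":
                t0.append(math.log(max(float(np.std(np.log(y))), 1e-2)))
            else:
                t0.append(math.log(max(float(np.std(y)), 1e-2)))
        if self.has_alpha:
            t0.append(1.0)
        if self.has_rw2:
            t0.append(0.0)
        if self.has_alpha_d:
            t0.append(1.0)
        return np.array(t0, dtype=float)


# ---------------------------------------------------------------------------
# inner Newton


def _splu_sym(A: sp.csc_matrix):
    """Sparse LU tuned for SPD stencils: symmetric permutation, diagonal pivots.

    With diagonal pivoting the U diagonal carries the pivots, so positivity of
    diag(U) certifies positive definiteness and its log-sum is the log det.
    """
    return spla.splu(
        A.tocsc(),
        permc_spec="MMD_AT_PLUS_A",
        options={"SymmetricMode": True, "DiagPivotThresh": 0.0},
    )


def _splu_logdet(lu) -> float:
    return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


def _newton(problem: Problem, hyper: HyperState, x0: np.ndarray, tol=INNER_TOL, maxit=INNER_MAXIT):
    """Newton optimization of the latent vector with step-halving line search."""
    x = np.asarray(x0, dtype=float).copy()
    val, g, H = problem.neg_log_posterior(x, hyper)
    lu = None
    n_iter = 0
    stalled = False
    for n_iter in range(1, maxit + 1):
        gmax = float(np.max(np.abs(g)))
        if gmax < tol:
            break
        d = None
        for ridge in (0.0, 1e-8, 1e-5, 1e-2):
            try:
                Hr = H if ridge == 0.0 else (H + ridge * sp.identity(problem.dim, format="csc"))
                lu = _splu_sym(Hr)
                if np.any(lu.U.diagonal() <= 0):
                    continue
                d = lu.solve(-g)
            except RuntimeError:
                continue
            slope = float(g @ d)
            if np.all(np.isfinite(d)) and slope < 0:
                break
            d = None
        if d is None:
            raise ConvergenceError(
                "inner Hessian not positive definite", {"iteration": n_iter, "grad_max": gmax}
            )
        if -slope < 1e-12 * (1.0 + abs(val)):
            stalled = True  # expected decrease below the floating-point noise floor
            break
        t = 1.0
        accepted = False
        while t > 1e-12:
            xn = x + t * d
            try:
                valn = problem.neg_log_posterior_value(xn, hyper)
            except (ArgumentError, FloatingPointError, OverflowError):
                valn = np.inf
            if valn <= val + 1e-4 * t * slope:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            raise ConvergenceError(
                "line search failed", {"iteration": n_iter, "grad_max": gmax, "value": val}
            )
        x = xn
        val, g, H = problem.neg_log_posterior(x, hyper)
    else:
        raise ConvergenceError(
            f"inner Newton did not converge in {maxit} iterations",
            {"grad_max": float(np.max(np.abs(g))), "value": val},
        )
    lu = _splu_sym(H)
    return {
        "x": x,
        "value": val,
        "grad_max": float(np.max(np.abs(g))),
        "H": H,
        "lu": lu,
        "logdet_H": _splu_logdet(lu),
        "iterations": n_iter,
        "stalled": stalled,
    }


# ---------------------------------------------------------------------------
# fit result


@dataclass
class FitResult:
    """Posterior summaries of one fitted model (empirical-Bayes Laplace)."""

    spec: ModelSpec
    grid: GridGeometry
    x_mode: np.ndarray
    w_mean: np.ndarray  # interior field posterior mode/mean
    w_sd: np.ndarray
    intercepts: dict
    smooth: Optional[CovariateSmooth]
    hyper_mode: dict
    theta_mode: np.ndarray
    theta_names: list
    theta_cov: np.ndarray
    hyper_summary: Optional[object]  # DataFrame when grid integration is on
    log_marginal: float
    deviance_obs: np.ndarray
    converged: bool
    diagnostics: dict
    _problem: Problem = dc_field(repr=False, default=None)
    _lu: object = dc_field(repr=False, default=None)
    _hyper: HyperState = dc_field(repr=False, default=None)

    # -- posterior access ---------------------------------------------------

    @property
    def obs_likelihood(self):
        return self._hyper.likelihood

    @property
    def eta_obs_mean(self) -> np.ndarray:
        return self._problem.A_mark @ self.x_mode

    def eta_obs_cov(self) -> np.ndarray:
        A = self._problem.A_mark
        X = self._lu.solve(A.T.toarray())
        return np.asarray(A @ X)

    def eta_obs_var(self) -> np.ndarray:
        return np.diag(self.eta_obs_cov()).copy()

    def sample_eta_obs(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """Draws of the mark linear predictor from the Gaussian approximation."""
        cov = self.eta_obs_cov()
        cov[np.diag_indices_from(cov)] += 1e-12
        chol = np.linalg.cholesky(cov)
        z = rng.standard_normal((n_draws, cov.shape[0]))
        return self.eta_obs_mean[None, :] + z @ chol.T

    def latent_var(self, S: sp.spmatrix) -> np.ndarray:
        """diag(S H^-1 S') for a sparse design S over the latent vector."""
        X = self._lu.solve(S.T.toarray())
        return np.maximum(np.asarray(S.multiply(X.T).sum(axis=1)).ravel(), 0.0)

    def hyper_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Equal-tailed Gaussian interval for one internal-scale hyperparameter."""
        from scipy.stats import norm

        i = self.theta_names.index(name)
        sd = math.sqrt(max(self.theta_cov[i, i], 0.0))
        half = norm.ppf(0.5 + level / 2.0) * sd
        return (float(self.theta_mode[i] - half), float(self.theta_mode[i] + half))


def _hyper_mode_dict(coder: _HyperCoder, hyper: HyperState) -> dict:
    out = {
        "range": hyper.matern.range_,
        "sigma2": hyper.matern.sigma2,
        "sd": math.sqrt(hyper.matern.sigma2),
        "kappa": hyper.matern.kappa,
        "tau": hyper.matern.tau,
    }
    if coder.has_obs:
        out["dispersion"] = getattr(hyper.likelihood, hyper.likelihood.hyper_name)
    if coder.has_alpha:
        out["alpha"] = hyper.alpha
    if coder.has_rw2:
        out["rho_d"] = hyper.rho_d
    if coder.has_alpha_d:
        out["alpha_d"] = hyper.alpha_d
    return out


def fit(
    spec: ModelSpec,
    data: MarkedSample,
    grid: Optional[GridGeometry] = None,
    covariate_raster: Optional[np.ndarray] = None,
    pattern_cells: Optional[np.ndarray] = None,
    *,
    outer_maxfev: int = 150,
    integrate_grid: bool = False,
    hyper_se: bool = True,
    inner_tol: float = INNER_TOL,
) -> FitResult:
    """Fit the model by nested Laplace approximation (empirical Bayes).

    Inner loop: Newton optimization of the latent vector at fixed
    hyperparameters.  Outer loop: Nelder-Mead maximization of the
    Laplace-approximated log marginal posterior of the hyperparameters from
    deterministic initials.  With ``integrate_grid`` a coarse grid around
    the mode is weighted for posterior-mean hyperparameter summaries.
    """
    problem = Problem(spec, data, grid, covariate_raster, pattern_cells)
    coder = problem.coder
    x_init = problem.initial_latent()
    warm = {"x": x_init.copy()}
    best = {"val": -np.inf, "t": None, "inner": None}
    n_fail = [0]

    def objective(t):
        try:
            hyper = coder.decode(np.asarray(t, dtype=float))
        except (ArgumentError, OverflowError):
            return np.inf
        try:
            inner = _newton(problem, hyper, warm["x"], tol=inner_tol)
        except ConvergenceError:
            n_fail[0] += 1
            try:
                inner = _newton(problem, hyper, x_init, tol=inner_tol)
            except ConvergenceError:
                return np.inf
        warm["x"] = inner["x"]
        ell = (
            -inner["value"]
            + 0.5 * problem.prior_log_det(hyper)
            - 0.5 * inner["logdet_H"]
            + coder.log_prior(np.asarray(t, dtype=float))
        )
        if not np.isfinite(ell):
            return np.inf
        if ell > best["val"]:
            best.update(val=ell, t=np.asarray(t, dtype=float).copy(), inner=inner)
        return -ell

    t0 = coder.initial()
    simplex = np.vstack([t0] + [t0 + 0.25 * np.eye(coder.dim)[i] for i in range(coder.dim)])
    res = minimize(
        objective,
        t0,
        method="Nelder-Mead",
        options={
            "maxfev": outer_maxfev,
            "xatol": 0.02,
            "fatol": 0.02,
            "adaptive": True,
            "initial_simplex": simplex,
        },
    )
    if best["t"] is None:
        raise ConvergenceError("outer optimization never found a finite objective", {"result": res})
    t_mode = best["t"]
    hyper = coder.decode(t_mode)
    inner = _newton(problem, hyper, best["inner"]["x"], tol=inner_tol)
    log_marginal = float(best["val"])

    # curvature of the outer objective -> hyperparameter covariance
    p = coder.dim
    clipped = False
    if hyper_se or integrate_grid:
        Hh = np.zeros((p, p))
        f0 = -objective(t_mode)

        def ev(dt):
            return -objective(t_mode + dt)

        steps = np.full(p, 0.15)
        for i in range(p):  # shrink any step that walks into a non-finite region
            while steps[i] > 1e-3:
                if np.isfinite(ev(np.eye(p)[i] * steps[i])) and np.isfinite(
                    ev(-np.eye(p)[i] * steps[i])
                ):
                    break
                steps[i] *= 0.5
        for i in range(p):
            ei = np.eye(p)[i] * steps[i]
            fp, fm = ev(ei), ev(-ei)
            Hh[i, i] = -(fp - 2 * f0 + fm) / steps[i] ** 2
            for j in range(i + 1, p):
                ej = np.eye(p)[j] * steps[j]
                fpp, fpm, fmp, fmm = ev(ei + ej), ev(ei - ej), ev(-ei + ej), ev(-ei - ej)
                Hh[i, j] = Hh[j, i] = -(fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
        Hh[~np.isfinite(Hh)] = 0.0
        evals, evecs = np.linalg.eigh(0.5 * (Hh + Hh.T))
        clipped = bool(np.any(evals < 1e-8))
        evals = np.clip(evals, 1e-8, None)
        theta_cov = (evecs / evals) @ evecs.T
    else:
        theta_cov = np.full((p, p), np.nan)

    # latent marginal sds for the reported quantities
    n_report = problem.grid.n_cells + problem.n_fixed + problem.n_knots
    idx = np.concatenate(
        [
            problem.interior,
            np.arange(problem.n_field, problem.n_field + problem.n_fixed),
            np.arange(problem.i_f, problem.i_f + problem.n_knots),
        ]
    ).astype(int)
    S = sp.csr_matrix((np.ones(n_report), (np.arange(n_report), idx)), shape=(n_report, problem.dim))
    X = inner["lu"].solve(S.T.toarray())
    var = np.maximum(np.asarray(S.multiply(X.T).sum(axis=1)).ravel(), 0.0)
    sds = np.sqrt(var)
    ni = problem.grid.n_cells
    w_mean = inner["x"][problem.interior]
    w_sd = sds[:ni]
    intercepts = {"b_mark": (float(inner["x"][problem.i_b_mark]), float(sds[ni]))}
    if spec.preferential:
        intercepts["b_pp"] = (float(inner["x"][problem.i_b_pp]), float(sds[ni + 1]))
    smooth = None
    if problem.n_knots:
        smooth = CovariateSmooth(
            knots=problem.knots.copy(),
            values=inner["x"][problem.i_f :].copy(),
            sd=sds[ni + problem.n_fixed :].copy(),
            precision=hyper.rho_d,
        )

    diagnostics = {
        "outer_nfev": res.nfev,
        "outer_status": res.status,
        "inner_iterations": inner["iterations"],
        "inner_grad_max": inner["grad_max"],
        "inner_restarts": n_fail[0],
        "hessian_clipped": bool(clipped),
    }
    if coder.has_alpha and coder.has_alpha_d:
        ia, id_ = coder.names.index("alpha"), coder.names.index("alpha_d")
        denom = math.sqrt(theta_cov[ia, ia] * theta_cov[id_, id_])
        corr = theta_cov[ia, id_] / denom if denom > 0 else 0.0
        if clipped or abs(corr) > 0.95:
            diagnostics["shared_confounding"] = True
            warnings.warn(
                "shared covariate smooth and shared spatial field carry nearly the same "
                "information in the point-process layer; the sharing scales are confounded",
                RuntimeWarning,
                stacklevel=2,
            )

    hyper_summary = None
    if integrate_grid:
        hyper_summary = _grid_integration(problem, coder, t_mode, theta_cov)
        # grid integration perturbs the warm state; refresh the mode solve
        inner = _newton(problem, hyper, inner["x"], tol=inner_tol)

    eta_m = problem.A_mark @ inner["x"]
    deviance_obs = -2.0 * hyper.likelihood.logpdf(data.marks, eta_m)

    return FitResult(
        spec=spec,
        grid=problem.grid,
        x_mode=inner["x"],
        w_mean=w_mean,
        w_sd=w_sd,
        intercepts=intercepts,
        smooth=smooth,
        hyper_mode=_hyper_mode_dict(coder, hyper),
        theta_mode=t_mode,
        theta_names=list(coder.names),
        theta_cov=theta_cov,
        hyper_summary=hyper_summary,
        log_marginal=log_marginal,
        deviance_obs=np.asarray(deviance_obs),
        converged=inner["grad_max"] < 1e-4 or (inner["stalled"] and inner["grad_max"] < 1e-2),
        diagnostics=diagnostics,
        _problem=problem,
        _lu=inner["lu"],
        _hyper=hyper,
    )


def _grid_integration(problem: Problem, coder: _HyperCoder, t_mode, theta_cov):
    """Coarse-grid posterior weighting of the hyperparameters around the mode."""
    import itertools

    import pandas as pd

    sds = np.sqrt(np.clip(np.diag(theta_cov), 1e-8, None))
    steps = 1.2 * sds
    pts, logw = [], []
    for offs in itertools.product((-1.0, 0.0, 1.0), repeat=coder.dim):
        t = t_mode + steps * np.array(offs)
        try:
            hyper = coder.decode(t)
            inner = _newton(problem, hyper, problem.initial_latent())
            ell = (
                -inner["value"]
                + 0.5 * problem.prior_log_det(hyper)
                - 0.5 * inner["logdet_H"]
                + coder.log_prior(t)
            )
        except ConvergenceError:
            continue
        if np.isfinite(ell):
            pts.append(t)
            logw.append(ell)
    pts = np.array(pts)
    logw = np.array(logw)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    rows = []
    naturals = np.array([[_natural_vector(coder, t) for t in pts]])[0]
    for j, name in enumerate(_natural_names(coder)):
        v = naturals[:, j]
        mean = float(np.sum(w * v))
        sd = float(math.sqrt(max(np.sum(w * (v - mean) ** 2), 0.0)))
        rows.append({"parameter": name, "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


def _natural_names(coder: _HyperCoder):
    names = ["range", "sd"]
    if coder.has_obs:
        names.append("dispersion")
    if coder.has_alpha:
        names.append("alpha")
    if coder.has_rw2:
        names.append("rho_d")
    if coder.has_alpha_d:
        names.append("alpha_d")
    return names


def _natural_vector(coder: _HyperCoder, t):
    h = coder.decode(t)
    out = [h.matern.range_, math.sqrt(h.matern.sigma2)]
    if coder.has_obs:
        out.append(getattr(h.likelihood, h.likelihood.hyper_name))
    if coder.has_alpha:
        out.append(h.alpha)
    if coder.has_rw2:
        out.append(h.rho_d)
    if coder.has_alpha_d:
        out.append(h.alpha_d)
    return out


# ---------------------------------------------------------------------------
# prediction


def predict_surface(
    fit_result: FitResult, covariate_raster: Optional[np.ndarray] = None
) -> tuple[LatentField, LatentField]:
    """Posterior predictive mean (and sd) of the mark mean surface per cell.

    For log-link families the mean applies the lognormal correction
    E[exp(eta)] = exp(m + v/2) under the Gaussian latent approximation; the
    identity link returns the Gaussian mean directly.
    """
    if not fit_result.converged:
        raise ConvergenceError("cannot predict from an unconverged fit")
    problem = fit_result._problem
    grid = problem.grid
    ni = grid.n_cells
    rows = np.concatenate([np.arange(ni), np.arange(ni)])
    cols = np.concatenate([problem.interior, np.full(ni, problem.i_b_mark)])
    vals = np.ones(2 * ni)
    if problem.n_knots:
        if covariate_raster is None:
            raise ArgumentError("prediction with a covariate smooth needs a covariate raster")
        raster = np.asarray(covariate_raster, dtype=float).ravel()
        if raster.size != ni:
            raise ArgumentError("covariate raster does not match the grid")
        cell_idx = np.argmin(np.abs(raster[:, None] - problem.knots[None, :]), axis=1)
        rows = np.concatenate([rows, np.arange(ni)])
        cols = np.concatenate([cols, problem.i_f + cell_idx])
        vals = np.concatenate([vals, np.ones(ni)])
    S = sp.csr_matrix((vals, (rows, cols)), shape=(ni, problem.dim))
    m = S @ fit_result.x_mode
    v = fit_result.latent_var(S)
    if fit_result.obs_likelihood.link == "log":
        mean = np.exp(m + 0.5 * v)
        sd = np.sqrt(np.maximum((np.exp(v) - 1.0) * np.exp(2.0 * m + v), 0.0))
    else:
        mean = m
        sd = np.sqrt(v)
    meta = {"quantity": "posterior predictive mean of mu"}
    return LatentField(grid, mean, dict(meta)), LatentField(grid, sd, {"quantity": "posterior sd of mu"})
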