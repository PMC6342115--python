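"""Matérn Gaussian random fields on a regular grid and their GMRF (SPDE) form.

The smoothness is fixed at nu = 1 (SPDE operator power alpha = 2).  The
*range* parameter follows the SPDE-literature convention

    range = sqrt(8 * nu) / kappa,

the distance at which the Matérn correlation has dropped to roughly 0.1
(the exact nu=1 value at one range is sqrt(8)*K1(sqrt(8)) ~ 0.139).  The
marginal variance relates to (kappa, tau) through the nu=1, d=2 identity

    sigma2 = 1 / (4 * pi * kappa**2 * tau**2).

The precision matrix comes from discretizing (kappa^2 - Laplacian) on the
lattice with a lumped mass matrix: with M = kappa^2 h^2 I + L (L the graph
Laplacian of the 4-neighbour lattice, h the cell size) the precision is

    Q = (tau / h)^2 * M @ M,

a 13-point stencil.  Natural (Neumann) boundaries inflate the variance near
the edge, so the precision is built on a grid extended on all sides and the
study window is recovered by selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.special import kv

from .exceptions import ArgumentError, CapabilityError
from .grids import GridGeometry, LatentField

_NU = 1.0  # fixed smoothness
_DENSE_MAX_CELLS = 64 * 64  # exact-covariance simulation path limit


@dataclass(frozen=True)
class MaternHyperparams:
    """Marginal variance and spatial range of a nu=1 Matérn field.

    ``sigma2`` is the marginal variance (mark-scale units squared) and
    ``range_`` the correlation range in length units.  ``kappa`` and ``tau``
    are the equivalent SPDE parameters; the two parameterizations are
    mutually recoverable.
    """

    sigma2: float
    range_: float

    def __post_init__(self):
        if not (self.sigma2 > 0 and np.isfinite(self.sigma2)):
            raise ArgumentError(f"sigma2 must be positive and finite, got {self.sigma2}")
        if not (self.range_ > 0 and np.isfinite(self.range_)):
            raise ArgumentError(f"range must be positive and finite, got {self.range_}")

    @property
    def nu(self) -> float:
        return _NU

    @property
    def kappa(self) -> float:
        return math.sqrt(8.0 * _NU) / self.range_

    @property
    def tau(self) -> float:
        return 1.0 / (2.0 * math.sqrt(math.pi) * self.kappa * math.sqrt(self.sigma2))

    @classmethod
    def from_kappa_tau(cls, kappa: float, tau: float) -> "MaternHyperparams":
        if not (kappa > 0 and tau > 0):
            raise ArgumentError("kappa and tau must be positive")
        sigma2 = 1.0 / (4.0 * math.pi * kappa ** 2 * tau ** 2)
        range_ = math.sqrt(8.0 * _NU) / kappa
        return cls(sigma2=sigma2, range_=range_)


def matern_correlation(distance, hyper: MaternHyperparams):
    """nu=1 Matérn correlation  rho(d) = kappa*d * K1(kappa*d).

    Evaluates stably at zero lag (limit 1) and underflows cleanly to 0 at
    long range.  ``distance`` may be a scalar or array; must be >= 0.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ArgumentError("distance must be non-negative")
    x = hyper.kappa * d
    out = np.ones_like(x)
    pos = x > 0
    with np.errstate(invalid="ignore", over="ignore"):
        out[pos] = x[pos] * kv(1, x[pos])
    out[~np.isfinite(out)] = 0.0  # kv underflow at very large arguments
    np.clip(out, 0.0, 1.0, out=out)
    if np.isscalar(distance) or np.ndim(distance) == 0:
        return float(out)
    return out


@lru_cache(maxsize=16)
def _lattice_laplacian(nx: int, ny: int) -> sp.csr_matrix:
    """Graph Laplacian of the 4-neighbour lattice (Neumann boundary)."""

    def path(n):
        d = np.full(n, 2.0)
        d[0] = d[-1] = 1.0
        off = -np.ones(n - 1)
        return sp.diags([off, d, off], [-1, 0, 1])

    # row-major x-fastest flattening: index = iy*nx + ix
    return (sp.kron(sp.identity(ny), path(nx)) + sp.kron(path(ny), sp.identity(nx))).tocsr()


@dataclass
class SpdePrecision:
    """Sparse GMRF precision of a Matérn field, built on an extended grid.

    ``Q`` lives on ``grid_ext``; ``interior`` gives the flat indices (on the
    extended grid) of the original study-window cells.  Selecting those
    entries of a simulated or inferred field realizes the boundary-corrected
    marginal on the study window.
    """

    grid: GridGeometry
    grid_ext: GridGeometry
    hyper: MaternHyperparams
    pad_cells: int
    Q: sp.csr_matrix
    interior: np.ndarray
    _M: sp.csr_matrix
    _scale: float  # tau / h; Q = scale^2 * M @ M

    def _lu(self):
        if not hasattr(self, "_lu_cache"):
            self._lu_cache = spla.splu(
                self._M.tocsc(),
                permc_spec="MMD_AT_PLUS_A",
                options={"SymmetricMode": True},
            )
        return self._lu_cache

    def log_det(self) -> float:
        """log det Q from the closed-form spectrum of the lattice operator.

        The Neumann path-graph Laplacian on n nodes has eigenvalues
        2(1 - cos(pi k / n)); the lattice operator M = kappa^2 h^2 I + L has
        eigenvalues kappa^2 h^2 + mu_i + mu_j, so log det Q = 2 n log(scale)
        + 2 sum log of those.
        """
        nx, ny = self.grid_ext.nx, self.grid_ext.ny
        mux = 2.0 * (1.0 - np.cos(np.pi * np.arange(nx) / nx))
        muy = 2.0 * (1.0 - np.cos(np.pi * np.arange(ny) / ny))
        lam = self.hyper.kappa ** 2 * self.grid.cell_size ** 2 + mux[None, :] + muy[:, None]
        n = self.grid_ext.n_cells
        return 2.0 * n * math.log(self._scale) + 2.0 * float(np.sum(np.log(lam)))

    def quadratic_form(self, w: np.ndarray) -> float:
        """w' Q w computed through the square-root operator."""
        mw = self._M @ np.asarray(w, dtype=float)
        return float(self._scale ** 2 * (mw @ mw))

    def solve_sqrt(self, z: np.ndarray) -> np.ndarray:
        """Return x with precision Q given white noise z: x = M^-1 z / scale."""
        return self._lu().solve(np.asarray(z, dtype=float)) / self._scale


def default_pad_cells(grid: GridGeometry, hyper: MaternHyperparams) -> int:
    """One correlation range of padding, in whole cells."""
    return int(math.ceil(hyper.range_ / grid.cell_size))


def build_spde_precision(
    grid: GridGeometry, hyper: MaternHyperparams, pad_cells: int | None = None
) -> SpdePrecision:
    """Sparse SPDE precision for a nu=1 Matérn field over ``grid``.

    The matrix is assembled on the grid extended by ``pad_cells`` on every
    side (default: one range) so that study-window cells are unaffected by
    the Neumann boundary; at most 13 nonzeros per row; exactly symmetric.
    """
    if pad_cells is None:
        pad_cells = default_pad_cells(grid, hyper)
    grid_ext = grid.expand(pad_cells)
    h = grid.cell_size
    L = _lattice_laplacian(grid_ext.nx, grid_ext.ny)
    M = (hyper.kappa ** 2 * h ** 2) * sp.identity(grid_ext.n_cells, format="csr") + L
    scale = hyper.tau / h
    Q = (scale ** 2) * (M @ M)
    Q = ((Q + Q.T) * 0.5).tocsr()  # enforce exact symmetry against fp round-off
    return SpdePrecision(
        grid=grid,
        grid_ext=grid_ext,
        hyper=hyper,
        pad_cells=pad_cells,
        Q=Q,
        interior=grid.interior_of(grid_ext, pad_cells),
        _M=M.tocsr(),
        _scale=scale,
    )


@lru_cache(maxsize=2)
def _dense_cholesky(grid: GridGeometry, hyper: MaternHyperparams) -> np.ndarray:
    centers = grid.cell_centers()
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(centers))
    cov = hyper.sigma2 * matern_correlation(d, hyper)
    cov[np.diag_indices_from(cov)] = hyper.sigma2 * (1.0 + 1e-8)
    return np.linalg.cholesky(cov)


def simulate_grf(
    grid: GridGeometry,
    hyper: MaternHyperparams,
    seed: int,
    method: str = "auto",
    pad_cells: int | None = None,
) -> LatentField:
    """Draw one zero-mean Matérn field on ``grid``.

    ``method='dense'`` factorizes the exact Matérn covariance (grids up to
    64x64); ``method='gmrf'`` solves white noise through the sparse SPDE
    square-root operator on the extended grid and selects the window.
    ``'auto'`` picks dense when feasible.  The path taken is recorded in the
    result metadata; the same seed always reproduces the same field.
    """
    if method not in ("auto", "dense", "gmrf"):
        raise ArgumentError(f"unknown simulation method {method!r}")
    if method == "auto":
        method = "dense" if grid.n_cells <= _DENSE_MAX_CELLS else "gmrf"
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if method == "dense":
        if grid.n_cells > _DENSE_MAX_CELLS:
            raise CapabilityError(
                f"dense simulation limited to {_DENSE_MAX_CELLS} cells, grid has {grid.n_cells}"
            )
        chol = _dense_cholesky(grid, hyper)
        values = chol @ rng.standard_normal(grid.n_cells)
    else:
        spde = build_spde_precision(grid, hyper, pad_cells=pad_cells)
        z = rng.standard_normal(spde.grid_ext.n_cells)
        values = spde.solve_sqrt(z)[spde.interior]
    return LatentField(grid=grid, values=values, metadata={"method": method, "seed": seed})
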