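"""Sampling designs over a latent field and mark extraction.

Implements the scenario generator behind the simulation experiment: a
latent Matérn surface W is simulated on a grid, sampling locations are
drawn either uniformly or with probability proportional to exp(b * W) —
the intensity of the log-Gaussian Cox process raised to the
preferentiality degree b (b = 0 is uniform, b = 1 matches sampling
proportional to the intensity itself) — and abundance marks are extracted
at the sampled cells under a gamma or gaussian observation model.

Sub-seeds are split deterministically from a master seed with
``numpy.random.SeedSequence(master, spawn_key=(stage,))`` so each stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .exceptions import ArgumentError
from .grids import GridGeometry, LatentField
from .random_fields import MaternHyperparams, simulate_grf

FAMILIES = ("gaussian", "gamma")

# stage indices of the seed-splitting rule
_STAGE_FIELD = 0
_STAGE_PREF_LOCS = 1
_STAGE_UNIF_LOCS = 2
_STAGE_PREF_MARKS = 3
_STAGE_UNIF_MARKS = 4


def stage_rng(master_seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage generator derived from a master seed."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(stage,)))


@dataclass(frozen=True)
class SampleDesign:
    """How sampling locations were (or are to be) drawn."""

    kind: str  # "preferential" | "uniform"
    n: int
    preferentiality: float = 0.0  # degree b; b=0 <=> uniform
    with_replacement: bool = True

    def __post_init__(self):
        if self.kind not in ("preferential", "uniform"):
            raise ArgumentError(f"unknown design kind {self.kind!r}")
        if self.n < 1:
            raise ArgumentError(f"need at least one sample, got n={self.n}")
        if not (np.isfinite(self.preferentiality) and self.preferentiality >= 0):
            raise ArgumentError(f"preferentiality must be finite and >= 0, got {self.preferentiality}")


@dataclass
class MarkedSample:
    """Sampling locations plus the marks measured there.

    ``cells`` are flat study-grid indices; ``x``/``y`` the cell-center
    coordinates.  Gamma-family marks are strictly positive.  ``truth``
    optionally links back to the generating field (simulation only).
    """

    grid: GridGeometry
    cells: np.ndarray
    marks: np.ndarray
    design: SampleDesign
    covariate: Optional[np.ndarray] = None
    truth: Optional[LatentField] = None
    obs_params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=int).ravel()
        self.marks = np.asarray(self.marks, dtype=float).ravel()
        if self.cells.size != self.marks.size:
            raise ArgumentError("locations and marks must have equal length")
        if self.cells.size and (self.cells.min() < 0 or self.cells.max() >= self.grid.n_cells):
            raise ArgumentError("sample location outside the grid")

    def __len__(self) -> int:
        return self.cells.size

    @property
    def coords(self) -> np.ndarray:
        return self.grid.cell_centers()[self.cells]


def preferential_sample(
    field: LatentField, n: int, b: float, seed: int, with_replacement: bool = True
) -> np.ndarray:
    """Draw ``n`` cells with probability proportional to exp(b * W).

    Selection probabilities are normalized through log-sum-exp, so extreme
    field values cannot overflow.  Returns flat cell indices.
    """
    if n < 1:
        raise ArgumentError(f"need at least one sample, got n={n}")
    if not (np.isfinite(b) and b >= 0):
        raise ArgumentError(f"preferentiality must be finite and >= 0, got {b}")
    w = np.asarray(field.values, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ArgumentError("field contains non-finite values")
    logp = b * w
    p = np.exp(logp - logsumexp(logp))
    p /= p.sum()  # clean residual round-off so probabilities sum to 1
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return rng.choice(field.grid.n_cells, size=n, replace=with_replacement, p=p)


def uniform_sample(grid: GridGeometry, n: int, seed: int, with_replacement: bool = True) -> np.ndarray:
    """Draw ``n`` cells uniformly at random; flat cell indices."""
    if n < 1:
        raise ArgumentError(f"need at least one sample, got n={n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return rng.choice(grid.n_cells, size=n, replace=with_replacement)


def extract_marks(
    field: LatentField,
    locations,
    family: str,
    obs_params: dict,
    intercept: float,
    seed: int,
    design: Optional[SampleDesign] = None,
) -> MarkedSample:
    """Simulate observed marks at the given cells.

    gaussian: mark = intercept + W(s) + N(0, sd^2)
    gamma:    mark ~ Gamma with mean exp(intercept + W(s)) and shape rho
    """
    if family not in FAMILIES:
        raise ArgumentError(f"unknown mark family {family!r}; choose from {FAMILIES}")
    cells = np.asarray(locations, dtype=int).ravel()
    if cells.size == 0:
        raise ArgumentError("no locations supplied")
    if cells.min() < 0 or cells.max() >= field.grid.n_cells:
        raise ArgumentError("sample location outside the grid")
    if not np.isfinite(intercept):
        raise ArgumentError("intercept must be finite")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    w = field.values[cells]
    if family == "gaussian":
        sd = float(obs_params.get("sd", 0.0))
        if sd < 0:
            raise ArgumentError(f"gaussian noise sd must be >= 0, got {sd}")
        marks = intercept + w + (sd * rng.standard_normal(cells.size) if sd > 0 else 0.0)
        params = {"sd": sd}
    else:
        shape = float(obs_params.get("shape", 10.0))
        if not shape > 0:
            raise ArgumentError(f"gamma shape must be > 0, got {shape}")
        mean = np.exp(intercept + w)
        if not np.all(np.isfinite(mean) & (mean > 0)):
            raise ArgumentError("gamma mean exp(intercept + W) must be positive and finite")
        marks = rng.gamma(shape=shape, scale=mean / shape)
        params = {"shape": shape}
    params["intercept"] = float(intercept)
    if design is None:
        design = SampleDesign(kind="uniform", n=cells.size)
    return MarkedSample(
        grid=field.grid, cells=cells, marks=marks, design=design, truth=field, obs_params=params
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: field + preferential and uniform samples.

    Defaults reproduce the reference experiment shape: a 100x100 grid,
    zero-mean unit-variance Matérn field with range 20% of the window
    width, 100 sampling locations per design, preferentiality b=1, gamma
    marks with shape 10 and zero intercept.
    """

    grid: GridGeometry = GridGeometry(100, 100)
    hyper: MaternHyperparams = MaternHyperparams(sigma2=1.0, range_=20.0)
    n: int = 100
    b: float = 1.0
    family: str = "gamma"
    shape: float = 10.0  # gamma dispersion (ignored for gaussian)
    noise_sd: float = 0.1  # gaussian noise sd (ignored for gamma)
    intercept: float = 0.0
    with_replacement: bool = True

    def obs_params(self) -> dict:
        if self.family == "gamma":
            return {"shape": self.shape}
        return {"sd": self.noise_sd}


@dataclass
class Scenario:
    field: LatentField
    preferential: MarkedSample
    uniform: MarkedSample
    config: ScenarioConfig
    seed: int


def make_scenario(config: ScenarioConfig = ScenarioConfig(), seed: int = 0) -> Scenario:
    """Simulate one field and extract one preferential and one uniform sample.

    All randomness is split from the master seed by stage, so the whole
    scenario — and each stage in isolation — is reproducible.
    """
    if config.family not in FAMILIES:
        raise ArgumentError(f"unknown mark family {config.family!r}")
    seeds = {
        s: int(np.random.SeedSequence(seed, spawn_key=(s,)).generate_state(1)[0] % (2**31))
        for s in range(5)
    }
    field = simulate_grf(config.grid, config.hyper, seed=seeds[_STAGE_FIELD])
    pref_cells = preferential_sample(
        field, config.n, config.b, seed=seeds[_STAGE_PREF_LOCS],
        with_replacement=config.with_replacement,
    )
    unif_cells = uniform_sample(
        config.grid, config.n, seed=seeds[_STAGE_UNIF_LOCS],
        with_replacement=config.with_replacement,
    )
    pref_design = SampleDesign(
        kind="preferential", n=config.n, preferentiality=config.b,
        with_replacement=config.with_replacement,
    )
    unif_design = SampleDesign(
        kind="uniform", n=config.n, with_replacement=config.with_replacement
    )
    pref = extract_marks(
        field, pref_cells, config.family, config.obs_params(), config.intercept,
        seed=seeds[_STAGE_PREF_MARKS], design=pref_design,
    )
    unif = extract_marks(
        field, unif_cells, config.family, config.obs_params(), config.intercept,
        seed=seeds[_STAGE_UNIF_MARKS], design=unif_design,
    )
    return Scenario(field=field, preferential=pref, uniform=unif, config=config, seed=seed)


def true_abundance_surface(scenario: Scenario) -> np.ndarray:
    """The mean abundance surface the marks were generated from."""
    eta = scenario.config.intercept + scenario.field.values
    if scenario.config.family == "gamma":
        return np.exp(eta)
    return eta
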