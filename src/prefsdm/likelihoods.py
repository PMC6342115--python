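"""Observation models for the marks, parameterized by the linear predictor.

Each family exposes the negative log-likelihood and its first two
derivatives with respect to the linear predictor eta (the scale on which
the latent field enters), plus the log-density for predictive scoring.

gamma:     y ~ Ga(mean mu, shape rho), log link eta = log mu.
gaussian:  y ~ N(eta, sd^2), identity link.
lognormal: log y ~ N(eta, sd^2).
poisson:   y ~ Po(exp(eta)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .exceptions import ArgumentError


@dataclass(frozen=True)
class GammaLikelihood:
    """Gamma marks with mean exp(eta) and shape rho: Var = mu^2 / rho."""

    shape: float

    link = "log"
    hyper_name = "shape"

    def __post_init__(self):
        if not self.shape > 0:
            raise ArgumentError(f"gamma shape must be > 0, got {self.shape}")

    def validate(self, y):
        if np.any(y <= 0):
            raise ArgumentError("gamma-family marks must be strictly positive")

    def logpdf(self, y, eta):
        r = self.shape
        return r * np.log(r) - gammaln(r) + (r - 1.0) * np.log(y) - r * eta - r * y * np.exp(-eta)

    def nll(self, y, eta):
        return -np.sum(self.logpdf(y, eta))

    def d_nll(self, y, eta):
        return self.shape * (1.0 - y * np.exp(-eta))

    def d2_nll(self, y, eta):
        return self.shape * y * np.exp(-eta)

    def mean(self, eta):
        return np.exp(eta)

    def expected_deviance(self, y, m, v):
        """E[-2 log p(y | eta)] for eta ~ N(m, v), elementwise (closed form)."""
        r = self.shape
        return -2.0 * (
            r * np.log(r) - gammaln(r) + (r - 1.0) * np.log(y)
            - r * m - r * y * np.exp(-m + 0.5 * v)
        )


@dataclass(frozen=True)
class GaussianLikelihood:
    """Gaussian marks with mean eta and known/estimated noise sd."""

    sd: float

    link = "identity"
    hyper_name = "sd"

    def __post_init__(self):
        if not self.sd > 0:
            raise ArgumentError(f"gaussian sd must be > 0, got {self.sd}")

    def validate(self, y):
        pass

    def logpdf(self, y, eta):
        v = self.sd ** 2
        return -0.5 * np.log(2.0 * np.pi * v) - 0.5 * (y - eta) ** 2 / v

    def nll(self, y, eta):
        return -np.sum(self.logpdf(y, eta))

    def d_nll(self, y, eta):
        return (eta - y) / self.sd ** 2

    def d2_nll(self, y, eta):
        return np.full_like(np.asarray(eta, dtype=float), 1.0 / self.sd ** 2)

    def mean(self, eta):
        return eta

    def expected_deviance(self, y, m, v):
        """E[-2 log p(y | eta)] for eta ~ N(m, v), elementwise (closed form)."""
        s2 = self.sd ** 2
        return np.log(2.0 * np.pi * s2) + ((y - m) ** 2 + v) / s2


@dataclass(frozen=True)
class LognormalLikelihood:
    """Lognormal marks: log y ~ N(eta, sd^2)."""

    sd: float

    link = "log"
    hyper_name = "sd"

    def __post_init__(self):
        if not self.sd > 0:
            raise ArgumentError(f"lognormal sd must be > 0, got {self.sd}")

    def validate(self, y):
        if np.any(y <= 0):
            raise ArgumentError("lognormal marks must be strictly positive")

    def logpdf(self, y, eta):
        v = self.sd ** 2
        ly = np.log(y)
        return -np.log(y) - 0.5 * np.log(2.0 * np.pi * v) - 0.5 * (ly - eta) ** 2 / v

    def nll(self, y, eta):
        return -np.sum(self.logpdf(y, eta))

    def d_nll(self, y, eta):
        return (eta - np.log(y)) / self.sd ** 2

    def d2_nll(self, y, eta):
        return np.full_like(np.asarray(eta, dtype=float), 1.0 / self.sd ** 2)

    def mean(self, eta):
        return np.exp(eta + 0.5 * self.sd ** 2)

    def expected_deviance(self, y, m, v):
        """E[-2 log p(y | eta)] for eta ~ N(m, v), elementwise (closed form)."""
        s2 = self.sd ** 2
        ly = np.log(y)
        return 2.0 * ly + np.log(2.0 * np.pi * s2) + ((ly - m) ** 2 + v) / s2


@dataclass(frozen=True)
class PoissonLikelihood:
    """Poisson counts with log link; no dispersion hyperparameter."""

    link = "log"
    hyper_name = None

    def validate(self, y):
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ArgumentError("poisson marks must be non-negative integers")

    def logpdf(self, y, eta):
        return y * eta - np.exp(eta) - gammaln(y + 1.0)

    def nll(self, y, eta):
        return -np.sum(self.logpdf(y, eta))

    def d_nll(self, y, eta):
        return np.exp(eta) - y

    def d2_nll(self, y, eta):
        return np.exp(eta)

    def mean(self, eta):
        return np.exp(eta)

    def expected_deviance(self, y, m, v):
        """E[-2 log p(y | eta)] for eta ~ N(m, v), elementwise (closed form)."""
        return -2.0 * (y * m - np.exp(m + 0.5 * v) - gammaln(y + 1.0))


def make_likelihood(family: str, hyper_value: float | None):
    if family == "gamma":
        return GammaLikelihood(shape=float(hyper_value))
    if family == "gaussian":
        return GaussianLikelihood(sd=float(hyper_value))
    if family == "lognormal":
        return LognormalLikelihood(sd=float(hyper_value))
    if family == "poisson":
        return PoissonLikelihood()
    raise ArgumentError(f"unknown mark family {family!r}")
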