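"""Test-only MCMC oracle for the joint posterior.

Samples the package's own unnormalized joint posterior of (latent,
hyperparameters):

* latent block — preconditioned MALA (Metropolis-adjusted Langevin) with
  the Hessian of the inner problem at the Laplace mode as a *fixed*
  preconditioner.  The preconditioner only shapes proposals; the
  accept/reject step targets the exact conditional, so the chain is valid
  regardless of how good the Laplace fit is.  Step size adapts to ~0.57
  acceptance during burn-in.
* hyperparameters — random-walk Metropolis, proposal covariance adapted
  from burn-in.

The target comes from ``Problem.neg_log_posterior`` /
``Problem.log_joint_density``, so the sampler and the Laplace fitter see
exactly the same posterior.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular

from prefsdm.model import Problem


class JointPosteriorSampler:
    def __init__(self, problem: Problem, theta_init, theta_cov, hessian):
        self.prob = problem
        self.coder = problem.coder
        self.theta_init = np.asarray(theta_init, dtype=float)
        self.theta_cov0 = np.asarray(theta_cov, dtype=float)
        H = hessian.toarray() if hasattr(hessian, "toarray") else np.asarray(hessian)
        self._L = cholesky(H, lower=True)  # H = L L'
        self._H = H

    # -- latent: preconditioned MALA --------------------------------------

    def _grad_nlp(self, x, hyper):
        val, g, _ = self.prob.neg_log_posterior(x, hyper)
        return val, g

    def _mala_step(self, x, val, g, hyper, eps, rng):
        Sg = cho_solve((self._L, True), g)
        mean_fwd = x - 0.5 * eps ** 2 * Sg
        z = rng.standard_normal(x.size)
        xp = mean_fwd + eps * solve_triangular(self._L, z, trans=1, lower=True)
        try:
            valp, gp = self._grad_nlp(xp, hyper)
        except Exception:
            return x, val, g, False
        if not np.isfinite(valp):
            return x, val, g, False
        Sgp = cho_solve((self._L, True), gp)
        mean_bwd = xp - 0.5 * eps ** 2 * Sgp
        d_fwd = xp - mean_fwd
        d_bwd = x - mean_bwd
        logq_fwd = -0.5 / eps ** 2 * float(d_fwd @ (self._H @ d_fwd))
        logq_bwd = -0.5 / eps ** 2 * float(d_bwd @ (self._H @ d_bwd))
        log_alpha = (-valp + logq_bwd) - (-val + logq_fwd)
        if math.log(rng.random()) < log_alpha:
            return xp, valp, gp, True
        return x, val, g, False

    def sample_latent_conditional(self, theta, x0, n_iter=6000, burn=1000, thin=2, seed=0):
        """MCMC draws of the latent vector at fixed hyperparameters."""
        rng = np.random.default_rng(seed)
        hyper = self.coder.decode(np.asarray(theta, dtype=float))
        x = np.asarray(x0, dtype=float).copy()
        val, g = self._grad_nlp(x, hyper)
        eps = 0.6
        keep = []
        for it in range(n_iter):
            x, val, g, acc = self._mala_step(x, val, g, hyper, eps, rng)
            if it < burn:
                eps *= math.exp(0.02 * ((1.0 if acc else 0.0) - 0.57))
                eps = min(max(eps, 1e-3), 5.0)
            elif it % thin == 0:
                keep.append(x.copy())
        return np.array(keep)

    # -- joint: pMALA-within-Gibbs ----------------------------------------

    def run_chain(self, seed, n_iter, thin=5, n_latent_steps=3, n_theta_steps=6,
                  adapt_until=None):
        rng = np.random.default_rng(seed)
        p = self.coder.dim
        if adapt_until is None:
            adapt_until = n_iter // 2
        t = self.theta_init + 0.5 * rng.standard_normal(p)
        hyper = self.coder.decode(t)
        x = np.zeros(self.prob.dim)
        x[self.prob.i_b_mark :] = self.prob.initial_latent()[self.prob.i_b_mark :]
        val, g = self._grad_nlp(x, hyper)
        eps = 0.6
        C = self.theta_cov0.copy()
        chol = np.linalg.cholesky(C * (2.4 ** 2 / p) + 1e-9 * np.eye(p))
        hist, keep_x, keep_t = [], [], []
        acc_t = tot_t = 0
        for it in range(n_iter):
            for _ in range(n_latent_steps):
                x, val, g, acc = self._mala_step(x, val, g, hyper, eps, rng)
                if it < adapt_until:
                    eps *= math.exp(0.02 * ((1.0 if acc else 0.0) - 0.57))
                    eps = min(max(eps, 1e-3), 5.0)
            lj = self.prob.log_joint_density(x, t)
            for _ in range(n_theta_steps):
                tp = t + chol @ rng.standard_normal(p)
                ljp = self.prob.log_joint_density(x, tp)
                tot_t += 1
                if math.log(rng.random()) < ljp - lj:
                    t, lj = tp, ljp
                    acc_t += 1
            new_hyper = self.coder.decode(t)
            if new_hyper is not hyper:
                hyper = new_hyper
                val, g = self._grad_nlp(x, hyper)
            hist.append(t.copy())
            if it in (1500, 4000, adapt_until) and it < n_iter:
                C = np.cov(np.array(hist[it // 3 :]).T) + 1e-6 * np.eye(p)
                chol = np.linalg.cholesky(C * (2.4 ** 2 / p) + 1e-9 * np.eye(p))
            if it % thin == 0 and it > n_iter // 2:
                keep_x.append(x.copy())
                keep_t.append(t.copy())
        return np.array(keep_x), np.array(keep_t), acc_t / max(tot_t, 1)

    def run(self, seeds, n_iter, **kw):
        chains = [self.run_chain(s, n_iter, **kw) for s in seeds]
        X = np.vstack([c[0] for c in chains])
        T = np.vstack([c[1] for c in chains])
        accept = [c[2] for c in chains]
        per_chain_latent_means = [c[0].mean(axis=0) for c in chains]
        return X, T, accept, per_chain_latent_means
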