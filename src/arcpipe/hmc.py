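"""Hamiltonian Monte Carlo machinery for the joint choice/response-time model.

A static-trajectory HMC sampler with dual-averaging step-size adaptation and
diagonal mass-matrix adaptation during warmup.  The log posterior and its
gradient are supplied by the model (see :mod:`arcpipe.model`); the
data-likelihood inner loop is numba-compiled for speed.

The kernel computes, for participant-indexed trial data, the joint
log likelihood of Bernoulli choices and gamma response times

    y_ij ~ Bernoulli(theta_ij),  theta_ij = logistic(x_ij . beta_j)
    z_ij ~ Gamma(k_j, rate=k_j / mu_ij),  mu_ij = alpha0_j + alpha1_j * d_ij
    d_ij = 0.25 - (0.5 - theta_ij)^2

together with analytic gradients with respect to every participant-level
parameter.  The response-time term back-propagates into the choice
coefficients through d(theta), which is what ties the two likelihoods into a
joint fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["loglik_grad_core", "pointwise_loglik", "HMCDiagnostics", "sample_chain"]


@njit(cache=True)
def _core(pid, X, y, z, log_z, beta, a0, a1, k, klog, kterm):
    N, P = X.shape
    J = a0.shape[0]
    gbeta = np.zeros((J, P))
    ga0 = np.zeros(J)
    ga1 = np.zeros(J)
    gk = np.zeros(J)  # missing the -n_j*digamma(k_j) term, added by the caller
    ll = 0.0
    for n in range(N):
        j = pid[n]
        eta = 0.0
        for p in range(P):
            eta += beta[j, p] * X[n, p]
        # numerically stable logistic pieces
        if eta >= 0.0:
            enm = math.exp(-eta)
            theta = 1.0 / (1.0 + enm)
            log1pe = eta + math.log1p(enm)
        else:
            ep = math.exp(eta)
            theta = ep / (1.0 + ep)
            log1pe = math.log1p(ep)
        ll += y[n] * eta - log1pe
        dll_deta = y[n] - theta

        d = 0.25 - (0.5 - theta) * (0.5 - theta)
        mu = a0[j] + a1[j] * d
        if mu <= 1e-10:
            return -np.inf, gbeta, ga0, ga1, gk
        kk = k[j]
        zn = z[n]
        lmu = math.log(mu)
        ll += kterm[j] - kk * lmu + (kk - 1.0) * log_z[n] - kk * zn / mu
        dll_dmu = kk * (zn - mu) / (mu * mu)
        ga0[j] += dll_dmu
        ga1[j] += dll_dmu * d
        gk[j] += klog[j] + 1.0 - lmu + log_z[n] - zn / mu
        dll_deta += dll_dmu * a1[j] * 2.0 * (0.5 - theta) * theta * (1.0 - theta)
        for p in range(P):
            gbeta[j, p] += dll_deta * X[n, p]
    return ll, gbeta, ga0, ga1, gk


def loglik_grad_core(pid, X, y, z, log_z, beta, a0, a1, k):
    """Joint log likelihood and per-participant gradients.

    The returned ``gk`` lacks the ``-n_j * digamma(k_j)`` contribution (numba
    has no digamma); callers must add it using the per-participant trial
    counts.  ``log_z`` is the precomputed log of the response times.
    """
    from scipy.special import gammaln

    klog = np.log(k)
    kterm = k * klog - gammaln(k)
    return _core(pid, X, y, z, log_z, beta, a0, a1, k, klog, kterm)


def pointwise_loglik(pid, X, y, z, beta, a0, a1, k):
    """Vectorized per-trial joint log likelihood (one term per trial)."""
    from scipy.special import gammaln

    eta = np.einsum("np,np->n", X, beta[pid])
    theta = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    ll_b = y * eta - np.logaddexp(0.0, eta)
    d = 0.25 - (0.5 - theta) ** 2
    mu = a0[pid] + a1[pid] * d
    kk = k[pid]
    ll_g = (
        kk * np.log(kk)
        - kk * np.log(mu)
        - gammaln(kk)
        + (kk - 1.0) * np.log(z)
        - kk * z / mu
    )
    return ll_b + ll_g


@dataclass
class HMCDiagnostics:
    accept_rate: float
    n_divergent: int
    step_size: float


def _leapfrog(q, p, grad, eps, n_steps, inv_mass, logp_grad):
    """Standard leapfrog integrator; returns proposal state and its logp/grad."""
    p = p + 0.5 * eps * grad
    for _ in range(n_steps):
        q = q + eps * inv_mass * p
        lp, grad = logp_grad(q)
        if not np.isfinite(lp):
            return q, p, lp, grad
        p = p + eps * grad
    p = p - 0.5 * eps * grad
    return q, p, lp, grad


def sample_chain(
    logp_grad,
    q0,
    n_steps: int,
    n_burnin: int,
    rng: np.random.Generator,
    n_leapfrog: int = 12,
    target_accept: float = 0.8,
    init_step: float = 0.05,
):
    """Run one HMC chain; returns (draws after burn-in, diagnostics).

    Warmup adapts the step size by dual averaging toward ``target_accept``
    and re-estimates a diagonal mass matrix from mid-warmup draws.
    """
    q = np.asarray(q0, dtype=float).copy()
    dim = q.size
    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log posterior")

    inv_mass = np.ones(dim)
    sqrt_mass = np.ones(dim)

    # dual averaging state (Hoffman & Gelman 2014 defaults)
    eps = init_step
    mu_da = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    da_count = 0
    gamma_da, t0, kappa = 0.05, 10.0, 0.75

    # staged diagonal mass re-estimation during warmup; the final quarter of
    # warmup is reserved for step-size-only adaptation
    windows = sorted({max(2, int(f * n_burnin)) for f in (0.25, 0.5, 0.75)})
    warm_buffer = []
    draws = np.empty((n_steps - n_burnin, dim))
    n_accept = 0
    n_div = 0
    kept = 0

    for it in range(n_steps):
        p0 = rng.standard_normal(dim) * sqrt_mass
        h0 = lp - 0.5 * np.dot(p0 * inv_mass, p0)
        L = int(rng.integers(max(1, n_leapfrog // 2), n_leapfrog + 1))
        q1, p1, lp1, grad1 = _leapfrog(q, p0, grad, eps, L, inv_mass, logp_grad)
        if np.isfinite(lp1):
            h1 = lp1 - 0.5 * np.dot(p1 * inv_mass, p1)
            log_alpha = min(0.0, h1 - h0)
            accept_prob = math.exp(log_alpha)
            if h0 - h1 > 1000.0:
                n_div += 1
        else:
            accept_prob = 0.0
            n_div += 1
        if rng.random() < accept_prob:
            q, lp, grad = q1, lp1, grad1
            n_accept += 1

        if it < n_burnin:
            # dual averaging update
            da_count += 1
            h_bar = (1 - 1 / (da_count + t0)) * h_bar + (
                target_accept - accept_prob
            ) / (da_count + t0)
            log_eps = mu_da - math.sqrt(da_count) / gamma_da * h_bar
            w = da_count ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = math.exp(log_eps)
            warm_buffer.append(q.copy())
            if it in windows and len(warm_buffer) > 10:
                var = np.var(np.asarray(warm_buffer[len(warm_buffer) // 2:]), axis=0)
                var = np.clip(var, 1e-8, 1e6)
                inv_mass = var
                sqrt_mass = 1.0 / np.sqrt(var)
                # restart step-size adaptation around a cautious value: the
                # new metric can make the previous step size too ambitious
                eps = 0.5 * eps
                mu_da = math.log(2.0 * eps)
                h_bar, log_eps_bar, da_count = 0.0, 0.0, 0
                warm_buffer = []
            if it == n_burnin - 1:
                eps = math.exp(log_eps_bar) if da_count > 0 else eps
        else:
            draws[kept] = q
            kept += 1

    diag = HMCDiagnostics(
        accept_rate=n_accept / n_steps, n_divergent=n_div, step_size=eps
    )
    return draws, diag
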