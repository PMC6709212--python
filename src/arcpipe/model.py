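"""Hierarchical Bayesian joint model of choices and response times.

The model couples a logistic regression on the binary safe/risky choice with
a gamma regression on the response time.  Per trial i and participant j,

    theta_ij = logistic(beta0_j + beta1_j * I[risk=50%] + beta2_j * I[risk=90%]
                        + beta3_j * reward_z)
    y_ij ~ Bernoulli(theta_ij)
    d_ij = 0.25 - (0.5 - theta_ij)^2          (conflict statistic)
    mu_ij = alpha0_j + alpha1_j * d_ij
    z_ij ~ Gamma(k_j, rate = k_j / mu_ij)     (mean mu_ij)

d is the distance-to-decision-boundary conflict statistic: an inverted
parabola in theta, maximal (0.25) when the risky and safe options are
equally likely, zero when the choice is certain.  Because d feeds the RT
mean, response times inform the choice coefficients; the fit maximizes the
joint posterior of both data streams.

Participant-level parameters are partially pooled through group-level
normals (Student-t priors on the group choice coefficients for robust
logistic regression, eta = 5 degrees of freedom by default).  Fitting uses
the in-package HMC sampler with a non-centered parameterization.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, psi

from . import hmc

__all__ = [
    "conflict",
    "likelihood_of_take",
    "rt_mean",
    "joint_log_likelihood",
    "ModelSpec",
    "PriorSpec",
    "PosteriorSamples",
    "fit",
    "rhat",
    "waic",
    "hdi",
    "modal_estimates",
    "extract_conflict",
    "posterior_predictive_rmse",
    "apply_exclusions",
]

logger = logging.getLogger(__name__)

MISSING_EXCLUSION_FRACTION = 0.20  # participants above this missing rate are dropped


# --------------------------------------------------------------------------
# elementary model functions
# --------------------------------------------------------------------------

def conflict(theta):
    """Distance-to-decision-boundary conflict statistic d = 0.25 - (0.5 - theta)^2.

    Maximal (0.25) at theta = 0.5, zero at theta = 0 or 1, symmetric about 0.5.
    """
    t = np.asarray(theta, dtype=float)
    if np.any(t < 0.0) or np.any(t > 1.0):
        raise ValueError("theta must lie in [0, 1]")
    d = 0.25 - (0.5 - t) ** 2
    return float(d) if np.isscalar(theta) else d


def _risk_indicators(risk_level):
    r = np.asarray(risk_level, dtype=float)
    ok = np.isclose(r[..., None], [0.10, 0.50, 0.90]).any(axis=-1)
    if not np.all(ok):
        raise ValueError("risk level must be one of 0.10, 0.50, 0.90")
    return np.isclose(r, 0.50).astype(float), np.isclose(r, 0.90).astype(float)


def likelihood_of_take(beta, risk_level, reward_z):
    """Probability of choosing the risky option.

    ``beta`` is (beta0, beta1, beta2, beta3): intercept (10%-risk reference),
    50%-risk offset, 90%-risk offset, standardized-reward slope.  With six
    elements, beta4/beta5 are 50%- and 90%-risk by reward interactions.
    """
    beta = np.asarray(beta, dtype=float)
    i50, i90 = _risk_indicators(risk_level)
    rz = np.asarray(reward_z, dtype=float)
    eta = beta[0] + beta[1] * i50 + beta[2] * i90 + beta[3] * rz
    if beta.size == 6:
        eta = eta + beta[4] * i50 * rz + beta[5] * i90 * rz
    elif beta.size != 4:
        raise ValueError("beta must have 4 (main effects) or 6 (interaction) entries")
    out = expit(eta)
    return float(out) if out.ndim == 0 else out


def rt_mean(alpha0, alpha1, d):
    """Mean response time mu = alpha0 + alpha1 * d (seconds); must be positive."""
    mu = np.asarray(alpha0, dtype=float) + np.asarray(alpha1, dtype=float) * np.asarray(
        d, dtype=float
    )
    if np.any(mu <= 0):
        raise ValueError("non-positive gamma mean: alpha0 + alpha1*d must be > 0")
    return float(mu) if mu.ndim == 0 else mu


# --------------------------------------------------------------------------
# dataset plumbing
# --------------------------------------------------------------------------

REQUIRED_COLUMNS = ("participant", "trial", "risk", "reward_z", "choice", "rt")


def _validate_dataset(dataset: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset missing columns: {sorted(missing)}")
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    obs = dataset["choice"].notna()
    if not (obs == dataset["rt"].notna()).all():
        raise ValueError("choice and rt must be missing together")
    if (dataset.loc[obs, "rt"] <= 0).any():
        raise ValueError("observed response times must be positive")
    return dataset


def apply_exclusions(
    dataset: pd.DataFrame, max_missing: float = MISSING_EXCLUSION_FRACTION
) -> pd.DataFrame:
    """Drop participants whose missing-trial fraction exceeds ``max_missing``."""
    miss = dataset.groupby("participant")["choice"].apply(lambda c: c.isna().mean())
    bad = miss[miss > max_missing].index.tolist()
    if bad:
        logger.warning(
            "excluding %d participant(s) with >%d%% missing responses: %s",
            len(bad), round(100 * max_missing), bad,
        )
    return dataset[~dataset["participant"].isin(bad)].copy()


def _design_columns(dataset: pd.DataFrame, interactions: bool) -> np.ndarray:
    i50, i90 = _risk_indicators(dataset["risk"].to_numpy())
    rz = dataset["reward_z"].to_numpy(dtype=float)
    cols = [np.ones(len(dataset)), i50, i90, rz]
    if interactions:
        cols += [i50 * rz, i90 * rz]
    return np.column_stack(cols)


@dataclass
class _FitData:
    pid: np.ndarray          # 0-based participant index per observed trial
    X: np.ndarray            # (N, P) predictors
    y: np.ndarray
    z: np.ndarray
    log_z: np.ndarray
    participants: list       # original labels, index-aligned with pid codes
    n_per: np.ndarray        # observed-trial count per participant


def _prepare(dataset: pd.DataFrame, interactions: bool) -> _FitData:
    obs = dataset[dataset["choice"].notna()].reset_index(drop=True)
    labels, codes = np.unique(obs["participant"].to_numpy(), return_inverse=True)
    X = _design_columns(obs, interactions)
    z = obs["rt"].to_numpy(dtype=float)
    return _FitData(
        pid=codes.astype(np.int64),
        X=np.ascontiguousarray(X, dtype=float),
        y=obs["choice"].to_numpy(dtype=float),
        z=z,
        log_z=np.log(z),
        participants=list(labels),
        n_per=np.bincount(codes, minlength=len(labels)).astype(float),
    )


def joint_log_likelihood(params: dict, dataset: pd.DataFrame):
    """Joint Bernoulli+gamma log likelihood and the per-trial pointwise vector.

    ``params`` maps participant label -> dict with keys ``beta`` (4- or
    6-vector), ``alpha0``, ``alpha1``, ``k``.  Missing trials contribute
    nothing.  Returns ``(total, pointwise)`` with one pointwise term per
    observed trial (the joint model's natural observation unit).
    """
    _validate_dataset(dataset)
    P = len(np.atleast_1d(next(iter(params.values()))["beta"]))
    data = _prepare(dataset, interactions=(P == 6))
    J = len(data.participants)
    beta = np.zeros((J, P))
    a0 = np.zeros(J)
    a1 = np.zeros(J)
    k = np.zeros(J)
    for j, lab in enumerate(data.participants):
        p = params[lab]
        beta[j] = np.asarray(p["beta"], dtype=float)
        a0[j], a1[j], k[j] = p["alpha0"], p["alpha1"], p["k"]
    pw = hmc.pointwise_loglik(data.pid, data.X, data.y, data.z, beta, a0, a1, k)
    return float(pw.sum()), pw


# --------------------------------------------------------------------------
# model specification and posterior container
# --------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Weakly-informative default priors (all config-overridable).

    Group choice coefficients: Student-t(eta, 0, beta_scale) for robust
    logistic regression; group SDs half-normal; baseline RT near 1 s.
    """
    eta: float = 5.0                # Student-t degrees of freedom
    beta_scale: float = 2.5
    beta_sd_scale: float = 2.5
    alpha0_loc: float = 1.0
    alpha0_scale: float = 1.0
    alpha1_scale: float = 1.0
    alpha_sd_scale: float = 0.5
    k_shape: float = 2.0            # gamma prior on the RT shape parameter
    k_rate: float = 0.1

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("Student-t degrees of freedom must be positive")


@dataclass
class ModelSpec:
    """Model variant and sampler settings.

    Defaults mirror the study fit: four chains of 2000 HMC steps each
    (1000 burn-in, thinning 4), i.e. 1000 retained posterior draws total.
    """
    variant: str = "hierarchical"   # hierarchical | non_hierarchical | hierarchical_with_interactions
    priors: PriorSpec = field(default_factory=PriorSpec)
    n_chains: int = 4
    n_steps: int = 2000
    n_burnin: int = 1000
    thin: int = 4
    n_leapfrog: int = 14
    target_accept: float = 0.8
    max_divergence_rate: float = 0.2

    def __post_init__(self):
        if self.variant not in (
            "hierarchical", "non_hierarchical", "hierarchical_with_interactions"
        ):
            raise ValueError(f"unknown model variant: {self.variant}")
        if self.n_steps <= self.n_burnin:
            raise ValueError("n_steps must exceed n_burnin")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def interactions(self) -> bool:
        return self.variant == "hierarchical_with_interactions"

    @property
    def hierarchical(self) -> bool:
        return self.variant != "non_hierarchical"

    @property
    def n_predictors(self) -> int:
        return 6 if self.interactions else 4


@dataclass
class PosteriorSamples:
    """Posterior draws plus fit diagnostics.

    ``draws`` maps parameter name -> array of shape (chains, kept_draws, ...);
    participant-level parameters carry a trailing participant axis aligned
    with ``participants``.  ``log_lik`` is (total_draws, n_observed_trials),
    one column per observed trial.
    """
    draws: dict
    participants: list
    rhat: dict
    ess: dict
    log_lik: np.ndarray
    spec: ModelSpec
    diagnostics: list
    seed: int

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[0] * \
            next(iter(self.draws.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws for ``name`` with chains flattened: (total_draws, ...)."""
        d = self.draws[name]
        return d.reshape(d.shape[0] * d.shape[1], *d.shape[2:])

    def group_mean_names(self):
        names = [f"beta{i}_G" for i in range(self.spec.n_predictors)]
        return names + ["alpha0_G", "alpha1_G"]

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.draws.items():
            flat = arr.reshape(arr.shape[0] * arr.shape[1], -1)
            for idx in range(flat.shape[1]):
                suffix = f"[{self.participants[idx]}]" if flat.shape[1] > 1 else ""
                lo, hi = hdi(flat[:, idx], 0.95)
                key = name + suffix
                rows.append(
                    {
                        "parameter": key,
                        "mean": flat[:, idx].mean(),
                        "sd": flat[:, idx].std(),
                        "hdi_2.5%": lo,
                        "hdi_97.5%": hi,
                        "rhat": self.rhat.get(key, np.nan),
                        "ess": self.ess.get(key, np.nan),
                    }
                )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# log posterior (non-centered parameterization) with analytic gradients
# --------------------------------------------------------------------------

class _Posterior:
    """Flattened-vector log posterior for one model variant."""

    def __init__(self, data: _FitData, spec: ModelSpec):
        self.data = data
        self.spec = spec
        self.P = data.X.shape[1]
        self.J = len(data.participants)
        if spec.hierarchical:
            # centered parameterization: participant parameters are sampled
            # directly (each is strongly informed by ~108 trials, so the
            # centered form avoids the group-mean/offset anticorrelation the
            # non-centered form induces in the strong-data regime):
            # [beta_G(P), log_sig_beta(P), a0G, a1G, log_sig_a0, log_sig_a1,
            #  beta_j(J*P), a0_j(J), a1_j(J), log_k(J)]
            self.dim = 2 * self.P + 4 + self.J * (self.P + 3)
        else:
            # single shared parameter set: [beta(P), a0, a1, log_k]
            self.dim = self.P + 3

    # -- packing helpers ---------------------------------------------------
    def unpack(self, q):
        P, J = self.P, self.J
        if not self.spec.hierarchical:
            beta = q[:P]
            return {"beta": beta, "a0": q[P], "a1": q[P + 1], "log_k": q[P + 2]}
        i = 0
        out = {}
        out["beta_G"] = q[i:i + P]; i += P
        out["log_sig_beta"] = q[i:i + P]; i += P
        out["a0G"], out["a1G"] = q[i], q[i + 1]; i += 2
        out["log_sig_a0"], out["log_sig_a1"] = q[i], q[i + 1]; i += 2
        out["beta_j"] = q[i:i + J * P].reshape(J, P); i += J * P
        out["a0_j"] = q[i:i + J]; i += J
        out["a1_j"] = q[i:i + J]; i += J
        out["log_k"] = q[i:i + J]; i += J
        return out

    def participant_params(self, q):
        """(beta (J,P), a0 (J), a1 (J), k (J)) implied by the flat vector."""
        u = self.unpack(q)
        if not self.spec.hierarchical:
            J = self.J
            beta = np.broadcast_to(u["beta"], (J, self.P)).copy()
            a0 = np.full(J, u["a0"])
            a1 = np.full(J, u["a1"])
            k = np.full(J, math.exp(u["log_k"]))
            return beta, a0, a1, k
        return u["beta_j"], u["a0_j"], u["a1_j"], np.exp(u["log_k"])

    # -- priors ------------------------------------------------------------
    @staticmethod
    def _student_t(x, df, scale):
        lp = -0.5 * (df + 1.0) * np.log1p(x * x / (df * scale * scale))
        g = -(df + 1.0) * x / (df * scale * scale + x * x)
        return np.sum(lp), g

    @staticmethod
    def _half_normal_logsig(log_sig, scale):
        # density on sigma plus the log-sigma Jacobian
        sig = np.exp(log_sig)
        lp = -0.5 * sig * sig / (scale * scale) + log_sig
        g = -sig * sig / (scale * scale) + 1.0
        return np.sum(lp), g

    def logp_grad(self, q):
        pr = self.spec.priors
        data = self.data
        if not np.all(np.isfinite(q)) or np.max(np.abs(q)) > 1e3:
            # divergent trajectory wandered off; reject
            return -np.inf, np.zeros(self.dim)
        u = self.unpack(q)
        log_scales = [np.atleast_1d(u["log_k"])]
        if self.spec.hierarchical:
            log_scales += [u["log_sig_beta"], [u["log_sig_a0"]], [u["log_sig_a1"]]]
        if max(np.max(np.abs(np.asarray(v, dtype=float))) for v in log_scales) > 30.0:
            return -np.inf, np.zeros(self.dim)
        beta, a0, a1, k = self.participant_params(q)
        ll, gbeta, ga0, ga1, gk = hmc.loglik_grad_core(
            data.pid, data.X, data.y, data.z, data.log_z, beta, a0, a1, k
        )
        grad = np.zeros(self.dim)
        if not np.isfinite(ll):
            return -np.inf, grad
        gk = gk - data.n_per * psi(k)  # complete the shape gradient

        P, J = self.P, self.J
        if not self.spec.hierarchical:
            gb = gbeta.sum(axis=0)
            lp_t, g_t = self._student_t(u["beta"], pr.eta, pr.beta_scale)
            ll += lp_t
            grad[:P] = gb + g_t
            ll += -0.5 * ((u["a0"] - pr.alpha0_loc) / pr.alpha0_scale) ** 2
            grad[P] = ga0.sum() - (u["a0"] - pr.alpha0_loc) / pr.alpha0_scale**2
            ll += -0.5 * (u["a1"] / pr.alpha1_scale) ** 2
            grad[P + 1] = ga1.sum() - u["a1"] / pr.alpha1_scale**2
            kk = math.exp(u["log_k"])
            ll += pr.k_shape * u["log_k"] - pr.k_rate * kk
            grad[P + 2] = gk.sum() * kk + pr.k_shape - pr.k_rate * kk
            return ll, grad

        sig_beta = np.exp(u["log_sig_beta"])
        sig_a0 = math.exp(u["log_sig_a0"])
        sig_a1 = math.exp(u["log_sig_a1"])

        # hierarchy terms: participant parameters normal around group means
        db = (u["beta_j"] - u["beta_G"][None, :]) / sig_beta[None, :]   # (J,P)
        da0 = (u["a0_j"] - u["a0G"]) / sig_a0
        da1 = (u["a1_j"] - u["a1G"]) / sig_a1
        ll += float(
            -0.5 * np.sum(db**2) - J * np.sum(u["log_sig_beta"])
            - 0.5 * np.sum(da0**2) - J * u["log_sig_a0"]
            - 0.5 * np.sum(da1**2) - J * u["log_sig_a1"]
        )

        i = 0
        # group means of the choice coefficients: Student-t priors
        lp_t, g_t = self._student_t(u["beta_G"], pr.eta, pr.beta_scale)
        ll += lp_t
        grad[i:i + P] = (db / sig_beta[None, :]).sum(axis=0) + g_t; i += P
        # group SDs: half-normal hyperpriors (log-scale Jacobian included)
        lp_s, g_s = self._half_normal_logsig(u["log_sig_beta"], pr.beta_sd_scale)
        ll += lp_s
        grad[i:i + P] = (db**2).sum(axis=0) - J + g_s; i += P
        # RT group means
        ll += -0.5 * ((u["a0G"] - pr.alpha0_loc) / pr.alpha0_scale) ** 2
        grad[i] = da0.sum() / sig_a0 - (u["a0G"] - pr.alpha0_loc) / pr.alpha0_scale**2
        ll += -0.5 * (u["a1G"] / pr.alpha1_scale) ** 2
        grad[i + 1] = da1.sum() / sig_a1 - u["a1G"] / pr.alpha1_scale**2
        i += 2
        # RT group SDs
        lp_s, g_s = self._half_normal_logsig(
            np.asarray([u["log_sig_a0"]]), pr.alpha_sd_scale
        )
        ll += lp_s
        grad[i] = (da0**2).sum() - J + g_s[0]
        lp_s, g_s = self._half_normal_logsig(
            np.asarray([u["log_sig_a1"]]), pr.alpha_sd_scale
        )
        ll += lp_s
        grad[i + 1] = (da1**2).sum() - J + g_s[0]
        i += 2
        # participant-level parameters (centered)
        grad[i:i + J * P] = (gbeta - db / sig_beta[None, :]).ravel(); i += J * P
        grad[i:i + J] = ga0 - da0 / sig_a0; i += J
        grad[i:i + J] = ga1 - da1 / sig_a1; i += J
        # participant gamma shapes: gamma prior, log-scale Jacobian folded in
        ll += float(np.sum(pr.k_shape * u["log_k"] - pr.k_rate * k))
        grad[i:i + J] = gk * k + pr.k_shape - pr.k_rate * k
        return ll, grad


def _map_point(post: _Posterior) -> np.ndarray:
    """Posterior mode (in the unconstrained parameterization) to seed chains.

    A shared-parameter MAP is found first, broadcast to every participant,
    then refined by L-BFGS on the full (hierarchical) posterior.  Starting
    every chain near the mode lets the short warmup concentrate on adapting
    the local metric instead of locating the typical set.
    """
    from scipy.optimize import minimize

    flat_spec = replace(post.spec, variant="non_hierarchical")
    flat = _Posterior(post.data, flat_spec)
    q0 = np.zeros(flat.dim)
    q0[flat.P] = max(0.5, float(np.median(post.data.z)))     # a0 near median RT
    q0[flat.P + 2] = math.log(5.0)                           # k

    def nlp_flat(q):
        lp, g = flat.logp_grad(q)
        return -lp, -g

    qf = minimize(nlp_flat, q0, jac=True, method="L-BFGS-B",
                  options={"maxiter": 200}).x
    if not post.spec.hierarchical:
        return qf

    q = np.zeros(post.dim)
    P, J = post.P, post.J
    q[:P] = qf[:P]
    q[P:2 * P] = math.log(0.5)                      # sigma_beta init
    q[2 * P] = max(qf[P], 0.3)                      # a0G
    q[2 * P + 1] = qf[P + 1]                        # a1G
    q[2 * P + 2] = math.log(0.1)                    # sigma_a0
    q[2 * P + 3] = math.log(0.1)                    # sigma_a1
    i = 2 * P + 4
    q[i:i + J * P] = np.tile(qf[:P], J)             # beta_j at the shared MAP
    q[i + J * P:i + J * P + J] = max(qf[P], 0.3)    # a0_j
    q[i + J * P + J:i + J * P + 2 * J] = qf[P + 1]  # a1_j
    q[i + J * P + 2 * J:] = qf[P + 2]               # log_k

    def nlp(qv):
        lp, g = post.logp_grad(qv)
        if not np.isfinite(lp):
            return 1e12, np.zeros_like(qv)
        return -lp, -g

    # refine participant-level parameters with the group SDs held fixed: the
    # unrestricted joint mode of a hierarchy is degenerate (SDs collapse)
    bounds = [(None, None)] * post.dim
    for idx in list(range(P, 2 * P)) + [2 * P + 2, 2 * P + 3]:
        bounds[idx] = (q[idx], q[idx])
    res = minimize(nlp, q, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 300})
    out = res.x if np.isfinite(post.logp_grad(res.x)[0]) else q
    # recentre group means on the refined participant parameters
    out[:P] = out[i:i + J * P].reshape(J, P).mean(axis=0)
    out[2 * P] = out[i + J * P:i + J * P + J].mean()
    out[2 * P + 1] = out[i + J * P + J:i + J * P + 2 * J].mean()
    return out


def _initial_point(
    post: _Posterior, qmap: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    for scale in (0.05, 0.01, 0.0):
        cand = qmap + scale * rng.standard_normal(post.dim)
        if np.isfinite(post.logp_grad(cand)[0]):
            return cand
    return qmap


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def fit(
    spec: ModelSpec,
    dataset: pd.DataFrame,
    seed: int = 0,
    exclude: bool = True,
) -> PosteriorSamples:
    """Fit the joint choice/RT model by HMC and return posterior draws.

    Participants with more than 20% missing responses are excluded before
    fitting (``exclude=False`` overrides).  Warns if any parameter's split-R̂
    exceeds 1.1 or the divergence rate exceeds the configured threshold.
    """
    _validate_dataset(dataset)
    if exclude:
        dataset = apply_exclusions(dataset)
    data = _prepare(dataset, spec.interactions)
    post = _Posterior(data, spec)

    rng = np.random.default_rng(seed)
    kept = (spec.n_steps - spec.n_burnin) // spec.thin
    chains = np.empty((spec.n_chains, kept, post.dim))
    diags = []
    qmap = _map_point(post)
    for c in range(spec.n_chains):
        q0 = _initial_point(post, qmap, rng)
        draws, diag = hmc.sample_chain(
            post.logp_grad,
            q0,
            n_steps=spec.n_steps,
            n_burnin=spec.n_burnin,
            rng=rng,
            n_leapfrog=spec.n_leapfrog,
            target_accept=spec.target_accept,
        )
        chains[c] = draws[::spec.thin][:kept]
        diags.append(diag)

    div_rate = sum(d.n_divergent for d in diags) / (spec.n_chains * spec.n_steps)
    if div_rate > spec.max_divergence_rate:
        raise RuntimeError(
            f"divergence rate {div_rate:.2f} exceeds {spec.max_divergence_rate}; "
            "consider lowering the step size target or reparameterizing"
        )

    return _package(post, chains, diags, seed)


def _package(post: _Posterior, chains, diags, seed) -> PosteriorSamples:
    spec, data = post.spec, post.data
    C, K, _ = chains.shape
    P, J = post.P, post.J

    draws: dict[str, np.ndarray] = {}

    # constrained-space draws for every participant- and group-level parameter
    beta_all = np.empty((C, K, J, P))
    a0_all = np.empty((C, K, J))
    a1_all = np.empty((C, K, J))
    k_all = np.empty((C, K, J))
    for c in range(C):
        for s in range(K):
            b, a0, a1, k = post.participant_params(chains[c, s])
            beta_all[c, s] = b
            a0_all[c, s] = a0
            a1_all[c, s] = a1
            k_all[c, s] = k
    for p in range(P):
        draws[f"beta{p}"] = beta_all[..., p]
    draws["alpha0"] = a0_all
    draws["alpha1"] = a1_all
    draws["k"] = k_all

    if spec.hierarchical:
        for p in range(P):
            draws[f"beta{p}_G"] = chains[..., p]
            draws[f"beta{p}_sd"] = np.exp(chains[..., P + p])
        draws["alpha0_G"] = chains[..., 2 * P]
        draws["alpha1_G"] = chains[..., 2 * P + 1]
        draws["alpha0_sd"] = np.exp(chains[..., 2 * P + 2])
        draws["alpha1_sd"] = np.exp(chains[..., 2 * P + 3])
    else:
        for p in range(P):
            draws[f"beta{p}_G"] = chains[..., p]
        draws["alpha0_G"] = chains[..., P]
        draws["alpha1_G"] = chains[..., P + 1]

    # convergence diagnostics on every free parameter
    rhats: dict[str, float] = {}
    esss: dict[str, float] = {}
    for name, arr in draws.items():
        flat = arr.reshape(C, K, -1)
        for idx in range(flat.shape[2]):
            key = name if flat.shape[2] == 1 else f"{name}[{data.participants[idx]}]"
            rhats[key] = rhat(flat[:, :, idx])
            esss[key] = _ess(flat[:, :, idx])
    worst = max(rhats.values())
    if worst > 1.1:
        warnings.warn(
            f"max split-R-hat {worst:.3f} exceeds 1.1: chains may not have converged",
            RuntimeWarning,
        )

    # pointwise joint log likelihood per observed trial, for WAIC
    total = C * K
    log_lik = np.empty((total, data.X.shape[0]))
    bfl = beta_all.reshape(total, J, P)
    a0f, a1f, kf = (x.reshape(total, J) for x in (a0_all, a1_all, k_all))
    for s in range(total):
        log_lik[s] = hmc.pointwise_loglik(
            data.pid, data.X, data.y, data.z, bfl[s], a0f[s], a1f[s], kf[s]
        )

    return PosteriorSamples(
        draws=draws,
        participants=list(data.participants),
        rhat=rhats,
        ess=esss,
        log_lik=log_lik,
        spec=spec,
        diagnostics=diags,
        seed=seed,
    )


# --------------------------------------------------------------------------
# diagnostics and summaries
# --------------------------------------------------------------------------

def rhat(chains) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    Each chain is split in half, then R-hat = sqrt(((n-1)/n * W + B/n) / W)
    with B the between- and W the within-(split-)chain variance.  Values
    near 1 indicate convergence.  Constant chains return 1.0.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 chains with >= 2 draws each")
    half = arr.shape[1] // 2
    splits = np.concatenate([arr[:, :half], arr[:, half: 2 * half]], axis=0)
    m, n = splits.shape
    means = splits.mean(axis=1)
    W = splits.var(axis=1, ddof=1).mean()
    if W <= 1e-300:
        return 1.0
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _ess(chains) -> float:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(np.asarray(chains, dtype=float))
        return float(az.ess(ds, method="bulk")["x"].values)


def waic(pointwise_loglik) -> float:
    """WAIC on the deviance scale: -2 * (lppd - p_waic); lower is better.

    ``pointwise_loglik`` is (draws, observations); p_waic is the sum over
    observations of the posterior variance of the log likelihood.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("need a (draws >= 2, observations) pointwise matrix")
    S = ll.shape[0]
    lppd = np.sum(np.logaddexp.reduce(ll, axis=0) - math.log(S))
    p_waic = np.sum(ll.var(axis=0, ddof=1))
    return float(-2.0 * (lppd - p_waic))


def hdi(samples, mass: float = 0.95):
    """Narrowest contiguous interval containing ``ceil(mass*n)`` sorted draws.

    Ties between equally narrow candidate intervals are broken toward the
    lowest lower bound.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 samples")
    m = int(math.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first (lowest) on ties
    return float(x[i]), float(x[i + m - 1])


def modal_estimates(samples: PosteriorSamples, method: str = "kde") -> pd.DataFrame:
    """Per-participant posterior point estimates (one row per participant).

    ``method="kde"`` (default) takes the per-parameter univariate posterior
    mode via a Gaussian-kernel density (Silverman bandwidth) maximized on a
    fine grid; ``method="mean"`` uses the posterior mean instead.
    """
    from scipy.stats import gaussian_kde

    P = samples.spec.n_predictors
    names = [f"beta{p}" for p in range(P)] + ["alpha0", "alpha1", "k"]
    rows = []
    for j, lab in enumerate(samples.participants):
        row = {"participant": lab}
        for name in names:
            x = samples.stacked(name)[:, j]
            if method == "mean":
                row[name] = float(x.mean())
                continue
            if x.size < 10:
                raise ValueError("too few draws for density estimation")
            if x.std() < 1e-12:
                row[name] = float(x[0])
                continue
            kde = gaussian_kde(x, bw_method="silverman")
            grid = np.linspace(x.min(), x.max(), 512)
            row[name] = float(grid[int(np.argmax(kde(grid)))])
        rows.append(row)
    return pd.DataFrame(rows)


def extract_conflict(point_estimates: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-trial likelihood-of-take and conflict from modal point estimates.

    Multiplies the observed trial features (risk level, standardized reward)
    by each participant's point estimates; returns columns ``participant``,
    ``trial``, ``theta_hat``, ``d_hat``.
    """
    beta_cols = [c for c in point_estimates.columns if c.startswith("beta")]
    rows = []
    risk = design["risk"].to_numpy()
    rz = design["reward_z"].to_numpy(dtype=float)
    for _, pe in point_estimates.iterrows():
        beta = pe[beta_cols].to_numpy(dtype=float)
        theta = likelihood_of_take(beta, risk, rz)
        rows.append(
            pd.DataFrame(
                {
                    "participant": pe["participant"],
                    "trial": design["trial"].to_numpy(),
                    "theta_hat": theta,
                    "d_hat": conflict(theta),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def posterior_predictive_rmse(samples: PosteriorSamples, dataset: pd.DataFrame) -> float:
    """RMSE between predicted and observed per-participant risky-choice rates.

    The prediction is the posterior-mean likelihood-of-take averaged over a
    participant's observed trials; the observation is that participant's
    empirical risky-choice rate.
    """
    obs = dataset[dataset["choice"].notna()]
    P = samples.spec.n_predictors
    beta_mean = np.stack(
        [samples.stacked(f"beta{p}").mean(axis=0) for p in range(P)], axis=1
    )  # (J, P), rows aligned with samples.participants
    errs = []
    for j, lab in enumerate(samples.participants):
        sub = obs[obs["participant"] == lab]
        theta = likelihood_of_take(
            beta_mean[j], sub["risk"].to_numpy(), sub["reward_z"].to_numpy(dtype=float)
        )
        errs.append(np.mean(theta) - sub["choice"].mean())
    return float(np.sqrt(np.mean(np.square(errs))))
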