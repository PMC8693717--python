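"""Gibbs sampler for robust marginal Bayesian variable selection in G×E studies.

The model for gene j is the marginal regression

    y_i = E_i alpha + C_i gamma + x_ij beta_j + W_ij eta_j + eps_i,

with W_ij the elementwise products of x_j with the q environmental exposures.
Errors are Laplace (Bayesian LAD): using the Kozumi–Kobayashi scale mixture at
quantile level theta = 0.5, eps_i = tau^(-1/2) xi2 sqrt(v_i) z_i with
v_i | tau ~ Exp(rate tau), z_i ~ N(0,1), xi2^2 = 2/(theta(1-theta)) = 8.

Sparsity on beta_j and eta_jk comes from spike-and-slab priors: a point mass at
zero mixed with a N(0, s) slab whose variance s carries the Laplace
(exponential scale-mixture) hierarchy, so the slab marginal is the Bayesian
LASSO prior.  Every full conditional is conjugate, giving a plain Gibbs scan.

All update functions below accept either a single model (vectors of shape
``(n,)``, scalar parameters) or a batch of G independent marginal models
stacked along a trailing gene axis (``(n, G)`` arrays, ``(G,)`` parameters).
The batch form is what makes a 500-gene marginal scan affordable: the per-gene
samplers share no state, so one vectorized sweep advances all genes at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

__all__ = [
    "MarginalDesign",
    "Hyperparameters",
    "ChainState",
    "ConditionalNormal",
    "SpikeSlabDraw",
    "PosteriorDraws",
    "BatchDraws",
    "weights",
    "normal_coef_update",
    "spike_slab_update",
    "update_slab_variance",
    "update_phi1sq",
    "update_phi2sq",
    "update_pi1",
    "update_pi2",
    "update_tau",
    "update_latent_v",
    "update_sigma2",
    "gibbs_sweep",
    "run_chain",
    "run_chain_batch",
]

# Numerical guards: the slab-variance and latent-scale conditionals are
# improper at coefficient/residual exactly 0 (probability-zero events that do
# occur in floating point).
COEF_FLOOR = 1e-10
RESID_SQ_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MarginalDesign:
    """Inputs of one gene's marginal regression.

    Parameters
    ----------
    y : (n,) response.
    E : (n, q) environmental exposures.
    C : (n, m) clinical covariates (m may be 0).
    x : (n,) genetic measurement for this gene (expression or 0/1/2 dosage).
    W : (n, q) interaction columns, ``W[:, k] = x * E[:, k]``; computed when
        omitted.
    """

    y: np.ndarray
    E: np.ndarray
    C: np.ndarray
    x: np.ndarray
    W: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.E = np.atleast_2d(np.asarray(self.E, dtype=float))
        self.C = np.asarray(self.C, dtype=float).reshape(len(self.y), -1)
        self.x = np.asarray(self.x, dtype=float)
        n = self.y.shape[0]
        if n < 1 or self.E.shape[0] != n or self.x.shape[0] != n or self.C.shape[0] != n:
            raise ValueError("y, E, C, x must share the sample dimension")
        if self.E.shape[1] < 1:
            raise ValueError("at least one environmental factor is required")
        if self.W is None:
            self.W = self.x[:, None] * self.E
        else:
            self.W = np.asarray(self.W, dtype=float)
            if self.W.shape != self.E.shape:
                raise ValueError("W must be n x q")
        for arr in (self.y, self.E, self.C, self.x, self.W):
            if not np.all(np.isfinite(arr)):
                raise ValueError("design contains non-finite entries")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def q(self) -> int:
        return self.E.shape[1]

    @property
    def m(self) -> int:
        return self.C.shape[1]


@dataclass
class Hyperparameters:
    """Fixed prior constants.

    Defaults are all 1 (Gamma priors on tau, phi1^2, phi2^2; Beta priors on
    pi1, pi2; prior variances alpha0, gamma0 of the environmental/clinical
    coefficients).  theta is the quantile level; LAD is theta = 0.5, giving
    xi1 = 0 and xi2^2 = 8.
    """

    a: float = 1.0
    b: float = 1.0
    c1: float = 1.0
    d1: float = 1.0
    c2: float = 1.0
    d2: float = 1.0
    r1: float = 1.0
    u1: float = 1.0
    r2: float = 1.0
    u2: float = 1.0
    alpha0: float = 1.0
    gamma0: float = 1.0
    theta: float = 0.5

    def __post_init__(self) -> None:
        for name in ("a", "b", "c1", "d1", "c2", "d2", "r1", "u1", "r2", "u2",
                     "alpha0", "gamma0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be positive")
        if not 0 < self.theta < 1:
            raise ValueError("theta must lie in (0, 1)")

    @property
    def xi1(self) -> float:
        return (1.0 - 2.0 * self.theta) / (self.theta * (1.0 - self.theta))

    @property
    def xi2sq(self) -> float:
        return 2.0 / (self.theta * (1.0 - self.theta))


@dataclass
class ConditionalNormal:
    """Mean/variance of a univariate normal full conditional."""

    mean: Union[float, np.ndarray]
    variance: Union[float, np.ndarray]


@dataclass
class SpikeSlabDraw:
    """Outcome of one spike-and-slab coefficient update.

    ``value`` is exactly 0 with probability ``spike_prob`` given the slab
    parameters, otherwise a draw from the slab normal.
    """

    spike_prob: Union[float, np.ndarray]
    value: Union[float, np.ndarray]
    slab: ConditionalNormal


@dataclass
class ChainState:
    """Current values of every sampled quantity for a single marginal model."""

    alpha: np.ndarray
    gamma: np.ndarray
    beta: float
    eta: np.ndarray
    v: np.ndarray
    s1: float
    s2: np.ndarray
    tau: float
    phi1sq: float
    phi2sq: float
    pi1: float
    pi2: float
    sigma2: float = 1.0  # Gaussian-likelihood variants only

    @property
    def ind_beta(self) -> int:
        return int(self.beta != 0)

    @property
    def ind_eta(self) -> np.ndarray:
        return (np.asarray(self.eta) != 0).astype(int)

    def validate(self) -> None:
        if np.any(np.asarray(self.v) <= 0) or self.tau <= 0 or self.s1 <= 0 \
                or np.any(np.asarray(self.s2) <= 0) or self.phi1sq <= 0 \
                or self.phi2sq <= 0 or self.sigma2 <= 0:
            raise ValueError("scale parameters must be strictly positive")
        if not (0 <= self.pi1 <= 1 and 0 <= self.pi2 <= 1):
            raise ValueError("pi1, pi2 must lie in [0, 1]")

    @classmethod
    def initial(cls, design: MarginalDesign, coef: float = 1.0) -> "ChainState":
        """Neutral initial state: regression parameters at ``coef`` (default 1,
        the conventional starting value), latents and scales at 1, mixing
        weights at 1/2."""
        q, m, n = design.q, design.m, design.n
        return cls(
            alpha=np.full(q, float(coef)),
            gamma=np.full(m, float(coef)),
            beta=float(coef),
            eta=np.full(q, float(coef)),
            v=np.ones(n),
            s1=1.0,
            s2=np.ones(q),
            tau=1.0,
            phi1sq=1.0,
            phi2sq=1.0,
            pi1=0.5,
            pi2=0.5,
            sigma2=1.0,
        )


@dataclass
class PosteriorDraws:
    """Stored post-burn-in sweeps for a single marginal model.

    Arrays have a leading sweep axis of length H = iterations - burn_in.
    A stored coefficient is exactly 0 iff its inclusion indicator was 0.
    """

    alpha: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    eta: np.ndarray
    tau: np.ndarray
    s1: np.ndarray
    phi1sq: np.ndarray
    phi2sq: np.ndarray
    pi1: np.ndarray
    pi2: np.ndarray
    sigma2: np.ndarray
    iterations: int
    burn_in: int
    seed: Optional[int]
    robust: bool = True
    sparse: bool = True

    @property
    def H(self) -> int:
        return self.beta.shape[0]

    @property
    def ind_beta(self) -> np.ndarray:
        return (self.beta != 0).astype(int)

    @property
    def ind_eta(self) -> np.ndarray:
        return (self.eta != 0).astype(int)

    def to_frame(self):
        """One row per sweep, one column per scalar parameter (CSV-friendly)."""
        import pandas as pd

        cols = {"beta": self.beta, "tau": self.tau, "s1": self.s1,
                "phi1sq": self.phi1sq, "phi2sq": self.phi2sq,
                "pi1": self.pi1, "pi2": self.pi2, "sigma2": self.sigma2}
        for k in range(self.alpha.shape[1]):
            cols[f"alpha{k + 1}"] = self.alpha[:, k]
        for t in range(self.gamma.shape[1]):
            cols[f"gamma{t + 1}"] = self.gamma[:, t]
        for k in range(self.eta.shape[1]):
            cols[f"eta{k + 1}"] = self.eta[:, k]
        return pd.DataFrame(cols)


@dataclass
class BatchDraws:
    """Post-burn-in coefficient draws for a batch of G marginal models.

    Only the selection-relevant arrays are kept (``beta``: (H, G);
    ``eta``: (H, q, G)) to bound memory at study scale.
    """

    beta: np.ndarray
    eta: np.ndarray
    iterations: int
    burn_in: int
    seed: Optional[int]
    robust: bool
    sparse: bool
    full: Optional[dict] = None  # populated for single-model runs only

    @property
    def H(self) -> int:
        return self.beta.shape[0]

    @property
    def G(self) -> int:
        return self.beta.shape[1]

    @property
    def pip_main(self) -> np.ndarray:
        """Posterior inclusion probability of each main effect, (G,)."""
        return (self.beta != 0).mean(axis=0)

    @property
    def pip_interaction(self) -> np.ndarray:
        """Posterior inclusion probabilities of the interactions, (q, G)."""
        return (self.eta != 0).mean(axis=0)


# ---------------------------------------------------------------------------
# Full conditionals
# ---------------------------------------------------------------------------

def weights(state: ChainState, hyper: Hyperparameters) -> np.ndarray:
    """Precision weight of each observation, w_i = tau / (xi2^2 v_i)."""
    v = np.asarray(state.v, dtype=float)
    if np.any(v <= 0) or state.tau <= 0:
        raise ValueError("v and tau must be strictly positive")
    return state.tau / (hyper.xi2sq * v)


def normal_coef_update(partial_residual, predictor, w, prior_var, rng):
    """Conjugate normal update for a coefficient with a N(0, prior_var) prior.

    ``partial_residual`` must exclude this coefficient's own contribution.
    variance = (sum_i w_i z_i^2 + 1/prior_var)^-1,
    mean = variance * sum_i w_i r_i z_i.
    """
    if np.any(np.asarray(prior_var) <= 0):
        raise ValueError("prior_var must be positive")
    z = np.asarray(predictor, dtype=float)
    r = np.asarray(partial_residual, dtype=float)
    wz = w * z
    precision = np.sum(wz * z, axis=0) + 1.0 / prior_var
    variance = 1.0 / precision
    mean = variance * np.sum(wz * r, axis=0)
    draw = rng.normal(mean, np.sqrt(variance))
    return ConditionalNormal(mean, variance), draw


def spike_slab_update(partial_residual, predictor, w, slab_var, pi_spike, rng):
    """Spike-and-slab coefficient update.

    The slab is the conjugate normal with prior variance ``slab_var``; the
    spike probability is

        l = pi / (pi + (1-pi) slab_var^{-1/2} sd * exp(mean^2 / (2 var)))

    computed in log space (the exponent overflows for strong signals).  The
    value is set to 0 with probability l, else drawn from the slab.  The RNG
    consumes one uniform and one normal regardless of the branch taken, so
    batched and scalar calls stay stream-compatible.
    """
    if np.any(np.asarray(slab_var) <= 0):
        raise ValueError("slab_var must be positive")
    z = np.asarray(predictor, dtype=float)
    r = np.asarray(partial_residual, dtype=float)
    wz = w * z
    precision = np.sum(wz * z, axis=0) + 1.0 / slab_var
    variance = 1.0 / precision
    mean = variance * np.sum(wz * r, axis=0)

    pi_spike = np.asarray(pi_spike, dtype=float)
    spike_prob = _spike_prob_from_logodds(pi_spike, np.asarray(slab_var),
                                          variance, mean)

    u = rng.random(np.shape(mean)) if np.ndim(mean) else rng.random()
    slab_draw = rng.normal(mean, np.sqrt(variance))
    value = np.where(u < spike_prob, 0.0, slab_draw)
    if np.ndim(mean) == 0:
        value = float(value)
        spike_prob = float(spike_prob)
    return SpikeSlabDraw(spike_prob, value, ConditionalNormal(mean, variance))


def update_slab_variance(coef, phisq, rng):
    """Slab variance update.

    coef == 0: s ~ Exponential(rate phi^2/2).  coef != 0: 1/s ~
    Inverse-Gaussian(mean sqrt(phi^2/coef^2), shape phi^2); |coef| is floored
    to keep the mean parameter finite.  Both branches consume a draw so the
    stream is branch-independent.
    """
    if np.any(np.asarray(phisq) <= 0):
        raise ValueError("phisq must be positive")
    coef = np.asarray(coef, dtype=float)
    abs_coef = np.maximum(np.abs(coef), COEF_FLOOR)
    exp_draw = rng.exponential(2.0 / phisq, size=np.shape(coef))
    ig_mean = np.sqrt(phisq) / abs_coef
    inv_s = rng.wald(ig_mean, phisq * np.ones_like(ig_mean))
    s = np.where(coef == 0.0, exp_draw, 1.0 / inv_s)
    return float(s) if np.ndim(coef) == 0 else s


def update_phi1sq(s1, c1, d1, rng):
    """phi1^2 | s1 ~ Gamma(shape c1 + 1, rate s1/2 + d1)."""
    return rng.gamma(c1 + 1.0, 1.0 / (0.5 * np.asarray(s1, dtype=float) + d1))


def update_phi2sq(s2, c2, d2, rng):
    """phi2^2 | s2 ~ Gamma(shape c2 + q, rate sum_k s2k/2 + d2)."""
    s2 = np.asarray(s2, dtype=float)
    q = s2.shape[0]
    rate = 0.5 * np.sum(s2, axis=0) + d2
    return rng.gamma(c2 + q, 1.0 / rate)


def update_pi1(ind_beta, r1, u1, rng):
    """pi1 | ind ~ Beta(r1 + 1 - ind, u1 + ind)."""
    ind = np.asarray(ind_beta, dtype=float)
    return rng.beta(r1 + 1.0 - ind, u1 + ind)


def update_pi2(ind_eta, r2, u2, rng):
    """pi2 | indicators ~ Beta(r2 + q - k, u2 + k) with k the number of
    nonzero interactions among the q slots (conjugate Beta-Bernoulli count
    update implied by the q-component mixture prior)."""
    ind = np.asarray(ind_eta, dtype=float)
    q = ind.shape[0]
    k = np.sum(ind, axis=0)
    return rng.beta(r2 + q - k, u2 + k)


def update_tau(residuals, v, a, b, hyper: Hyperparameters, rng):
    """tau | rest ~ Gamma(a + 3n/2, b + sum_i [r_i^2/(2 xi2^2 v_i) + v_i])."""
    r = np.asarray(residuals, dtype=float)
    v = np.asarray(v, dtype=float)
    n = r.shape[0]
    rate = b + np.sum(r * r / (2.0 * hyper.xi2sq * v) + v, axis=0)
    return rng.gamma(a + 1.5 * n, 1.0 / rate)


def update_latent_v(residuals, tau, hyper: Hyperparameters, rng):
    """Latent scale update: independently per observation,
    1/v_i ~ Inverse-Gaussian(mean sqrt(2 xi2^2 / r_i^2), shape 2 tau);
    returns v.  r_i^2 is floored (the conditional is improper at r_i = 0)."""
    if np.any(np.asarray(tau) <= 0):
        raise ValueError("tau must be positive")
    r = np.asarray(residuals, dtype=float)
    r2 = np.maximum(r * r, RESID_SQ_FLOOR)
    mean = np.sqrt(2.0 * hyper.xi2sq / r2)
    shape = 2.0 * tau * np.ones_like(mean)
    return 1.0 / rng.wald(mean, shape)


def update_sigma2(residuals, a_sigma, b_sigma, rng):
    """Gaussian-likelihood error variance: sigma^2 | rest ~
    Inverse-Gamma(a_sigma + n/2, b_sigma + SSR/2)."""
    r = np.asarray(residuals, dtype=float)
    n = r.shape[0]
    rate = b_sigma + 0.5 * np.sum(r * r, axis=0)
    return 1.0 / rng.gamma(a_sigma + 0.5 * n, 1.0 / rate)


# ---------------------------------------------------------------------------
# Batched sweep engine
# ---------------------------------------------------------------------------

class _BatchState:
    """Mutable arrays for G stacked marginal models (gene axis last)."""

    __slots__ = ("alpha", "gamma", "beta", "eta", "v", "s1", "s2", "tau",
                 "phi1sq", "phi2sq", "pi1", "pi2", "sigma2", "resid")

    def __init__(self, n: int, q: int, m: int, G: int, init_coef: float = 1.0):
        self.alpha = np.full((q, G), float(init_coef))
        self.gamma = np.full((m, G), float(init_coef))
        self.beta = np.full(G, float(init_coef))
        self.eta = np.full((q, G), float(init_coef))
        self.v = np.ones((n, G))
        self.s1 = np.ones(G)
        self.s2 = np.ones((q, G))
        self.tau = np.ones(G)
        self.phi1sq = np.ones(G)
        self.phi2sq = np.ones(G)
        self.pi1 = np.full(G, 0.5)
        self.pi2 = np.full(G, 0.5)
        self.sigma2 = np.ones(G)
        self.resid = None  # set by the runner


def _spike_prob_from_logodds(pi_spike, slab_var, variance, mean):
    """Spike probability in log space (shared by the op function and the
    fused sweep): sigmoid of -(log slab odds)."""
    with np.errstate(divide="ignore"):
        log_odds = (np.log1p(-pi_spike) - np.log(pi_spike)
                    - 0.5 * np.log(slab_var) + 0.5 * np.log(variance)
                    + 0.5 * mean * mean / variance)
    spike_prob = np.where(log_odds >= 0,
                          np.exp(-np.logaddexp(0.0, log_odds)),
                          1.0 - np.exp(-np.logaddexp(0.0, -log_odds)))
    spike_prob = np.where(pi_spike == 0.0, 0.0, spike_prob)
    return np.where(pi_spike == 1.0, 1.0, spike_prob)


def _batch_sweep(bs: _BatchState, y, E, C, X, W, hyper: Hyperparameters,
                 rng, robust: bool, sparse: bool,
                 sigma_prior=(1.0, 1.0), pre=None) -> None:
    """One full systematic scan over all G models, in the fixed order:
    alpha_k, gamma_t, beta, eta_k, s1, s2k, phi1^2, phi2^2, pi1, pi2, then
    tau and v (robust) or sigma^2 (Gaussian).  Residuals are maintained
    incrementally under the mu_(-.) partial-residual convention.

    The coefficient conditionals are the same conjugate formulas as
    :func:`normal_coef_update` / :func:`spike_slab_update`, written in fused
    einsum form with an RNG call sequence identical to those functions (the
    test suite checks bit-equality of a sweep against their composition).
    ``pre`` optionally carries precomputed squared-column sums (Gaussian
    path, where the weights are constant across observations).
    """
    q = E.shape[1]
    m = C.shape[1]
    resid = bs.resid
    if robust:
        iv = 1.0 / bs.v                     # (n, G)
        w = (bs.tau / hyper.xi2sq) * iv

        def col_moments(z, z2):             # z: (n,), predictor column
            A = np.einsum("ng,n->g", w, z2)
            Bp = np.einsum("ng,n,ng->g", w, z, resid)
            return A, Bp

        def gene_moments(Z, Z2):            # Z: (n, G), per-gene predictor
            A = np.einsum("ng,ng->g", w, Z2)
            Bp = np.einsum("ng,ng,ng->g", w, Z, resid)
            return A, Bp
    else:
        w = 1.0 / bs.sigma2                 # (G,)

        def col_moments(z, z2):
            A = w * np.sum(z2)
            Bp = w * (z @ resid)
            return A, Bp

        def gene_moments(Z, Z2):
            A = w * np.einsum("ng->g", Z2)
            Bp = w * np.einsum("ng,ng->g", Z, resid)
            return A, Bp

    if pre is None:
        E2 = E * E
        C2 = C * C
        X2 = X * X
        W2 = W * W
    else:
        E2, C2, X2, W2 = pre

    # --- environmental and clinical coefficients (normal priors) ---
    for k in range(q):
        z = E[:, k]
        A, Bp = col_moments(z, E2[:, k])
        variance = 1.0 / (A + 1.0 / hyper.alpha0)
        mean = variance * (Bp + bs.alpha[k] * A)
        draw = rng.normal(mean, np.sqrt(variance))
        resid += z[:, None] * (bs.alpha[k] - draw)
        bs.alpha[k] = draw
    for t in range(m):
        z = C[:, t]
        A, Bp = col_moments(z, C2[:, t])
        variance = 1.0 / (A + 1.0 / hyper.gamma0)
        mean = variance * (Bp + bs.gamma[t] * A)
        draw = rng.normal(mean, np.sqrt(variance))
        resid += z[:, None] * (bs.gamma[t] - draw)
        bs.gamma[t] = draw

    # --- genetic main effect and interactions (spike-and-slab) ---
    A, Bp = gene_moments(X, X2)
    variance = 1.0 / (A + 1.0 / bs.s1)
    mean = variance * (Bp + bs.beta * A)
    spike = _spike_prob_from_logodds(bs.pi1, bs.s1, variance, mean)
    u = rng.random(mean.shape)
    slab_draw = rng.normal(mean, np.sqrt(variance))
    new = np.where(u < spike, 0.0, slab_draw)
    resid += X * (bs.beta - new)
    bs.beta = new
    for k in range(q):
        Zk = W[:, k, :]
        A, Bp = gene_moments(Zk, W2[:, k, :])
        variance = 1.0 / (A + 1.0 / bs.s2[k])
        mean = variance * (Bp + bs.eta[k] * A)
        spike = _spike_prob_from_logodds(bs.pi2, bs.s2[k], variance, mean)
        u = rng.random(mean.shape)
        slab_draw = rng.normal(mean, np.sqrt(variance))
        new = np.where(u < spike, 0.0, slab_draw)
        resid += Zk * (bs.eta[k] - new)
        bs.eta[k] = new
    bs.resid = resid

    # --- slab variances and their Gamma hyper-scales ---
    bs.s1 = update_slab_variance(bs.beta, bs.phi1sq, rng)
    for k in range(q):
        bs.s2[k] = update_slab_variance(bs.eta[k], bs.phi2sq, rng)
    bs.phi1sq = update_phi1sq(bs.s1, hyper.c1, hyper.d1, rng)
    bs.phi2sq = update_phi2sq(bs.s2, hyper.c2, hyper.d2, rng)

    # --- mixture weights (pinned at 0 for the plain-LASSO variants, which
    # keeps the RNG call sequence identical to the sparse samplers) ---
    bs.pi1 = update_pi1((bs.beta != 0).astype(float), hyper.r1, hyper.u1, rng)
    bs.pi2 = update_pi2((bs.eta != 0).astype(float), hyper.r2, hyper.u2, rng)
    if not sparse:
        bs.pi1 = np.zeros_like(bs.pi1)
        bs.pi2 = np.zeros_like(bs.pi2)

    # --- scale of the error law ---
    if robust:
        bs.tau = update_tau(bs.resid, bs.v, hyper.a, hyper.b, hyper, rng)
        bs.v = update_latent_v(bs.resid, bs.tau, hyper, rng)
    else:
        a_s, b_s = sigma_prior
        bs.sigma2 = update_sigma2(bs.resid, a_s, b_s, rng)


def run_chain_batch(y, E, C, X, hyper: Hyperparameters = None, *,
                    iterations: int = 10_000, burn_in: int = 5_000,
                    seed: Optional[int] = None, rng=None,
                    robust: bool = True, sparse: bool = True,
                    sigma_prior=(1.0, 1.0), init_coef: float = 1.0,
                    dtype=np.float32) -> BatchDraws:
    """Run one Gibbs chain jointly over all G marginal models.

    ``X`` is (n, G); each column defines one marginal model (its interactions
    with the shared E are formed internally).  Stores post-burn-in beta and
    eta draws only; use :func:`run_chain` for the full per-parameter record of
    a single model.
    """
    if hyper is None:
        hyper = Hyperparameters()
    if iterations <= burn_in or burn_in < 0:
        raise ValueError("need iterations > burn_in >= 0")
    y = np.asarray(y, dtype=float)
    E = np.asarray(E, dtype=float)
    C = np.asarray(C, dtype=float).reshape(len(y), -1)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, G = X.shape
    q, m = E.shape[1], C.shape[1]
    W = X[:, None, :] * E[:, :, None]  # (n, q, G)

    if rng is None:
        rng = np.random.default_rng(seed)
    bs = _BatchState(n, q, m, G, init_coef=init_coef)
    if not sparse:
        bs.pi1[:] = 0.0
        bs.pi2[:] = 0.0
    fitted = (E @ bs.alpha + C @ bs.gamma + X * bs.beta
              + np.einsum("nkg,kg->ng", W, bs.eta))
    bs.resid = y[:, None] - fitted
    pre = (E * E, C * C, X * X, W * W)

    H = iterations - burn_in
    beta_store = np.empty((H, G), dtype=dtype)
    eta_store = np.empty((H, q, G), dtype=dtype)
    full_record = G == 1  # cheap; run_chain consumes it
    if full_record:
        extras = {name: np.empty((H, G)) for name in
                  ("tau", "s1", "phi1sq", "phi2sq", "pi1", "pi2", "sigma2")}
        alpha_store = np.empty((H, q, G))
        gamma_store = np.empty((H, m, G))
    for it in range(iterations):
        _batch_sweep(bs, y, E, C, X, W, hyper, rng, robust, sparse,
                     sigma_prior, pre=pre)
        h = it - burn_in
        if h >= 0:
            beta_store[h] = bs.beta
            eta_store[h] = bs.eta
            if full_record:
                alpha_store[h] = bs.alpha
                gamma_store[h] = bs.gamma
                for name in extras:
                    extras[name][h] = getattr(bs, name)

    out = BatchDraws(beta_store, eta_store, iterations, burn_in, seed,
                     robust, sparse)
    if full_record:
        out.full = {"alpha": alpha_store, "gamma": gamma_store, **extras}
    return out


def gibbs_sweep(state: ChainState, design: MarginalDesign,
                hyper: Hyperparameters, rng) -> ChainState:
    """One full systematic scan of all full conditionals for one model."""
    state.validate()
    q, m, n = design.q, design.m, design.n
    bs = _BatchState(n, q, m, 1)
    bs.alpha = np.asarray(state.alpha, dtype=float).reshape(q, 1).copy()
    bs.gamma = np.asarray(state.gamma, dtype=float).reshape(m, 1).copy()
    bs.beta = np.array([float(state.beta)])
    bs.eta = np.asarray(state.eta, dtype=float).reshape(q, 1).copy()
    bs.v = np.asarray(state.v, dtype=float).reshape(n, 1).copy()
    bs.s1 = np.array([float(state.s1)])
    bs.s2 = np.asarray(state.s2, dtype=float).reshape(q, 1).copy()
    bs.tau = np.array([float(state.tau)])
    bs.phi1sq = np.array([float(state.phi1sq)])
    bs.phi2sq = np.array([float(state.phi2sq)])
    bs.pi1 = np.array([float(state.pi1)])
    bs.pi2 = np.array([float(state.pi2)])
    bs.sigma2 = np.array([float(state.sigma2)])
    X = design.x[:, None]
    W = design.W[:, :, None]
    fitted = (design.E @ bs.alpha + design.C @ bs.gamma + X * bs.beta
              + np.einsum("nkg,kg->ng", W, bs.eta))
    bs.resid = design.y[:, None] - fitted
    _batch_sweep(bs, design.y, design.E, design.C, X, W, hyper, rng,
                 robust=True, sparse=True)
    return ChainState(
        alpha=bs.alpha[:, 0].copy(), gamma=bs.gamma[:, 0].copy(),
        beta=float(bs.beta[0]), eta=bs.eta[:, 0].copy(),
        v=bs.v[:, 0].copy(), s1=float(bs.s1[0]), s2=bs.s2[:, 0].copy(),
        tau=float(bs.tau[0]), phi1sq=float(bs.phi1sq[0]),
        phi2sq=float(bs.phi2sq[0]), pi1=float(bs.pi1[0]),
        pi2=float(bs.pi2[0]), sigma2=float(bs.sigma2[0]))


def run_chain(design: MarginalDesign, hyper: Hyperparameters = None, *,
              iterations: int = 10_000, burn_in: int = 5_000,
              seed: Optional[int] = None, rng=None,
              init_coef: float = 1.0, robust: bool = True,
              sparse: bool = True, sigma_prior=(1.0, 1.0)) -> PosteriorDraws:
    """Run one chain for a single marginal model and keep every parameter.

    Defaults follow the study protocol: 10,000 iterations, the first 5,000
    discarded as burn-in, regression parameters initialized at 1.
    """
    batch = run_chain_batch(
        design.y, design.E, design.C, design.x[:, None], hyper,
        iterations=iterations, burn_in=burn_in, seed=seed, rng=rng,
        robust=robust, sparse=sparse, sigma_prior=sigma_prior,
        init_coef=init_coef, dtype=np.float64)
    full = batch.full
    return PosteriorDraws(
        alpha=full["alpha"][:, :, 0], gamma=full["gamma"][:, :, 0],
        beta=batch.beta[:, 0], eta=batch.eta[:, :, 0],
        tau=full["tau"][:, 0], s1=full["s1"][:, 0],
        phi1sq=full["phi1sq"][:, 0], phi2sq=full["phi2sq"][:, 0],
        pi1=full["pi1"][:, 0], pi2=full["pi2"][:, 0],
        sigma2=full["sigma2"][:, 0],
        iterations=iterations, burn_in=burn_in, seed=seed,
        robust=robust, sparse=sparse)
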