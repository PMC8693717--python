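"""The four marginal samplers: LADBLSS and its three comparators.

LADBLSS  robust (LAD likelihood) + spike-and-slab priors — the main method.
LADBL    robust, plain Laplace (scale-mixture) priors, no point mass.
BLSS     Gaussian likelihood + spike-and-slab priors.
BL       Gaussian likelihood, plain Laplace priors (standard Bayesian LASSO).

All four share the Gibbs machinery in :mod:`robustgxe.gibbs_core`.  The
Gaussian-likelihood variants replace the latent-scale weights tau/(xi2^2 v_i)
with 1/sigma^2 and update sigma^2 from its conjugate Inverse-Gamma
conditional.  The non-sparse variants run the identical sampler with the
mixture weights pi1 = pi2 pinned to 0, which reduces the spike-and-slab
coefficient conditionals to their slab (Bayesian LASSO) form while keeping
the RNG call sequence unchanged — LADBLSS with pinned mixing weights is
LADBL draw for draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .gibbs_core import (BatchDraws, Hyperparameters, MarginalDesign,
                         PosteriorDraws, run_chain, run_chain_batch)

__all__ = ["MethodSpec", "METHODS", "get_method", "run_marginal_model",
           "run_marginal_batch"]


@dataclass(frozen=True)
class MethodSpec:
    """Which likelihood and which coefficient prior a sampler uses."""

    name: str
    robust: bool   # LAD (Laplace) likelihood vs Gaussian
    sparse: bool   # spike-and-slab vs plain Laplace prior
    sigma_prior: Tuple[float, float] = (1.0, 1.0)  # IG(a, b) on sigma^2


METHODS = {
    "LADBLSS": MethodSpec("LADBLSS", robust=True, sparse=True),
    "LADBL": MethodSpec("LADBL", robust=True, sparse=False),
    "BLSS": MethodSpec("BLSS", robust=False, sparse=True),
    "BL": MethodSpec("BL", robust=False, sparse=False),
}


def get_method(name: str) -> MethodSpec:
    try:
        return METHODS[name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown method {name!r}; expected one of {sorted(METHODS)}"
        ) from None


def run_marginal_model(method, design: MarginalDesign,
                       hyper: Hyperparameters = None, *,
                       iterations: int = 10_000, burn_in: int = 5_000,
                       seed: Optional[int] = None,
                       init_coef: float = 1.0) -> PosteriorDraws:
    """Fit one gene's marginal model with the requested sampler."""
    if isinstance(method, str):
        method = get_method(method)
    return run_chain(design, hyper, iterations=iterations, burn_in=burn_in,
                     seed=seed, init_coef=init_coef, robust=method.robust,
                     sparse=method.sparse, sigma_prior=method.sigma_prior)


def run_marginal_batch(method, y, E, C, X, hyper: Hyperparameters = None, *,
                       iterations: int = 10_000, burn_in: int = 5_000,
                       seed: Optional[int] = None,
                       dtype=np.float32) -> BatchDraws:
    """Fit all p marginal models (columns of X) in one vectorized chain.

    Statistically identical to looping :func:`run_marginal_model` over genes
    (the marginal models share no parameters); one chain's draws per gene.
    """
    if isinstance(method, str):
        method = get_method(method)
    return run_chain_batch(y, E, C, X, hyper, iterations=iterations,
                           burn_in=burn_in, seed=seed, robust=method.robust,
                           sparse=method.sparse,
                           sigma_prior=method.sigma_prior, dtype=dtype)
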