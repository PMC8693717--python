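"""MCMC convergence assessment via the potential scale reduction factor.

Implements the Gelman–Rubin statistic with the Brooks–Gelman
degrees-of-freedom correction and its upper 97.5% limit, computed per
parameter from two or more equal-length chains.  The study decision rule is
PSRF <= 1.1.  Identical chains (zero between-chain variance) are reported as
the limit value 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["PSRF_THRESHOLD", "PsrfReport", "psrf", "psrf_report",
           "psrf_trajectory", "run_parallel_chains"]

PSRF_THRESHOLD = 1.1


@dataclass
class PsrfReport:
    psrf: Dict[str, float]
    upper: Dict[str, float]
    converged: Dict[str, bool]
    iteration: Optional[int] = None

    @property
    def all_converged(self) -> bool:
        return all(self.converged.values())


def _psrf_single(chains: np.ndarray):
    """(m, L) draws of one parameter -> (psrf, upper 97.5% limit)."""
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two chains of equal length")
    m, L = x.shape
    if L < 2:
        raise ValueError("chains must have length >= 2")
    xbar = x.mean(axis=1)
    s2 = x.var(axis=1, ddof=1)
    W = s2.mean()
    B = L * xbar.var(ddof=1)
    if W == 0.0:
        # zero within-chain variance: defined limit (constant chains)
        return (1.0, 1.0) if B == 0.0 else (np.inf, np.inf)
    sig2 = (L - 1) / L * W + B / L
    Vhat = sig2 + B / (m * L)

    var_w = s2.var(ddof=1) / m
    var_b = 2.0 * B * B / (m - 1)
    cov_s2_xbar2 = np.cov(s2, xbar ** 2, ddof=1)[0, 1]
    cov_s2_xbar = np.cov(s2, xbar, ddof=1)[0, 1]
    cov_wb = (L / m) * (cov_s2_xbar2 - 2.0 * xbar.mean() * cov_s2_xbar)
    var_V = (((L - 1) ** 2 * var_w + (1 + 1 / m) ** 2 * var_b
              + 2.0 * (L - 1) * (1 + 1 / m) * cov_wb) / L ** 2)
    rhat2 = Vhat / W
    if var_V <= 0:
        return float(np.sqrt(rhat2)), float(np.sqrt(rhat2))
    df = 2.0 * Vhat ** 2 / var_V
    rhat2_corr = (df + 3.0) / (df + 1.0) * rhat2
    df_w = 2.0 * W ** 2 / var_w if var_w > 0 else np.inf
    fq = stats.f.ppf(0.975, m - 1, df_w) if np.isfinite(df_w) else \
        stats.chi2.ppf(0.975, m - 1) / (m - 1)
    upper2 = (df + 3.0) / (df + 1.0) * ((L - 1.0) / L
                                        + (1.0 + 1.0 / m) / L * (B / W) * fq)
    return float(np.sqrt(rhat2_corr)), float(np.sqrt(upper2))


def psrf(chains, iteration: Optional[int] = None) -> PsrfReport:
    """PSRF per parameter.

    ``chains`` is a dict mapping parameter name to an (m, L) array, or a
    single (m, L) array (reported under the name "param").
    """
    if not isinstance(chains, dict):
        chains = {"param": np.asarray(chains)}
    vals, uppers, conv = {}, {}, {}
    for name, arr in chains.items():
        r, u = _psrf_single(arr)
        vals[name] = r
        uppers[name] = u
        conv[name] = bool(r <= PSRF_THRESHOLD)
    return PsrfReport(vals, uppers, conv, iteration)


def _coef_chain_dict(draws_list: Sequence) -> Dict[str, np.ndarray]:
    """Stack the target parameters (beta, eta_k, tau) of several chains."""
    q = draws_list[0].eta.shape[1]
    out = {"beta": np.stack([np.asarray(d.beta) for d in draws_list])}
    for k in range(q):
        out[f"eta{k + 1}"] = np.stack(
            [np.asarray(d.eta)[:, k] for d in draws_list])
    out["tau"] = np.stack([np.asarray(d.tau) for d in draws_list])
    return out


def psrf_report(draws_list: Sequence) -> PsrfReport:
    """Convergence report over the inferential targets of several
    :class:`~robustgxe.gibbs_core.PosteriorDraws` chains (main and
    interaction coefficients plus tau; the n latent scales are excluded)."""
    if len(draws_list) < 2:
        raise ValueError("need at least two chains")
    return psrf(_coef_chain_dict(draws_list))


def psrf_trajectory(draws_list: Sequence, n_points: int = 20):
    """PSRF against the number of retained sweeps, for trajectory plots.

    Returns a DataFrame with columns (iteration, parameter, psrf, upper).
    """
    import pandas as pd

    chains = _coef_chain_dict(draws_list)
    H = next(iter(chains.values())).shape[1]
    grid = np.unique(np.linspace(max(10, H // n_points), H,
                                 n_points).astype(int))
    rows = []
    for t in grid:
        rep = psrf({k: v[:, :t] for k, v in chains.items()}, iteration=int(t))
        for name in rep.psrf:
            rows.append({"iteration": int(t), "parameter": name,
                         "psrf": rep.psrf[name], "upper": rep.upper[name]})
    return pd.DataFrame(rows)


def run_parallel_chains(design, hyper=None, *, method="LADBLSS",
                        n_chains: int = 3, iterations: int = 10_000,
                        burn_in: int = 5_000, seed: Optional[int] = None):
    """Fit one marginal model with ``n_chains`` overdispersed chains
    (regression initials 1, 0, -1, then cycling) for convergence checks."""
    from .method_variants import run_marginal_model

    inits = [1.0, 0.0, -1.0]
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                   ss.spawn(n_chains)]
    return [run_marginal_model(method, design, hyper, iterations=iterations,
                               burn_in=burn_in, seed=child_seeds[c],
                               init_coef=inits[c % len(inits)])
            for c in range(n_chains)]
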