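"""Simulation designs for the marginal G×E study.

A dataset has n subjects, q environmental exposures, m clinical covariates
and p genetic measurements.  The response follows the linear G×E model

    y = E alpha + C gamma + sum_j x_j beta_j + sum_{j,k} (x_j * E_k) eta_jk + eps,

with a fixed number of nonzero genetic main effects (default 8) and G×E
interactions (default 12).  Three genetic designs are supported:

* setting 1 — continuous expression, AR(1) column correlation rho^|j-k|;
* setting 2 — SNP codes 0/1/2 from quartile-dichotomized setting-1 values;
* setting 3 — SNP codes under pairwise linkage disequilibrium, built from
  haplotype frequencies under Hardy–Weinberg equilibrium.

Five error laws cover light and heavy tails: N(0,1), t(2), LogNormal(0,2)
(log-scale variance 2, not centered), and 90/10 and 80/20 normal–Cauchy
mixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .gibbs_core import MarginalDesign

__all__ = [
    "ERROR_MODELS",
    "SimConfig",
    "SimulatedDataset",
    "gen_env_clinical",
    "gen_gene_continuous",
    "dichotomize_to_snp",
    "gen_snp_ld",
    "assign_effects",
    "gen_errors",
    "assemble_dataset",
]

ERROR_MODELS = ("normal", "t2", "lognormal", "cauchy10", "cauchy20")


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset (defaults are the standard
    design: n=200, p=500, q=4, m=3, AR(1) rho=0.5, 8 true main effects,
    12 true interactions, coefficients Unif[0.1, 0.5])."""

    n: int = 200
    p: int = 500
    q: int = 4
    m: int = 3
    rho: float = 0.5
    n_true_main: int = 8
    n_true_int: int = 12
    coef_low: float = 0.1
    coef_high: float = 0.5
    error_model: str = "normal"
    setting: int = 1
    maf: float = 0.3
    ld_r: float = 0.6
    truth_placement: str = "block"  # "block" (leading genes) or "random"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not 0 < self.maf < 0.5:
            raise ValueError("maf must lie in (0, 0.5)")
        if self.error_model not in ERROR_MODELS:
            raise ValueError(f"unknown error model {self.error_model!r}")
        if self.setting not in (1, 2, 3):
            raise ValueError("setting must be 1, 2 or 3")
        if self.n_true_main > self.p:
            raise ValueError("more true main effects than genes")
        if self.n_true_int > self.p * self.q:
            raise ValueError("more true interactions than (gene, env) slots")
        if self.truth_placement not in ("block", "random"):
            raise ValueError("truth_placement must be 'block' or 'random'")


@dataclass
class SimulatedDataset:
    """Simulated study data plus ground truth."""

    y: np.ndarray
    E: np.ndarray
    C: np.ndarray
    X: np.ndarray
    alpha: np.ndarray
    gamma: np.ndarray
    beta_values: np.ndarray   # (p,), zero off the true support
    eta_values: np.ndarray    # (p, q)
    errors: np.ndarray
    error_model: str
    setting: int
    seed: Optional[int]

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.E.shape[1]

    @property
    def truth_main(self) -> np.ndarray:
        """(p,) bool mask of true genetic main effects."""
        return self.beta_values != 0

    @property
    def truth_interaction(self) -> np.ndarray:
        """(p, q) bool mask of true G×E interactions."""
        return self.eta_values != 0

    def design_for_gene(self, j: int) -> MarginalDesign:
        return MarginalDesign(self.y, self.E, self.C, self.X[:, j])

    def signal(self) -> np.ndarray:
        """The noiseless part of the response (bookkeeping identity:
        ``signal() + errors == y`` exactly)."""
        return (self.E @ self.alpha + self.C @ self.gamma
                + self.X @ self.beta_values
                + np.einsum("np,nk,pk->n", self.X, self.E, self.eta_values))

    def save_bundle(self, directory) -> None:
        """Write y/E/C/X as headered CSVs plus truth.json."""
        import pandas as pd

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"y": self.y}).to_csv(d / "y.csv", index=False)
        pd.DataFrame(self.E, columns=[f"E{k+1}" for k in range(self.q)]
                     ).to_csv(d / "E.csv", index=False)
        pd.DataFrame(self.C, columns=[f"C{t+1}" for t in range(self.C.shape[1])]
                     ).to_csv(d / "C.csv", index=False)
        pd.DataFrame(self.X, columns=[f"X{j+1}" for j in range(self.p)]
                     ).to_csv(d / "X.csv", index=False)
        truth = {
            "alpha": self.alpha.tolist(),
            "gamma": self.gamma.tolist(),
            "beta_values": self.beta_values.tolist(),
            "eta_values": self.eta_values.tolist(),
            "errors": self.errors.tolist(),
            "error_model": self.error_model,
            "setting": self.setting,
            "seed": self.seed,
        }
        (d / "truth.json").write_text(json.dumps(truth))

    @classmethod
    def load_bundle(cls, directory) -> "SimulatedDataset":
        import pandas as pd

        d = Path(directory)
        truth = json.loads((d / "truth.json").read_text())
        return cls(
            y=pd.read_csv(d / "y.csv")["y"].to_numpy(),
            E=pd.read_csv(d / "E.csv").to_numpy(),
            C=pd.read_csv(d / "C.csv").to_numpy(),
            X=pd.read_csv(d / "X.csv").to_numpy(),
            alpha=np.asarray(truth["alpha"]),
            gamma=np.asarray(truth["gamma"]),
            beta_values=np.asarray(truth["beta_values"]),
            eta_values=np.asarray(truth["eta_values"]),
            errors=np.asarray(truth["errors"]),
            error_model=truth["error_model"],
            setting=truth["setting"],
            seed=truth["seed"],
        )


def _ar1_normal(n: int, d: int, rho: float, rng) -> np.ndarray:
    """n iid rows from N(0, Sigma), Sigma_jk = rho^|j-k| (sequential
    construction: x_j = rho x_{j-1} + sqrt(1-rho^2) innovation; exact)."""
    Z = rng.standard_normal((n, d))
    X = np.empty((n, d))
    X[:, 0] = Z[:, 0]
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, d):
        X[:, j] = rho * X[:, j - 1] + scale * Z[:, j]
    return X


def gen_env_clinical(n, q, m, rho, rng):
    """Environmental (n×q) and clinical (n×m) covariates: multivariate normal,
    marginal mean 0 and variance 1, AR(1) correlation rho within each block."""
    E = _ar1_normal(n, q, rho, rng)
    C = _ar1_normal(n, m, rho, rng) if m > 0 else np.empty((n, 0))
    return E, C


def gen_gene_continuous(n, p, rho, rng) -> np.ndarray:
    """Continuous expression matrix: AR(1) column correlation rho^|j-k|,
    standard normal marginals."""
    return _ar1_normal(n, p, rho, rng)


def dichotomize_to_snp(X_continuous: np.ndarray) -> np.ndarray:
    """Trichotomize expression at each column's 1st/3rd quartiles into SNP
    codes: value < Q1 -> 0, Q1 <= value < Q3 -> 1, value >= Q3 -> 2."""
    X = np.asarray(X_continuous, dtype=float)
    q1 = np.quantile(X, 0.25, axis=0)
    q3 = np.quantile(X, 0.75, axis=0)
    if np.any(q1 == q3):
        raise ValueError("degenerate quartiles: constant column(s)")
    return (X >= q1).astype(float) + (X >= q3)


def haplotype_frequencies(q1: float, q2: float, r: float):
    """Two-locus haplotype frequencies at LD level delta =
    r sqrt(q1(1-q1)q2(1-q2)): (p_AB, p_Ab, p_aB, p_ab)."""
    delta = r * np.sqrt(q1 * (1 - q1) * q2 * (1 - q2))
    p_ab_tbl = (q1 * q2 + delta,
                q1 * (1 - q2) - delta,
                (1 - q1) * q2 - delta,
                (1 - q1) * (1 - q2) + delta)
    if any(f < 0 or f > 1 for f in p_ab_tbl):
        raise ValueError("delta too large: invalid haplotype frequency")
    return p_ab_tbl


def gen_snp_ld(n, p, maf, ld_r, rng) -> np.ndarray:
    """SNP genotypes (minor-allele counts 0/1/2) with pairwise LD between
    adjacent loci.

    Locus 1 genotypes follow Hardy–Weinberg frequencies (q^2, 2q(1-q),
    (1-q)^2).  Each subject carries two haplotypes; the minor allele at locus
    t+1 is drawn per haplotype from its conditional frequency given the
    allele at locus t (P(B|A) = p_AB/q, P(B|a) = p_aB/(1-q)), i.e. the
    conditional genotype probability matrix under random haplotype pairing.
    The induced adjacent-genotype correlation is ld_r.
    """
    p_AB, _, p_aB, _ = haplotype_frequencies(maf, maf, ld_r)
    pB_given_A = p_AB / maf
    pB_given_a = p_aB / (1 - maf)
    hap = rng.random((n, 2)) < maf  # minor-allele indicators at locus 1
    X = np.empty((n, p))
    X[:, 0] = hap.sum(axis=1)
    for t in range(1, p):
        cond = np.where(hap, pB_given_A, pB_given_a)
        hap = rng.random((n, 2)) < cond
        X[:, t] = hap.sum(axis=1)
    return X


def assign_effects(config: SimConfig, rng):
    """Draw coefficients and place the true support.

    All environmental/clinical coefficients are nonzero,
    Unif[coef_low, coef_high]; genetic main and interaction magnitudes use
    the same law.  Interactions are placed on the main-effect genes first
    (weak-hierarchy-friendly, one random environmental slot per gene), any
    surplus on further genes.  Under the default "block" placement the true
    genes are the leading ones (the bookkeeping convention of this
    simulation literature); "random" scatters them over all p positions.
    """
    lo, hi = config.coef_low, config.coef_high
    alpha = rng.uniform(lo, hi, config.q)
    gamma = rng.uniform(lo, hi, config.m)

    if config.truth_placement == "block":
        main_genes = np.arange(config.n_true_main)
    else:
        main_genes = np.sort(rng.choice(config.p, config.n_true_main,
                                        replace=False))
    beta_values = np.zeros(config.p)
    beta_values[main_genes] = rng.uniform(lo, hi, config.n_true_main)

    eta_values = np.zeros((config.p, config.q))
    n_on_main = min(config.n_true_int, config.n_true_main)
    for g in main_genes[:n_on_main]:
        eta_values[g, rng.integers(config.q)] = rng.uniform(lo, hi)
    n_extra = config.n_true_int - n_on_main
    if n_extra > 0:
        others = np.setdiff1d(np.arange(config.p), main_genes)
        if config.truth_placement == "block":
            extra_genes = others[:n_extra]
        else:
            extra_genes = rng.choice(others, n_extra, replace=False)
        for g in extra_genes:
            eta_values[g, rng.integers(config.q)] = rng.uniform(lo, hi)
    return alpha, gamma, beta_values, eta_values


def gen_errors(n, error_model, rng) -> np.ndarray:
    """i.i.d. draws from one of the five error laws."""
    if error_model == "normal":
        return rng.standard_normal(n)
    if error_model == "t2":
        return rng.standard_t(2, n)
    if error_model == "lognormal":
        return rng.lognormal(0.0, np.sqrt(2.0), n)
    if error_model in ("cauchy10", "cauchy20"):
        frac = 0.1 if error_model == "cauchy10" else 0.2
        normal = rng.standard_normal(n)
        cauchy = rng.standard_cauchy(n)
        is_cauchy = rng.random(n) < frac
        return np.where(is_cauchy, cauchy, normal)
    raise ValueError(f"unknown error model {error_model!r}")


def assemble_dataset(config: SimConfig, rng=None) -> SimulatedDataset:
    """Generate a full study dataset under ``config``."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    E, C = gen_env_clinical(config.n, config.q, config.m, config.rho, rng)
    if config.setting == 1:
        X = gen_gene_continuous(config.n, config.p, config.rho, rng)
    elif config.setting == 2:
        X = dichotomize_to_snp(
            gen_gene_continuous(config.n, config.p, config.rho, rng))
    else:
        X = gen_snp_ld(config.n, config.p, config.maf, config.ld_r, rng)
    alpha, gamma, beta_values, eta_values = assign_effects(config, rng)
    errors = gen_errors(config.n, config.error_model, rng)
    y = (E @ alpha + C @ gamma + X @ beta_values
         + np.einsum("np,nk,pk->n", X, E, eta_values) + errors)
    return SimulatedDataset(y=y, E=E, C=C, X=X, alpha=alpha, gamma=gamma,
                            beta_values=beta_values, eta_values=eta_values,
                            errors=errors, error_model=config.error_model,
                            setting=config.setting, seed=config.seed)
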