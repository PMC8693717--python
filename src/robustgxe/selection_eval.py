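"""Selection scores and evaluation metrics for marginal G×E fits.

Spike-and-slab methods score each candidate effect by its posterior inclusion
probability (PIP), the fraction of stored sweeps in which the effect's
indicator is 1.  Plain-LASSO methods have no indicators; an effect is instead
"identified" at credible level c when its equal-tailed c-interval excludes 0,
and its ranking score is the average of that indicator over a grid of levels.

With simulation ground truth, sweeping the cutoff (PIP threshold for spike
methods, credible level for the others) yields TPR/FPR curves and a
trapezoidal AUC; Top-k counts the true signals among the k highest-scoring
candidates of a kind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_CUTOFF_GRID",
    "DEFAULT_LEVEL_GRID",
    "RocResult",
    "inclusion_probability",
    "ci_indicator",
    "ci_indicator_matrix",
    "average_identification",
    "roc_auc",
    "roc_from_indicators",
    "top_k",
    "posterior_estimates",
]

# Cutoff grid for inclusion-probability sweeps; credible-level grid for
# interval-based selection.  Fixed dense grids make the AUC reproducible.
DEFAULT_CUTOFF_GRID = np.linspace(0.0, 1.0, 101)
DEFAULT_LEVEL_GRID = np.arange(0.01, 1.00, 0.01)


@dataclass
class RocResult:
    cutoffs: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _effect_draws(draws, effect) -> np.ndarray:
    """Pull the (H,) draw vector for ``effect``: "main" or ("interaction", k)."""
    if effect == "main":
        return np.asarray(draws.beta)
    if isinstance(effect, tuple) and effect[0] == "interaction":
        return np.asarray(draws.eta)[:, effect[1]]
    raise ValueError(f"unknown effect identifier {effect!r}")


def inclusion_probability(draws, effect="main") -> float:
    """Mean of the 0/1 inclusion indicators across stored sweeps."""
    if not getattr(draws, "sparse", True):
        raise ValueError("inclusion probabilities require a spike-and-slab fit")
    x = _effect_draws(draws, effect)
    return float((x != 0).mean())


def ci_indicator(draws, effect="main", level: float = 0.95) -> int:
    """1 iff the equal-tailed credible interval at ``level`` excludes 0."""
    if not 0 < level < 1:
        raise ValueError("credible level must lie in (0, 1)")
    x = _effect_draws(draws, effect)
    lo, hi = np.quantile(x, [(1 - level) / 2, (1 + level) / 2])
    return int(lo > 0 or hi < 0)


def ci_indicator_matrix(coef_draws: np.ndarray,
                        levels: np.ndarray = DEFAULT_LEVEL_GRID) -> np.ndarray:
    """Interval-exclusion indicators for many effects at many levels.

    ``coef_draws``: (H, n_effects).  Returns a 0/1 array (n_levels, n_effects).
    """
    levels = np.asarray(levels, dtype=float)
    qs = np.concatenate([(1 - levels) / 2, (1 + levels) / 2])
    quants = np.quantile(np.asarray(coef_draws, dtype=float), qs, axis=0)
    L = levels.size
    lo, hi = quants[:L], quants[L:]
    return ((lo > 0) | (hi < 0)).astype(int)


def average_identification(coef_draws: np.ndarray,
                           levels: np.ndarray = DEFAULT_LEVEL_GRID) -> np.ndarray:
    """Ranking score for plain-LASSO methods: per effect, the mean of the
    interval-exclusion indicator over the credible-level grid."""
    return ci_indicator_matrix(coef_draws, levels).mean(axis=0)


def _rates(selected: np.ndarray, truth: np.ndarray):
    tp = np.sum(selected & truth)
    fp = np.sum(selected & ~truth)
    return tp / truth.sum(), fp / (~truth).sum()


def roc_auc(scores, truth_mask, cutoffs: np.ndarray = None) -> RocResult:
    """TPR/FPR sweep and trapezoidal AUC.

    ``scores`` is either a 1-D score vector (selection: score > cutoff,
    strict, so nothing is selected at cutoff 1.0) or a 2-D 0/1 indicator
    matrix (n_cutoffs, n_effects) whose rows are precomputed selections (the
    credible-level route).  The curve is anchored at (0,0) and (1,1).
    """
    truth = np.asarray(truth_mask, dtype=bool).ravel()
    if truth.all() or not truth.any():
        raise ValueError("truth mask must contain both true and null effects")
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        if cutoffs is None:
            cutoffs = DEFAULT_CUTOFF_GRID
        sel = scores[None, :] > np.asarray(cutoffs, dtype=float)[:, None]
    elif scores.ndim == 2:
        sel = scores.astype(bool)
        if cutoffs is None:
            cutoffs = np.arange(sel.shape[0], dtype=float)
    else:
        raise ValueError("scores must be 1-D scores or a 2-D indicator matrix")
    if sel.shape[1] != truth.size:
        raise ValueError("scores and truth mask disagree on effect count")

    tpr = np.empty(sel.shape[0])
    fpr = np.empty(sel.shape[0])
    for i, row in enumerate(sel):
        tpr[i], fpr[i] = _rates(row, truth)
    fx = np.concatenate([[0.0], fpr, [1.0]])
    fy = np.concatenate([[0.0], tpr, [1.0]])
    order = np.lexsort((fy, fx))
    auc = float(np.trapezoid(fy[order], fx[order]))
    return RocResult(np.asarray(cutoffs, dtype=float), tpr, fpr, auc)


def roc_from_indicators(indicator_matrix: np.ndarray, truth_mask,
                        levels: np.ndarray = DEFAULT_LEVEL_GRID) -> RocResult:
    """ROC/AUC from a (n_levels, n_effects) credible-interval indicator
    matrix (selection at level c = interval excludes 0)."""
    return roc_auc(np.asarray(indicator_matrix), truth_mask,
                   cutoffs=np.asarray(levels, dtype=float))


def top_k(scores, k: int, truth_mask, estimates=None) -> int:
    """Number of true signals among the k highest-scoring candidates.

    Ties in score are broken by larger |posterior estimate| (when supplied),
    then by candidate index; the ordering is deterministic.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth_mask, dtype=bool).ravel()
    if k > scores.size:
        raise ValueError(f"k={k} exceeds the candidate pool ({scores.size})")
    if estimates is None:
        estimates = np.zeros_like(scores)
    est = np.abs(np.asarray(estimates, dtype=float).ravel())
    idx = np.arange(scores.size)
    # lexsort: last key is primary
    order = np.lexsort((idx, -est, -scores))
    return int(truth[order[:k]].sum())


def posterior_estimates(draws) -> dict:
    """Elementwise posterior medians of every coefficient block."""
    if draws.beta.shape[0] == 0:
        raise ValueError("no stored draws")
    out = {
        "beta": float(np.median(draws.beta)) if draws.beta.ndim == 1
        else np.median(draws.beta, axis=0),
        "eta": np.median(draws.eta, axis=0),
    }
    for name in ("alpha", "gamma"):
        arr = getattr(draws, name, None)
        if arr is not None and not isinstance(arr, dict):
            out[name] = np.median(arr, axis=0)
    return out
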