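"""Approximately unbiased (AU) tree test via multiscale RELL bootstrap.

Per-site log-likelihoods are resampled (with replacement) at several
replicate sizes r*n ("scales").  For each tree the bootstrap proportion of
replicates it wins is probit-transformed and regressed on (sqrt(r),
1/sqrt(r)) by weighted least squares, giving a signed distance d and a
curvature c; the AU p-value is 1 - Phi(d - c).  Trees with p >= alpha form
the "plausible" set; the maximum-likelihood tree is always kept plausible
so the set is never empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .likelihood import SiteLnLMatrix

__all__ = [
    "AUResult",
    "DEFAULT_SCALES",
    "rell_bootstrap_proportions",
    "au_pvalue",
    "plausible_set",
]

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))
DEFAULT_B = 10_000


@dataclass
class AUResult:
    tree_id: str
    bp: np.ndarray  # bootstrap proportion per scale
    d: float  # fitted signed distance
    c: float  # fitted curvature
    p_au: float
    plausible: bool
    fit_residual: float = 0.0


def rell_bootstrap_proportions(
    m: SiteLnLMatrix,
    scales=DEFAULT_SCALES,
    B: int = DEFAULT_B,
    seed=None,
) -> np.ndarray:
    """Winning proportions per tree (rows) and scale (columns).

    For each scale r, B replicates of round(r*n) site draws with
    replacement; a tree scores a replicate win when its resampled total lnL
    is maximal (exact ties share the credit equally).  Columns sum to 1.
    """
    if m.n_trees < 2:
        raise ValueError("the AU test needs at least 2 trees")
    rng = np.random.default_rng(seed)
    n = m.n_sites
    L = m.matrix  # (T, n)
    out = np.empty((m.n_trees, len(scales)))
    row_offset = np.arange(B, dtype=np.int64)[:, None] * n
    for si, r in enumerate(scales):
        n_rep = int(round(r * n))
        if n_rep < 1:
            raise ValueError(f"scale {r} gives an empty replicate at n={n}")
        idx = rng.integers(0, n, size=(B, n_rep))
        # per-replicate site multiplicities, then one matmul for the totals
        W = np.bincount((idx + row_offset).ravel(), minlength=B * n)
        W = W.reshape(B, n).astype(np.float64)
        totals = W @ L.T  # (B, T)
        best = totals.max(axis=1, keepdims=True)
        winners = totals >= best - 1e-10
        credit = winners / winners.sum(axis=1, keepdims=True)
        out[:, si] = credit.mean(axis=0)
    return out


def au_pvalue(bp: np.ndarray, scales=DEFAULT_SCALES, B: int = DEFAULT_B):
    """Fit the multiscale-bootstrap signed distance and curvature for one tree.

    Returns (d, c, p_au, weighted residual sum of squares).  Proportions
    are clamped to [1/(B+1), B/(B+1)] before the probit transform; weights
    come from the binomial variance through the delta method.
    """
    bp = np.asarray(bp, float)
    r = np.asarray(scales, float)
    if len(np.unique(r)) < 2:
        raise ValueError("need at least 2 distinct scales")
    lo, hi = 1.0 / (B + 1), B / (B + 1.0)
    # a tree that wins (or loses) essentially every replicate at every scale
    # carries no scale signal for the regression; resolve it directly
    if np.all(bp >= hi):
        return -37.0, 0.0, 1.0, 0.0
    if np.all(bp <= lo):
        return 37.0, 0.0, 0.0, 0.0
    bp = np.clip(bp, lo, hi)
    z = norm.ppf(1.0 - bp)
    # var(z) ~ bp(1-bp) / (B * phi(z)^2)  =>  weight = inverse variance
    w = B * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    WX = X * w[:, None]
    beta = np.linalg.solve(X.T @ WX, WX.T @ z)
    d, c = float(beta[0]), float(beta[1])
    resid = z - X @ beta
    rss = float(resid @ (w * resid))
    p_au = float(1.0 - norm.cdf(d - c))
    return d, c, p_au, rss


def plausible_set(
    m: SiteLnLMatrix,
    alpha: float = 0.05,
    scales=DEFAULT_SCALES,
    B: int = DEFAULT_B,
    seed=None,
) -> list[AUResult]:
    """AU test over all trees jointly; flags trees with p_au >= alpha.

    The highest-total-lnL tree is always flagged plausible, so the
    plausible count is at least 1.
    """
    bp = rell_bootstrap_proportions(m, scales=scales, B=B, seed=seed)
    best_tree = int(np.argmax(m.totals()))
    results: list[AUResult] = []
    for i, tid in enumerate(m.tree_ids):
        d, c, p, rss = au_pvalue(bp[i], scales=scales, B=B)
        flag = bool(p >= alpha) or i == best_tree
        results.append(AUResult(tid, bp[i], d, c, p, flag, rss))
    return results
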