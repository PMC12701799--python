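"""Substitution and indel models.

The substitution model is GTR+Γ(+I) on nucleotides: a general
time-reversible rate matrix built from stationary frequencies π and six
exchangeabilities, with among-site rate heterogeneity discretized into k
equal-probability Gamma categories (category rate = within-bin mean) and an
optional proportion of invariant sites.  The rate matrix is normalized so
branch lengths are in expected substitutions per site.

Indel lengths follow a truncated Zipf (power-law) distribution; insertion
and deletion event rates are per site per unit branch length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = [
    "GTRGammaModel",
    "IndelModel",
    "NUCLEOTIDES",
    "discrete_gamma_rates",
    "gtr_rate_matrix",
    "transition_matrix",
    "stationary_distribution",
]

NUCLEOTIDES = "ACGT"
# order of the six exchangeabilities
EXCH_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))  # AC AG AT CG CT GT


@dataclass(frozen=True)
class GTRGammaModel:
    """GTR+Γ(+I) model parameters.

    pi: stationary frequencies (A, C, G, T), positive, summing to 1.
    exch: exchangeabilities (AC, AG, AT, CG, CT, GT), positive.
    alpha: Gamma shape for among-site rate variation.
    k: number of discrete rate categories.
    p_inv: proportion of invariant sites.
    """

    pi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    exch: tuple[float, float, float, float, float, float] = (1.0,) * 6
    alpha: float = 1.0
    k: int = 4
    p_inv: float = 0.0

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, float)
        if pi.shape != (4,) or np.any(pi <= 0):
            raise ValueError("pi must be 4 positive frequencies")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError(f"pi must sum to 1 (got {pi.sum():.12f})")
        exch = np.asarray(self.exch, float)
        if exch.shape != (6,) or np.any(exch <= 0):
            raise ValueError("exch must be 6 positive exchangeabilities")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.p_inv < 1.0:
            raise ValueError("p_inv must be in [0, 1)")

    @classmethod
    def jc(cls, alpha: float = 1.0, k: int = 1, p_inv: float = 0.0) -> "GTRGammaModel":
        """Jukes-Cantor: equal frequencies, equal exchangeabilities."""
        return cls(alpha=alpha, k=k, p_inv=p_inv)

    def pi_array(self) -> np.ndarray:
        return np.asarray(self.pi, float)

    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.alpha, self.k)


@dataclass(frozen=True)
class IndelModel:
    """Zipf-length insertion/deletion process.

    ins_rate / del_rate: events per site per unit branch length.
    zipf_s: power-law exponent of the length distribution.
    max_len: truncation of the length distribution.
    """

    ins_rate: float = 0.0
    del_rate: float = 0.0
    zipf_s: float = 1.5
    max_len: int = 10

    def __post_init__(self) -> None:
        if self.ins_rate < 0 or self.del_rate < 0:
            raise ValueError("indel rates must be >= 0")
        if self.zipf_s <= 0:
            raise ValueError("zipf_s must be > 0")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")

    def length_pmf(self) -> np.ndarray:
        """P(L = l) for l = 1..max_len, normalized truncated Zipf."""
        lengths = np.arange(1, self.max_len + 1, dtype=float)
        w = lengths ** (-self.zipf_s)
        return w / w.sum()

    def mean_length(self) -> float:
        pmf = self.length_pmf()
        return float(np.sum(pmf * np.arange(1, self.max_len + 1)))


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean-of-bin discretization of the mean-1 Gamma(alpha) rate distribution.

    The rate axis is split into k equal-probability bins; each category's
    rate is the conditional mean of the Gamma(alpha, scale=1/alpha) density
    within its bin, so the category rates average exactly 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(k + 1) / k, a=alpha, scale=1.0 / alpha)
    # E[X; a < X < b] = (alpha*scale) * [F_{alpha+1}(b) - F_{alpha+1}(a)], and
    # alpha*scale = 1 here; conditional mean over a 1/k-probability bin is k times that.
    cdf_up = gamma_dist.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    rates = k * np.diff(cdf_up)
    rates[-1] = k * (1.0 - cdf_up[-2])  # guard against ppf(1)=inf round-off
    return rates


def gtr_rate_matrix(model: GTRGammaModel) -> np.ndarray:
    """Normalized GTR rate matrix Q with q_ij = s_ij * pi_j (i != j).

    Scaled so the expected substitution rate at stationarity,
    -sum_i pi_i q_ii, equals 1.
    """
    pi = model.pi_array()
    Q = np.zeros((4, 4))
    for s, (i, j) in zip(model.exch, EXCH_PAIRS):
        Q[i, j] = s * pi[j]
        Q[j, i] = s * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    return Q / mu


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary frequencies of a reversible rate matrix (left null vector)."""
    w, v = np.linalg.eig(Q.T)
    idx = int(np.argmin(np.abs(w)))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


class EigenQ:
    """Cached symmetrized eigendecomposition of a reversible Q.

    With B = D^{1/2} Q D^{-1/2} symmetric (D = diag(pi)), we have
    P(t) = D^{-1/2} V exp(L t) V^T D^{1/2} for B = V L V^T.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        self.Q = Q
        sqrt_pi = np.sqrt(pi)
        B = sqrt_pi[:, None] * Q / sqrt_pi[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2)
        self.lam = lam
        self.left = V / sqrt_pi[:, None]  # D^{-1/2} V
        self.right = (V * sqrt_pi[:, None]).T  # V^T D^{1/2}

    def p_matrix(self, t: float) -> np.ndarray:
        P = (self.left * np.exp(self.lam * t)) @ self.right
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def p_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Batch of transition matrices, one per entry of `ts` (shape (k,4,4)).

        Round-off negatives are clamped to 0; rows are not renormalized (the
        deficit is ~1e-16 and irrelevant inside likelihood sums).
        """
        E = np.exp(np.outer(np.asarray(ts, float), self.lam))  # (k, 4)
        P = np.einsum("il,kl,lj->kij", self.left, E, self.right, optimize=True)
        return np.maximum(P, 0.0, out=P)


def transition_matrix(
    Q: np.ndarray, t: float, rate: float = 1.0, pi: np.ndarray | None = None
) -> np.ndarray:
    """Transition probabilities P = exp(Q * t * rate).

    Uses the symmetrized eigendecomposition; `pi` is recovered from Q when
    not supplied.  Rows sum to 1; t = 0 gives the identity.
    """
    if t < 0 or rate < 0:
        raise ValueError("branch length and rate must be >= 0")
    if pi is None:
        pi = stationary_distribution(Q)
    return EigenQ(Q, np.asarray(pi, float)).p_matrix(t * rate)
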