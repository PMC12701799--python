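"""Felsenstein-pruning log-likelihood under GTR+Γ(+I).

Per-site log-likelihoods (natural log) are computed over pattern-compressed
alignments with per-node rescaling to avoid underflow.  Gap and ambiguity
characters contribute a partial likelihood of 1 for every compatible state
(gap = fully missing).  Branch lengths are optimized edge-by-edge with a
bounded Brent search on the exact one-edge likelihood function; model
parameters (alpha, exchangeabilities, frequencies) by coordinate descent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .models import EigenQ, GTRGammaModel, gtr_rate_matrix, NUCLEOTIDES
from .msa import IUPAC_SETS, MSA
from .trees import Tree

__all__ = [
    "SiteLnLMatrix",
    "site_log_likelihoods",
    "tree_log_likelihood",
    "optimize_branch_lengths",
    "evaluate_tree",
]

BL_MIN, BL_MAX = 1e-9, 100.0


def maximize_edge_length(f) -> tuple[float, float]:
    """Maximize a one-branch lnL function over [BL_MIN, BL_MAX].

    Brent search over log branch length (the transform keeps the problem
    unimodal and puts the short-branch basin within reach of the initial
    golden-section probes).

    Returns (argmax, max value).
    """
    res = minimize_scalar(
        lambda u: -f(float(np.exp(u))),
        bounds=(np.log(BL_MIN), np.log(BL_MAX)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    t = float(np.exp(res.x))
    return t, -float(res.fun)


@dataclass
class SiteLnLMatrix:
    """Per-tree x per-site log-likelihoods on one alignment."""

    tree_ids: list[str]
    matrix: np.ndarray  # (n_trees, n_sites)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, float))
        if len(self.tree_ids) != self.matrix.shape[0]:
            raise ValueError("one row of site log-likelihoods per tree id required")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("site log-likelihoods must be finite")

    @property
    def n_trees(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def totals(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("tree\tsite\tlnl\n")
            for tid, row in zip(self.tree_ids, self.matrix):
                for s, v in enumerate(row):
                    fh.write(f"{tid}\t{s}\t{v:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SiteLnLMatrix":
        ids: list[str] = []
        rows: dict[str, dict[int, float]] = {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("tree"):
                raise ValueError("expected a header line 'tree\\tsite\\tlnl'")
            for line in fh:
                tid, site, lnl = line.rstrip("\n").split("\t")
                if tid not in rows:
                    rows[tid] = {}
                    ids.append(tid)
                rows[tid][int(site)] = float(lnl)
        n_sites = max(len(r) for r in rows.values())
        mat = np.array([[rows[t][s] for s in range(n_sites)] for t in ids])
        return cls(ids, mat)


# ---------------------------------------------------------------------------
# Pattern compression and leaf partials
# ---------------------------------------------------------------------------

_STATE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}


def _leaf_row(ch: str) -> np.ndarray:
    try:
        states = IUPAC_SETS[ch.upper()]
    except KeyError:
        raise ValueError(f"unknown alignment character {ch!r}") from None
    row = np.zeros(4)
    for b in states:
        row[_STATE_INDEX[b]] = 1.0
    return row


class _PatternData:
    """Unique alignment columns, their weights, and leaf partials."""

    def __init__(self, msa: MSA, taxa_order: list[str], compress: bool = True):
        data = msa.row_order(taxa_order).data
        cols = np.ascontiguousarray(data.T).view(f"<U{data.shape[0]}").ravel()
        if compress:
            uniq, inverse, counts = np.unique(
                cols, return_inverse=True, return_counts=True
            )
        else:
            uniq = cols
            inverse = np.arange(len(cols))
            counts = np.ones(len(cols))
        self.weights = counts.astype(float)
        self.inverse = inverse
        self.n_patterns = len(uniq)
        self.n_sites = len(cols)
        char_row = {c: _leaf_row(c) for c in set("".join(uniq))}
        # partials[taxon_row] : (n_patterns, 4)
        self.partials = np.empty((len(taxa_order), self.n_patterns, 4))
        for p, col in enumerate(uniq):
            for r, ch in enumerate(col):
                self.partials[r, p] = char_row[ch]

    def invariant_log_component(self, pi: np.ndarray) -> np.ndarray:
        """log sum_x pi_x [pattern compatible with constant state x], per pattern."""
        compat = self.partials.prod(axis=0)  # (n_patterns, 4)
        lik = compat @ pi
        with np.errstate(divide="ignore"):
            return np.log(lik)


class _Engine:
    """Bound state for repeated likelihood evaluations on one (tree, MSA)."""

    def __init__(self, tree: Tree, msa: MSA, model: GTRGammaModel, compress=True):
        if tree.leaf_labels != frozenset(msa.taxa):
            only_t = sorted(tree.leaf_labels - set(msa.taxa))
            only_m = sorted(set(msa.taxa) - tree.leaf_labels)
            raise ValueError(
                f"tree/alignment taxa mismatch: only in tree {only_t}, "
                f"only in alignment {only_m}"
            )
        self.tree = tree
        self.model = model
        label_to_leaf = {lab: nid for nid, lab in tree.labels.items()}
        self.taxa_order = list(msa.taxa)
        self.leaf_row = {label_to_leaf[t]: i for i, t in enumerate(self.taxa_order)}
        self.pat = _PatternData(msa, self.taxa_order, compress=compress)
        self.set_model(model)

    def set_model(self, model: GTRGammaModel) -> None:
        self.model = model
        self.pi = model.pi_array()
        self.eig = EigenQ(gtr_rate_matrix(model), self.pi)
        self.rates = model.category_rates()
        if model.p_inv > 0:
            self.log_inv = self.pat.invariant_log_component(self.pi)
        else:
            self.log_inv = None

    # -- conditional likelihoods ------------------------------------------

    def _leaf_partial(self, nid: int) -> np.ndarray:
        return self.pat.partials[self.leaf_row[nid]]

    def conditional(self, node: int, exclude: int | None):
        """Partials of the subtree at `node` looking away from `exclude`.

        Returns (partial, log_scale): partial is (k, n_patterns, 4),
        log_scale is (n_patterns,) shared across categories' rescale trail.
        """
        k = self.model.k
        npat = self.pat.n_patterns
        order = []
        stack = [(node, exclude)]
        while stack:
            u, par = stack.pop()
            order.append((u, par))
            for v in self.tree.adj[u]:
                if v != par:
                    stack.append((v, u))
        order.reverse()
        partials: dict[int, np.ndarray] = {}
        scales: dict[int, np.ndarray] = {}
        for u, par in order:
            if u in self.tree.labels:
                part = np.broadcast_to(self._leaf_partial(u), (k, npat, 4)).copy()
            else:
                part = np.ones((k, npat, 4))
            sc = np.zeros(npat)
            has_children = False
            for v in self.tree.adj[u]:
                if v == par:
                    continue
                has_children = True
                t = self.tree.adj[u][v]
                child = partials.pop(v)
                sc += scales.pop(v)
                P = self.eig.p_matrices(t * self.rates)  # (k, 4, 4)
                part *= np.matmul(child, P.transpose(0, 2, 1))
            if has_children:
                mx = part.max(axis=(0, 2))
                mx = np.where(mx > 0, mx, 1.0)
                part /= mx[None, :, None]
                sc += np.log(mx)
            partials[u] = part
            scales[u] = sc
        return partials[node], scales[node]

    # -- likelihood evaluations -------------------------------------------

    def _mix_site_lnl(self, log_gamma_site: np.ndarray) -> np.ndarray:
        """Combine Gamma-mixture and invariant components per pattern."""
        m = self.model
        if self.log_inv is None:
            return log_gamma_site
        out = np.logaddexp(
            np.log1p(-m.p_inv) + log_gamma_site,
            np.where(
                np.isneginf(self.log_inv), -np.inf, np.log(m.p_inv) + self.log_inv
            ),
        )
        return out

    def _root(self) -> int:
        for n in self.tree.adj:
            if n not in self.tree.labels:
                return n
        return next(iter(self.tree.adj))

    def pattern_lnl_at_node(self, node: int) -> np.ndarray:
        part, sc = self.conditional(node, None)
        lik = part @ self.pi  # (k, n_patterns); rescaled, so no under/overflow
        log_gamma = np.log(np.maximum(lik.mean(axis=0), 1e-300))
        return self._mix_site_lnl(log_gamma + sc)

    def site_lnl(self) -> np.ndarray:
        per_pattern = self.pattern_lnl_at_node(self._root())
        return per_pattern[self.pat.inverse]

    def total_lnl(self) -> float:
        return float(self.pattern_lnl_at_node(self._root()) @ self.pat.weights)

    def edge_lnl_function(self, u: int, v: int):
        """Return f(t) -> total lnL as a function of one branch length."""
        part_u, sc_u = self.conditional(u, v)
        part_v, sc_v = self.conditional(v, u)
        sc = sc_u + sc_v
        k = self.model.k
        w = self.pat.weights
        pi = self.pi
        left = part_u * pi[None, None, :]  # fold pi into the u side

        eig = self.eig
        rates = self.rates
        mix = self._mix_site_lnl

        def f(t: float) -> float:
            P = eig.p_matrices(t * rates)  # (k, 4, 4)
            lik = (np.matmul(left, P) * part_v).sum(axis=2)  # (k, n_patterns)
            log_gamma = np.log(np.maximum(lik.mean(axis=0), 1e-300))
            return float(mix(log_gamma + sc) @ w)

        return f

    def optimize_branch_lengths(self, tol: float, max_rounds: int) -> float:
        lnl = self.total_lnl()
        for _ in range(max_rounds):
            for a, b, t0 in self.tree.edges():
                f = self.edge_lnl_function(a, b)
                t_new, f_new = maximize_edge_length(f)
                if f_new >= f(t0):  # guard: Brent may stop short of t0's value
                    self.tree.adj[a][b] = t_new
                    self.tree.adj[b][a] = t_new
            new_lnl = self.total_lnl()
            improved = new_lnl - lnl
            lnl = new_lnl
            if improved < tol:
                break
        return lnl


# ---------------------------------------------------------------------------
# Public functions
# ---------------------------------------------------------------------------


def site_log_likelihoods(
    tree: Tree, msa: MSA, model: GTRGammaModel, compress: bool = True
) -> np.ndarray:
    """Per-site natural-log likelihoods; their sum is the tree's total lnL."""
    return _Engine(tree, msa, model, compress=compress).site_lnl()


def tree_log_likelihood(
    tree: Tree, msa: MSA, model: GTRGammaModel, compress: bool = True
) -> float:
    return _Engine(tree, msa, model, compress=compress).total_lnl()


def optimize_branch_lengths(
    tree: Tree,
    msa: MSA,
    model: GTRGammaModel,
    tol: float = 1e-3,
    max_rounds: int = 10,
) -> tuple[Tree, float]:
    """Round-robin Brent optimization of every branch length.

    Returns a new tree; the input is not modified.  The returned lnL never
    falls below the input tree's lnL (each accepted move is an improvement
    on the exact one-edge likelihood).
    """
    eng = _Engine(tree.copy(), msa, model)
    lnl = eng.optimize_branch_lengths(tol, max_rounds)
    return eng.tree, lnl


def _optimize_alpha(eng: _Engine) -> None:
    m = eng.model

    def neg(log_alpha: float) -> float:
        eng.set_model(replace(m, alpha=float(np.exp(log_alpha))))
        return -eng.total_lnl()

    res = minimize_scalar(neg, bounds=(np.log(0.02), np.log(100.0)), method="bounded",
                          options={"xatol": 1e-4})
    best = float(np.exp(res.x))
    eng.set_model(replace(m, alpha=best))


def _optimize_exch(eng: _Engine) -> None:
    m = eng.model
    x0 = np.log(np.asarray(m.exch[:5]) / m.exch[5])

    def neg(x: np.ndarray) -> float:
        exch = tuple(np.exp(x)) + (1.0,)
        eng.set_model(replace(m, exch=exch))
        return -eng.total_lnl()

    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 200})
    eng.set_model(replace(m, exch=tuple(np.exp(res.x)) + (1.0,)))


def _optimize_pi(eng: _Engine) -> None:
    m = eng.model
    x0 = np.log(np.asarray(m.pi[:3]) / m.pi[3])

    def neg(x: np.ndarray) -> float:
        raw = np.append(np.exp(x), 1.0)
        pi = tuple(raw / raw.sum())
        eng.set_model(replace(m, pi=pi))
        return -eng.total_lnl()

    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 200})
    raw = np.append(np.exp(res.x), 1.0)
    eng.set_model(replace(m, pi=tuple(raw / raw.sum())))


def evaluate_tree(
    tree: Tree,
    msa: MSA,
    model: GTRGammaModel,
    optimize: frozenset[str] | set[str] = frozenset({"brlens"}),
    tol: float = 1e-3,
    max_outer: int = 5,
) -> tuple[float, Tree, GTRGammaModel]:
    """Evaluate (and optionally re-fit) a tree on an alignment.

    `optimize` is a subset of {"brlens", "alpha", "exch", "pi"}; enabled
    blocks are refined by coordinate descent until the lnL gain per outer
    round drops below `tol`.  With an empty set this is a plain likelihood
    evaluation.  Using identical flags across trees yields comparable lnL
    scores.
    """
    unknown = set(optimize) - {"brlens", "alpha", "exch", "pi"}
    if unknown:
        raise ValueError(f"unknown optimization flags: {sorted(unknown)}")
    eng = _Engine(tree.copy(), msa, model)
    if not optimize:
        return eng.total_lnl(), eng.tree, eng.model
    if optimize == {"brlens"} or optimize == frozenset({"brlens"}):
        # single-block case: the edge optimizer converges by itself
        lnl = eng.optimize_branch_lengths(tol, max_rounds=2 * max_outer)
        return lnl, eng.tree, eng.model
    lnl = eng.total_lnl()
    for _ in range(max_outer):
        if "brlens" in optimize:
            eng.optimize_branch_lengths(tol, max_rounds=2)
        if "alpha" in optimize and model.k > 1:
            _optimize_alpha(eng)
        if "exch" in optimize:
            _optimize_exch(eng)
        if "pi" in optimize:
            _optimize_pi(eng)
        new_lnl = eng.total_lnl()
        if new_lnl - lnl < tol:
            lnl = max(new_lnl, lnl)
            break
        lnl = new_lnl
    return lnl, eng.tree, eng.model
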