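"""Built-in tree inferrers and the external-tool adapter.

Built-ins: BIONJ on JC-corrected distances, Fitch parsimony with random
stepwise addition plus NNI hill climbing, and a likelihood NNI search.
These provide self-contained baselines so the whole benchmark runs without
external binaries; external maximum-likelihood tools plug in through a
small argument-template contract.
"""

from __future__ import annotations

import shlex
import shutil
import subprocess
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from .likelihood import _Engine, maximize_edge_length, optimize_branch_lengths
from .models import GTRGammaModel
from .msa import IUPAC_SETS, MSA
from .trees import Tree, parse_newick

__all__ = [
    "DistanceMatrix",
    "jc_distance_matrix",
    "bionj",
    "fitch_score",
    "parsimony_tree",
    "nni_ml_search",
    "run_external_tool",
    "ToolResult",
    "BUILTIN_TOOLS",
]

JC_DMAX = 10.0
BUILTIN_TOOLS = ("bionj", "parsimony", "nni-ml")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} for {n} taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite and non-negative")


def jc_distance_matrix(msa: MSA, d_max: float = JC_DMAX) -> DistanceMatrix:
    """Jukes-Cantor corrected pairwise distances.

    Sites where either sequence carries a gap or ambiguity code are ignored
    for that pair; saturated pairs (mismatch fraction >= 3/4) are clamped
    to `d_max`.
    """
    plain = np.isin(msa.data, list("ACGT"))
    n = msa.n_taxa
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = plain[i] & plain[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites between {msa.taxa[i]!r} and {msa.taxa[j]!r}"
                )
            p = float(np.mean(msa.data[i, ok] != msa.data[j, ok]))
            if p >= 0.75:
                dij = d_max
            else:
                dij = min(-0.75 * np.log1p(-4.0 * p / 3.0), d_max)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(msa.taxa), d)


def bionj(dm: DistanceMatrix) -> Tree:
    """BIONJ agglomeration.

    Neighbor-joining selection criterion with variance-weighted branch
    length estimation and distance-matrix reduction (lambda weighting);
    exact on additive distance matrices.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("BIONJ needs at least 3 taxa")
    tree = Tree()
    active: list[int] = []  # tree node id per active cluster
    for lab in dm.taxa:
        active.append(tree.add_node(label=lab))
    D = dm.d.copy()
    V = dm.d.copy()  # variance estimates, initialized to the distances

    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=1)
        Qc = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Qc, np.inf)
        i, j = np.unravel_index(int(np.argmin(Qc)), Qc.shape)
        if i > j:
            i, j = j, i
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        # lambda weight from the variance matrix
        if V[i, j] > 0:
            others = [k for k in range(m) if k not in (i, j)]
            lam = 0.5 + (V[j, others].sum() - V[i, others].sum()) / (
                2.0 * (m - 2) * V[i, j]
            )
            lam = float(np.clip(lam, 0.0, 1.0))
        else:
            lam = 0.5
        new = tree.add_node()
        tree.add_edge(new, active[i], li)
        tree.add_edge(new, active[j], lj)
        # reduce
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = lam * (D[i, keep] - li) + (1.0 - lam) * (D[j, keep] - lj)
        d_new = np.maximum(d_new, 0.0)
        v_new = lam * V[i, keep] + (1.0 - lam) * V[j, keep] - lam * (1.0 - lam) * V[i, j]
        v_new = np.maximum(v_new, 0.0)
        D = np.pad(D[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        V = np.pad(V[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        D[-1, :-1] = D[:-1, -1] = d_new
        V[-1, :-1] = V[:-1, -1] = v_new
        active = [active[k] for k in keep] + [new]

    # final three-cluster join by the three-point formulas
    center = tree.add_node()
    (a, b, c) = range(3)
    la = max((D[a, b] + D[a, c] - D[b, c]) / 2.0, 0.0)
    lb = max((D[a, b] + D[b, c] - D[a, c]) / 2.0, 0.0)
    lc = max((D[a, c] + D[b, c] - D[a, b]) / 2.0, 0.0)
    for node, ln in zip(active, (la, lb, lc)):
        tree.add_edge(center, node, ln)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}


def _char_mask(ch: str) -> int:
    states = IUPAC_SETS.get(ch.upper())
    if states is None:
        raise ValueError(f"unknown alignment character {ch!r}")
    return sum(_BIT[b] for b in states)


def _leaf_masks(msa: MSA) -> dict[str, np.ndarray]:
    lut = np.zeros(128, dtype=np.uint8)
    for ch in IUPAC_SETS:
        lut[ord(ch)] = _char_mask(ch)
    out = {}
    for taxon, row in zip(msa.taxa, msa.data):
        codes = np.ascontiguousarray(row).view(np.uint32).astype(np.int64)
        m = lut[codes]
        if np.any(m == 0):
            bad = row[m == 0][0]
            raise ValueError(f"unknown alignment character {bad!r} in {taxon!r}")
        out[taxon] = m
    return out


def fitch_score(tree: Tree, msa: MSA, masks: dict[str, np.ndarray] | None = None) -> int:
    """Fitch small-parsimony change count summed over sites.

    Gaps and ambiguity codes contribute their full compatible state set.
    The count is invariant to the (arbitrary) rooting used for the pass.
    """
    if tree.leaf_labels != frozenset(msa.taxa):
        raise ValueError("tree and alignment taxa differ")
    if masks is None:
        masks = _leaf_masks(msa)
    root = next(n for n in tree.adj if n not in tree.labels)
    sets: dict[int, np.ndarray] = {}
    score = np.zeros(msa.n_sites, dtype=np.int64)
    for node, parent in tree.postorder(root):
        if node in tree.labels:
            sets[node] = masks[tree.labels[node]]
            continue
        acc = None
        for child in tree.adj[node]:
            if child == parent:
                continue
            s = sets.pop(child)
            if acc is None:
                acc = s
            else:
                inter = acc & s
                miss = inter == 0
                score += miss
                acc = np.where(miss, acc | s, inter)
        sets[node] = acc
    return int(score.sum())


def _fitch_branch_lengths(tree: Tree, msa: MSA) -> None:
    """Per-edge parsimony changes / site count, floored at 1e-6 (in place)."""
    masks = _leaf_masks(msa)
    root = next(n for n in tree.adj if n not in tree.labels)
    order = tree.postorder(root)
    down: dict[int, np.ndarray] = {}
    for node, parent in order:
        if node in tree.labels:
            down[node] = masks[tree.labels[node]]
            continue
        acc = None
        for child in tree.adj[node]:
            if child == parent:
                continue
            s = down[child]
            if acc is None:
                acc = s.copy()
            else:
                inter = acc & s
                acc = np.where(inter == 0, acc | s, inter)
        down[node] = acc

    def lowest_bit(x: np.ndarray) -> np.ndarray:
        return (x & (-x.astype(np.int64))).astype(np.uint8)

    assign: dict[int, np.ndarray] = {root: lowest_bit(down[root])}
    for node, parent in reversed(order):
        if parent is None:
            continue
        pa = assign[parent]
        s = down[node]
        ok = (s & pa) != 0
        assign[node] = np.where(ok, pa, lowest_bit(s))
        changes = float(np.mean(~ok))
        ln = max(changes, 1e-6)
        tree.adj[node][parent] = ln
        tree.adj[parent][node] = ln


def _nni_swap(tree: Tree, u: int, v: int, a: int, c: int) -> None:
    """Swap subtree a (neighbor of u) with subtree c (neighbor of v)."""
    la = tree.adj[u][a]
    lc = tree.adj[v][c]
    tree.remove_edge(u, a)
    tree.remove_edge(v, c)
    tree.add_edge(u, c, lc)
    tree.add_edge(v, a, la)


def _nni_candidates(tree: Tree) -> list[tuple[int, int, int, int]]:
    """(u, v, a, c) quadruples describing the two NNI moves per internal edge."""
    moves = []
    for u, v, _ in tree.internal_edges():
        a_nbs = [x for x in tree.adj[u] if x != v]
        c_nbs = [x for x in tree.adj[v] if x != u]
        if len(a_nbs) < 2 or len(c_nbs) < 2:
            continue  # multifurcation handled by its resolution elsewhere
        a = a_nbs[0]
        for c in c_nbs[:2]:
            moves.append((u, v, a, c))
    return moves


def parsimony_tree(msa: MSA, seed=None, nni_rounds: int = 5) -> Tree:
    """Fitch parsimony tree by random stepwise addition + NNI hill climbing.

    Each leaf is inserted at the edge minimizing the Fitch score (first
    minimum wins); `nni_rounds` rounds of first-improvement NNI follow.
    Branch lengths are per-edge parsimony changes per site.
    """
    if msa.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(msa.n_taxa))
    masks = _leaf_masks(msa)

    tree = Tree()
    center = tree.add_node()
    for idx in order[:3]:
        tree.add_edge(center, tree.add_node(label=msa.taxa[idx]))

    for idx in order[3:]:
        label = msa.taxa[idx]
        best = None
        for u, v, ln in tree.edges():
            mid = tree.add_node()
            tree.remove_edge(u, v)
            tree.add_edge(u, mid)
            tree.add_edge(mid, v)
            leaf = tree.add_node(label=label)
            tree.add_edge(mid, leaf)
            sub = {t: masks[t] for t in list(tree.labels.values())}
            s = fitch_score_partial(tree, sub)
            if best is None or s < best[0]:
                best = (s, u, v)
            # undo
            tree.remove_node(leaf)
            tree.remove_node(mid)
            tree.add_edge(u, v, ln)
        _, u, v = best
        ln = tree.adj[u][v]
        mid = tree.add_node()
        tree.remove_edge(u, v)
        tree.add_edge(u, mid)
        tree.add_edge(mid, v)
        tree.add_edge(mid, tree.add_node(label=label))

    score = fitch_score(tree, msa, masks)
    for _ in range(nni_rounds):
        improved = False
        for u, v, a, c in _nni_candidates(tree):
            if not all(x in tree.adj.get(u, {}) for x in (a, v)):
                continue
            if c not in tree.adj.get(v, {}):
                continue
            _nni_swap(tree, u, v, a, c)
            s = fitch_score(tree, msa, masks)
            if s < score:
                score = s
                improved = True
            else:
                _nni_swap(tree, u, v, c, a)  # undo
        if not improved:
            break
    _fitch_branch_lengths(tree, msa)
    return tree


def fitch_score_partial(tree: Tree, masks: dict[str, np.ndarray]) -> int:
    """Fitch score over whatever leaves the (possibly growing) tree carries."""
    root = next(n for n in tree.adj if n not in tree.labels)
    sets: dict[int, np.ndarray] = {}
    total = 0
    for node, parent in tree.postorder(root):
        if node in tree.labels:
            sets[node] = masks[tree.labels[node]]
            continue
        acc = None
        for child in tree.adj[node]:
            if child == parent:
                continue
            s = sets.pop(child)
            if acc is None:
                acc = s
            else:
                inter = acc & s
                miss = inter == 0
                total += int(miss.sum())
                acc = np.where(miss, acc | s, inter)
        sets[node] = acc
    return total


def nni_ml_search(
    msa: MSA,
    model: GTRGammaModel,
    start: Tree,
    tol: float = 0.1,
    max_rounds: int = 20,
) -> tuple[Tree, float]:
    """Likelihood hill climbing over NNI moves.

    Each round optimizes all branch lengths, scores both NNI neighbors of
    every internal edge (with the central branch re-optimized), and accepts
    the best strictly improving move.  Stops when no move gains more than
    `tol` lnL units or after `max_rounds` rounds.
    """
    tree, lnl = optimize_branch_lengths(start, msa, model, tol=tol / 10, max_rounds=3)
    for _ in range(max_rounds):
        # screen every move by re-optimizing only the central branch, then
        # confirm the most promising few with a full branch-length pass
        scored = []
        for u, v, a, c in _nni_candidates(tree):
            cand = tree.copy()
            _nni_swap(cand, u, v, a, c)
            eng = _Engine(cand, msa, model)
            t_opt, cand_lnl = maximize_edge_length(eng.edge_lnl_function(u, v))
            cand.adj[u][v] = cand.adj[v][u] = t_opt
            scored.append((cand_lnl, cand))
        scored.sort(key=lambda x: x[0], reverse=True)
        accepted = None
        for _, cand in scored[:3]:
            opt_cand, cand_lnl = optimize_branch_lengths(
                cand, msa, model, tol=tol / 10, max_rounds=2
            )
            if cand_lnl > lnl + tol:
                accepted = (opt_cand, cand_lnl)
                break
        if accepted is None:
            break
        tree, lnl = accepted
    return tree, lnl


# ---------------------------------------------------------------------------
# External tool adapter
# ---------------------------------------------------------------------------


@dataclass
class ToolResult:
    tool: str
    status: str  # ok | skipped | failed
    tree: Tree | None = None
    wall_time: float = 0.0
    message: str = ""


def run_external_tool(
    name: str,
    msa_path: str | Path,
    config: dict,
    workdir: str | Path | None = None,
) -> ToolResult:
    """Run a registered external inference tool on an alignment file.

    `config` maps tool names to {"cmd": template, "best_tree": path
    template}; templates may use {msa}, {workdir} and {prefix}.  A missing
    executable yields status "skipped"; a nonzero exit or unparsable output
    yields "failed".  Built-in tool names never reach this path.
    """
    if name in BUILTIN_TOOLS:
        raise ValueError(
            f"{name!r} is a built-in inferrer; call it directly instead of "
            "through the external-tool adapter"
        )
    tools = config.get("tools", {})
    if name not in tools:
        raise ValueError(
            f"tool {name!r} is not registered; registered: {sorted(tools)}"
        )
    entry = tools[name]
    workdir = Path(workdir or ".")
    workdir.mkdir(parents=True, exist_ok=True)
    subs = {
        "msa": str(msa_path),
        "workdir": str(workdir),
        "prefix": str(workdir / name),
    }
    cmd = shlex.split(entry["cmd"].format(**subs))
    if shutil.which(cmd[0]) is None:
        return ToolResult(name, "skipped", message=f"executable {cmd[0]!r} not found")
    t0 = time.monotonic()
    try:
        proc = subprocess.run(
            cmd, cwd=workdir, capture_output=True, text=True, timeout=entry.get("timeout", 3600)
        )
    except (OSError, subprocess.TimeoutExpired) as exc:
        return ToolResult(name, "failed", wall_time=time.monotonic() - t0,
                          message=str(exc))
    wall = time.monotonic() - t0
    if proc.returncode != 0:
        return ToolResult(name, "failed", wall_time=wall,
                          message=f"exit {proc.returncode}: {proc.stderr[-500:]}")
    tree_path = Path(entry["best_tree"].format(**subs))
    try:
        tree = parse_newick(tree_path.read_text())
    except (OSError, ValueError) as exc:
        return ToolResult(name, "failed", wall_time=wall,
                          message=f"could not read best tree: {exc}")
    return ToolResult(name, "ok", tree=tree, wall_time=wall)
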