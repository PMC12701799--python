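"""Sequence simulation along trees under GTR+Γ(+I) with optional Zipf indels.

Substitutions are simulated site-by-site down the tree with per-category
transition matrices.  The indel process is a per-edge Poisson scheme: event
counts are Poisson with mean rate * branch length * current sequence
length, positions are uniform, lengths are truncated-Zipf.  Insertions open
new alignment columns globally (gaps in every lineage that never carried
the column); deletions leave gaps in the deleted lineage's descendants.

Both entry points share one code path and one seed discipline, so a
zero-rate indel process reproduces the gapless simulation bit for bit.
"""

from __future__ import annotations

import numpy as np

from .models import GTRGammaModel, IndelModel, EigenQ, gtr_rate_matrix, NUCLEOTIDES
from .msa import MSA, GAP
from .trees import Tree

__all__ = [
    "random_tree",
    "sample_zipf",
    "simulate_gapless",
    "simulate_with_indels",
    "SimulationError",
]


class SimulationError(RuntimeError):
    pass


def random_tree(n_taxa: int, bl_mean: float = 0.1, seed=None) -> Tree:
    """Random binary unrooted tree on leaves T1..Tn.

    Topology by sequential random attachment (each new leaf subdivides a
    uniformly chosen edge), which is uniform over unrooted binary
    topologies; branch lengths i.i.d. exponential with mean `bl_mean`.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if bl_mean <= 0:
        raise ValueError("bl_mean must be > 0")
    rng = np.random.default_rng(seed)
    tree = Tree()
    center = tree.add_node()
    for i in range(3):
        leaf = tree.add_node(label=f"T{i + 1}")
        tree.add_edge(center, leaf)
    for i in range(3, n_taxa):
        edges = tree.edges()
        u, v, _ = edges[rng.integers(len(edges))]
        mid = tree.add_node()
        tree.remove_edge(u, v)
        tree.add_edge(u, mid)
        tree.add_edge(mid, v)
        leaf = tree.add_node(label=f"T{i + 1}")
        tree.add_edge(mid, leaf)
    for u, v, _ in tree.edges():
        ln = float(rng.exponential(bl_mean))
        tree.adj[u][v] = ln
        tree.adj[v][u] = ln
    return tree


def sample_zipf(indel: IndelModel, rng: np.random.Generator, size: int | None = None):
    """Indel length draw(s) from the truncated normalized Zipf pmf."""
    pmf = indel.length_pmf()
    draw = rng.choice(indel.max_len, p=pmf, size=size)
    return draw + 1


def _draw_states(P_rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Sample next states given per-residue transition probability rows."""
    cum = np.cumsum(P_rows, axis=1)
    return (u[:, None] > cum).sum(axis=1).astype(np.int8)


def _simulate(
    tree: Tree,
    model: GTRGammaModel,
    root_len: int,
    indel: IndelModel | None,
    seed,
) -> MSA:
    if root_len < 1:
        raise ValueError("root sequence length must be >= 1")
    rng = np.random.default_rng(seed)
    subst_rng, indel_rng = rng.spawn(2)

    pi = model.pi_array()
    Q = gtr_rate_matrix(model)
    eig = EigenQ(Q, pi)
    rates = model.category_rates()
    k = model.k

    def draw_categories(n: int, r: np.random.Generator) -> np.ndarray:
        cats = r.integers(0, k, size=n).astype(np.int8)
        if model.p_inv > 0:
            cats[r.random(n) < model.p_inv] = -1  # invariant sites
        return cats

    def draw_root_states(n: int, r: np.random.Generator) -> np.ndarray:
        u = r.random(n)
        return (u[:, None] > np.cumsum(pi)[None, :-1]).sum(axis=1).astype(np.int8)

    # global alignment bookkeeping: every residue ever created has a column id
    col_order: list[int] = list(range(root_len))
    col_cats: list[int] = []
    next_col = root_len

    root_cats = draw_categories(root_len, subst_rng)
    col_cats.extend(root_cats.tolist())
    root_states = draw_root_states(root_len, subst_rng)

    root = next(n for n in tree.adj if n not in tree.labels)
    # (node, parent, column ids, states) walked pre-order
    leaf_seqs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    stack = [(root, None, np.arange(root_len, dtype=np.int64), root_states)]
    while stack:
        node, parent, cols, states = stack.pop()
        if node in tree.labels:
            leaf_seqs[node] = (cols, states)
        for child in tree.adj[node]:
            if child == parent:
                continue
            t = tree.adj[node][child]
            c_cols, c_states = cols, states

            if indel is not None and (indel.ins_rate > 0 or indel.del_rate > 0):
                c_cols = c_cols.copy()
                c_states = c_states.copy()
                L0 = len(c_cols)
                n_ins = int(indel_rng.poisson(indel.ins_rate * t * L0))
                n_del = int(indel_rng.poisson(indel.del_rate * t * L0))
                events = ["I"] * n_ins + ["D"] * n_del
                indel_rng.shuffle(events)
                for ev in events:
                    L = len(c_cols)
                    length = int(sample_zipf(indel, indel_rng))
                    if ev == "I":
                        pos = int(indel_rng.integers(0, L + 1))
                        new_ids = np.arange(next_col, next_col + length, dtype=np.int64)
                        next_col += length
                        new_cats = draw_categories(length, indel_rng)
                        col_cats.extend(new_cats.tolist())
                        new_states = draw_root_states(length, indel_rng)
                        # splice into the global column order next to the anchor
                        if pos == 0:
                            if L > 0:
                                g = col_order.index(int(c_cols[0]))
                            else:
                                g = 0
                        else:
                            g = col_order.index(int(c_cols[pos - 1])) + 1
                        col_order[g:g] = new_ids.tolist()
                        c_cols = np.concatenate([c_cols[:pos], new_ids, c_cols[pos:]])
                        c_states = np.concatenate(
                            [c_states[:pos], new_states, c_states[pos:]]
                        )
                    else:
                        if L == 0:
                            continue
                        start = int(indel_rng.integers(0, L))
                        c_cols = np.concatenate(
                            [c_cols[:start], c_cols[start + length:]]
                        )
                        c_states = np.concatenate(
                            [c_states[:start], c_states[start + length:]]
                        )

            # substitutions along the edge, per rate category
            if len(c_cols) > 0 and t > 0:
                cats = np.asarray(col_cats, dtype=np.int8)[c_cols]
                new_states = c_states.copy()
                u = subst_rng.random(len(c_cols))
                for ci in range(k):
                    mask = cats == ci
                    if not mask.any():
                        continue
                    P = eig.p_matrix(t * rates[ci])
                    new_states[mask] = _draw_states(P[c_states[mask]], u[mask])
                c_states = new_states
            elif len(c_cols) > 0:
                # keep the stream position independent of branch length zero-ness?
                # no: t == 0 means no substitutions and no draws, mirroring an
                # edge with no events; determinism only requires a fixed seed.
                c_states = c_states.copy()

            stack.append((child, node, c_cols, c_states))

    # assemble the alignment over columns present in at least one leaf
    present: set[int] = set()
    for cols, _ in leaf_seqs.values():
        present.update(int(c) for c in cols)
    if not present:
        raise SimulationError(
            "all alignment columns were deleted; lower del_rate or shorten the tree"
        )
    kept = [c for c in col_order if c in present]
    col_index = {c: i for i, c in enumerate(kept)}

    taxa = [tree.labels[leaf] for leaf in tree.leaves()]
    data = np.full((len(taxa), len(kept)), GAP, dtype="<U1")
    alphabet = np.array(list(NUCLEOTIDES))
    for row, leaf in enumerate(tree.leaves()):
        cols, states = leaf_seqs[leaf]
        idx = np.array([col_index[int(c)] for c in cols], dtype=np.int64)
        data[row, idx] = alphabet[states]
    return MSA(taxa, data)


def simulate_gapless(tree: Tree, model: GTRGammaModel, n_sites: int, seed) -> MSA:
    """Simulate a gapless alignment of `n_sites` columns along `tree`."""
    return _simulate(tree, model, n_sites, None, seed)


def simulate_with_indels(
    tree: Tree,
    model: GTRGammaModel,
    root_len: int,
    indel: IndelModel,
    seed,
) -> MSA:
    """Simulate with the Zipf indel process; root sequence has `root_len` sites.

    With both indel rates zero this is identical to
    :func:`simulate_gapless` at the same seed.
    """
    return _simulate(tree, model, root_len, indel, seed)
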