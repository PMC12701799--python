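"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pytest

from treebench import GTRGammaModel, random_tree
from treebench.trees import Tree, parse_newick


@pytest.fixture
def jc1() -> GTRGammaModel:
    """Jukes-Cantor with a single rate category."""
    return GTRGammaModel.jc(k=1)


@pytest.fixture
def gtr_model() -> GTRGammaModel:
    return GTRGammaModel(
        pi=(0.35, 0.18, 0.22, 0.25),
        exch=(1.2, 3.1, 0.8, 0.9, 3.5, 1.0),
        alpha=0.7,
        k=4,
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def path_distances(tree: Tree) -> tuple[list[str], np.ndarray]:
    """All pairwise leaf path-length distances by breadth-first traversal."""
    leaves = tree.leaves()
    labels = [tree.labels[l] for l in leaves]
    n = len(leaves)
    d = np.zeros((n, n))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        stack = [(src, None)]
        while stack:
            u, p = stack.pop()
            for v, ln in tree.adj[u].items():
                if v != p:
                    dist[v] = dist[u] + ln
                    stack.append((v, u))
        for j, dst in enumerate(leaves):
            d[i, j] = dist[dst]
    return labels, d


def splits_by_edge_removal(tree: Tree) -> set[frozenset[str]]:
    """Brute-force split set: cut each internal edge, flood-fill one side."""
    out: set[frozenset[str]] = set()
    n = tree.n_leaves()
    ref = min(tree.labels.values())
    for u, v, _ in tree.internal_edges():
        side: set[str] = set()
        stack = [(v, u)]
        while stack:
            x, par = stack.pop()
            if x in tree.labels:
                side.add(tree.labels[x])
            for y in tree.adj[x]:
                if y != par:
                    stack.append((y, x))
        if not 2 <= len(side) <= n - 2:
            continue
        if ref in side:
            side = set(tree.labels.values()) - side
        out.add(frozenset(side))
    return out


def quartet_topology_from_paths(
    labels: list[str], d: np.ndarray, quad: tuple[str, ...]
) -> int:
    """Four-point condition: pairing with the strictly smallest path sum.

    Returns 0 = ab|cd, 1 = ac|bd, 2 = ad|bc, -1 if no strict minimum.
    """
    ia, ib, ic, id_ = (labels.index(x) for x in quad)
    sums = [
        d[ia, ib] + d[ic, id_],
        d[ia, ic] + d[ib, id_],
        d[ia, id_] + d[ib, ic],
    ]
    order = np.argsort(sums)
    if sums[order[1]] - sums[order[0]] < 1e-12:
        return -1
    return int(order[0])


def quartet_distance_oracle(t1: Tree, t2: Tree) -> float:
    """Quartet distance re-derived from pairwise path lengths."""
    l1, d1 = path_distances(t1)
    l2, d2 = path_distances(t2)
    labels = sorted(t1.leaf_labels)
    diff = total = 0
    for quad in combinations(labels, 4):
        total += 1
        if quartet_topology_from_paths(l1, d1, quad) != quartet_topology_from_paths(
            l2, d2, quad
        ):
            diff += 1
    return diff / total


def enumerate_topologies(labels: list[str]) -> list[Tree]:
    """All unrooted binary topologies on the given leaves (stepwise addition)."""
    base = parse_newick(f"({labels[0]},{labels[1]},{labels[2]});")
    trees = [base]
    for lab in labels[3:]:
        nxt = []
        for t in trees:
            for ei in range(len(t.edges())):
                c = t.copy()
                u, v, ln = c.edges()[ei]
                mid = c.add_node()
                c.remove_edge(u, v)
                c.add_edge(u, mid, 0.1)
                c.add_edge(mid, v, 0.1)
                c.add_edge(mid, c.add_node(label=lab), 0.1)
                nxt.append(c)
        trees = nxt
    return trees


def exhaustive_log_likelihood(tree: Tree, msa, model: GTRGammaModel) -> float:
    """Total lnL by explicit summation over internal-node state assignments.

    Independent of the pruning engine: for every rate category and every
    assignment of states to internal vertices, multiply the root prior and
    per-edge transition probabilities, summing leaf contributions over
    their compatible state sets.
    """
    from treebench.models import EigenQ, gtr_rate_matrix
    from treebench.msa import IUPAC_SETS

    pi = model.pi_array()
    eig = EigenQ(gtr_rate_matrix(model), pi)
    rates = model.category_rates()
    label_row = {t: i for i, t in enumerate(msa.taxa)}
    internals = [n for n in tree.adj if n not in tree.labels]
    root = internals[0]
    order = tree.postorder(root)
    edges = [(node, parent) for node, parent in order if parent is not None]
    total = 0.0
    state_idx = {b: i for i, b in enumerate("ACGT")}
    for s in range(msa.n_sites):
        site_lik = 0.0
        for rate in rates:
            Ps = {
                (node, parent): eig.p_matrix(tree.adj[node][parent] * rate)
                for node, parent in edges
            }
            cat_lik = 0.0
            for assign in product(range(4), repeat=len(internals)):
                states = dict(zip(internals, assign))
                p = pi[states[root]]
                for node, parent in edges:
                    P = Ps[(node, parent)]
                    if node in tree.labels:
                        ch = msa.data[label_row[tree.labels[node]], s]
                        compat = [state_idx[b] for b in IUPAC_SETS[ch]]
                        p *= sum(P[states[parent], x] for x in compat)
                    else:
                        p *= P[states[parent], states[node]]
                cat_lik += p
            site_lik += cat_lik / len(rates)
        total += np.log(site_lik)
    return total


def fitch_brute_force(tree: Tree, msa) -> int:
    """Minimum change count over all internal state assignments, per site."""
    from treebench.msa import IUPAC_SETS

    label_row = {t: i for i, t in enumerate(msa.taxa)}
    internals = [n for n in tree.adj if n not in tree.labels]
    root = internals[0]
    edges = [
        (node, parent) for node, parent in tree.postorder(root) if parent is not None
    ]
    state_idx = {b: i for i, b in enumerate("ACGT")}
    total = 0
    for s in range(msa.n_sites):
        best = None
        leaf_sets = {
            n: [state_idx[b] for b in IUPAC_SETS[msa.data[label_row[lab], s]]]
            for n, lab in tree.labels.items()
        }
        for assign in product(range(4), repeat=len(internals)):
            states = dict(zip(internals, assign))
            changes = 0
            for node, parent in edges:
                if node in tree.labels:
                    changes += min(
                        0 if x == states[parent] else 1 for x in leaf_sets[node]
                    )
                else:
                    changes += states[node] != states[parent]
            if best is None or changes < best:
                best = changes
        total += best
    return total
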