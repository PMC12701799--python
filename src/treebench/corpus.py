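"""Dataset corpora: descriptor tables, representative selection, synthesis.

A corpus is a table of dataset descriptors (taxa, sites, patterns, gap
fraction, GTR parameters, reference tree), the unit the benchmark selects
from.  Selection mirrors common practice for building representative
collections: drop the extreme tail via a percentile cut, sort by the
patterns-to-taxa ratio (a proxy for signal strength), split into
equal-count buckets, and sample one dataset per bucket.  A synthetic
generator emulates such corpora when no database export is at hand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import GTRGammaModel
from .simulate import random_tree
from .trees import Tree, parse_newick, write_newick

__all__ = [
    "CorpusEntry",
    "percentile_filter",
    "select_representatives",
    "generate_synthetic_corpus",
    "read_corpus",
    "write_corpus",
]

log = logging.getLogger(__name__)

TSV_COLUMNS = [
    "id", "n_taxa", "n_sites", "n_patterns", "gap_fraction",
    "pi_A", "pi_C", "pi_G", "pi_T",
    "exch_AC", "exch_AG", "exch_AT", "exch_CG", "exch_CT", "exch_GT",
    "alpha", "tree_path",
]


@dataclass
class CorpusEntry:
    """Descriptor of one benchmark dataset."""

    id: str
    n_taxa: int
    n_sites: int
    n_patterns: int
    gap_fraction: float
    model: GTRGammaModel
    tree: Tree | None = None
    tree_path: str | None = None
    msa_path: str | None = None
    source: str = "synthetic"  # synthetic | rg-export | treebase-export | user

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError(f"{self.id}: n_taxa must be >= 3")
        if self.n_sites < 1 or self.n_patterns < 1:
            raise ValueError(f"{self.id}: sites and patterns must be >= 1")
        if self.n_patterns > self.n_sites:
            raise ValueError(f"{self.id}: patterns exceed sites")
        if not 0.0 <= self.gap_fraction <= 1.0:
            raise ValueError(f"{self.id}: gap_fraction outside [0, 1]")
        if self.tree is not None and self.tree.n_leaves() != self.n_taxa:
            raise ValueError(f"{self.id}: tree leaf count != n_taxa")

    @property
    def ratio(self) -> float:
        """Site patterns-to-taxa ratio (signal-strength proxy)."""
        return self.n_patterns / self.n_taxa

    def load_tree(self) -> Tree:
        if self.tree is not None:
            return self.tree
        if self.tree_path is None:
            raise ValueError(f"{self.id}: no tree attached or referenced")
        self.tree = parse_newick(Path(self.tree_path).read_text())
        return self.tree


def percentile_filter(
    corpus: Sequence[CorpusEntry],
    q: float = 0.95,
    fields: Iterable[str] = ("n_taxa", "n_patterns"),
) -> list[CorpusEntry]:
    """Keep entries strictly below the q-quantile of every named field.

    Quantiles use linear interpolation; computed thresholds are logged.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if not 0.0 < q <= 1.0:
        raise ValueError("q must be in (0, 1]")
    fields = list(fields)
    bad = set(fields) - {"n_taxa", "n_patterns"}
    if bad:
        raise ValueError(f"unsupported filter fields: {sorted(bad)}")
    thresholds = {
        f: float(np.quantile([getattr(e, f) for e in corpus], q)) for f in fields
    }
    log.info("percentile filter q=%s thresholds: %s", q, thresholds)
    kept = [
        e for e in corpus if all(getattr(e, f) < thr for f, thr in thresholds.items())
    ]
    if not kept:
        log.warning("percentile filter removed every entry")
    return kept


def select_representatives(
    corpus: Sequence[CorpusEntry], n_buckets: int, seed=None
) -> list[CorpusEntry]:
    """One random dataset per equal-count bucket of the sorted ratio axis.

    Entries are sorted by patterns-to-taxa ratio (ties by id) and split
    into `n_buckets` contiguous groups whose sizes differ by at most one;
    the seeded RNG draws one entry per group.
    """
    if n_buckets < 1:
        raise ValueError("n_buckets must be >= 1")
    if len(corpus) < n_buckets:
        raise ValueError(
            f"corpus has {len(corpus)} entries, fewer than {n_buckets} buckets; "
            "use a smaller n_buckets"
        )
    rng = np.random.default_rng(seed)
    ordered = sorted(corpus, key=lambda e: (e.ratio, e.id))
    picks: list[CorpusEntry] = []
    for bucket in np.array_split(np.arange(len(ordered)), n_buckets):
        picks.append(ordered[int(rng.choice(bucket))])
    return picks


DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "n_taxa": (10, 120),
    "n_sites": (200, 5000),
    "alpha": (0.05, 5.0),  # log-uniform
    "gap_target": (0.0, 0.5),
    "bl_mean": (0.01, 0.5),  # log-uniform
    "exch": (0.2, 5.0),  # log-uniform
}


def generate_synthetic_corpus(
    n: int,
    seed=None,
    out_dir: str | Path | None = None,
    ranges: dict | None = None,
) -> list[CorpusEntry]:
    """Generate `n` synthetic dataset descriptors with random trees.

    Emulates a database export: random binary trees, Dirichlet-style base
    frequencies, log-uniform exchangeabilities and Gamma shape, target gap
    fractions and pattern counts within plausible bounds.  With `out_dir`
    set, writes corpus.tsv plus one Newick file per entry.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    rng = np.random.default_rng(seed)
    entries: list[CorpusEntry] = []
    for i in range(n):
        n_taxa = int(rng.integers(int(r["n_taxa"][0]), int(r["n_taxa"][1]) + 1))
        n_sites = int(rng.integers(int(r["n_sites"][0]), int(r["n_sites"][1]) + 1))
        alpha = float(np.exp(rng.uniform(*np.log(r["alpha"]))))
        bl_mean = float(np.exp(rng.uniform(*np.log(r["bl_mean"]))))
        gaps = float(rng.uniform(*r["gap_target"]))
        raw = rng.gamma(5.0, size=4)
        pi = raw / raw.sum()
        pi = np.round(pi, 9)
        pi[0] += 1.0 - pi.sum()  # exact unit sum after rounding
        exch = np.exp(rng.uniform(*np.log(r["exch"]), size=6))
        exch = exch / exch[5]  # GT-normalized, the usual convention
        model = GTRGammaModel(
            pi=tuple(pi), exch=tuple(exch), alpha=alpha, k=4, p_inv=0.0
        )
        tree = random_tree(n_taxa, bl_mean=bl_mean, seed=rng.integers(2**31))
        # plausible distinct-column fraction for a descriptor-only entry
        patterns = int(np.clip(round(n_sites * rng.uniform(0.15, 0.9)), 1, n_sites))
        entries.append(
            CorpusEntry(
                id=f"syn{i:04d}",
                n_taxa=n_taxa,
                n_sites=n_sites,
                n_patterns=patterns,
                gap_fraction=gaps,
                model=model,
                tree=tree,
                source="synthetic",
            )
        )
    if out_dir is not None:
        write_corpus(entries, out_dir)
    return entries


def write_corpus(entries: Sequence[CorpusEntry], out_dir: str | Path) -> Path:
    """Write corpus.tsv and per-entry Newick files; returns the TSV path."""
    out_dir = Path(out_dir)
    (out_dir / "trees").mkdir(parents=True, exist_ok=True)
    rows = []
    for e in entries:
        tree_path = e.tree_path
        if e.tree is not None:
            tree_path = str(out_dir / "trees" / f"{e.id}.nwk")
            Path(tree_path).write_text(write_newick(e.tree) + "\n")
        m = e.model
        rows.append(
            dict(
                zip(
                    TSV_COLUMNS,
                    [e.id, e.n_taxa, e.n_sites, e.n_patterns, e.gap_fraction,
                     *m.pi, *m.exch, m.alpha, tree_path],
                )
            )
        )
    path = out_dir / "corpus.tsv"
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_corpus(path: str | Path, source: str = "user") -> list[CorpusEntry]:
    df = pd.read_csv(path, sep="\t")
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"corpus table lacks columns: {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        pi = np.array([row[f"pi_{b}"] for b in "ACGT"], float)
        pi = pi / pi.sum()
        model = GTRGammaModel(
            pi=tuple(pi),
            exch=tuple(row[f"exch_{p}"] for p in ("AC", "AG", "AT", "CG", "CT", "GT")),
            alpha=float(row["alpha"]),
            k=4,
        )
        entries.append(
            CorpusEntry(
                id=str(row["id"]),
                n_taxa=int(row["n_taxa"]),
                n_sites=int(row["n_sites"]),
                n_patterns=int(row["n_patterns"]),
                gap_fraction=float(row["gap_fraction"]),
                model=model,
                tree_path=None if pd.isna(row["tree_path"]) else str(row["tree_path"]),
                source=source,
            )
        )
    return entries
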