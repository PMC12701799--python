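"""Ground-truth difficulty of a dataset from replicate tree searches.

The score summarizes tree-space ruggedness on a [0, 1] scale from the
topological diversity and statistical plausibility of a set of replicate
search trees:

    difficulty = 1/5 * [ RF_all + RF_pl + N*_all/N_all + N*_pl/N_pl
                         + (1 - N_pl/N_all) ]

where N_all replicate trees contain N*_all unique topologies with mean
pairwise normalized RF distance RF_all, and the N_pl statistically
plausible trees (AU test) contain N*_pl unique topologies with mean
pairwise RF distance RF_pl.  A low score indicates a single easy-to-find
likelihood peak; a high score a rugged landscape of distinct, equally
plausible trees.  Reporting buckets the [0, 1] range into five 0.2-wide
difficulty classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .trees import Tree, mean_pairwise_rf, unique_topology_count

__all__ = [
    "DifficultyComponents",
    "ground_truth_difficulty",
    "difficulty_from_searches",
    "difficulty_bucket",
]


@dataclass(frozen=True)
class DifficultyComponents:
    """Summary statistics of a replicate search-tree set."""

    n_all: int  # number of search trees
    n_pl: int  # number of plausible trees, >= 1
    n_star_all: int  # unique topologies among all trees
    n_star_pl: int  # unique topologies among plausible trees
    rf_all: float  # mean pairwise normalized RF, all trees
    rf_pl: float  # mean pairwise normalized RF, plausible trees

    def __post_init__(self) -> None:
        if self.n_all < 1:
            raise ValueError("n_all must be >= 1")
        if not 1 <= self.n_pl <= self.n_all:
            raise ValueError("n_pl must be in [1, n_all]")
        if not 1 <= self.n_star_all <= self.n_all:
            raise ValueError("n_star_all must be in [1, n_all]")
        if not 1 <= self.n_star_pl <= min(self.n_pl, self.n_star_all):
            raise ValueError("n_star_pl must be in [1, min(n_pl, n_star_all)]")
        for name in ("rf_all", "rf_pl"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_pl == 1 and self.rf_pl != 0.0:
            raise ValueError("rf_pl must be 0 when only one tree is plausible")


def ground_truth_difficulty(c: DifficultyComponents) -> float:
    """Evaluate the five-term difficulty formula; result in [0, 1]."""
    return (
        c.rf_all
        + c.rf_pl
        + c.n_star_all / c.n_all
        + c.n_star_pl / c.n_pl
        + (1.0 - c.n_pl / c.n_all)
    ) / 5.0


def difficulty_from_searches(
    trees: Sequence[Tree], plausible: Sequence[bool]
) -> tuple[DifficultyComponents, float]:
    """Assemble the components from search trees and AU plausibility flags."""
    if not trees:
        raise ValueError("need at least one search tree")
    if len(plausible) != len(trees):
        raise ValueError("one plausibility flag per tree required")
    pl_trees = [t for t, f in zip(trees, plausible) if f]
    if not pl_trees:
        raise ValueError("at least one tree must be plausible (the ML tree always is)")
    comps = DifficultyComponents(
        n_all=len(trees),
        n_pl=len(pl_trees),
        n_star_all=unique_topology_count(list(trees)),
        n_star_pl=unique_topology_count(pl_trees),
        rf_all=mean_pairwise_rf(list(trees)),
        rf_pl=mean_pairwise_rf(pl_trees),
    )
    return comps, ground_truth_difficulty(comps)


def difficulty_bucket(d: float) -> int:
    """Bucket index 0..4 for a difficulty score; 0.2-wide half-open cells,
    the last closed so 1.0 falls in bucket 4."""
    if not 0.0 <= d <= 1.0:
        raise ValueError(f"difficulty must be in [0, 1], got {d}")
    return min(int(math.floor(d / 0.2)), 4)
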