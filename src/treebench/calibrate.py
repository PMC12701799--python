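"""Indel-parameter calibration against target alignment statistics.

Empirical alignments are summarized by three statistics — site count,
distinct site-pattern count, and gap fraction.  Simulations without an
indel process systematically undershoot the pattern count, so the indel
model (insertion/deletion rates, Zipf length exponent, truncation) is
tuned so that simulated alignments match a target triple.  The objective
is the weighted mean of relative absolute errors of the three statistics;
the optimizer is a seeded sequential search: a zero-indel baseline first,
random log-space exploration, then local refinement around the incumbent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import GTRGammaModel, IndelModel
from .msa import MSA, count_patterns, gap_fraction
from .simulate import simulate_with_indels
from .trees import Tree

__all__ = [
    "MsaStats",
    "msa_stats",
    "calibration_loss",
    "calibrate_indels",
    "CalibrationResult",
]


@dataclass(frozen=True)
class MsaStats:
    """Alignment summary triple: columns, distinct columns, gap fraction."""

    sites: int
    patterns: int
    gaps: float

    def __post_init__(self) -> None:
        if self.sites < 1 or self.patterns < 1:
            raise ValueError("sites and patterns must be >= 1")
        if self.patterns > self.sites:
            raise ValueError(
                f"patterns ({self.patterns}) cannot exceed sites ({self.sites})"
            )
        if not 0.0 <= self.gaps <= 1.0:
            raise ValueError("gap fraction must be in [0, 1]")


def msa_stats(msa: MSA) -> MsaStats:
    return MsaStats(msa.n_sites, count_patterns(msa), gap_fraction(msa))


def calibration_loss(
    sim: MsaStats,
    target: MsaStats,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> float:
    """Weighted mean relative absolute error over (sites, patterns, gaps).

    Each term is |sim - target| / target; the gaps denominator falls back
    to 1 when the target has no gaps.  Zero iff all statistics match.
    """
    w = np.asarray(weights, float)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    gaps_denom = target.gaps if target.gaps > 0 else 1.0
    errs = np.array(
        [
            abs(sim.sites - target.sites) / target.sites,
            abs(sim.patterns - target.patterns) / target.patterns,
            abs(sim.gaps - target.gaps) / gaps_denom,
        ]
    )
    return float((w * errs).sum() / w.sum())


@dataclass
class CalibrationResult:
    indel: IndelModel
    loss: float
    root_len: int
    n_trials: int
    trace: list[float]  # best-so-far loss after each trial

    def __iter__(self):  # (indel, loss) unpacking convenience
        yield self.indel
        yield self.loss


# search-space bounds
_RATE_FLOOR, _RATE_MAX = 1e-4, 0.2
_ZIPF_LO, _ZIPF_HI = 1.01, 4.0
_MAXLEN_HI = 50


def _evaluate(
    tree: Tree,
    model: GTRGammaModel,
    indel: IndelModel,
    target: MsaStats,
    replicates: int,
    weights,
    trial_ss: np.random.SeedSequence,
) -> tuple[float, int]:
    """Mean loss over seeded replicate simulations, with the root length
    rescaled once (two pilot runs) so simulated site counts land near the
    target."""
    seeds = trial_ss.spawn(replicates + 2)
    root_len = target.sites
    if indel.ins_rate > 0 or indel.del_rate > 0:
        pilot_sites = np.mean(
            [
                simulate_with_indels(tree, model, root_len, indel, s).n_sites
                for s in seeds[:2]
            ]
        )
        ratio = target.sites / max(pilot_sites, 1.0)
        root_len = int(np.clip(round(root_len * ratio), 4, 4 * target.sites))
    losses = []
    for rep_seed in seeds[2:]:
        sim = simulate_with_indels(tree, model, root_len, indel, rep_seed)
        losses.append(calibration_loss(msa_stats(sim), target, weights))
    return float(np.mean(losses)), root_len


def calibrate_indels(
    tree: Tree,
    model: GTRGammaModel,
    target: MsaStats,
    budget: int = 60,
    replicates: int = 3,
    seed=None,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> CalibrationResult:
    """Find indel parameters whose simulations match the target statistics.

    Trial 1 is always the zero-indel baseline.  The first ~half of the
    budget explores the (log) parameter space at random; the rest perturbs
    the incumbent best.  Deterministic for a fixed seed and budget; the
    best-so-far loss is non-increasing in the budget.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    root_ss = np.random.SeedSequence(seed)
    draw_rng = np.random.default_rng(root_ss.spawn(1)[0])
    trial_sss = root_ss.spawn(budget)

    def random_candidate() -> IndelModel:
        lo, hi = np.log(_RATE_FLOOR), np.log(_RATE_MAX)
        return IndelModel(
            ins_rate=float(np.exp(draw_rng.uniform(lo, hi))),
            del_rate=float(np.exp(draw_rng.uniform(lo, hi))),
            zipf_s=float(draw_rng.uniform(_ZIPF_LO, _ZIPF_HI)),
            max_len=int(draw_rng.integers(1, _MAXLEN_HI + 1)),
        )

    def perturb(base: IndelModel, sigma: float) -> IndelModel:
        jitter = lambda x: float(
            np.clip(x * np.exp(draw_rng.normal(0.0, sigma)), _RATE_FLOOR, _RATE_MAX)
        )
        return IndelModel(
            ins_rate=jitter(max(base.ins_rate, _RATE_FLOOR)),
            del_rate=jitter(max(base.del_rate, _RATE_FLOOR)),
            zipf_s=float(
                np.clip(
                    base.zipf_s + draw_rng.normal(0.0, sigma * 0.7),
                    _ZIPF_LO, _ZIPF_HI,
                )
            ),
            max_len=int(
                np.clip(
                    round(base.max_len * np.exp(draw_rng.normal(0.0, sigma))),
                    1,
                    _MAXLEN_HI,
                )
            ),
        )

    zero = IndelModel(0.0, 0.0, 1.5, 1)
    best_loss, best_root = _evaluate(
        tree, model, zero, target, replicates, weights, trial_sss[0]
    )
    best = zero
    trace = [best_loss]

    if target.gaps == 0.0:
        # nothing for the indel process to match; the zero-rate model wins
        return CalibrationResult(zero, best_loss, best_root, 1, trace)

    n_explore = max(min(budget // 3, 20), min(budget, 10))
    for t in range(1, budget):
        if t < n_explore:
            cand = random_candidate()
        else:
            # local refinement with a decaying step size
            frac = (t - n_explore) / max(budget - n_explore, 1)
            cand = perturb(best, sigma=0.4 * (1.0 - 0.75 * frac))
        loss, root_len = _evaluate(
            tree, model, cand, target, replicates, weights, trial_sss[t]
        )
        if loss < best_loss:
            best_loss, best, best_root = loss, cand, root_len
        trace.append(best_loss)
    return CalibrationResult(best, best_loss, best_root, budget, trace)
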