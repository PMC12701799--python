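# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `treebench`, in the order the pipeline uses them.

## Trees and topological distances

Trees are unrooted, leaf-labeled, with non-negative branch lengths in
expected substitutions per site; internal vertices may be multifurcating.
Rooted Newick input is accepted and its degree-2 root suppressed (the two
incident branch lengths are summed), because every comparison in the
package is between unrooted hypotheses.  Multifurcations are preserved,
never randomly resolved.

Splits are canonicalized as the side *not* containing the lexicographically
smallest leaf, and hashed as frozen sets.  Distances:

- **Robinson–Foulds**: `|S₁ Δ S₂|`, normalized by `2(n−3)` (the binary-tree
  maximum).
- **Normalized tree distance (NTD)**: `|S₁ Δ S₂| / (|S₁| + |S₂|)`.  The
  literature attaches several formulas to this name; this one coincides
  with normalized RF on binary trees, stays well-defined for
  multifurcations, and is isolated behind a single function so it can be
  swapped.  Two star trees are defined to be at distance 0.
- **Quartet distance**: exact brute force over all C(n,4) leaf quadruples;
  a quartet resolved in one tree and unresolved in the other counts as
  differing.  A practical cap (default 200 leaves, configurable) guards
  the O(n⁴) cost; the benchmark pipeline uses a lower per-run cap.

## Substitution model and simulation

GTR+Γ(+I): stationary frequencies π, six exchangeabilities (GT-normalized
by convention), and k discrete Gamma categories (default 4) using
*category means* over equal-probability bins — so the category rates
average exactly 1 — plus an optional invariant-site proportion (default 0,
supported because reference inferences are typically GTR+Γ(+I)).  The rate
matrix is scaled so −Σ πᵢqᵢᵢ = 1; transition matrices come from the
symmetrized eigendecomposition (exact for reversible Q, numerically stable,
and cheap to evaluate for many branch lengths).

Simulation draws a rate category and a root state per site, then walks the
tree.  The indel process is a per-edge Poisson scheme: along an edge of
length t, insertion and deletion *event counts* are Poisson with mean
`rate · t · L` (L = sequence length entering the edge), positions uniform,
lengths truncated-Zipf `P(ℓ) ∝ ℓ^(−s)`, ℓ = 1..max_len.  Events are applied
in shuffled order.  An insertion opens new alignment columns globally —
every lineage outside the inserting subtree shows gaps there — and inserted
residues are drawn from π with fresh rate categories.  A deletion removes
columns from the lineage and its descendants only.  Rates are *per site per
unit branch length*; simulators differ on this parameterization, so it is
stated here and kept in one place.

Substitutions and indels consume two independent random streams spawned
from one seed, so a zero-rate indel process reproduces the gapless
simulation bit for bit — a property the tests rely on.

Not modeled (deliberately): branch-heterogeneous composition, codon/AA
alphabets, alignment error.  Simulated gap structure is simpler than real
gap structure; the gap-superimposition pipeline mode exists precisely to
transplant an empirical gap mask onto a gapless simulation when realism of
gaps matters.

## Indel calibration

Targets are the triple (sites, distinct site patterns, gap fraction).  The
loss is the weighted mean of relative absolute errors (weights default
1,1,1; the gap denominator falls back to 1 for gapless targets).  The
optimizer is a seeded sequential search: trial 1 is always the zero-indel
baseline; roughly the first third of the budget draws rates log-uniformly
in [1e-4, 0.2], the Zipf exponent uniformly in [1.01, 4] and the length cap
in 1..50; the remainder perturbs the incumbent in log space with a step
size decaying from 0.4 to 0.1.  Each trial is scored by the mean loss over
3 seeded replicate simulations, after one root-length rescaling (two pilot
runs) so expected output sites land near the target.  Gapless targets
return the zero-rate model immediately.

**Sizing matters.**  The three statistics are themselves random.  On an
8-taxon tree with 250-site targets at realistic rates, only a handful of
indel events occur per simulation and the gap fraction has a ~36% relative
standard deviation — the loss then has a floor near 0.12 regardless of the
optimizer.  The recovery experiments therefore use 12-taxon trees and
500-site targets (typical single-gene scale), where the gap fraction is
reproducible (~17% rel. sd) and self-targets are recovered with loss ≤ 0.05
in ≥ 80% of cases at a 60-trial budget.

## Likelihood engine

Felsenstein pruning over pattern-compressed columns (unique columns
weighted by multiplicity; compression is exact and verified against the
uncompressed path).  Gap and ambiguity characters contribute partial
likelihood 1 for every compatible state — the standard "missing data"
treatment.  Per-node rescaling by the per-pattern maximum keeps partials in
(0, 1] with a log-scale trail, so likelihoods never underflow and the
Gamma mixture can be averaged directly.

Branch lengths are optimized edge by edge: the two flanking conditional
likelihood vectors are computed once per edge, making the one-branch lnL a
cheap function of t; a bounded Brent search runs over **log branch length**
in [1e-9, 100] (the log transform keeps the problem unimodal and puts the
short-branch basin inside the initial golden-section probes — a plain
bounded search on the raw scale can stall on the long-branch plateau).
Accepted moves must not decrease the one-edge lnL, so the total lnL trace
is non-decreasing.  Model parameters are refined by coordinate descent
(branch lengths → α → exchangeabilities → frequencies, as enabled), with α
on a log scale and the simplex-constrained blocks via softmax
reparameterization, until the outer gain drops below the tolerance
(default 1e-3 lnL units).  Whether model parameters are re-fit per tree or
held fixed is a caller decision via flags; the pipeline default optimizes
branch lengths only, identically for every tree, which is what makes the
scores comparable.

## AU test

RELL: per-site log-likelihoods are resampled with replacement (implemented
as uniform index draws + bincount, one matmul per scale), B replicates per
scale, scales 0.5..1.4 in steps of 0.1.  Exact lnL ties split a replicate's
credit equally, so proportions always sum to 1 per scale.  Defaults:
B = 10,000 standalone, smaller inside the pipeline (1000) and difficulty
stage (500) where many tests run per dataset.

The signed distance d and curvature c are a weighted least-squares fit of
`Φ⁻¹(1 − bp_r)` on `(√r, 1/√r)` with delta-method binomial weights;
p = 1 − Φ(d − c).  Proportions are clamped to [1/(B+1), B/(B+1)] before
the probit.  One degenerate case needs special handling: a tree at the
clamp bound at *every* scale gives a constant transformed response, the
regression splits it evenly between d and c, and p collapses to 0.5 — the
opposite of what the evidence says.  Such trees are resolved directly to
p = 1 (wins everywhere) or p = 0 (loses everywhere).  The
maximum-likelihood tree is always flagged plausible, so the plausible set
is never empty.

Under mean-zero i.i.d. per-site differences the rejection rate at α = 0.05
stays within a loose nominal band (roughly 1–12% in seeded experiments);
the test is approximately, not exactly, calibrated at these B and n.

## Difficulty

The five-term formula over replicate search trees (see README).  The
package computes *ground-truth* difficulty from its own replicate searches
rather than predicting it from MSA features: the pipeline runs a
configurable number of seeded parsimony searches per dataset (default 20;
the definitional protocol uses 100 searches, which is prohibitive per
dataset at desk scale — the count is a logged config knob, and the
acceptance benchmark uses 10), evaluates them under identical settings,
runs the AU test among them, and assembles the components.  RF_pl is 0 by
definition when a single tree is plausible.  Buckets are
`floor(d/0.2)` with 1.0 clamped into bucket 4.

## Built-in inferrers

- **BIONJ** on Jukes–Cantor distances (closed form, gap/ambiguity sites
  excluded pairwise, saturation clamped at d = 10).  Variance-weighted
  branch estimates and matrix reduction with λ clamped to [0, 1]; exact on
  additive matrices.  JC rather than GTR-ML distances is a documented
  simplicity choice — the input matrix is swappable.
- **Parsimony**: Fitch state sets as 4-bit masks vectorized over sites
  (gap = full state set); random-order stepwise addition inserting each
  leaf at the first Fitch-minimal edge, then first-improvement NNI rounds.
  Branch lengths are per-edge parsimony changes per site (floored at 1e-6)
  from a single down-pass/up-pass state assignment.
- **NNI-ML**: rounds of {screen both NNI neighbors of every internal edge
  by re-optimizing only the central branch; confirm the top 3 candidates
  with a full branch-length pass; accept the best strict improvement}.
  Central-edge screening alone underestimates some moves' gains and can
  strand the search in spurious local optima; the confirmation pass fixes
  the cases that matter at small n (verified against exhaustive 5-leaf
  evaluation).  This is a reference searcher, not a competitor to
  production ML tools.

External tools plug in via command templates (`{msa}`, `{workdir}`,
`{prefix}`); a missing executable marks the cell "skipped", a nonzero exit
or unparsable output "failed" — never a crash of the run.

## Corpus selection and synthesis

The percentile filter keeps entries strictly below the linearly
interpolated q-quantile (default 0.95) of taxa and pattern counts —
thresholds are data-relative, not absolute, and are logged.
Representative selection sorts by the patterns-to-taxa ratio (ties by id),
splits into equal-*count* contiguous buckets (rank-based, sizes differing
by ≤ 1), and draws one entry per bucket with the seeded RNG.

The synthetic generator emulates a database export: uniform-topology
random trees (sequential random attachment), exponential branch lengths,
Dirichlet-style frequencies (Gamma(5) draws renormalized), log-uniform
exchangeabilities in [0.2, 5] and Gamma shape in [0.05, 5], and descriptor
pattern counts at 15–90% of sites.  It emulates descriptor *statistics*,
not the empirical correlation structure between them — conclusions about
real databases require real exports in the same TSV schema.

## Pipeline

Three modes decide the reference tree: `simulated-truth` (the generating
tree), `empirical-bestknown` (highest-lnL tree among extra thorough
searches and all tool trees, ties resolved thorough-first then tool
registration order), and `gap-superimposed` (simulate gapless on the
reference, transplant a gap mask from the source alignment or an indel
simulation).  In simulated-truth mode the truth is fixed by construction
and never re-defined by a better-scoring tool tree; the reference does
participate in the AU test alongside the inferred trees.

ΔlnL is `lnL_ref − lnL_tool` after identical re-optimization; the relative
form divides by |lnL_ref|.  Aggregation reports per-(bucket, tool) counts,
means, medians and plausible fractions, plus a per-tool Spearman rank
correlation between difficulty and normalized RF across datasets.

Resumability is artifact-based: per-dataset directories hold the
alignment, per-tool Newick trees, per-site lnL and AU tables, a difficulty
cache and a completion stamp listing the tools covered.  An untouched
re-run recomputes nothing; adding a tool re-runs only that tool's
inference plus the comparison stage (which depends on the candidate set);
deleting a dataset directory recomputes only that dataset.

## Desk-scale defaults and what they show

The shipped acceptance benchmark uses 20 synthetic datasets of 10–14 taxa
and 150–500 sites with branch-length means log-spread over [0.008, 0.3] to
span easy through hard regimes, 10 difficulty searches, AU B = 500, on one
CPU in a few minutes.  At this scale the qualitative structure reproduces
what larger studies report — accuracy degrades with difficulty (positive
Spearman ρ for every tool), the ML searcher dominates the distance and
parsimony baselines on easy data, and inferred trees sometimes exceed the
true tree's likelihood — but absolute numbers (ρ magnitudes, plausibility
fractions) are corpus- and scale-dependent and should not be read as
estimates of any published value.

## Known limitations

- Quartet distance is O(n⁴); fine to ~60 taxa, a cost wall beyond.
- The NNI-ML searcher explores NNI space only; it will not cross SPR-width
  valleys on hard datasets (by design — it is a baseline).
- The AU implementation tests the full candidate set jointly; pairwise
  testing against the best tree is not offered.
- Difficulty from 10–20 replicate searches is noisier than the 100-search
  definition; comparisons across runs should hold the count fixed.
- DNA only; the alphabet is isolated enough to generalize, but amino-acid
  models are not implemented.
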