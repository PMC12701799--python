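"""Ground-truth difficulty of an easy versus a hard dataset.

Difficulty summarizes tree-space ruggedness from replicate searches: how
many distinct topologies the searches find, how far apart they are, and
how many are statistically indistinguishable.
"""

import numpy as np

from treebench import (
    GTRGammaModel,
    evaluate_tree,
    parsimony_tree,
    random_tree,
    simulate_gapless,
    site_log_likelihoods,
)
from treebench.autest import plausible_set
from treebench.difficulty import difficulty_bucket, difficulty_from_searches
from treebench.likelihood import SiteLnLMatrix

model = GTRGammaModel.jc(k=1)

for label, bl_mean, n_sites in [("easy", 0.15, 800), ("hard", 0.01, 120)]:
    truth = random_tree(10, bl_mean=bl_mean, seed=7)
    msa = simulate_gapless(truth, model, n_sites, seed=8)
    trees = [parsimony_tree(msa, seed=s) for s in range(10)]
    rows = []
    for t in trees:
        lnl, opt_t, opt_m = evaluate_tree(t, msa, model, optimize={"brlens"})
        rows.append(site_log_likelihoods(opt_t, msa, opt_m))
    m = SiteLnLMatrix([f"s{i}" for i in range(len(trees))], np.vstack(rows))
    flags = [r.plausible for r in plausible_set(m, B=1000, seed=9)]
    comps, d = difficulty_from_searches(trees, flags)
    print(
        f"{label}: difficulty={d:.3f} bucket={difficulty_bucket(d)} "
        f"(unique={comps.n_star_all}/{comps.n_all}, plausible={comps.n_pl}, "
        f"mean RF={comps.rf_all:.3f})"
    )
# Short branches and few sites leave weak signal: searches scatter across
# many distinct yet equally plausible topologies, and the score rises.
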