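"""Compare two tree hypotheses with RF, NTD and quartet distances.

Builds two 4x-leaf Newick trees differing by one internal rearrangement
and prints the three topological distances the benchmark reports.
"""

from treebench import ntd_distance, parse_newick, quartet_distance, rf_distance

t1 = parse_newick("((A,B),C,(D,(E,F)));")
t2 = parse_newick("((A,C),B,(D,(E,F)));")

raw, norm = rf_distance(t1, t2)
print(f"RF raw        = {raw}")          # 2: one split swapped for another
print(f"RF normalized = {norm:.4f}")     # raw / (2(n-3))
print(f"NTD           = {ntd_distance(t1, t2):.4f}")
print(f"quartet       = {quartet_distance(t1, t2):.4f}")
# The quartet distance counts 4-leaf subsets whose induced topology differs;
# here 3 of the 15 quadruples disagree.
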