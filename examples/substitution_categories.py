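"""GC-category substitution rates on a simulated branch.

Evolves a 300-codon gene along one branch with a planted 3:1 S->W
mutation bias, counts substitutions by (syn/nonsyn x S->W/W->S/
GC-conservative) with opportunity normalization, and prints the rate
ratio that a neutral observer would use to read off the mutation bias.
"""

import numpy as np

from lepcodon.rates import CELLS, pairwise_rates, sw_ratio
from lepcodon.simulate import AlignmentSimConfig, simulate_branch_pair

rng = np.random.default_rng(11)
mult = {cell: (3.0 if cell[1] == "SW" else 1.0) for cell in CELLS}
cfg = AlignmentSimConfig(gene_length_codons=300, multipliers=mult)

tallies = []
for _ in range(50):
    anc, der, _ = simulate_branch_pair(cfg, rng, branch_length=0.1)
    tallies.append(pairwise_rates(anc, der))

one = tallies[0]
print("one replicate branch:")
for effect in ("syn", "nonsyn"):
    rates = {d: one.rate(effect, d) for d in ("SW", "WS", "conservative")}
    print(f"  {effect:7s} " + "  ".join(f"d_{d}={v:.4f}" for d, v in rates.items()))
print(f"  dN = {one.dn:.4f}, dS = {one.ds:.4f}, omega = {one.omega:.3f}")

res = sw_ratio(tallies)
print(f"\nsynonymous S->W/W->S ratio over {res['n']} replicates: "
      f"median {res['median']:.2f} (mean {res['mean']:.2f} +/- {res['sd']:.2f})")
print("the planted mutation bias was 3:1 -- a ratio near 3 means no fixation")
print("bias is masking the mutation process; gBGC would push it below 3.")
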