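"""Codon usage bias of a single gene: RSCU, ENC_obs, ENC_exp, ENC_diff.

Builds a short synthetic gene whose codon choice follows third-position
composition alone, then a biased version concentrating each family on one
codon, and prints the usage statistics for both.
"""

import numpy as np

from lepcodon.genetics import gc_by_position, standard_code
from lepcodon.simulate import compositional_gene
from lepcodon.usage import codon_frequencies, enc_diff, enc_exp, enc_obs

rng = np.random.default_rng(7)
code = standard_code()

neutral = compositional_gene(rng, 600, gc3=0.45)
# biased gene: always the first codon of each family
biased = "".join(
    code.families[code.translate(neutral[i:i + 3])][0]
    for i in range(0, len(neutral), 3)
)

for name, seq in [("composition-only gene", neutral), ("maximally biased gene", biased)]:
    table = codon_frequencies(seq, scope=name)
    gc3 = gc_by_position(seq).gc3
    obs = enc_obs(table)
    exp = enc_exp(gc3)
    print(f"{name}: GC3 = {gc3:.3f}")
    print(f"  ENC_obs  = {obs:.2f}   (20 = one codon per amino acid, 61 = uniform)")
    print(f"  ENC_exp  = {exp:.2f}   (expected from composition alone, clamped to [20, 61])")
    print(f"  ENC_diff = {enc_diff(exp, obs):+.3f} (positive = stronger bias than composition explains)")
    top = sorted(table.rscu_values.items(), key=lambda kv: -kv[1])[:3]
    print("  top RSCU:", ", ".join(f"{c}={v:.2f}" for c, v in top))
    print()
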