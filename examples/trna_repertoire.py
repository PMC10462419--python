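"""tRNA repertoire statistics from a tRNAscan-SE-style table.

Generates a planted gene table (including pseudogenes and a copy-number
outlier), filters it, and prints copy numbers, RAIT values and the
GC-content of the codon equivalents.
"""

import tempfile
from pathlib import Path

import numpy as np

from lepcodon.simulate import TRNASimConfig, simulate_trnascan_fixture
from lepcodon.trna import (
    copy_numbers,
    filter_functional,
    gc3_of_codon_equivalents,
    parse_trnascan,
)

rng = np.random.default_rng(5)
cfg = TRNASimConfig(outlier=("GGT", 57))
text, truth = simulate_trnascan_fixture(cfg, rng)

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "trnascan.txt"
    path.write_text(text)
    genes, skipped = parse_trnascan(path)

functional = filter_functional(genes)
summary = copy_numbers(functional)

print(f"parsed {len(genes)} gene models ({skipped} malformed rows skipped)")
print(f"functional after removing pseudo/truncated: {summary.total_genes}")
print(f"unique anticodons: {summary.unique_anticodons}")
print(f"copy-number summary: {summary.copy_number_summary()}")
print(f"outliers (possible repeat-driven expansions): {summary.outliers()}")
for ac, v in sorted(summary.rait_values.items()):
    print(f"  {ac}: copies {summary.copies_per_anticodon[ac]:3d}  RAIT {v:.2f}")
gc_all = gc3_of_codon_equivalents(summary)
gc_noout = gc3_of_codon_equivalents(summary, exclude_anticodons=set(summary.outliers()))
print(f"copy-weighted GC3 of codon equivalents: {gc_all:.3f} "
      f"({gc_noout:.3f} excluding the outlier)")
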