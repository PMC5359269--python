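"""Calibrate thresholds on a synthetic library and morph one molecule.

A reference library of synthesizable-looking molecules defines, per 50-Da
molecular-weight bin and per index, the maximum / 99.9% / 99% complexity
levels.  A starting structure then takes random structural steps until its
complexity first exceeds the 99.9%-level threshold for at least one index —
that first-crossing morph is the generated hard-to-synthesize structure.
"""

import numpy as np

import hardmorph as hm

library = hm.fixture_library(1100, seed=0)
table = hm.calibrate_thresholds(library)
print(f"calibrated {table.n_bins} bins from {len(library)} molecules")
b = 4  # the 200-250 Da bin
print(f"bin {b} thresholds (max / p999 / p99) per index:")
for idx in hm.INDEX_NAMES:
    row = [table.threshold(b, idx, lev) for lev in ("max", "p999", "p99")]
    print(f"  {idx:9s} {row[0]:8.1f} {row[1]:8.1f} {row[2]:8.1f}")

start = hm.parse_smiles("CC(=O)Nc1ccc(O)cc1")  # paracetamol
path = hm.morph_until_complex(start, table, rng=np.random.default_rng(7))
print(f"\nstart: {hm.canonical_smiles(start)}")
for i, (op, mol) in enumerate(path.steps, 1):
    print(f"  step {i:2d} {op.kind.value:12s} -> {hm.canonical_smiles(mol)}")
print(f"terminal status: {path.terminal_status} after {path.n_steps} steps")
if path.terminal_status == "HIT":
    print(
        "The last structure is the first on the path to exceed the calibrated\n"
        "complexity thresholds: it is kept as a hard-to-synthesize example."
    )
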