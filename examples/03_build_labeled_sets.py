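"""Build easy/hard training sets by the three competing strategies.

Morphing: hard = first-crossing morphs, easy = their starting structures.
Score threshold: hard = precomputed synthetic-accessibility score > 6,
easy sampled from score < 4.  Dense region: easy = molecules with >= 20
fingerprint neighbours at Tanimoto 0.6, hard = molecules with <= 1.
"""

import numpy as np

import hardmorph as hm

library = hm.fixture_library(660, seed=3)
table = hm.calibrate_thresholds(hm.fixture_library(1100, seed=2))

# 1. morphing-based sets
morph_sets, records = hm.build_morph_sets(
    library, table, rng=np.random.default_rng(4)
)
n_hit = sum(1 for r in records if r["status"] == "HIT")
print(f"morphing: {n_hit}/{len(records)} paths crossed; "
      f"{len(morph_sets.easy)} easy / {len(morph_sets.hard)} hard")

# 2. score-threshold sets from a mock precomputed score column
rng = np.random.default_rng(5)
scored = [
    {"smiles": hm.canonical_smiles(m), "sascore": float(rng.uniform(1, 9))}
    for m in library
]
sa_sets = hm.build_sascore_sets(scored, rng=rng)
print(f"score threshold: {len(sa_sets.easy)} easy / {len(sa_sets.hard)} hard "
      "(scores in [4,6] excluded)")

# 3. dense-region sets
dr_sets, unlabeled = hm.build_dr_sets(library, rng=np.random.default_rng(6))
print(f"dense region: {len(dr_sets.easy)} easy / {len(dr_sets.hard)} hard, "
      f"{len(unlabeled)} mid-density unlabeled")
print(
    "\nEach builder returns a deduplicated, binary-labeled SMILES collection\n"
    "ready for fingerprint random-forest training."
)
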