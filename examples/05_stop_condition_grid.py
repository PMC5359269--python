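"""Compare all twelve morphing stop conditions.

The stop rule has two dials: the threshold level (library maximum, 999th
permille, 99th percentile) and how many of the four indices must exceed it
(k = 1..4).  Each of the 12 combinations builds its own training set and
forest; rows are ranked by test accuracy.  Stricter rules (max level, high k)
produce more extreme but fewer hard examples.
"""

import numpy as np

import hardmorph as hm

table = hm.calibrate_thresholds(hm.fixture_library(1100, seed=2))
starts = hm.fixture_library(150, seed=30)
test_pool = hm.fixture_library(150, seed=31)
test, _ = hm.build_morph_sets(test_pool, table, rng=np.random.default_rng(32))
test.role = "test"

grid = hm.stop_condition_grid(starts, table, test, seed=33)
print(grid.sort_values("acc", ascending=False).to_string(index=False))
best = grid[grid["best"]].iloc[0]
print(f"\nbest configuration: level={best['level']} k={best['k_indices']} "
      f"(acc {best['acc']:.3f}, auc {best['auc']:.3f})")
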