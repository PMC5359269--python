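"""Shared fixtures: a synthetic reference library and thresholds calibrated on it.

All molecule inputs are generated programmatically; no external data files.
"""

from __future__ import annotations

import numpy as np
import pytest

import hardmorph as hm


@pytest.fixture(scope="session")
def ref_library():
    """330 synthetic molecules, 30 per molecular-weight bin."""
    return hm.fixture_library(330, seed=11)


@pytest.fixture(scope="session")
def table(ref_library):
    return hm.calibrate_thresholds(ref_library)


@pytest.fixture(scope="session")
def starts():
    """A separate synthetic batch used as morphing starts."""
    return hm.fixture_library(66, seed=12)


@pytest.fixture(scope="session")
def small_mols(ref_library):
    """Library molecules with at most 12 heavy atoms (the low-MW bins)."""
    return [m for m in ref_library if m.GetNumHeavyAtoms() <= 12]


def degenerate_table(value: float) -> hm.ThresholdTable:
    """A threshold table with every threshold set to one constant."""
    values = np.full((11, 4, 3), value)
    return hm.ThresholdTable(values=values, populated=np.ones(11, dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
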