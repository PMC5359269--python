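"""Molecular-weight-binned complexity thresholds and the stop decision.

A reference library of synthetically accessible molecules defines, per 50-Da
molecular-weight bin and per complexity index, three threshold levels: the
observed maximum, the 999th permille (99.9% of the library lies below) and
the 99th percentile.  A structure whose complexity strictly exceeds the
threshold for at least ``k`` of the four indices in its bin is considered
hard to synthesize.

Percentiles are nearest-rank (the value at rank ``ceil(q·n)`` of the sorted
sample, no interpolation), which reads the "99.9% lie below" phrasing as a
count statement and avoids interpolation-mode ambiguity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

from .chem import mol_weight
from .complexity import INDEX_NAMES, ComplexityVector, complexity_vector

#: Threshold levels in array-column order.
LEVELS = ("max", "p999", "p99")
_LEVEL_Q = {"p999": 0.999, "p99": 0.99}

DEFAULT_BIN_WIDTH = 50.0
DEFAULT_N_BINS = 11


class UncalibratedBinError(ValueError):
    """A molecular-weight bin has no calibration data."""


@dataclass(frozen=True)
class StopCondition:
    """Morphing stop rule: threshold level and number of indices that must exceed it.

    The default (999th permille, at least one index) is the best-performing
    configuration of the twelve-combination grid experiment.
    """

    level: str = "p999"
    k_indices: int = 1

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        if not 1 <= self.k_indices <= 4:
            raise ValueError(f"k_indices must be in 1..4, got {self.k_indices}")


@dataclass
class ThresholdTable:
    """Per-(bin, index) thresholds at the three levels.

    ``values`` has shape (n_bins, 4 indices, 3 levels) in the order of
    :data:`hardmorph.complexity.INDEX_NAMES` and :data:`LEVELS`; unpopulated
    bins are NaN and flagged in ``populated``.
    """

    values: np.ndarray
    populated: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH
    provenance: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def threshold(self, bin_idx: int, index: str, level: str) -> float:
        return float(
            self.values[bin_idx, INDEX_NAMES.index(index), LEVELS.index(level)]
        )

    def to_csv(self, path: str | Path) -> None:
        """Write ``bin,index,level,value`` rows plus a JSON provenance sidecar."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("bin,index,level,value\n")
            for b in range(self.n_bins):
                for i, idx in enumerate(INDEX_NAMES):
                    for l, lev in enumerate(LEVELS):
                        fh.write(f"{b},{idx},{lev},{float(self.values[b, i, l])!r}\n")
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = dict(self.provenance)
        meta.update(bin_width=self.bin_width, n_bins=self.n_bins)
        sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ThresholdTable":
        path = Path(path)
        rows = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("bin,index,level,value"):
                raise ValueError(f"{path}: not a threshold table CSV")
            for line in fh:
                b, idx, lev, val = line.strip().split(",")
                rows.append((int(b), idx, lev, float(val)))
        n_bins = max(r[0] for r in rows) + 1
        values = np.full((n_bins, len(INDEX_NAMES), len(LEVELS)), np.nan)
        for b, idx, lev, val in rows:
            values[b, INDEX_NAMES.index(idx), LEVELS.index(lev)] = val
        populated = ~np.isnan(values).any(axis=(1, 2))
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        bin_width = float(meta.pop("bin_width", DEFAULT_BIN_WIDTH))
        meta.pop("n_bins", None)
        return cls(values=values, populated=populated, bin_width=bin_width, provenance=meta)


def mw_bin(
    mw: float, bin_width: float = DEFAULT_BIN_WIDTH, n_bins: int = DEFAULT_N_BINS
) -> int:
    """0-based bin via half-open intervals [i·w, (i+1)·w); clamped to the last bin.

    Molecules above the top of the calibrated range share the last bin's
    thresholds rather than being rejected.
    """
    if mw < 0:
        raise ValueError(f"negative molecular weight: {mw}")
    return min(int(mw // bin_width), n_bins - 1)


def _nearest_rank(sorted_vals: np.ndarray, q: float) -> float:
    """Value at 1-based rank ceil(q·n) of an ascending-sorted array."""
    n = len(sorted_vals)
    rank = max(1, math.ceil(q * n))
    return float(sorted_vals[rank - 1])


def calibrate_from_values(
    mws: Sequence[float],
    index_values: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_bins: int = DEFAULT_N_BINS,
    provenance: dict | None = None,
) -> ThresholdTable:
    """Calibrate thresholds from precomputed weights and a (n, 4) index matrix."""
    mws = np.asarray(mws, dtype=float)
    index_values = np.asarray(index_values, dtype=float)
    if len(mws) == 0:
        raise ValueError("empty calibration library")
    if index_values.shape != (len(mws), len(INDEX_NAMES)):
        raise ValueError(f"index matrix must be (n, {len(INDEX_NAMES)})")
    bins = np.minimum((mws // bin_width).astype(int), n_bins - 1)
    values = np.full((n_bins, len(INDEX_NAMES), len(LEVELS)), np.nan)
    populated = np.zeros(n_bins, dtype=bool)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = bins == b
        counts[b] = int(mask.sum())
        if counts[b] == 0:
            continue
        populated[b] = True
        for i in range(len(INDEX_NAMES)):
            vals = np.sort(index_values[mask, i])
            values[b, i, LEVELS.index("max")] = vals[-1]
            for lev, q in _LEVEL_Q.items():
                values[b, i, LEVELS.index(lev)] = _nearest_rank(vals, q)
    prov = dict(provenance or {})
    prov.setdefault("library_size", int(len(mws)))
    prov["bin_counts"] = counts.tolist()
    return ThresholdTable(
        values=values, populated=populated, bin_width=bin_width, provenance=prov
    )


def calibrate_thresholds(
    library: Iterable[Chem.Mol],
    bin_width: float = DEFAULT_BIN_WIDTH,
    n_bins: int = DEFAULT_N_BINS,
    provenance: dict | None = None,
) -> ThresholdTable:
    """Derive a :class:`ThresholdTable` from a reference molecule library.

    Each molecule contributes its four complexity-index values to its
    molecular-weight bin; per (bin, index) the maximum and the nearest-rank
    99.9% / 99% values become the thresholds.  Bins with no molecules are
    flagged unpopulated; morphs falling into them are rejected downstream.
    """
    mols = list(library)
    if not mols:
        raise ValueError("empty calibration library")
    mws = [mol_weight(m) for m in mols]
    idx = np.array([complexity_vector(m).as_array() for m in mols])
    return calibrate_from_values(mws, idx, bin_width, n_bins, provenance)


def exceeds(
    cv: ComplexityVector,
    mw: float,
    table: ThresholdTable,
    cond: StopCondition = StopCondition(),
) -> bool:
    """True iff at least ``cond.k_indices`` of the four index values strictly
    exceed their (bin, index, level) thresholds."""
    b = mw_bin(mw, table.bin_width, table.n_bins)
    if not table.populated[b]:
        raise UncalibratedBinError(
            f"no calibration data for MW bin {b} "
            f"([{b * table.bin_width}, {(b + 1) * table.bin_width}) Da)"
        )
    thresholds = table.values[b, :, LEVELS.index(cond.level)]
    n_over = int(np.sum(cv.as_array() > thresholds))
    return n_over >= cond.k_indices
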