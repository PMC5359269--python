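"""Labeled easy/hard training and test sets, built three competing ways.

* morphing sets: hard examples are threshold-crossing terminal morphs, easy
  examples either the corresponding starting structures or a random sample
  from a reference library;
* score-threshold sets: hard = precomputed synthetic-accessibility score > 6,
  easy sampled from score < 4 (the 4–6 band is excluded entirely);
* dense-region (DR) sets: easy = molecules with ≥ 20 fingerprint neighbours
  at Tanimoto 0.6, hard = molecules with ≤ 1 neighbour.

Also provides a deterministic synthetic molecule generator that spans all
eleven 50-Da molecular-weight bins, so calibration, morphing and
classification experiments run without any external compound database.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import DataStructs

from .calibration import StopCondition, ThresholdTable
from .chem import SmilesRecord, canonical_smiles, morgan_fp, parse_smiles, read_smi, write_smi
from .morphing import DEFAULT_ALPHABET, generate_library

logger = logging.getLogger(__name__)

LABELS = ("easy", "hard")


@dataclass(frozen=True)
class LabeledRecord:
    smiles: str
    label: str
    source: str = ""
    score: float | None = None


@dataclass
class LabeledSet:
    """Binary-labeled SMILES collection (no duplicates within a label class)."""

    records: list[LabeledRecord] = field(default_factory=list)
    role: str = "train"

    @classmethod
    def from_smiles(
        cls,
        easy: list[str],
        hard: list[str],
        role: str = "train",
        source: str = "",
    ) -> "LabeledSet":
        records = []
        for label, smis in (("easy", easy), ("hard", hard)):
            seen: set[str] = set()
            for s in smis:
                if s not in seen:
                    seen.add(s)
                    records.append(LabeledRecord(smiles=s, label=label, source=source))
        return cls(records=records, role=role)

    @property
    def easy(self) -> list[str]:
        return [r.smiles for r in self.records if r.label == "easy"]

    @property
    def hard(self) -> list[str]:
        return [r.smiles for r in self.records if r.label == "hard"]

    def __len__(self) -> int:
        return len(self.records)

    def manifest(self) -> dict:
        return {
            "role": self.role,
            "n_easy": len(self.easy),
            "n_hard": len(self.hard),
            "sources": sorted({r.source for r in self.records}),
        }

    def write(self, path: str | Path, manifest_extra: dict | None = None) -> None:
        """Write as labeled .smi plus a JSON manifest sidecar."""
        path = Path(path)
        write_smi(
            path,
            [
                SmilesRecord(smiles=r.smiles, mol_id=str(i), label=r.label)
                for i, r in enumerate(self.records)
            ],
        )
        meta = self.manifest()
        meta.update(manifest_extra or {})
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2, sort_keys=True)
        )


def build_morph_sets(
    starts: list[Chem.Mol],
    table: ThresholdTable,
    cond: StopCondition = StopCondition(),
    rng: np.random.Generator | None = None,
    max_steps: int = 30,
    easy_pool: list[Chem.Mol] | None = None,
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET,
    kinds=None,
) -> tuple[LabeledSet, list[dict]]:
    """Morph the starts and pair the hard terminals with easy examples.

    With ``easy_pool`` given, easy examples are a random equal-size sample
    from that reference library.  Without it (the grid-experiment variant),
    the easy class consists of the corresponding starting structures of
    paths that crossed the threshold after at least one step; both classes
    are trimmed to a common size so the set is balanced.

    Returns the labeled set and the per-start path records.
    """
    if rng is None:
        rng = np.random.default_rng()
    hard, records = generate_library(starts, table, cond, max_steps, rng, alphabet, kinds)
    if not hard:
        logger.warning("no morphing path crossed the thresholds; empty set")
        return LabeledSet(role="train"), records
    hard_set = set(hard)
    if easy_pool is not None:
        pool = sorted({canonical_smiles(m) for m in easy_pool} - hard_set)
        if len(pool) < len(hard):
            raise ValueError(
                f"reference library ({len(pool)} unique) smaller than hard set ({len(hard)})"
            )
        easy = [pool[i] for i in rng.choice(len(pool), size=len(hard), replace=False)]
    else:
        seen: set[str] = set()
        easy = []
        for rec in records:
            # zero-step hits are starts that already exceed: not easy examples
            if rec["status"] == "HIT" and rec["n_steps"] >= 1:
                s = rec["start"]
                if s not in seen and s not in hard_set:
                    seen.add(s)
                    easy.append(s)
        m = min(len(easy), len(hard))
        if len(easy) > m:
            easy = [easy[i] for i in sorted(rng.choice(len(easy), size=m, replace=False))]
        if len(hard) > m:
            hard = [hard[i] for i in sorted(rng.choice(len(hard), size=m, replace=False))]
    return LabeledSet.from_smiles(easy=easy, hard=hard, source="morph"), records


def build_sascore_sets(
    scored: list[dict],
    n_easy: int | None = None,
    rng: np.random.Generator | None = None,
    score_col: str = "sascore",
    hard_above: float = 6.0,
    easy_below: float = 4.0,
) -> LabeledSet:
    """Build easy/hard sets from a precomputed synthetic-accessibility score.

    hard = score strictly above 6, easy = sampled from score strictly below
    4; the intermediate band is excluded from both classes.  Scores are
    consumed, never computed here.
    """
    if rng is None:
        rng = np.random.default_rng()
    hard, easy_pool = [], []
    for row in scored:
        score = row[score_col]
        smi = canonical_smiles(parse_smiles(row["smiles"]))
        if score > hard_above:
            hard.append((smi, score))
        elif score < easy_below:
            easy_pool.append((smi, score))
    if n_easy is None:
        n_easy = len(hard)
    if n_easy > len(easy_pool):
        raise ValueError(
            f"requested {n_easy} easy examples but only {len(easy_pool)} have "
            f"score < {easy_below}"
        )
    idx = rng.choice(len(easy_pool), size=n_easy, replace=False)
    easy = [easy_pool[i] for i in sorted(idx)]
    records = [
        LabeledRecord(smiles=s, label="easy", source="sascore", score=v) for s, v in easy
    ] + [LabeledRecord(smiles=s, label="hard", source="sascore", score=v) for s, v in hard]
    # dedup within class, first occurrence wins
    out: list[LabeledRecord] = []
    seen: dict[str, set[str]] = {"easy": set(), "hard": set()}
    for r in records:
        if r.smiles not in seen[r.label]:
            seen[r.label].add(r.smiles)
            out.append(r)
    return LabeledSet(records=out, role="train")


def neighbor_counts(fps: list, t: float = 0.6) -> np.ndarray:
    """Per-molecule count of other molecules with Tanimoto similarity ≥ t."""
    n = len(fps)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        if i + 1 < n:
            sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1 :])
            for off, s in enumerate(sims):
                if s >= t:
                    counts[i] += 1
                    counts[i + 1 + off] += 1
    return counts


def neighbor_count(i: int, fps: list, t: float = 0.6) -> int:
    """Number of j ≠ i with tanimoto(fps[i], fps[j]) ≥ t (self excluded)."""
    if not 0 <= i < len(fps):
        raise IndexError(f"index {i} out of range for {len(fps)} fingerprints")
    if not fps:
        raise ValueError("empty fingerprint list")
    sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps)
    return sum(1 for j, s in enumerate(sims) if j != i and s >= t)


def build_dr_sets(
    library: list[Chem.Mol],
    t: float = 0.6,
    easy_min: int = 20,
    hard_max: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[LabeledSet, list[str]]:
    """Dense-region labeling by fingerprint-neighbourhood density.

    Molecules with ≥ ``easy_min`` neighbours are easy, with ≤ ``hard_max``
    hard; the middle band stays unlabeled and is returned separately (never
    silently dropped).  The easy class is subsampled to the hard-class size
    for training parity.
    """
    if not library:
        return LabeledSet(role="train"), []
    if rng is None:
        rng = np.random.default_rng()
    smiles = [canonical_smiles(m) for m in library]
    fps = [morgan_fp(m) for m in library]
    counts = neighbor_counts(fps, t)
    easy = [s for s, c in zip(smiles, counts) if c >= easy_min]
    hard = [s for s, c in zip(smiles, counts) if c <= hard_max]
    unlabeled = [s for s, c in zip(smiles, counts) if hard_max < c < easy_min]
    # dedup before parity subsampling
    easy = list(dict.fromkeys(easy))
    hard = list(dict.fromkeys(hard))
    if len(easy) > len(hard) and hard:
        idx = sorted(rng.choice(len(easy), size=len(hard), replace=False))
        easy = [easy[i] for i in idx]
    return LabeledSet.from_smiles(easy=easy, hard=hard, source="dr"), unlabeled


# ---------------------------------------------------------------------------
# synthetic fixture library


_GROW_ELEMENTS = ("C", "N", "O", "S", "F", "Cl")
_GROW_WEIGHTS = (0.58, 0.12, 0.15, 0.05, 0.05, 0.05)
_MASS = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "F": 18.998, "Cl": 35.45}
_MAXVAL = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1}
_H_MASS = 1.008


def _grow_molecule(target_low: float, target_high: float, rng: np.random.Generator) -> Chem.Mol:
    """Grow a random valence-tracked molecule with MW inside [low, high)."""
    rw = Chem.RWMol()
    elements = ["C"]
    rw.AddAtom(Chem.Atom("C"))
    bonded = [0]
    adj: list[set[int]] = [set()]
    mw = _MASS["C"] + 4 * _H_MASS

    def spare(i: int) -> int:
        return _MAXVAL[elements[i]] - bonded[i]

    while mw < target_low:
        # occasional ring closure (consumes 2 H, -2.016 Da)
        if len(elements) >= 5 and rng.random() < 0.12:
            open_sites = [i for i in range(len(elements)) if spare(i) >= 1]
            pairs = [
                (i, j)
                for ii, i in enumerate(open_sites)
                for j in open_sites[ii + 1 :]
                if j not in adj[i]
            ]
            if pairs:
                i, j = pairs[rng.integers(len(pairs))]
                rw.AddBond(i, j, Chem.BondType.SINGLE)
                bonded[i] += 1
                bonded[j] += 1
                adj[i].add(j)
                adj[j].add(i)
                mw -= 2 * _H_MASS
                continue
        # occasional unsaturation (consumes 2 H)
        if rng.random() < 0.08:
            cands = [
                b
                for b in rw.GetBonds()
                if b.GetBondType() == Chem.BondType.SINGLE
                and spare(b.GetBeginAtomIdx()) >= 1
                and spare(b.GetEndAtomIdx()) >= 1
            ]
            if cands:
                b = cands[rng.integers(len(cands))]
                b.SetBondType(Chem.BondType.DOUBLE)
                bonded[b.GetBeginAtomIdx()] += 1
                bonded[b.GetEndAtomIdx()] += 1
                mw -= 2 * _H_MASS
                continue
        sites = [i for i in range(len(elements)) if spare(i) >= 1]
        if not sites:
            break
        site = sites[rng.integers(len(sites))]
        probs = np.array(_GROW_WEIGHTS)
        el = _GROW_ELEMENTS[rng.choice(len(_GROW_ELEMENTS), p=probs / probs.sum())]
        delta = _MASS[el] + (_MAXVAL[el] - 1) * _H_MASS - _H_MASS
        if mw + delta >= target_high:
            # close with the lightest element that still fits, else stop
            fits = [
                e
                for e in _GROW_ELEMENTS
                if mw + _MASS[e] + (_MAXVAL[e] - 1) * _H_MASS - _H_MASS < target_high
            ]
            if not fits:
                break
            el = min(fits, key=lambda e: _MASS[e])
            delta = _MASS[el] + (_MAXVAL[el] - 1) * _H_MASS - _H_MASS
        new_idx = rw.AddAtom(Chem.Atom(el))
        rw.AddBond(site, new_idx, Chem.BondType.SINGLE)
        elements.append(el)
        bonded.append(1)
        bonded[site] += 1
        adj.append({site})
        adj[site].add(new_idx)
        mw += delta
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def fixture_library(n: int, seed: int = 0) -> list[Chem.Mol]:
    """Deterministic synthetic library spanning all eleven 50-Da bins.

    Molecules are random drug-like organic graphs (C/N/O/S plus halogens,
    occasional rings and unsaturations) grown to a target weight; targets
    cycle through the bins so that ``n = 1100`` populates every bin with 100
    molecules.  Same (n, seed) yields an identical library.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mols = []
    for i in range(n):
        b = i % 11
        low = 50.0 * b + (5.0 if b else 14.0)  # bin 0 floor: nothing lighter than CH4
        high = 50.0 * (b + 1) - 2.0
        lo = low + rng.uniform(0, (high - low) * 0.6)
        mols.append(_grow_molecule(lo, high, rng))
    return mols


def load_test_set(path: str | Path) -> LabeledSet:
    """Load an external labeled test set from labeled .smi.

    Each record must carry a label ``easy`` or ``hard``; offending lines are
    collected and reported together.  Unparsable SMILES are reported too.
    """
    easy, hard, bad = [], [], []
    n = 0
    for lineno, rec in enumerate(read_smi(path), start=1):
        n += 1
        label = rec.label if rec.label is not None else rec.mol_id
        if label not in LABELS:
            bad.append(f"line {lineno}: missing or unknown label {label!r}")
            continue
        try:
            smi = canonical_smiles(parse_smiles(rec.smiles))
        except Exception as exc:
            bad.append(f"line {lineno}: {exc}")
            continue
        (easy if label == "easy" else hard).append(smi)
    if n == 0:
        raise ValueError(f"{path}: empty test-set file")
    if bad:
        raise ValueError(f"{path}: invalid records:\n" + "\n".join(bad))
    return LabeledSet.from_smiles(easy=easy, hard=hard, role="test", source="external")
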