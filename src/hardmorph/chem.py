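"""Shared molecular substrate: parsing, canonicalization, weights, fingerprints.

All molecules are RDKit ``Mol`` objects with implicit hydrogens; every public
function expects a sanitized molecule as produced by :func:`parse_smiles`.
Fingerprints are 512-bit Morgan (circular) bit vectors of radius 2, the RDKit
equivalent of ECFP4 at that length.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Fingerprint parameters used everywhere in the package.  Bit positions are
#: specific to the RDKit Morgan hashing; only set-level properties (Tanimoto
#: similarities, learned models) are portable across backends.
FP_RADIUS = 2
FP_NBITS = 512

_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_NBITS)


class SmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed or sanitized."""


def parse_smiles(smiles: str, largest_fragment: bool = False) -> Chem.Mol:
    """Parse and sanitize a SMILES string into an RDKit molecule.

    Parameters
    ----------
    smiles
        Input SMILES.  Implicit hydrogens are resolved during sanitization.
    largest_fragment
        If true, keep only the largest connected component (simple desalting).

    Raises
    ------
    SmilesError
        On syntax errors or valence violations, with a diagnostic message.
    """
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise SmilesError(f"SMILES syntax error: {smiles!r}")
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several exception types
        raise SmilesError(f"sanitization failed for {smiles!r}: {exc}") from exc
    if largest_fragment:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
        if len(frags) > 1:
            mol = max(frags, key=lambda f: f.GetNumHeavyAtoms())
    return mol


def canonical_smiles(mol: Chem.Mol) -> str:
    """Deterministic canonical SMILES; equal for all encodings of a structure."""
    return Chem.MolToSmiles(mol)


def mol_weight(mol: Chem.Mol) -> float:
    """Average molecular weight in Da, implicit hydrogens included."""
    return Descriptors.MolWt(mol)


def num_fragments(mol: Chem.Mol) -> int:
    """Number of connected components."""
    return len(Chem.GetMolFrags(mol))


def morgan_fp(mol: Chem.Mol, radius: int = FP_RADIUS, nbits: int = FP_NBITS):
    """Hashed circular-substructure fingerprint (RDKit ExplicitBitVect)."""
    if radius == FP_RADIUS and nbits == FP_NBITS:
        return _FP_GEN.GetFingerprint(mol)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    return gen.GetFingerprint(mol)


def fp_array(mols: Iterable[Chem.Mol], radius: int = FP_RADIUS, nbits: int = FP_NBITS) -> np.ndarray:
    """Stack fingerprints of many molecules into a (n, nbits) uint8 array."""
    rows = []
    for m in mols:
        fp = morgan_fp(m, radius, nbits)
        arr = np.zeros(nbits, dtype=np.uint8)
        for bit in fp.GetOnBits():
            arr[bit] = 1
        rows.append(arr)
    if not rows:
        return np.zeros((0, nbits), dtype=np.uint8)
    return np.stack(rows)


def tanimoto(a, b) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| between two equal-length bit vectors.

    Returns 1.0 when both vectors are empty (conventional limit).
    """
    if a.GetNumBits() != b.GetNumBits():
        raise ValueError(
            f"fingerprint length mismatch: {a.GetNumBits()} vs {b.GetNumBits()}"
        )
    from rdkit import DataStructs

    na, nb = a.GetNumOnBits(), b.GetNumOnBits()
    if na == 0 and nb == 0:
        return 1.0
    return DataStructs.TanimotoSimilarity(a, b)


@dataclass
class SmilesRecord:
    """One record of a .smi file: SMILES, optional id, optional label."""

    smiles: str
    mol_id: str | None = None
    label: str | None = None


def read_smi(path: str | Path) -> Iterator[SmilesRecord]:
    """Iterate records of a .smi file.

    Format: one record per line, ``SMILES [ws] optional-id [ws] optional-label``;
    lines starting with ``#`` and blank lines are ignored.
    """
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            yield SmilesRecord(
                smiles=parts[0],
                mol_id=parts[1] if len(parts) > 1 else None,
                label=parts[2] if len(parts) > 2 else None,
            )


def read_smi_molecules(path: str | Path) -> list[Chem.Mol]:
    """Parse all molecules of a .smi file, skipping (and logging) invalid records.

    Invalid records are not fatal: large SMILES libraries routinely contain a
    few broken entries.
    """
    mols = []
    for rec in read_smi(path):
        try:
            mols.append(parse_smiles(rec.smiles))
        except SmilesError as exc:
            logger.warning("skipping invalid record %r: %s", rec.smiles, exc)
    return mols


def write_smi(path: str | Path, records: Iterable[SmilesRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fields = [rec.smiles]
            if rec.mol_id is not None:
                fields.append(rec.mol_id)
            if rec.label is not None:
                if rec.mol_id is None:
                    fields.append("-")
                fields.append(rec.label)
            fh.write("\t".join(fields) + "\n")


def read_scored_csv(path: str | Path, smiles_col: str = "smiles") -> list[dict]:
    """Read a CSV with a SMILES column plus arbitrary numeric columns.

    Numeric columns are converted to float where possible; the SMILES column
    is kept as a string.  Used e.g. for precomputed synthetic-accessibility
    score tables.
    """
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or smiles_col not in reader.fieldnames:
            raise ValueError(f"CSV must contain a {smiles_col!r} column")
        for row in reader:
            parsed: dict = {}
            for key, val in row.items():
                if key == smiles_col:
                    parsed[key] = val
                else:
                    try:
                        parsed[key] = float(val)
                    except (TypeError, ValueError):
                        parsed[key] = val
            out.append(parsed)
    return out
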