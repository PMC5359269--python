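"""Molecular-complexity indices used as the morphing stop signal.

Four scalar indices are computed per molecule:

* **Bertz** — the graph-theoretic information-content index, taken from
  RDKit's ``GraphDescriptors.BertzCT``.
* **Whitlock** — a weighted count: 4 per ring, 2 per unsaturation (counted on
  the kekulized graph: a double bond is one unsaturation, a triple bond two),
  1 per heteroatom, 2 per chiral center.
* **BC** — an additive connectivity index in the Barone–Chanon style:
  3 points per heavy-atom connection of every atom, 3 per heteroatom,
  6 per ring.
* **SMCM** — a synthetic-complexity metric built from electronegativity-
  weighted atom and bond terms plus ring, ring-fusion and chirality terms.

Absolute scales differ between published variants and toolkit versions of
these indices; the downstream method is insensitive to scale because all
thresholds are percentile-calibrated on a reference library.  Chiral-center
counts include unassigned potential stereocenters, so complexity of
stereo-rich skeletons registers even though morphing never assigns labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
from rdkit import Chem
from rdkit.Chem import GraphDescriptors

#: Order of index columns in array form; fixed package-wide.
INDEX_NAMES = ("bertz", "whitlock", "bc", "smcm")

# Allred-Rochow electronegativities, normalized to carbon inside smcm_index.
_CHI = {
    1: 2.20, 5: 2.01, 6: 2.50, 7: 3.07, 8: 3.50, 9: 4.10,
    14: 1.74, 15: 2.06, 16: 2.44, 17: 2.83, 35: 2.74, 53: 2.21,
}
_CHI_C = _CHI[6]

# Bond-order factors for the SMCM bond term.
_BOND_FACTOR = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.AROMATIC: 1.25,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
}


@dataclass(frozen=True)
class ComplexityVector:
    """The four index values for one molecule."""

    bertz: float
    whitlock: float
    bc: float
    smcm: float

    def as_array(self) -> np.ndarray:
        return np.array([self.bertz, self.whitlock, self.bc, self.smcm])


def _normalized(mol: Chem.Mol) -> Chem.Mol:
    # Ring perception (symmetrized smallest-ring sets) can differ between an
    # edited in-memory molecule and its SMILES round-trip.  Re-deriving the
    # molecule from its canonical SMILES makes every index a pure function of
    # the structure, invariant under encoding and construction route.
    return Chem.MolFromSmiles(Chem.MolToSmiles(mol))


def _num_chiral_centers(mol: Chem.Mol) -> int:
    # includeUnassigned: morphing never assigns stereo labels, but potential
    # stereocenters must still register in the complexity.
    centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    return len(centers)


def _num_rings(mol: Chem.Mol) -> int:
    return mol.GetRingInfo().NumRings()


def bertz_index(mol: Chem.Mol) -> float:
    """Bertz graph-complexity index (RDKit implementation)."""
    return float(GraphDescriptors.BertzCT(_normalized(mol)))


def _whitlock(mol: Chem.Mol, n_chiral: int) -> float:
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    unsat = 0
    for bond in kek.GetBonds():
        if bond.GetBondType() == Chem.BondType.DOUBLE:
            unsat += 1
        elif bond.GetBondType() == Chem.BondType.TRIPLE:
            unsat += 2
    hetero = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))
    return float(4 * _num_rings(mol) + 2 * unsat + 1 * hetero + 2 * n_chiral)


def whitlock_index(mol: Chem.Mol) -> float:
    """Weighted ring/unsaturation/heteroatom/stereocenter count.

    The molecule is kekulized before unsaturation counting, so benzene counts
    three unsaturations (plus one ring): 4·1 + 2·3 = 10.
    """
    mol = _normalized(mol)
    return _whitlock(mol, _num_chiral_centers(mol))


def _bc(mol: Chem.Mol) -> float:
    val = 0.0
    for atom in mol.GetAtoms():
        val += 3.0 * atom.GetDegree()
        if atom.GetAtomicNum() not in (1, 6):
            val += 3.0
    val += 6.0 * _num_rings(mol)
    return val


def bc_index(mol: Chem.Mol) -> float:
    """Additive connectivity/heteroatom/ring complexity score.

    Each atom contributes 3 per heavy-atom neighbour, each heteroatom a flat
    3, each ring 6.  Monotone under attachment of a new singly-bonded atom.
    """
    return _bc(_normalized(mol))


def _smcm(mol: Chem.Mol, n_chiral: int) -> float:
    chi = {}
    atom_term = 0.0
    for atom in mol.GetAtoms():
        c = _CHI.get(atom.GetAtomicNum(), _CHI_C) / _CHI_C
        chi[atom.GetIdx()] = c
        atom_term += c
    bond_term = 0.0
    ring_info = mol.GetRingInfo()
    fusion_bonds = 0
    for bond in mol.GetBonds():
        # aromaticity by flag, not bond type: a kekulized in-memory product
        # and its aromatic-SMILES round-trip must score identically
        if bond.GetIsAromatic():
            factor = _BOND_FACTOR[Chem.BondType.AROMATIC]
        else:
            factor = _BOND_FACTOR.get(bond.GetBondType(), 1.0)
        bond_term += factor * sqrt(
            chi[bond.GetBeginAtomIdx()] * chi[bond.GetEndAtomIdx()]
        )
        if ring_info.NumBondRings(bond.GetIdx()) >= 2:
            fusion_bonds += 1
    ring_term = float(_num_rings(mol) + fusion_bonds)
    return atom_term + bond_term + ring_term + 2.0 * n_chiral


def smcm_index(mol: Chem.Mol) -> float:
    """Synthetic-complexity metric from atom, bond, ring and chirality terms.

    * atom term: relative electronegativity χ(el)/χ(C) per heavy atom;
    * bond term: order factor (1 / 1.25 / 2 / 3 for single / aromatic /
      double / triple) × geometric mean of the two relative χ values;
    * ring term: 1 per ring plus 1 per ring-fusion bond (bond in ≥2 rings);
    * chirality term: 2 per (possibly unassigned) stereocenter.
    """
    mol = _normalized(mol)
    return _smcm(mol, _num_chiral_centers(mol))


def complexity_vector(mol: Chem.Mol) -> ComplexityVector:
    """All four indices, bundled in the package-wide column order.

    Normalizes the molecule and perceives stereocenters once, then evaluates
    the four indices on the shared representation.
    """
    norm = _normalized(mol)
    n_chiral = _num_chiral_centers(norm)
    return ComplexityVector(
        bertz=float(GraphDescriptors.BertzCT(norm)),
        whitlock=_whitlock(norm, n_chiral),
        bc=_bc(norm),
        smcm=_smcm(norm, n_chiral),
    )
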