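"""Stochastic molecular morphing terminated by calibrated complexity thresholds.

A starting structure undergoes a random walk of elementary structural
variations — add / remove / mutate an atom or a bond — and the walk stops at
the first morph whose complexity exceeds the calibrated thresholds for its
molecular-weight bin (the "first crossing").  Paths that fail to cross within
the step cap yield no hard-to-synthesize example.

Operators act on the kekulized molecular graph (aromatic flags cleared before
editing, re-perceived on sanitization), so bond orders are always integral.
Every intermediate is valence-valid and single-component by construction;
candidate moves use cheap valence/connectivity pre-filters and the chosen
move is verified by full sanitization, with bounded resampling on the rare
failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from rdkit import Chem

from .calibration import StopCondition, ThresholdTable, UncalibratedBinError, exceeds
from .chem import canonical_smiles, mol_weight, num_fragments
from .complexity import ComplexityVector, complexity_vector

logger = logging.getLogger(__name__)

#: Elements available to ADD_ATOM / MUTATE_ATOM: the standard drug-like
#: organic subset.
DEFAULT_ALPHABET = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")

#: Resampling cap when a sampled operation fails sanitization.
DEFAULT_MAX_RETRIES = 50

_PT = Chem.GetPeriodicTable()


class OpKind(Enum):
    ADD_ATOM = "ADD_ATOM"
    REMOVE_ATOM = "REMOVE_ATOM"
    MUTATE_ATOM = "MUTATE_ATOM"
    ADD_BOND = "ADD_BOND"
    REMOVE_BOND = "REMOVE_BOND"
    MUTATE_BOND = "MUTATE_BOND"


@dataclass(frozen=True)
class MorphOperation:
    """One elementary structural variation, addressed by atom indices of the
    molecule it applies to.

    ``element`` is the new element symbol for ADD_ATOM / MUTATE_ATOM;
    ``bond_order`` the new integral order for MUTATE_BOND.
    """

    kind: OpKind
    atom_idx: int | None = None
    atom_idx2: int | None = None
    element: str | None = None
    bond_order: int | None = None


class InapplicableOperationError(ValueError):
    """The operation cannot be applied to this molecule."""


class DeadEndError(RuntimeError):
    """No applicable operation remains (or all sampled ones failed)."""


def _kekulized(mol: Chem.Mol) -> Chem.RWMol:
    rw = Chem.RWMol(mol)
    Chem.Kekulize(rw, clearAromaticFlags=True)
    return rw


def _free_valence(atom: Chem.Atom) -> int:
    # Hydrogens (implicit or explicit count) are the substitutable valence.
    return atom.GetTotalNumHs()


def _bonded_valence(atom: Chem.Atom) -> int:
    return int(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))


def _articulation_points(mol: Chem.Mol) -> set[int]:
    """Atoms whose removal disconnects the graph (iterative Tarjan DFS)."""
    n = mol.GetNumAtoms()
    adj = [[] for _ in range(n)]
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        adj[i].append(j)
        adj[j].append(i)
    visited = [False] * n
    disc = [0] * n
    low = [0] * n
    parent = [-1] * n
    points: set[int] = set()
    timer = 0
    for root in range(n):
        if visited[root]:
            continue
        stack = [(root, iter(adj[root]))]
        visited[root] = True
        disc[root] = low[root] = timer = timer + 1
        root_children = 0
        while stack:
            v, it = stack[-1]
            advanced = False
            for w in it:
                if not visited[w]:
                    if v == root:
                        root_children += 1
                    visited[w] = True
                    timer += 1
                    disc[w] = low[w] = timer
                    parent[w] = v
                    stack.append((w, iter(adj[w])))
                    advanced = True
                    break
                elif w != parent[v]:
                    low[v] = min(low[v], disc[w])
            if not advanced:
                stack.pop()
                if stack:
                    u = stack[-1][0]
                    low[u] = min(low[u], low[v])
                    if u != root and low[v] >= disc[u]:
                        points.add(u)
        if root_children > 1:
            points.add(root)
    return points


def applicable_operations(
    mol: Chem.Mol,
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET,
    kinds: frozenset[OpKind] | None = None,
) -> list[MorphOperation]:
    """Enumerate candidate operations that keep the molecule valence-valid,
    connected and single-component.

    Candidates are screened by valence arithmetic and connectivity checks on
    the kekulized graph; :func:`apply_operation` performs the authoritative
    sanitization.  ADD_BOND always closes a ring (the graph is connected);
    REMOVE_BOND is restricted to ring bonds and REMOVE_ATOM to atoms that are
    not articulation points, so connectivity is preserved.  ``kinds`` limits
    enumeration to an enabled subset of the six operator kinds.
    """
    if kinds is not None:
        kinds = frozenset(kinds)
    enabled = kinds if kinds is not None else frozenset(OpKind)
    kek = _kekulized(mol)
    ops: list[MorphOperation] = []
    n = kek.GetNumAtoms()
    art = _articulation_points(kek)
    free = [_free_valence(a) for a in kek.GetAtoms()]

    for a in kek.GetAtoms():
        i = a.GetIdx()
        # ADD_ATOM: new singly-bonded alphabet atom at any site with free valence
        if free[i] >= 1:
            for el in alphabet:
                ops.append(MorphOperation(OpKind.ADD_ATOM, atom_idx=i, element=el))
        # REMOVE_ATOM: deletion must keep the graph connected and nonempty
        if n > 1 and i not in art:
            ops.append(MorphOperation(OpKind.REMOVE_ATOM, atom_idx=i))
        # MUTATE_ATOM: element swap with sufficient default valence
        if a.GetFormalCharge() == 0:
            bonded = _bonded_valence(a)
            for el in alphabet:
                num = _PT.GetAtomicNumber(el)
                if num != a.GetAtomicNum() and _PT.GetDefaultValence(num) >= bonded:
                    ops.append(MorphOperation(OpKind.MUTATE_ATOM, atom_idx=i, element=el))

    # ADD_BOND: single bond between unbonded atoms with free valence (new ring)
    if OpKind.ADD_BOND in enabled:
        for i in range(n):
            if free[i] < 1:
                continue
            for j in range(i + 1, n):
                if free[j] >= 1 and kek.GetBondBetweenAtoms(i, j) is None:
                    ops.append(MorphOperation(OpKind.ADD_BOND, atom_idx=i, atom_idx2=j))

    ring_info = kek.GetRingInfo()
    for b in kek.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        order = int(b.GetBondTypeAsDouble())
        # REMOVE_BOND: ring bonds only (acyclic deletion would disconnect)
        if ring_info.NumBondRings(b.GetIdx()) > 0:
            ops.append(MorphOperation(OpKind.REMOVE_BOND, atom_idx=i, atom_idx2=j))
        # MUTATE_BOND: order change within the available valence
        for new_order in (1, 2, 3):
            if new_order == order:
                continue
            delta = new_order - order
            if delta <= 0 or (free[i] >= delta and free[j] >= delta):
                ops.append(
                    MorphOperation(
                        OpKind.MUTATE_BOND, atom_idx=i, atom_idx2=j, bond_order=new_order
                    )
                )
    if kinds is not None:
        ops = [op for op in ops if op.kind in enabled]
    return ops


_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def _reset_hs(atom: Chem.Atom) -> None:
    atom.SetNumExplicitHs(0)
    atom.SetNoImplicit(False)


def apply_operation(mol: Chem.Mol, op: MorphOperation) -> Chem.Mol:
    """Apply one operation and return the sanitized product.

    The input molecule is never modified.  Raises
    :class:`InapplicableOperationError` if the edit is structurally invalid
    or the product fails sanitization or is not single-component.
    """
    kek = _kekulized(mol)
    try:
        if op.kind is OpKind.ADD_ATOM:
            atom = kek.GetAtomWithIdx(op.atom_idx)
            if _free_valence(atom) < 1:
                raise InapplicableOperationError("no free valence at site")
            new_idx = kek.AddAtom(Chem.Atom(op.element))
            kek.AddBond(op.atom_idx, new_idx, Chem.BondType.SINGLE)
            _reset_hs(kek.GetAtomWithIdx(op.atom_idx))
        elif op.kind is OpKind.REMOVE_ATOM:
            if kek.GetNumAtoms() <= 1:
                raise InapplicableOperationError("cannot remove the only atom")
            for nbr in kek.GetAtomWithIdx(op.atom_idx).GetNeighbors():
                _reset_hs(nbr)
            kek.RemoveAtom(op.atom_idx)
        elif op.kind is OpKind.MUTATE_ATOM:
            atom = kek.GetAtomWithIdx(op.atom_idx)
            atom.SetAtomicNum(_PT.GetAtomicNumber(op.element))
            _reset_hs(atom)
        elif op.kind is OpKind.ADD_BOND:
            if kek.GetBondBetweenAtoms(op.atom_idx, op.atom_idx2) is not None:
                raise InapplicableOperationError("atoms already bonded")
            kek.AddBond(op.atom_idx, op.atom_idx2, Chem.BondType.SINGLE)
            _reset_hs(kek.GetAtomWithIdx(op.atom_idx))
            _reset_hs(kek.GetAtomWithIdx(op.atom_idx2))
        elif op.kind is OpKind.REMOVE_BOND:
            bond = kek.GetBondBetweenAtoms(op.atom_idx, op.atom_idx2)
            if bond is None:
                raise InapplicableOperationError("no such bond")
            if kek.GetRingInfo().NumBondRings(bond.GetIdx()) == 0:
                raise InapplicableOperationError("removing an acyclic bond would disconnect")
            kek.RemoveBond(op.atom_idx, op.atom_idx2)
            _reset_hs(kek.GetAtomWithIdx(op.atom_idx))
            _reset_hs(kek.GetAtomWithIdx(op.atom_idx2))
        elif op.kind is OpKind.MUTATE_BOND:
            bond = kek.GetBondBetweenAtoms(op.atom_idx, op.atom_idx2)
            if bond is None:
                raise InapplicableOperationError("no such bond")
            if int(bond.GetBondTypeAsDouble()) == op.bond_order:
                raise InapplicableOperationError("bond already has that order")
            bond.SetBondType(_BOND_TYPES[op.bond_order])
            _reset_hs(kek.GetAtomWithIdx(op.atom_idx))
            _reset_hs(kek.GetAtomWithIdx(op.atom_idx2))
        else:  # pragma: no cover
            raise InapplicableOperationError(f"unknown operation {op.kind}")
    except InapplicableOperationError:
        raise
    except Exception as exc:
        raise InapplicableOperationError(f"edit failed: {exc}") from exc

    product = kek.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception as exc:
        raise InapplicableOperationError(f"product fails sanitization: {exc}") from exc
    if num_fragments(product) != 1:
        raise InapplicableOperationError("product is not single-component")
    return product


def random_morph_step(
    mol: Chem.Mol,
    rng: np.random.Generator,
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET,
    max_retries: int = DEFAULT_MAX_RETRIES,
    kinds: frozenset[OpKind] | None = None,
) -> tuple[MorphOperation, Chem.Mol]:
    """Sample and apply one operation by two-stage uniform sampling.

    First a kind is drawn uniformly among kinds with at least one candidate,
    then an instance uniformly within that kind.  A draw whose product fails
    sanitization is discarded and redrawn, up to ``max_retries`` attempts;
    exhaustion raises :class:`DeadEndError`.
    """
    ops = applicable_operations(mol, alphabet, kinds)
    by_kind: dict[OpKind, list[MorphOperation]] = {}
    for op in ops:
        by_kind.setdefault(op.kind, []).append(op)
    if not by_kind:
        raise DeadEndError("no applicable operations")
    for _ in range(max_retries):
        kinds = sorted(by_kind, key=lambda k: k.value)
        kind = kinds[rng.integers(len(kinds))]
        pool = by_kind[kind]
        pick = int(rng.integers(len(pool)))
        op = pool[pick]
        try:
            return op, apply_operation(mol, op)
        except InapplicableOperationError:
            pool.pop(pick)
            if not pool:
                del by_kind[kind]
            if not by_kind:
                break
    raise DeadEndError("all sampled operations failed sanitization")


@dataclass
class MorphPath:
    """One morphing path: the start, the applied steps, and how it ended.

    ``terminal_status`` is HIT (threshold crossed), EXHAUSTED (step cap
    reached without crossing) or DEAD_END (no applicable/sanitizable move,
    or an uncalibrated molecular-weight bin was reached — see ``reason``).
    """

    start: Chem.Mol
    steps: list[tuple[MorphOperation, Chem.Mol]] = field(default_factory=list)
    terminal_status: str = "EXHAUSTED"
    reason: str | None = None
    terminal_complexity: ComplexityVector | None = None

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def terminal(self) -> Chem.Mol:
        return self.steps[-1][1] if self.steps else self.start

    def molecules(self) -> list[Chem.Mol]:
        return [self.start] + [m for _, m in self.steps]


def morph_until_complex(
    start: Chem.Mol,
    table: ThresholdTable,
    cond: StopCondition = StopCondition(),
    max_steps: int = 30,
    rng: np.random.Generator | None = None,
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET,
    max_retries: int = DEFAULT_MAX_RETRIES,
    kinds: frozenset[OpKind] | None = None,
) -> MorphPath:
    """Morph ``start`` until the first threshold crossing (or the step cap).

    After each step the four complexity indices and the molecular weight of
    the new morph are computed; the path returns at the FIRST morph for which
    :func:`hardmorph.calibration.exceeds` is true.  A start that already
    exceeds is returned as a zero-step HIT with a warning.
    """
    if rng is None:
        rng = np.random.default_rng()
    path = MorphPath(start=start)
    try:
        cv = complexity_vector(start)
        if exceeds(cv, mol_weight(start), table, cond):
            logger.warning(
                "starting structure %s already exceeds thresholds",
                canonical_smiles(start),
            )
            path.terminal_status = "HIT"
            path.terminal_complexity = cv
            return path
        current = start
        for _ in range(max_steps):
            try:
                op, nxt = random_morph_step(current, rng, alphabet, max_retries, kinds)
            except DeadEndError as exc:
                path.terminal_status = "DEAD_END"
                path.reason = str(exc)
                return path
            path.steps.append((op, nxt))
            cv = complexity_vector(nxt)
            if exceeds(cv, mol_weight(nxt), table, cond):
                path.terminal_status = "HIT"
                path.terminal_complexity = cv
                return path
            current = nxt
        path.terminal_status = "EXHAUSTED"
        return path
    except UncalibratedBinError as exc:
        logger.warning("path aborted: %s", exc)
        path.terminal_status = "DEAD_END"
        path.reason = f"uncalibrated bin: {exc}"
        return path


def generate_library(
    starts: list[Chem.Mol],
    table: ThresholdTable,
    cond: StopCondition = StopCondition(),
    max_steps: int = 30,
    rng: np.random.Generator | None = None,
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET,
    kinds: frozenset[OpKind] | None = None,
) -> tuple[list[str], list[dict]]:
    """Morph every start and collect the HIT terminals as the hard library.

    Returns ``(hard_smiles, path_records)``: the deduplicated canonical
    SMILES of threshold-crossing terminal morphs, and one bookkeeping record
    per start (start SMILES, terminal status, step count, terminal SMILES).
    Starts that already exceed the thresholds (zero-step hits) are recorded
    but not emitted: they are members of the reference distribution, not
    products of morphing.  Deterministic for a fixed seeded ``rng`` and
    fixed inputs.
    """
    if not starts:
        raise ValueError("empty starting-structure list")
    if rng is None:
        rng = np.random.default_rng()
    hard: list[str] = []
    seen: set[str] = set()
    records: list[dict] = []
    for start in starts:
        path = morph_until_complex(start, table, cond, max_steps, rng, alphabet, kinds=kinds)
        terminal = canonical_smiles(path.terminal)
        records.append(
            {
                "start": canonical_smiles(start),
                "status": path.terminal_status,
                "n_steps": path.n_steps,
                "terminal": terminal,
                "reason": path.reason,
            }
        )
        if path.terminal_status == "HIT" and path.n_steps >= 1 and terminal not in seen:
            seen.add(terminal)
            hard.append(terminal)
    return hard, records
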