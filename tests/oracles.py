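"""Independent brute-force oracles used by the test suite.

The single-edit checker re-derives the expected product graph of a morphing
operation by pure adjacency-list arithmetic (no RDKit editing) and compares
it to the actual product by labeled-graph isomorphism.
"""

from __future__ import annotations

import networkx as nx
from rdkit import Chem

from hardmorph.morphing import MorphOperation, OpKind


def mol_graph(mol: Chem.Mol) -> nx.Graph:
    """Heavy-atom graph with element node labels and integral bond orders."""
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    g = nx.Graph()
    for a in kek.GetAtoms():
        g.add_node(a.GetIdx(), el=a.GetSymbol())
    for b in kek.GetBonds():
        g.add_edge(
            b.GetBeginAtomIdx(), b.GetEndAtomIdx(), o=int(b.GetBondTypeAsDouble())
        )
    return g


def graphs_isomorphic(g1: nx.Graph, g2: nx.Graph) -> bool:
    return nx.is_isomorphic(
        g1,
        g2,
        node_match=lambda a, b: a["el"] == b["el"],
        edge_match=lambda a, b: a["o"] == b["o"],
    )


def expected_graph_after(parent: Chem.Mol, op: MorphOperation) -> nx.Graph:
    """Apply the operation on a plain graph copy of the parent."""
    g = mol_graph(parent)
    if op.kind is OpKind.ADD_ATOM:
        new = max(g.nodes) + 1
        g.add_node(new, el=op.element)
        g.add_edge(op.atom_idx, new, o=1)
    elif op.kind is OpKind.REMOVE_ATOM:
        g.remove_node(op.atom_idx)
    elif op.kind is OpKind.MUTATE_ATOM:
        g.nodes[op.atom_idx]["el"] = op.element
    elif op.kind is OpKind.ADD_BOND:
        g.add_edge(op.atom_idx, op.atom_idx2, o=1)
    elif op.kind is OpKind.REMOVE_BOND:
        g.remove_edge(op.atom_idx, op.atom_idx2)
    elif op.kind is OpKind.MUTATE_BOND:
        g.edges[op.atom_idx, op.atom_idx2]["o"] = op.bond_order
    return g


def is_single_edit(parent: Chem.Mol, op: MorphOperation, child: Chem.Mol) -> bool:
    """True iff the child equals the parent modified by exactly this operation.

    Aromatic re-perception may re-kekulize the product differently; labeled
    isomorphism absorbs the alternative kekule patterns of the same molecule.
    """
    expected = expected_graph_after(parent, op)
    actual = mol_graph(child)
    if graphs_isomorphic(expected, actual):
        return True
    # a different but equivalent kekule assignment of an aromatic system:
    # compare with bond orders collapsed inside aromatic rings
    def collapse(mol):
        g = nx.Graph()
        for a in mol.GetAtoms():
            g.add_node(a.GetIdx(), el=a.GetSymbol())
        for b in mol.GetBonds():
            o = 9 if b.GetIsAromatic() else int(b.GetBondTypeAsDouble())
            g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), o=o)
        return g

    alt = collapse(child)
    # rebuild the expected graph from a sanitized parent copy with aromatic
    # flags intact, then apply the edit on that labeling
    g = collapse(parent)
    try:
        if op.kind is OpKind.ADD_ATOM:
            new = max(g.nodes) + 1
            g.add_node(new, el=op.element)
            g.add_edge(op.atom_idx, new, o=1)
        elif op.kind is OpKind.REMOVE_ATOM:
            g.remove_node(op.atom_idx)
        elif op.kind is OpKind.MUTATE_ATOM:
            g.nodes[op.atom_idx]["el"] = op.element
        elif op.kind is OpKind.ADD_BOND:
            g.add_edge(op.atom_idx, op.atom_idx2, o=1)
        elif op.kind is OpKind.REMOVE_BOND:
            g.remove_edge(op.atom_idx, op.atom_idx2)
        elif op.kind is OpKind.MUTATE_BOND:
            g.edges[op.atom_idx, op.atom_idx2]["o"] = op.bond_order
    except Exception:
        return False
    return graphs_isomorphic(g, alt)


def pairwise_auc(scores, labels) -> float:
    """Mann-Whitney pair statistic: P(random positive > random negative),
    ties counted one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
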