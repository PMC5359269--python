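"""Score a few molecules with the four complexity indices.

Each molecule gets a Bertz (graph information content), Whitlock (weighted
ring/unsaturation/heteroatom/stereocenter count), BC (additive connectivity)
and SMCM (electronegativity-weighted synthetic complexity) value.  Higher
values mean structurally more complex; the morphing engine stops when these
cross library-calibrated thresholds.
"""

import hardmorph as hm

molecules = {
    "ethanol": "CCO",
    "benzene": "c1ccccc1",
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
    "norbornane": "C1CC2CCC1C2",
    "morphine-like scaffold": "CN1CCC23c4c5ccc(O)c4OC2C(O)C=CC3C1C5",
}

print(f"{'molecule':28s} {'MW':>7s} {'Bertz':>8s} {'Whitlock':>8s} {'BC':>6s} {'SMCM':>7s}")
for name, smi in molecules.items():
    m = hm.parse_smiles(smi)
    cv = hm.complexity_vector(m)
    print(
        f"{name:28s} {hm.mol_weight(m):7.1f} {cv.bertz:8.1f} "
        f"{cv.whitlock:8.0f} {cv.bc:6.0f} {cv.smcm:7.1f}"
    )
print(
    "\nAll four indices rise together from simple solvents to fused polycyclic"
    "\nnatural-product scaffolds; each captures a different facet of complexity."
)
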