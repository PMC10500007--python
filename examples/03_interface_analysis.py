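"""Classify interface contacts and scan a homologue for selectivity sites.

Constructs a toy receptor-ligand interface with a planted salt bridge, then
compares the receptor against a homologue carrying a Glu->Lys charge
reversal and a Tyr->Leu packing change — the kind of divergence (E316/K304,
Y185/L174 between integrin beta-subunits) exploited to make a binder
selective for one family member.
"""

import numpy as np

from graftkit.interface import classify_contacts, contact_pairs, selectivity_scan
from graftkit.structio import AtomRecord, Residue, Structure


def residue(chain, num, name, atoms):
    return Residue(chain, num, "", name, [AtomRecord(a, a[0], np.array(p, float)) for a, p in atoms.items()])


receptor_names = ["ALA", "GLY", "GLU", "LEU", "THR", "TYR", "SER", "VAL"]
cplx = Structure(id="complex")
for i, name in enumerate(receptor_names):
    x = 5.0 * i
    rec_atoms = {"CA": [x, 0, 0], "CB": [x, 1.5, 0]}
    if name == "GLU":
        rec_atoms["OE1"] = [x, 2.5, 0]
    cplx.add_residue(residue("B", 300 + i, name, rec_atoms))
    if name == "GLU":
        cplx.add_residue(residue("C", 10 + i, "LYS", {"CA": [x, 4.5, 0], "NZ": [x, 3.2, 0]}))
    else:
        cplx.add_residue(residue("C", 10 + i, "GLY", {"CA": [x, 4.5, 0]}))

contacts = classify_contacts(contact_pairs(cplx, "B", "C", cutoff=4.0), cplx)
print(f"interface: {len(contacts)} residue pairs at 4.0 A")
print(f"  salt bridges: {contacts.count_type('salt_bridge')}, "
      f"hydrogen bonds: {contacts.count_type('hydrogen_bond')}")
# the planted Lys NZ ... Glu OE1 contact (0.7 A inside the 4.0 A salt-bridge
# criterion) is typed as both salt bridge and hydrogen bond; the remaining
# pairs stay generic.

homolog_names = list(receptor_names)
homolog_names[2] = "LYS"   # charge reversal at the Glu position
homolog_names[5] = "LEU"   # bulky-to-small packing change at the Tyr position
homolog = Structure(id="homolog")
for i, name in enumerate(homolog_names):
    homolog.add_residue(residue("B", 500 + i, name, {"CA": [5.0 * i, 0, 0]}))

sites = selectivity_scan(cplx, "C", "B", homolog, "B")
for s in sites:
    r1, r2 = s.position_target1, s.position_target2
    print(f"  site {r1[0][1]} {r1[1]} -> {r2[0][1]} {r2[1]}: {s.class_change}")
# charge_reversal and steric flags mark the interface positions where the
# two targets diverge enough to engineer selectivity.
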