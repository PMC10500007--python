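"""Interface analysis of a deposited minibinder-integrin complex (needs network).

Downloads a cryoEM model of a designed minibinder bound to an integrin
headpiece from the RCSB (e.g. 8TCG), enumerates minibinder-integrin residue
contacts at the default 4.0 A heavy-atom criterion and counts typed
interactions.  Run it only where downloads are possible; every other
example works fully offline.

    python examples/05_deposited_complex_interface.py 8TCG C A,B

Arguments: PDB id, minibinder chain, comma-separated integrin chains (check
the entry's chain naming on RCSB first).
"""

import sys
import urllib.request
from pathlib import Path

from graftkit.interface import classify_contacts, contact_pairs
from graftkit.structio import read_structure

pdb_id = (sys.argv[1] if len(sys.argv) > 1 else "8TCG").lower()
binder_chain = sys.argv[2] if len(sys.argv) > 2 else "C"
integrin_chains = tuple((sys.argv[3] if len(sys.argv) > 3 else "A,B").split(","))

dest = Path(f"{pdb_id}.cif")
if not dest.exists():
    url = f"https://files.rcsb.org/download/{pdb_id}.cif"
    print(f"downloading {url} ...")
    urllib.request.urlretrieve(url, dest)

model = read_structure(dest)
contacts = classify_contacts(
    contact_pairs(model, (binder_chain,), integrin_chains, cutoff=4.0), model
)
print(f"{pdb_id}: {len(contacts)} minibinder-integrin residue pairs at 4.0 A")
print(f"  salt bridges: {contacts.count_type('salt_bridge')}")
print(f"  hydrogen bonds: {contacts.count_type('hydrogen_bond')}")
for p in contacts.pairs:
    if "salt_bridge" in p.types:
        (ka, na), (kb, nb) = p.residue_a, p.residue_b
        print(f"    {na} {ka[0]}{ka[1]} -- {nb} {kb[0]}{kb[1]}  ({p.min_distance:.2f} A)")
# the pair count depends on the distance criterion; 4.0 A heavy-atom is this
# package's default and can be tightened or relaxed via the cutoff argument.
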