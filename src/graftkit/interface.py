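"""Interface contact enumeration, classification and selectivity scanning.

Residue pairs across a protein-protein interface are collected by heavy-atom
distance, typed (hydrogen bond, salt bridge, hydrophobic packing), and
compared between models — e.g. a computational design model against the
experimentally determined structure of the same complex.  A selectivity scan
maps the interface positions of one receptor onto a homologue through a
sequence alignment and flags positions whose residue change could be
exploited for selective binding: formal charge reversals (such as a
glutamate/lysine swap between integrin beta-subunits) and large side-chain
volume changes at packing positions.

Hydrogen bonds are assessed by donor/acceptor heavy-atom distance only,
since the experimental inputs carry no hydrogens; this is a deliberate
simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import ResidueKey, Residue, Structure, kabsch_superpose, neighbor_pairs, select

__all__ = [
    "ContactPair",
    "ContactSet",
    "SelectivitySite",
    "contact_pairs",
    "classify_contacts",
    "compare_interfaces",
    "segment_displacement",
    "selectivity_scan",
    "VOLUME_CLASS",
]

DEFAULT_CONTACT_CUTOFF = 4.0
HBOND_CUTOFF = 3.5
SALT_BRIDGE_CUTOFF = 4.0
HYDROPHOBIC_CUTOFF = 4.5

#: Basic side-chain nitrogens and acidic carboxylate oxygens for salt bridges.
BASIC_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
    "HIS": {"ND1", "NE2"},
}
ACIDIC_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}

#: Apolar residues eligible for the hydrophobic-packing contact type.
APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"}

#: Five-class side-chain volume scale used for the steric-change flag.
VOLUME_CLASS = {
    **{aa: 0 for aa in "GAS"},
    **{aa: 1 for aa in "CTPV"},
    **{aa: 2 for aa in "NDLIMQEH"},
    **{aa: 3 for aa in "KRF"},
    **{aa: 4 for aa in "YW"},
}

CHARGE = {**{aa: -1 for aa in "DE"}, **{aa: +1 for aa in "KR"}}
POLAR = set("STNQYCHKRDE")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass
class ContactPair:
    """One interacting residue pair with its minimum heavy-atom distance."""

    residue_a: tuple[ResidueKey, str]  # (key, residue name)
    residue_b: tuple[ResidueKey, str]
    min_distance: float
    types: set[str] = field(default_factory=lambda: {"generic"})

    @property
    def pair_id(self) -> tuple:
        return (self.residue_a[0], self.residue_b[0])


@dataclass
class ContactSet:
    """Residue pairs across one interface, with the criteria that produced them."""

    pairs: list[ContactPair]
    side_a: tuple[str, ...]
    side_b: tuple[str, ...]
    cutoff: float

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_ids(self) -> set[tuple]:
        return {p.pair_id for p in self.pairs}

    def count_type(self, contact_type: str) -> int:
        return sum(1 for p in self.pairs if contact_type in p.types)


@dataclass
class SelectivitySite:
    """An interface position whose residue differs between two targets."""

    position_target1: tuple[ResidueKey, str]
    position_target2: tuple[ResidueKey, str] | None
    class_change: str  # charge_reversal | steric | polarity | none | unmapped
    at_interface: bool = True


def _one_letter(name: str) -> str:
    return THREE_TO_ONE.get(name.upper(), "X")


def contact_pairs(
    complex_structure: Structure,
    side_a: tuple[str, ...] | list[str] | str,
    side_b: tuple[str, ...] | list[str] | str,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ContactSet:
    """Residue pairs with any heavy-atom distance at or under the cutoff.

    The two sides are disjoint chain groups; each residue pair is reported
    once with its minimum heavy-atom distance.
    """
    side_a = (side_a,) if isinstance(side_a, str) else tuple(side_a)
    side_b = (side_b,) if isinstance(side_b, str) else tuple(side_b)
    if set(side_a) & set(side_b):
        raise ValueError(f"chain groups overlap: {set(side_a) & set(side_b)}")

    def _gather(chains):
        atoms, owners = [], []
        for cid in chains:
            for res in complex_structure.residues(cid):
                for a in res.heavy_atoms():
                    atoms.append(a.position)
                    owners.append((res.key, res.name))
        return np.array(atoms).reshape(-1, 3), owners

    a_xyz, a_own = _gather(side_a)
    b_xyz, b_own = _gather(side_b)
    best: dict[tuple, float] = {}
    names: dict[tuple, tuple] = {}
    if len(a_xyz) and len(b_xyz):
        for i, j, d in neighbor_pairs(a_xyz, b_xyz, cutoff):
            pid = (a_own[i][0], b_own[j][0])
            if d < best.get(pid, np.inf):
                best[pid] = d
                names[pid] = (a_own[i], b_own[j])
    pairs = [
        ContactPair(residue_a=names[pid][0], residue_b=names[pid][1], min_distance=best[pid])
        for pid in sorted(best)
    ]
    return ContactSet(pairs=pairs, side_a=side_a, side_b=side_b, cutoff=cutoff)


def classify_contacts(cs: ContactSet, complex_structure: Structure) -> ContactSet:
    """Assign interaction types to every pair of a ContactSet.

    salt_bridge: basic side-chain N (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2)
    within 4.0 A of a carboxylate O (Asp OD1/OD2; Glu OE1/OE2).
    hydrogen_bond: any N/O to N/O heavy-atom pair within 3.5 A.
    hydrophobic: side-chain carbon to side-chain carbon within 4.5 A between
    apolar residues.  Types are added on top of the generic contact.
    """
    for pair in cs.pairs:
        res_a = complex_structure.residue(pair.residue_a[0])
        res_b = complex_structure.residue(pair.residue_b[0])
        types = {"generic"}
        for r1, r2 in ((res_a, res_b), (res_b, res_a)):
            basic = BASIC_ATOMS.get(r1.name.upper(), set())
            acidic = ACIDIC_ATOMS.get(r2.name.upper(), set())
            for a1 in r1.heavy_atoms():
                if a1.name not in basic:
                    continue
                for a2 in r2.heavy_atoms():
                    if a2.name in acidic and np.linalg.norm(a1.position - a2.position) <= SALT_BRIDGE_CUTOFF:
                        types.add("salt_bridge")
        for a1 in res_a.heavy_atoms():
            if a1.element.upper() not in ("N", "O"):
                continue
            for a2 in res_b.heavy_atoms():
                if a2.element.upper() in ("N", "O") and np.linalg.norm(a1.position - a2.position) <= HBOND_CUTOFF:
                    types.add("hydrogen_bond")
        if res_a.name.upper() in APOLAR_RESIDUES and res_b.name.upper() in APOLAR_RESIDUES:
            for a1 in res_a.heavy_atoms():
                if a1.element.upper() != "C" or a1.name in ("N", "CA", "C", "O"):
                    continue
                for a2 in res_b.heavy_atoms():
                    if (
                        a2.element.upper() == "C"
                        and a2.name not in ("N", "CA", "C", "O")
                        and np.linalg.norm(a1.position - a2.position) <= HYDROPHOBIC_CUTOFF
                    ):
                        types.add("hydrophobic")
        pair.types = types
    return cs


def compare_interfaces(
    model_a: ContactSet,
    model_b: ContactSet,
    key_map: dict[ResidueKey, ResidueKey] | None = None,
) -> dict:
    """Partition two contact sets into shared and model-unique pairs.

    ``key_map`` translates model_a residue keys into model_b's convention
    (e.g. between author numberings of a design model and a deposited
    structure); unmappable keys are reported, never silently dropped.
    """
    unmapped = []

    def _mapped(pid):
        if key_map is None:
            return pid
        out = []
        for key in pid:
            if key in key_map:
                out.append(key_map[key])
            else:
                unmapped.append(key)
                out.append(key)
        return tuple(out)

    ids_a = {_mapped(p.pair_id): p for p in model_a.pairs}
    ids_b = {p.pair_id: p for p in model_b.pairs}
    shared = sorted(set(ids_a) & set(ids_b))
    only_a = sorted(set(ids_a) - set(ids_b))
    only_b = sorted(set(ids_b) - set(ids_a))

    def _type_counts(ids, lookup):
        counts: dict[str, int] = {}
        for pid in ids:
            for t in lookup[pid].types:
                counts[t] = counts.get(t, 0) + 1
        return counts

    return {
        "shared": shared,
        "only_a": only_a,
        "only_b": only_b,
        "shared_types": _type_counts(shared, ids_a),
        "unmapped_keys": unmapped,
    }


def segment_displacement(
    model_a: Structure,
    model_b: Structure,
    frame_selection: str,
    segment_selection: str,
) -> dict:
    """Rigid displacement of a segment between two models sharing a core.

    Both models are superposed on the CA atoms of ``frame_selection`` (the
    common rigid core); the reported displacement is then the segment's CA
    centroid shift, with its projection onto the segment's principal axis in
    model A.  Captures motions such as a C-terminal helix translated along
    its own axis by one helical turn (~3.4 A).
    """

    def _ca(s: Structure, expr: str) -> np.ndarray:
        sub = select(s, f"({expr}) and name CA")
        return np.array([r.atom("CA").position for r in sub.residues()]).reshape(-1, 3)

    frame_a = _ca(model_a, frame_selection)
    frame_b = _ca(model_b, frame_selection)
    seg_a = _ca(model_a, segment_selection)
    seg_b = _ca(model_b, segment_selection)
    if len(seg_a) < 3 or len(seg_b) < 3:
        raise ValueError("segment needs at least 3 CA atoms")
    if frame_a.shape != frame_b.shape or len(frame_a) < 3:
        raise ValueError("frame selections must match and hold at least 3 CA atoms")
    sup = kabsch_superpose(frame_a, frame_b)
    seg_b_aligned = sup.apply(seg_b)
    disp = seg_b_aligned.mean(axis=0) - seg_a.mean(axis=0)
    centered = seg_a - seg_a.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    axial = float(np.dot(disp, axis))
    return {
        "displacement": disp,
        "magnitude": float(np.linalg.norm(disp)),
        "axis": axis,
        "axial_component": axial,
        "frame_rmsd": sup.rmsd,
    }


def _align_sequences(seq1: str, seq2: str) -> list[tuple[int | None, int | None]]:
    """Global affine-gap alignment (BLOSUM62, open 10 / extend 0.5)."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq1, seq2)[0]
    mapping = []
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        for k in range(e1 - s1):
            mapping.append((s1 + k, s2 + k))
    return mapping


def selectivity_scan(
    complex1: Structure,
    ligand_chains: tuple[str, ...] | list[str] | str,
    receptor_chain: str,
    target2: Structure,
    target2_chain: str,
    alignment: dict[int, int] | None = None,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[SelectivitySite]:
    """Scan a homologous target for selectivity-determining interface positions.

    Interface positions of the receptor chain in ``complex1`` (within the
    ligand-contact cutoff) are mapped onto ``target2_chain`` — through an
    explicit ``alignment`` (receptor residue number -> homologue residue
    number, authoritative when known residue correspondences exist) or, by
    default, a global sequence alignment.  Positions with differing residues
    are classified: opposite formal side-chain charge (D/E vs K/R) is a
    charge reversal; a side-chain volume class difference of at least 2 on
    the five-class scale is steric; a polar/apolar change is polarity.
    Unalignable interface positions are reported as unmapped.
    """
    ligand_chains = (ligand_chains,) if isinstance(ligand_chains, str) else tuple(ligand_chains)
    contacts = contact_pairs(complex1, (receptor_chain,), ligand_chains, cutoff=cutoff)
    interface_keys = sorted({p.residue_a[0] for p in contacts.pairs})
    rec_residues = [r for r in complex1.residues(receptor_chain) if r.polymer]
    hom_residues = [r for r in target2.residues(target2_chain) if r.polymer]
    hom_by_number = {r.number: r for r in hom_residues}
    if alignment is None:
        seq1 = "".join(_one_letter(r.name) for r in rec_residues)
        seq2 = "".join(_one_letter(r.name) for r in hom_residues)
        index_map = dict(_align_sequences(seq1, seq2))
        number_map = {
            rec_residues[i].number: hom_residues[j].number for i, j in index_map.items()
        }
    else:
        number_map = dict(alignment)
    sites: list[SelectivitySite] = []
    rec_by_number = {r.number: r for r in rec_residues}
    for key in interface_keys:
        res1 = rec_by_number[key[1]]
        hom_number = number_map.get(res1.number)
        hom_res = hom_by_number.get(hom_number) if hom_number is not None else None
        if hom_res is None:
            sites.append(SelectivitySite((key, res1.name), None, "unmapped"))
            continue
        aa1, aa2 = _one_letter(res1.name), _one_letter(hom_res.name)
        if aa1 == aa2:
            continue
        if CHARGE.get(aa1, 0) * CHARGE.get(aa2, 0) == -1:
            change = "charge_reversal"
        elif abs(VOLUME_CLASS.get(aa1, 2) - VOLUME_CLASS.get(aa2, 2)) >= 2:
            change = "steric"
        elif (aa1 in POLAR) != (aa2 in POLAR):
            change = "polarity"
        else:
            change = "none"
        sites.append(SelectivitySite((key, res1.name), (hom_res.key, hom_res.name), change))
    return sites
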