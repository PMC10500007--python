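import numpy as np
import pytest

from conftest import make_residue, random_rotation
from oracles import brute_force_pairs

from graftkit._build import build_backbone
from graftkit.fixtures import coords_to_structure
from graftkit.interface import (
    classify_contacts,
    compare_interfaces,
    contact_pairs,
    segment_displacement,
    selectivity_scan,
)
from graftkit.structio import Structure


def _two_chain_complex(seed=0, n_atoms=100, box=25.0):
    """Random pseudo-residues (one CA each) split over two chains."""
    rng = np.random.default_rng(seed)
    s = Structure(id="cplx")
    for k in range(n_atoms):
        chain = "A" if k < n_atoms // 2 else "B"
        s.add_residue(make_residue(chain, k + 1, "GLY", {"CA": rng.uniform(0, box, 3)}))
    return s


# ---------------------------------------------------------------------------
# contact enumeration
# ---------------------------------------------------------------------------


def test_single_pair_within_cutoff():
    s = Structure(id="two")
    s.add_residue(make_residue("A", 1, "ALA", {"CA": [0.0, 0.0, 0.0]}))
    s.add_residue(make_residue("B", 1, "GLY", {"CA": [3.5, 0.0, 0.0]}))
    cs = contact_pairs(s, "A", "B", cutoff=4.0)
    assert len(cs) == 1
    assert cs.pairs[0].min_distance == pytest.approx(3.5)


def test_contact_pairs_match_exhaustive_scan():
    s = _two_chain_complex(seed=1, n_atoms=200)
    cs = contact_pairs(s, "A", "B", cutoff=4.0)
    a = np.array([r.atom("CA").position for r in s.residues("A")])
    b = np.array([r.atom("CA").position for r in s.residues("B")])
    expected = {
        (("A", int(i) + 1, ""), ("B", int(j) + 101, ""))
        for i, j in brute_force_pairs(a, b, 4.0)
    }
    assert cs.pair_ids() == expected


def test_contact_pairs_symmetric_under_side_swap():
    s = _two_chain_complex(seed=2)
    ab = contact_pairs(s, "A", "B", cutoff=4.5)
    ba = contact_pairs(s, "B", "A", cutoff=4.5)
    assert {frozenset(p) for p in ab.pair_ids()} == {frozenset(p) for p in ba.pair_ids()}


def test_contact_cutoff_monotonicity():
    s = _two_chain_complex(seed=3)
    tight = contact_pairs(s, "A", "B", cutoff=4.0)
    loose = contact_pairs(s, "A", "B", cutoff=5.0)
    assert tight.pair_ids() <= loose.pair_ids()


def test_overlapping_chain_groups_rejected():
    s = _two_chain_complex(seed=4)
    with pytest.raises(ValueError):
        contact_pairs(s, ("A", "B"), ("B",))


# ---------------------------------------------------------------------------
# contact classification
# ---------------------------------------------------------------------------


def test_lysine_glutamate_pair_is_salt_bridge_and_hbond():
    s = Structure(id="sb")
    s.add_residue(make_residue("A", 1, "LYS", {"CA": [0, 0, 0], "NZ": [5.0, 0, 0]}))
    s.add_residue(make_residue("B", 1, "GLU", {"CA": [11.0, 0, 0], "OE1": [8.0, 0, 0]}))
    cs = classify_contacts(contact_pairs(s, "A", "B", cutoff=4.0), s)
    types = cs.pairs[0].types
    assert "salt_bridge" in types and "hydrogen_bond" in types


def test_apolar_sidechain_carbons_are_hydrophobic():
    s = Structure(id="hp")
    s.add_residue(make_residue("A", 1, "LEU", {"CA": [0, 0, 0], "CD1": [4.0, 0, 0]}))
    s.add_residue(make_residue("B", 1, "TYR", {"CA": [12.0, 0, 0], "CE1": [8.2, 0, 0]}))
    cs = classify_contacts(contact_pairs(s, "A", "B", cutoff=4.5), s)
    assert "hydrophobic" in cs.pairs[0].types
    assert "salt_bridge" not in cs.pairs[0].types


def test_planted_salt_bridges_counted_exactly():
    """Ten generic contacts, two of them genuine salt bridges."""
    s = Structure(id="mix")
    for k in range(10):
        y = 10.0 * k
        if k < 2:  # Lys...Glu at 3.0 A
            s.add_residue(make_residue("A", k + 1, "LYS", {"CA": [0, y, 0], "NZ": [2.0, y, 0]}))
            s.add_residue(make_residue("B", k + 1, "GLU", {"CA": [7.0, y, 0], "OE1": [5.0, y, 0]}))
        else:  # plain backbone-ish contacts
            s.add_residue(make_residue("A", k + 1, "ALA", {"CA": [0, y, 0], "CB": [2.0, y, 0]}))
            s.add_residue(make_residue("B", k + 1, "SER", {"CA": [7.0, y, 0], "CB": [5.0, y, 0]}))
    cs = classify_contacts(contact_pairs(s, "A", "B", cutoff=4.0), s)
    assert len(cs) == 10
    assert cs.count_type("salt_bridge") == 2


def test_every_typed_pair_is_in_generic_set():
    s = Structure(id="sb2")
    s.add_residue(make_residue("A", 1, "ARG", {"CA": [0, 0, 0], "NH1": [2.5, 0, 0]}))
    s.add_residue(make_residue("B", 1, "ASP", {"CA": [8.0, 0, 0], "OD1": [5.5, 0, 0]}))
    cs = classify_contacts(contact_pairs(s, "A", "B", cutoff=4.0), s)
    for p in cs.pairs:
        assert "generic" in p.types


# ---------------------------------------------------------------------------
# interface comparison
# ---------------------------------------------------------------------------


def test_identical_sets_fully_shared():
    s = _two_chain_complex(seed=5)
    cs = contact_pairs(s, "A", "B", cutoff=4.5)
    result = compare_interfaces(cs, cs)
    assert len(result["shared"]) == len(cs)
    assert result["only_a"] == [] and result["only_b"] == []


def test_removing_pairs_shrinks_shared_set():
    s = _two_chain_complex(seed=6, n_atoms=300, box=20.0)
    full = contact_pairs(s, "A", "B", cutoff=5.0)
    assert len(full) > 4
    import copy

    reduced = copy.deepcopy(full)
    reduced.pairs = reduced.pairs[:-2]
    result = compare_interfaces(full, reduced)
    assert len(result["shared"]) == len(full) - 2
    assert len(result["only_a"]) == 2 and result["only_b"] == []


def test_random_deletions_match_set_algebra():
    rng = np.random.default_rng(7)
    s = _two_chain_complex(seed=7, n_atoms=300, box=20.0)
    full = contact_pairs(s, "A", "B", cutoff=5.0)
    import copy

    for _ in range(20):
        a = copy.deepcopy(full)
        b = copy.deepcopy(full)
        a.pairs = [p for p in a.pairs if rng.random() > 0.3]
        b.pairs = [p for p in b.pairs if rng.random() > 0.3]
        result = compare_interfaces(a, b)
        ia, ib = a.pair_ids(), b.pair_ids()
        assert set(result["shared"]) == ia & ib
        assert set(result["only_a"]) == ia - ib
        assert set(result["only_b"]) == ib - ia


def test_key_mapping_reconciles_numbering():
    s1 = Structure(id="m1")
    s1.add_residue(make_residue("A", 10, "ALA", {"CA": [0, 0, 0]}))
    s1.add_residue(make_residue("B", 20, "GLY", {"CA": [3.0, 0, 0]}))
    s2 = Structure(id="m2")
    s2.add_residue(make_residue("A", 110, "ALA", {"CA": [0, 0, 0]}))
    s2.add_residue(make_residue("B", 120, "GLY", {"CA": [3.0, 0, 0]}))
    cs1 = contact_pairs(s1, "A", "B", cutoff=4.0)
    cs2 = contact_pairs(s2, "A", "B", cutoff=4.0)
    key_map = {("A", 10, ""): ("A", 110, ""), ("B", 20, ""): ("B", 120, "")}
    result = compare_interfaces(cs1, cs2, key_map=key_map)
    assert len(result["shared"]) == 1 and result["unmapped_keys"] == []


# ---------------------------------------------------------------------------
# segment displacement
# ---------------------------------------------------------------------------


def _helix_model(n=20):
    return coords_to_structure(build_backbone(np.full(n, -57.0), np.full(n, -47.0)))


def test_identical_models_show_zero_displacement():
    m = _helix_model()
    out = segment_displacement(m, m, "resi 1-10", "resi 11-20")
    assert out["magnitude"] < 1e-9


def test_axial_helix_translation_recovered():
    """A C-terminal helix shifted one helical turn along its own axis."""
    a = _helix_model()
    b = a.copy()
    seg = [r for r in b.residues() if 11 <= r.number <= 20]
    ca = np.array([r.atom("CA").position for r in seg])
    centered = ca - ca.mean(axis=0)
    axis = np.linalg.svd(centered)[2][0]
    for r in seg:
        for atom in r.atoms:
            atom.position = atom.position + 3.4 * axis
    out = segment_displacement(a, b, "resi 1-10", "resi 11-20")
    assert abs(abs(out["axial_component"]) - 3.4) < 0.01
    assert out["magnitude"] == pytest.approx(3.4, abs=0.01)


def test_orthogonal_translation_has_no_axial_component():
    a = _helix_model()
    b = a.copy()
    seg = [r for r in b.residues() if 11 <= r.number <= 20]
    ca = np.array([r.atom("CA").position for r in seg])
    axis = np.linalg.svd(ca - ca.mean(axis=0))[2][0]
    ortho = np.cross(axis, [0.0, 0.0, 1.0])
    ortho /= np.linalg.norm(ortho)
    for r in seg:
        for atom in r.atoms:
            atom.position = atom.position + 2.5 * ortho
    out = segment_displacement(a, b, "resi 1-10", "resi 11-20")
    assert abs(out["axial_component"]) < 0.05
    assert out["magnitude"] == pytest.approx(2.5, abs=0.01)


def test_degenerate_segment_rejected():
    m = _helix_model()
    with pytest.raises(ValueError):
        segment_displacement(m, m, "resi 1-10", "resi 19-20")


# ---------------------------------------------------------------------------
# selectivity scanning
# ---------------------------------------------------------------------------


def _receptor_ligand_complex(receptor_names):
    """A receptor chain B with CB probes facing a short ligand chain C."""
    s = Structure(id="cplx")
    for i, name in enumerate(receptor_names):
        x = 5.0 * i
        s.add_residue(
            make_residue("B", 300 + i, name, {"CA": [x, 0.0, 0.0], "CB": [x, 1.5, 0.0]})
        )
    for i in range(len(receptor_names)):
        x = 5.0 * i
        s.add_residue(make_residue("C", 10 + i, "GLY", {"CA": [x, 4.5, 0.0]}))
    return s


def _homolog(names, start=500):
    s = Structure(id="hom")
    for i, name in enumerate(names):
        s.add_residue(make_residue("B", start + i, name, {"CA": [5.0 * i, 0.0, 0.0]}))
    return s


RECEPTOR = ["ALA", "GLY", "GLU", "LEU", "THR", "TYR", "SER", "VAL"]


def test_identical_homolog_yields_no_sites():
    s = _receptor_ligand_complex(RECEPTOR)
    hom = _homolog(RECEPTOR)
    sites = selectivity_scan(s, "C", "B", hom, "B")
    assert sites == []


def test_charge_reversal_detected():
    """Glu on target 1 vs Lys on target 2 at an interface position."""
    s = _receptor_ligand_complex(RECEPTOR)
    names2 = list(RECEPTOR)
    names2[2] = "LYS"  # E -> K
    hom = _homolog(names2)
    sites = selectivity_scan(s, "C", "B", hom, "B")
    assert len(sites) == 1
    site = sites[0]
    assert site.class_change == "charge_reversal"
    assert site.position_target1[1] == "GLU" and site.position_target2[1] == "LYS"


def test_steric_change_detected_at_packing_position():
    """Tyr vs Leu mirrors the SDL2 packing difference between targets."""
    s = _receptor_ligand_complex(RECEPTOR)
    names2 = list(RECEPTOR)
    names2[5] = "LEU"  # Y -> L
    hom = _homolog(names2)
    sites = selectivity_scan(s, "C", "B", hom, "B")
    assert [x.class_change for x in sites] == ["steric"]


def test_explicit_mapping_overrides_alignment():
    s = _receptor_ligand_complex(RECEPTOR)
    names2 = list(RECEPTOR)
    names2[2] = "LYS"
    hom = _homolog(names2, start=700)
    mapping = {300 + i: 700 + i for i in range(len(RECEPTOR))}
    sites = selectivity_scan(s, "C", "B", hom, "B", alignment=mapping)
    assert len(sites) == 1 and sites[0].class_change == "charge_reversal"
    assert sites[0].position_target2[0] == ("B", 702, "")


def test_unmapped_interface_position_reported():
    s = _receptor_ligand_complex(RECEPTOR)
    hom = _homolog(["ALA", "GLY"])  # too short to cover all interface positions
    mapping = {300: 500, 301: 501}
    sites = selectivity_scan(s, "C", "B", hom, "B", alignment=mapping)
    unmapped = [x for x in sites if x.class_change == "unmapped"]
    assert len(unmapped) == len(RECEPTOR) - 2
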