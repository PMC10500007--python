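import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_residue, random_rotation
from oracles import brute_force_pairs, quaternion_rmsd

from graftkit._build import build_backbone
from graftkit.fixtures import coords_to_structure
from graftkit.structio import (
    DegenerateGeometryError,
    SelectionSyntaxError,
    Structure,
    StructureFormatError,
    kabsch_superpose,
    measure_torsions,
    neighbor_pairs,
    read_structure,
    select,
    write_structure,
)


# ---------------------------------------------------------------------------
# file round trips
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("dialect,suffix", [("pdb", ".pdb"), ("mmcif", ".cif")])
def test_write_read_round_trip(helix_structure, tmp_path, dialect, suffix):
    path = tmp_path / f"model{suffix}"
    write_structure(helix_structure, path, dialect)
    back = read_structure(path)
    assert back.source_format == dialect
    orig = list(helix_structure.atoms())
    got = list(back.atoms())
    assert len(orig) == len(got)
    for (r1, a1), (r2, a2) in zip(orig, got):
        assert r1.key == r2.key and r1.name == r2.name and a1.name == a2.name
        assert np.abs(a1.position - a2.position).max() <= 1e-3


def test_double_round_trip_is_stable(helix_structure, tmp_path):
    """write -> read -> write -> read preserves coordinates exactly after the first write."""
    p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
    write_structure(helix_structure, p1, "pdb")
    s1 = read_structure(p1)
    write_structure(s1, p2, "pdb")
    s2 = read_structure(p2)
    for (_, a1), (_, a2) in zip(s1.atoms(), s2.atoms()):
        assert np.array_equal(a1.position, a2.position)


def test_empty_structure_round_trip(tmp_path):
    path = tmp_path / "empty.pdb"
    write_structure(Structure(id="empty"), path, "pdb")
    assert read_structure(path).n_atoms == 0


def test_long_chain_id_rejected_in_pdb(tmp_path):
    s = Structure(id="x")
    s.add_residue(make_residue("LONGCHAIN", 1, "GLY", {"CA": [0, 0, 0]}))
    with pytest.raises(StructureFormatError):
        write_structure(s, tmp_path / "x.pdb", "pdb")


def test_unreadable_file_raises(tmp_path):
    bad = tmp_path / "bad.cif"
    bad.write_text("this is not a structure file\n")
    with pytest.raises(Exception):
        read_structure(bad, dialect="mmcif")


def test_altloc_resolution_keeps_highest_occupancy(tmp_path):
    pdb_text = (
        "ATOM      1  CA ASER A   1      11.000  22.000  33.000  0.40 10.00           C\n"
        "ATOM      2  CA BSER A   1      44.000  55.000  66.000  0.60 10.00           C\n"
        "END\n"
    )
    path = tmp_path / "alt.pdb"
    path.write_text(pdb_text)
    s = read_structure(path)
    res = s.chain("A")[0]
    cas = [a for a in res.atoms if a.name == "CA"]
    assert len(cas) == 1
    assert np.allclose(cas[0].position, [44.0, 55.0, 66.0])  # occupancy 0.6 wins


def test_altloc_tie_prefers_altloc_a(tmp_path):
    pdb_text = (
        "ATOM      1  CA BSER A   1      44.000  55.000  66.000  0.50 10.00           C\n"
        "ATOM      2  CA ASER A   1      11.000  22.000  33.000  0.50 10.00           C\n"
        "END\n"
    )
    path = tmp_path / "alt.pdb"
    path.write_text(pdb_text)
    res = read_structure(path).chain("A")[0]
    assert np.allclose(res.atom("CA").position, [11.0, 22.0, 33.0])


def test_heteroatoms_flagged_non_polymer(tmp_path):
    pdb_text = (
        "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00 10.00           C\n"
        "HETATM    2 MG    MG A 201       5.000   5.000   5.000  1.00 10.00          MG\n"
        "END\n"
    )
    path = tmp_path / "het.pdb"
    path.write_text(pdb_text)
    residues = list(read_structure(path).residues())
    flags = {r.name: r.polymer for r in residues}
    assert flags["GLY"] is True and flags["MG"] is False


def test_large_model_io_speed(tmp_path):
    import time

    n = 2500  # 10,000 atoms at 4 backbone atoms per residue
    coords = build_backbone(np.full(n, -120.0), np.full(n, 130.0))
    s = coords_to_structure(coords, structure_id="big")
    t0 = time.time()
    path = tmp_path / "big.pdb"
    write_structure(s, path, "pdb")
    back = read_structure(path)
    assert back.n_atoms == 10_000
    assert time.time() - t0 < 5.0


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------


def test_selection_chain_and_residue_range():
    s = Structure(id="sel")
    for num in range(180, 200):
        s.add_residue(make_residue("B", num, "ALA", {"CA": [num, 0, 0]}))
        s.add_residue(make_residue("C", num, "GLY", {"CA": [num, 5, 0]}))
    view = select(s, "chain B and resi 180-190")
    assert len(list(view.residues())) == 11
    assert all(r.chain_id == "B" for r in view.residues())


def test_selection_backbone_returns_n_ca_c_o(helix_structure):
    view = select(helix_structure, "backbone")
    for res in view.residues():
        assert [a.name for a in res.atoms] == ["N", "CA", "C", "O"]


def test_selection_by_residue_name_mimics_author_numbering():
    """A beta-6-like chain where author position 316 is a glutamate."""
    s = Structure(id="b6")
    for num, name in [(315, "ALA"), (316, "GLU"), (317, "LYS")]:
        s.add_residue(make_residue("B", num, name, {"CA": [num, 0, 0]}))
    view = select(s, "chain B and resi 316")
    (res,) = list(view.residues())
    assert res.name == "GLU"


def test_selection_empty_is_valid(helix_structure):
    assert list(select(helix_structure, "chain Z").residues()) == []


def test_selection_syntax_error_reports_position():
    s = Structure(id="x")
    with pytest.raises(SelectionSyntaxError) as exc:
        select(s, "chain A and bogus")
    assert exc.value.position == 12


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def test_kabsch_identity():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(10, 3))
    res = kabsch_superpose(pts, pts)
    assert res.rmsd < 1e-12
    assert np.allclose(res.rotation, np.eye(3), atol=1e-9)


def test_kabsch_recovers_pure_rigid_transform():
    rng = np.random.default_rng(1)
    fixed = rng.normal(size=(8, 3))
    Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])  # 90 deg about z
    mobile = fixed @ Rz.T + np.array([3.0, -2.0, 7.0])
    res = kabsch_superpose(fixed, mobile)
    assert res.rmsd < 1e-12
    assert np.allclose(res.apply(mobile), fixed, atol=1e-9)


def test_kabsch_matches_quaternion_oracle_and_is_symmetric():
    rng = np.random.default_rng(2)
    for _ in range(100):
        n = int(rng.integers(4, 30))
        a = rng.normal(scale=5.0, size=(n, 3))
        b = rng.normal(scale=5.0, size=(n, 3))
        r_ab = kabsch_superpose(a, b)
        assert abs(r_ab.rmsd - quaternion_rmsd(a, b)) < 1e-9
        assert abs(r_ab.rmsd - kabsch_superpose(b, a).rmsd) < 1e-9
        assert np.linalg.det(r_ab.rotation) == pytest.approx(1.0, abs=1e-9)


@settings(deadline=None, max_examples=25)
@given(st.integers(min_value=0, max_value=10_000))
def test_kabsch_rmsd_invariant_under_joint_rigid_motion(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(7, 3))
    b = rng.normal(size=(7, 3))
    base = kabsch_superpose(a, b).rmsd
    R = random_rotation(rng)
    t = rng.uniform(-50, 50, 3)
    moved = kabsch_superpose(a @ R.T + t, b @ R.T + t).rmsd
    assert abs(base - moved) < 1e-9


def test_kabsch_rejects_degenerate_inputs():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    cloud = np.random.default_rng(0).normal(size=(5, 3))
    with pytest.raises(DegenerateGeometryError):
        kabsch_superpose(line, cloud)
    with pytest.raises(DegenerateGeometryError):
        kabsch_superpose(cloud, cloud[:4])


def test_kabsch_transform_reproduces_reported_rmsd():
    rng = np.random.default_rng(3)
    a = rng.normal(size=(12, 3))
    b = rng.normal(size=(12, 3))
    res = kabsch_superpose(a, b)
    moved = res.apply(b)
    direct = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    assert abs(direct - res.rmsd) < 1e-9


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------


def test_trans_and_cis_omega():
    for omega_set, expected in [(180.0, 180.0), (0.0, 0.0)]:
        coords = build_backbone(
            np.full(3, -120.0), np.full(3, 130.0), omega=np.full(3, omega_set)
        )
        s = coords_to_structure(coords)
        ts = measure_torsions(s, "A")
        for val in ts.omega[1:]:
            assert abs(val - expected) < 1e-6 or abs(abs(val) - 180.0) < 1e-6 and expected == 180.0


def test_helix_torsion_round_trip(helix_structure):
    ts = measure_torsions(helix_structure, "A")
    for phi in ts.phi[1:]:
        assert phi == pytest.approx(-57.0, abs=1e-6)
    for psi in ts.psi[:-1]:
        assert psi == pytest.approx(-47.0, abs=1e-6)


def test_chain_break_leaves_torsions_undefined():
    coords = build_backbone(np.full(6, -120.0), np.full(6, 130.0))
    coords[3:] += np.array([50.0, 0.0, 0.0])  # break between residues 3 and 4
    s = coords_to_structure(coords)
    ts = measure_torsions(s, "A")
    assert ts.psi[2] is None and ts.phi[3] is None and ts.omega[3] is None
    assert ts.phi[2] is not None and ts.psi[3] is not None


def test_terminal_torsions_undefined(helix_structure):
    ts = measure_torsions(helix_structure, "A")
    assert ts.phi[0] is None and ts.omega[0] is None and ts.psi[-1] is None


# ---------------------------------------------------------------------------
# neighbor search
# ---------------------------------------------------------------------------


def test_neighbor_pairs_cutoff_boundary():
    a = np.array([[0.0, 0.0, 0.0]])
    assert len(neighbor_pairs(a, np.array([[3.99, 0, 0]]), 4.0)) == 1
    assert len(neighbor_pairs(a, np.array([[4.01, 0, 0]]), 4.0)) == 0


def test_neighbor_pairs_empty_inputs():
    assert neighbor_pairs(np.empty((0, 3)), np.ones((3, 3)), 4.0) == []


def test_neighbor_pairs_equals_brute_force():
    rng = np.random.default_rng(4)
    for _ in range(100):
        na, nb = int(rng.integers(1, 60)), int(rng.integers(1, 60))
        a = rng.uniform(0, 30, size=(na, 3))
        b = rng.uniform(0, 30, size=(nb, 3))
        cutoff = float(rng.uniform(2.0, 10.0))
        got = {(i, j) for i, j, _ in neighbor_pairs(a, b, cutoff)}
        assert got == brute_force_pairs(a, b, cutoff)


def test_neighbor_pairs_large_matches_brute_force():
    rng = np.random.default_rng(5)
    a = rng.uniform(0, 50, size=(1000, 3))
    b = rng.uniform(0, 50, size=(1000, 3))
    got = {(i, j) for i, j, _ in neighbor_pairs(a, b, 4.0)}
    assert got == brute_force_pairs(a, b, 4.0)
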