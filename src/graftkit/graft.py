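"""Docking matched scaffolds into the target frame, clash screening and splicing.

A harvested scaffold window is rigidly superposed onto the bound motif
conformation, carrying the whole scaffold into the frame of the target
complex.  Scaffolds whose backbone collides with the target are discarded
(the "backbone level clash" screen), survivors receive the motif backbone by
splicing, and the motif-region torsions are verified against the reference
conformation observed in the co-crystal structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motif_search import MotifMatch, MotifQuery
from .structio import (
    AtomRecord,
    BACKBONE_ATOMS,
    Residue,
    ResidueKey,
    Structure,
    TorsionSet,
    neighbor_pairs,
)

__all__ = [
    "ClashReport",
    "GraftModel",
    "ConstraintReport",
    "dock_by_motif",
    "clash_filter",
    "splice_motif",
    "check_torsion_constraints",
    "circular_difference",
]

#: Default clash cutoff (A) between screened scaffold backbone atoms and any
#: target heavy atom; approximates severe van der Waals overlap.
DEFAULT_CLASH_CUTOFF = 3.0

#: Junction acceptance windows for a trans peptide seam.
JUNCTION_C_N = (1.13, 1.53)
JUNCTION_CA_CA = (3.3, 4.3)


@dataclass
class ClashReport:
    """Outcome of the backbone-level clash screen for one docked scaffold."""

    clash_pairs: list[tuple[tuple[ResidueKey, str], tuple[ResidueKey, str], float]]
    cutoff: float
    mode: str
    clash_limit: int = 1

    @property
    def n_clashes(self) -> int:
        return len(self.clash_pairs)

    @property
    def verdict(self) -> str:
        return "discarded" if self.n_clashes >= self.clash_limit else "retained"


@dataclass
class GraftModel:
    """A scaffold with the motif backbone spliced in, plus seam geometry."""

    model: Structure
    window_keys: list[ResidueKey]
    junctions: dict[str, dict]
    constraint_report: "ConstraintReport | None" = None

    @property
    def junctions_ok(self) -> bool:
        return all(j["ok"] for j in self.junctions.values())


@dataclass
class ConstraintReport:
    """Per-residue circular torsion deviations from a reference conformation."""

    entries: list[dict]
    tolerance: float

    @property
    def violations(self) -> list[dict]:
        return [e for e in self.entries if e["violation"]]

    @property
    def max_deviation(self) -> float:
        devs = [
            d
            for e in self.entries
            for d in (e["dphi"], e["dpsi"])
            if d is not None
        ]
        return max(devs) if devs else 0.0


def dock_by_motif(
    scaffold: Structure, match: MotifMatch, complex_frame: Structure | None = None
) -> Structure:
    """Rigidly place a scaffold so its matched window sits on the bound motif.

    The transform recorded on the match (window -> query frame) is applied to
    every atom of the scaffold.  ``complex_frame`` is accepted for interface
    symmetry with the pipeline and is not modified.  A match whose window
    residues are not present in the scaffold (same keys, same coordinates)
    raises ``ValueError``.
    """
    for res in match.residues:
        try:
            own = scaffold.residue(res.key)
        except KeyError as exc:
            raise ValueError(f"match window residue {res.key} not in scaffold {scaffold.id!r}") from exc
        if not own.backbone_complete or not np.allclose(own.backbone(), res.backbone(), atol=1e-6):
            raise ValueError(
                f"match window residue {res.key} does not coincide with scaffold {scaffold.id!r}"
            )
    return scaffold.transform(match.transform.rotation, match.transform.translation)


def clash_filter(
    docked: Structure,
    target: Structure,
    cutoff: float = DEFAULT_CLASH_CUTOFF,
    mode: str = "backbone",
    motif_keys: set[ResidueKey] | frozenset[ResidueKey] = frozenset(),
    clash_limit: int = 1,
) -> ClashReport:
    """Screen a docked scaffold against the target for steric collisions.

    In ``backbone`` mode only N, CA, C, O of the scaffold are screened; in
    ``all-heavy`` mode every heavy scaffold atom is.  Residues named in
    ``motif_keys`` are exempt (they are the designed contact); hydrogens are
    never screened on either side.  The verdict is ``discarded`` when the
    clash count reaches ``clash_limit``.
    """
    if mode not in ("backbone", "all-heavy"):
        raise ValueError(f"unknown clash mode {mode!r}")
    s_atoms: list[tuple[ResidueKey, str, np.ndarray]] = []
    for res in docked.residues():
        if res.key in motif_keys:
            continue
        for a in res.heavy_atoms():
            if mode == "backbone" and a.name not in BACKBONE_ATOMS:
                continue
            s_atoms.append((res.key, a.name, a.position))
    t_atoms = [
        (res.key, a.name, a.position) for res in target.residues() for a in res.heavy_atoms()
    ]
    pairs = []
    if s_atoms and t_atoms:
        a = np.array([p for _, _, p in s_atoms])
        b = np.array([p for _, _, p in t_atoms])
        for i, j, d in neighbor_pairs(a, b, cutoff):
            pairs.append(((s_atoms[i][0], s_atoms[i][1]), (t_atoms[j][0], t_atoms[j][1]), d))
    return ClashReport(clash_pairs=pairs, cutoff=cutoff, mode=mode, clash_limit=clash_limit)


def _junction(prev: Residue | None, nxt: Residue | None) -> dict | None:
    if prev is None or nxt is None:
        return None
    c = prev.atom("C")
    n = nxt.atom("N")
    ca1 = prev.atom("CA")
    ca2 = nxt.atom("CA")
    if None in (c, n, ca1, ca2):
        return None
    c_n = float(np.linalg.norm(c.position - n.position))
    ca_ca = float(np.linalg.norm(ca1.position - ca2.position))
    ok = JUNCTION_C_N[0] <= c_n <= JUNCTION_C_N[1] and JUNCTION_CA_CA[0] <= ca_ca <= JUNCTION_CA_CA[1]
    return {"c_n": c_n, "ca_ca": ca_ca, "ok": ok}


def splice_motif(
    scaffold: Structure, window: tuple[str, int, int], motif: MotifQuery
) -> GraftModel:
    """Replace a scaffold window's backbone with the motif backbone.

    ``window`` is (chain id, first residue number, last residue number) in
    author numbering.  Replaced residues lose their side chains and take the
    motif residue names; seam geometry (C--N bond and CA--CA distance at each
    junction) is measured and flagged if outside the trans-peptide window,
    never silently repaired.
    """
    chain_id, start, end = window
    model = scaffold.copy()
    chain = model.chain(chain_id)
    idx = [i for i, r in enumerate(chain) if start <= r.number <= end]
    if len(idx) != len(motif):
        raise ValueError(
            f"window {chain_id}:{start}-{end} has {len(idx)} residues; motif core has {len(motif)}"
        )
    element_of = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    for k, i in enumerate(idx):
        old = chain[i]
        atoms = [
            AtomRecord(name, element_of[name], motif.core_coords[k, j].copy())
            for j, name in enumerate(BACKBONE_ATOMS)
        ]
        chain[i] = Residue(old.chain_id, old.number, old.insertion_code, motif.sequence[k], atoms, old.polymer)
    junctions = {}
    jn = _junction(chain[idx[0] - 1] if idx[0] > 0 else None, chain[idx[0]])
    jc = _junction(chain[idx[-1]], chain[idx[-1] + 1] if idx[-1] + 1 < len(chain) else None)
    if jn is not None:
        junctions["n_seam"] = jn
    if jc is not None:
        junctions["c_seam"] = jc
    return GraftModel(model=model, window_keys=[chain[i].key for i in idx], junctions=junctions)


def circular_difference(a: float, b: float) -> float:
    """Absolute circular difference of two angles in degrees, in [0, 180]."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


def check_torsion_constraints(
    measured: TorsionSet, reference: TorsionSet, tolerance: float
) -> ConstraintReport:
    """Compare motif-region torsions to the reference conformation.

    Entries are matched positionally (the grafted window and the reference
    motif have the same length by construction); deviations are circular
    differences of phi and psi, and a residue is a violation when either
    defined deviation exceeds ``tolerance`` degrees.  Torsions undefined on
    either side (termini, chain breaks) are skipped, not flagged.
    """
    if len(measured) != len(reference):
        raise ValueError(
            f"torsion sets differ in length ({len(measured)} vs {len(reference)})"
        )
    entries = []
    for i, key in enumerate(measured.keys):
        dphi = (
            circular_difference(measured.phi[i], reference.phi[i])
            if measured.phi[i] is not None and reference.phi[i] is not None
            else None
        )
        dpsi = (
            circular_difference(measured.psi[i], reference.psi[i])
            if measured.psi[i] is not None and reference.psi[i] is not None
            else None
        )
        violation = any(d is not None and d > tolerance for d in (dphi, dpsi))
        entries.append({"key": key, "dphi": dphi, "dpsi": dpsi, "violation": violation})
    return ConstraintReport(entries=entries, tolerance=tolerance)
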