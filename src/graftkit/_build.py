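"""Internal-coordinate peptide backbone construction (NeRF extension).

Chains are grown atom by atom from ideal bond lengths and angles, with all
conformational freedom carried by the backbone torsions.  The same ideal
values are used by the synthetic-structure builder and by loop remodelling,
so a chain rebuilt from its measured torsions reproduces them exactly.
"""

from __future__ import annotations

import math

import numpy as np

# ideal backbone internal coordinates (lengths in Angstrom, angles in degrees)
IDEAL = {
    "N-CA": 1.458,
    "CA-C": 1.525,
    "C-N": 1.329,
    "C-O": 1.231,
    "N-CA-C": 111.2,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "CA-C-O": 120.5,
    "OMEGA": 180.0,
}


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float
) -> np.ndarray:
    """Position atom D from frame atoms A, B, C.

    ``bond`` is |C-D|, ``angle`` the B-C-D angle and ``torsion`` the
    A-B-C-D dihedral, both in degrees.
    """
    theta = math.radians(angle)
    chi = math.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * math.cos(theta), bond * math.sin(theta) * math.cos(chi), -bond * math.sin(theta) * math.sin(chi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi: np.ndarray,
    psi: np.ndarray,
    omega: np.ndarray | None = None,
    first_frame: np.ndarray | None = None,
) -> np.ndarray:
    """Build an n-residue backbone, returning an (n, 4, 3) array of N, CA, C, O.

    ``phi[0]`` and ``omega[0]`` are only used when ``first_frame`` (a (3, 3)
    array holding N, CA, C of a preceding, already-placed residue plus its
    psi packed separately via :func:`extend_backbone`) is given; for a free
    chain the first residue is placed canonically at the origin.
    ``psi[i]`` orients the carbonyl oxygen of residue i (O dihedral =
    psi + 180) and, except for the last residue, places the next amide
    nitrogen.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n = len(phi)
    if len(psi) != n:
        raise ValueError("phi and psi must have equal length")
    if omega is None:
        omega = np.full(n, IDEAL["OMEGA"])
    omega = np.asarray(omega, dtype=float)
    coords = np.zeros((n, 4, 3))
    # first residue: N at origin, CA on x, C in the xy-plane
    N0 = np.zeros(3)
    CA0 = np.array([IDEAL["N-CA"], 0.0, 0.0])
    ang = math.radians(IDEAL["N-CA-C"])
    C0 = CA0 + IDEAL["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    coords[0, 0], coords[0, 1], coords[0, 2] = N0, CA0, C0
    for i in range(n - 1):
        N_i, CA_i, C_i = coords[i, 0], coords[i, 1], coords[i, 2]
        N_next = place_atom(N_i, CA_i, C_i, IDEAL["C-N"], IDEAL["CA-C-N"], psi[i])
        CA_next = place_atom(CA_i, C_i, N_next, IDEAL["N-CA"], IDEAL["C-N-CA"], omega[i + 1])
        C_next = place_atom(C_i, N_next, CA_next, IDEAL["CA-C"], IDEAL["N-CA-C"], phi[i + 1])
        coords[i + 1, 0], coords[i + 1, 1], coords[i + 1, 2] = N_next, CA_next, C_next
    for i in range(n):
        coords[i, 3] = place_atom(
            coords[i, 0], coords[i, 1], coords[i, 2], IDEAL["C-O"], IDEAL["CA-C-O"], psi[i] + 180.0
        )
    return coords


def extend_backbone(
    anchor_nca: np.ndarray,
    psi_anchor: float,
    phi: np.ndarray,
    psi: np.ndarray,
    omega: np.ndarray | None = None,
) -> np.ndarray:
    """Grow n new residues after an existing residue whose N, CA, C are fixed.

    ``psi_anchor`` is the torsion placing the first new nitrogen; each new
    residue i is then placed by omega[i] (CA), phi[i] (C) and psi[i] (O and
    the following N).  Returns (n, 4, 3) N, CA, C, O coordinates of the new
    residues only.
    """
    anchor_nca = np.asarray(anchor_nca, dtype=float)
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n = len(phi)
    if omega is None:
        omega = np.full(n, IDEAL["OMEGA"])
    omega = np.asarray(omega, dtype=float)
    coords = np.zeros((n, 4, 3))
    N_p, CA_p, C_p = anchor_nca
    psi_prev = psi_anchor
    for i in range(n):
        N_i = place_atom(N_p, CA_p, C_p, IDEAL["C-N"], IDEAL["CA-C-N"], psi_prev)
        CA_i = place_atom(CA_p, C_p, N_i, IDEAL["N-CA"], IDEAL["C-N-CA"], omega[i])
        C_i = place_atom(C_p, N_i, CA_i, IDEAL["CA-C"], IDEAL["N-CA-C"], phi[i])
        coords[i, 0], coords[i, 1], coords[i, 2] = N_i, CA_i, C_i
        N_p, CA_p, C_p = N_i, CA_i, C_i
        psi_prev = psi[i]
    for i in range(n):
        coords[i, 3] = place_atom(
            coords[i, 0], coords[i, 1], coords[i, 2], IDEAL["C-O"], IDEAL["CA-C-O"], psi[i] + 180.0
        )
    return coords


def extend_backbone_backward(
    anchor_nca: np.ndarray,
    phi_anchor: float,
    phi: np.ndarray,
    psi: np.ndarray,
) -> np.ndarray:
    """Grow n new residues before an existing residue (N-terminal extension).

    ``phi_anchor`` is the phi of the existing residue (it places the new
    carbonyl carbon); ``phi[i]``/``psi[i]`` belong to the new residues,
    ordered as they will appear in the chain (phi[-1]/psi[-1] is the residue
    adjacent to the anchor).  Returns (n, 4, 3) N, CA, C, O coordinates in
    chain order.  Dihedrals are invariant under atom-order reversal, so the
    same placement torsions apply.
    """
    anchor_nca = np.asarray(anchor_nca, dtype=float)
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n = len(phi)
    coords = np.zeros((n, 4, 3))
    N_i, CA_i, C_i = anchor_nca
    phi_next = phi_anchor
    for k in range(n - 1, -1, -1):
        C_p = place_atom(C_i, CA_i, N_i, IDEAL["C-N"], IDEAL["C-N-CA"], phi_next)
        CA_p = place_atom(CA_i, N_i, C_p, IDEAL["CA-C"], IDEAL["CA-C-N"], IDEAL["OMEGA"])
        N_p = place_atom(N_i, C_p, CA_p, IDEAL["N-CA"], IDEAL["N-CA-C"], psi[k])
        coords[k, 0], coords[k, 1], coords[k, 2] = N_p, CA_p, C_p
        coords[k, 3] = place_atom(N_p, CA_p, C_p, IDEAL["C-O"], IDEAL["CA-C-O"], psi[k] + 180.0)
        N_i, CA_i, C_i = N_p, CA_p, C_p
        phi_next = phi[k]
    return coords


def rotation_about_axis(origin: np.ndarray, axis: np.ndarray, angle_deg: float):
    """Return a function rotating points about (origin, axis) by angle_deg."""
    u = axis / np.linalg.norm(axis)
    th = math.radians(angle_deg)
    c, s = math.cos(th), math.sin(th)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    R = np.eye(3) * c + s * K + (1 - c) * np.outer(u, u)

    def rot(points: np.ndarray) -> np.ndarray:
        return (points - origin) @ R.T + origin

    return rot
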