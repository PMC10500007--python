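"""Independent reference implementations used only to check the package.

These deliberately use different algorithms from the library code: the
quaternion characteristic-polynomial method for optimal RMSD (vs the SVD
Kabsch route) and plain O(N^2) distance scans (vs k-d trees).
"""

from __future__ import annotations

import math

import numpy as np


def quaternion_rmsd(fixed: np.ndarray, mobile: np.ndarray) -> float:
    """Minimum RMSD over proper rigid transforms, via the Horn quaternion method."""
    P = np.asarray(fixed, float)
    Q = np.asarray(mobile, float)
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    S = Q.T @ P
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = float(np.linalg.eigvalsh(K)[-1])
    ga = float((P**2).sum())
    gb = float((Q**2).sum())
    return math.sqrt(max(ga + gb - 2.0 * lam, 0.0) / len(P))


def brute_force_pairs(a: np.ndarray, b: np.ndarray, cutoff: float) -> set[tuple[int, int]]:
    """All (i, j) with |a_i - b_j| <= cutoff by exhaustive scan."""
    a = np.asarray(a, float).reshape(-1, 3)
    b = np.asarray(b, float).reshape(-1, 3)
    if len(a) == 0 or len(b) == 0:
        return set()
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))
    return {(int(i), int(j)) for i, j in np.argwhere(d <= cutoff)}


def brute_force_window_scan(structures, query_flat: np.ndarray, core_len: int, threshold: float):
    """Exhaustive sliding-window motif scan over backbone-complete runs.

    Returns {(structure id, chain, start residue number): rmsd} for windows
    at or under the threshold, using the quaternion oracle for each window.
    """
    from graftkit.motif_search import _complete_runs

    hits = {}
    for s in structures:
        for chain_id in s.chains:
            for run in _complete_runs(s, chain_id):
                for i in range(len(run) - core_len + 1):
                    seg = [r for _, r in run[i : i + core_len]]
                    win = np.concatenate([r.backbone() for r in seg])
                    rmsd = quaternion_rmsd(query_flat, win)
                    if rmsd <= threshold:
                        hits[(s.id, chain_id, seg[0].number)] = rmsd
    return hits
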