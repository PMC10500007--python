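"""Harvesting backbone windows that match a query binding-motif conformation.

The search mirrors the first stage of motif-grafted binder design: a bound
peptide conformation (for the integrin work, the 8-residue extended turn
RGDLGALA with five flanking residues carried on either side) is swept over
every contiguous backbone window of a scaffold library, and windows whose
optimally superposed N,CA,C,O RMSD falls under a threshold are returned as
graftable matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .structio import (
    Residue,
    Structure,
    SuperpositionResult,
    backbone_coords,
    chain_is_connected,
    kabsch_superpose,
)

__all__ = ["MotifQuery", "MotifMatch", "enumerate_windows", "harvest_matches", "batched_backbone_rmsd"]


@dataclass
class MotifQuery:
    """A backbone motif to search for: core frames plus flank bookkeeping.

    ``core_coords`` holds N,CA,C,O per core residue, shape (L, 4, 3), in the
    frame of the bound complex.  Flanking residues (default five per side,
    as carried in the original screen) provide clash context downstream and
    may optionally be included in the RMSD fit.
    """

    core_coords: np.ndarray
    sequence: list[str] = field(default_factory=list)
    n_flank: int = 5
    c_flank: int = 5
    rmsd_threshold: float = 1.0
    n_flank_coords: np.ndarray | None = None
    c_flank_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.core_coords = np.asarray(self.core_coords, dtype=float)
        if self.core_coords.ndim != 3 or self.core_coords.shape[1:] != (4, 3):
            raise ValueError("core_coords must have shape (L, 4, 3)")
        if len(self) < 3:
            raise ValueError("motif core must have at least 3 residues")
        if self.n_flank < 0 or self.c_flank < 0:
            raise ValueError("flank lengths must be non-negative")
        if self.rmsd_threshold <= 0:
            raise ValueError("rmsd threshold must be positive")
        if not self.sequence:
            self.sequence = ["UNK"] * len(self)
        for attr in ("n_flank_coords", "c_flank_coords"):
            val = getattr(self, attr)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if val.ndim != 3 or val.shape[1:] != (4, 3):
                    raise ValueError(f"{attr} must have shape (k, 4, 3)")
                setattr(self, attr, val)

    def __len__(self) -> int:
        return self.core_coords.shape[0]

    def flank_lengths(self) -> tuple[int, int]:
        """Flank residues actually carried with coordinates (n-side, c-side)."""
        n = 0 if self.n_flank_coords is None else self.n_flank_coords.shape[0]
        c = 0 if self.c_flank_coords is None else self.c_flank_coords.shape[0]
        return n, c

    @property
    def flat_core(self) -> np.ndarray:
        return self.core_coords.reshape(-1, 3)

    @classmethod
    def from_structure(
        cls,
        s: Structure,
        chain_id: str,
        start: int,
        end: int,
        n_flank: int = 5,
        c_flank: int = 5,
        rmsd_threshold: float = 1.0,
    ) -> "MotifQuery":
        """Extract a motif from author-numbered residues start..end (inclusive)."""
        chain = [r for r in s.residues(chain_id) if r.polymer]
        idx = [i for i, r in enumerate(chain) if start <= r.number <= end]
        if not idx:
            raise ValueError(f"no residues {start}-{end} in chain {chain_id!r}")
        residues = [chain[i] for i in idx]
        coords = np.stack([r.backbone() for r in residues])

        def _walk(from_idx: int, step: int, want: int) -> list[Residue]:
            out: list[Residue] = []
            prev = chain[from_idx]
            j = from_idx + step
            while 0 <= j < len(chain) and len(out) < want:
                cur = chain[j]
                a, b = (cur, prev) if step < 0 else (prev, cur)
                if not (cur.backbone_complete and chain_is_connected(a, b)):
                    break
                out.append(cur)
                prev = cur
                j += step
            return out

        n_res = _walk(idx[0], -1, n_flank)[::-1]
        c_res = _walk(idx[-1], +1, c_flank)
        return cls(
            core_coords=coords,
            sequence=[r.name for r in residues],
            n_flank=n_flank,
            c_flank=c_flank,
            rmsd_threshold=rmsd_threshold,
            n_flank_coords=np.stack([r.backbone() for r in n_res]) if n_res else None,
            c_flank_coords=np.stack([r.backbone() for r in c_res]) if c_res else None,
        )


@dataclass
class MotifMatch:
    """One harvested hit: a scaffold window superposable onto the query core."""

    source_id: str
    chain_id: str
    start_index: int
    residues: list[Residue]
    rmsd: float
    transform: SuperpositionResult
    flank_n: int
    flank_c: int

    @property
    def start_number(self) -> int:
        return self.residues[0].number

    @property
    def end_number(self) -> int:
        return self.residues[-1].number

    def window_coords(self) -> np.ndarray:
        return backbone_coords(self.residues)


def _complete_runs(s: Structure, chain_id: str) -> list[list[tuple[int, Residue]]]:
    """Maximal runs of backbone-complete, peptide-bonded residues with indices."""
    residues = list(s.residues(chain_id))
    runs: list[list[tuple[int, Residue]]] = []
    current: list[tuple[int, Residue]] = []
    for idx, res in enumerate(residues):
        if not (res.polymer and res.backbone_complete):
            if current:
                runs.append(current)
            current = []
            continue
        if current and not chain_is_connected(current[-1][1], res):
            runs.append(current)
            current = []
        current.append((idx, res))
    if current:
        runs.append(current)
    return runs


def enumerate_windows(s: Structure, length: int) -> list[tuple[str, int, list[Residue]]]:
    """All contiguous stride-1 windows of backbone-complete residues.

    Windows never span a chain break; chains shorter than ``length`` simply
    contribute none.  Returns tuples of (chain_id, start_index, residues).
    """
    if length < 1:
        raise ValueError("window length must be >= 1")
    windows = []
    for chain_id in s.chains:
        for run in _complete_runs(s, chain_id):
            for i in range(len(run) - length + 1):
                seg = run[i : i + length]
                windows.append((chain_id, seg[0][0], [r for _, r in seg]))
    return windows


def batched_backbone_rmsd(windows: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Minimum RMSD of each window onto the query after optimal superposition.

    ``windows`` has shape (W, P, 3) and ``query`` (P, 3).  Uses the singular
    values of the per-window covariance (with the proper-rotation sign
    correction), avoiding per-window transforms.
    """
    windows = np.asarray(windows, dtype=float)
    query = np.asarray(query, dtype=float)
    qc = query - query.mean(axis=0)
    wc = windows - windows.mean(axis=1, keepdims=True)
    H = np.einsum("wpi,pj->wij", wc, qc)
    sv = np.linalg.svd(H, compute_uv=False)
    s3 = np.where(np.linalg.det(H) < 0, -sv[:, 2], sv[:, 2])
    num = (qc**2).sum() + (wc**2).sum(axis=(1, 2)) - 2.0 * (sv[:, 0] + sv[:, 1] + s3)
    return np.sqrt(np.maximum(num, 0.0) / query.shape[0])


def harvest_matches(
    query: MotifQuery,
    library: Iterable[Structure],
    fit_flanks: bool = False,
) -> list[MotifMatch]:
    """Scan a scaffold library for windows matching the query core.

    Every window whose core backbone RMSD (N,CA,C,O, optimal superposition)
    is at or below ``query.rmsd_threshold`` is returned, sorted by RMSD with
    ties broken by (source id, chain, window start).  With ``fit_flanks``
    the requested flanks are included in the fitted point set, so only
    windows with full flank coverage can match.

    The reported transform maps window coordinates onto the query frame.
    """
    library = list(library)
    if not library:
        raise ValueError("scaffold library is empty")
    core_len = len(query)
    nfl, cfl = (query.flank_lengths() if fit_flanks else (0, 0))
    fit_parts = []
    if fit_flanks and nfl:
        fit_parts.append(query.n_flank_coords.reshape(-1, 3))
    fit_parts.append(query.flat_core)
    if fit_flanks and cfl:
        fit_parts.append(query.c_flank_coords.reshape(-1, 3))
    qfit = np.concatenate(fit_parts)
    fit_len = nfl + core_len + cfl
    matches: list[MotifMatch] = []
    for s in library:
        for chain_id in s.chains:
            for run in _complete_runs(s, chain_id):
                n_run = len(run)
                if n_run < fit_len:
                    continue
                run_bb = np.stack([r.backbone() for _, r in run])  # (n_run, 4, 3)
                starts = np.arange(n_run - fit_len + 1)
                win = np.stack([run_bb[i : i + fit_len].reshape(-1, 3) for i in starts])
                rmsds = batched_backbone_rmsd(win, qfit)
                for local_i in np.nonzero(rmsds <= query.rmsd_threshold)[0]:
                    core_i = int(local_i) + nfl
                    seg = run[core_i : core_i + core_len]
                    residues = [r for _, r in seg]
                    sup = kabsch_superpose(qfit, win[local_i])
                    matches.append(
                        MotifMatch(
                            source_id=s.id,
                            chain_id=chain_id,
                            start_index=seg[0][0],
                            residues=residues,
                            rmsd=sup.rmsd,
                            transform=sup,
                            flank_n=min(query.n_flank, core_i),
                            flank_c=min(query.c_flank, int(n_run - core_len - core_i)),
                        )
                    )
    matches.sort(key=lambda m: (m.rmsd, m.source_id, m.chain_id, m.start_number))
    return matches
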