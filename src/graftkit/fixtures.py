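"""Synthetic structures and assay data with known ground truth.

Everything the pipeline consumes can be generated here without downloads:
ideal secondary-structure elements, scaffold libraries with a planted copy
of a query motif among verified non-matching decoys, toy docking scenarios
with a target that discriminates benign from clashing scaffolds, and
simulated titration / kinetics / decay / sequencing-count datasets whose
generating parameters travel alongside the data.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._build import IDEAL, build_backbone, extend_backbone, extend_backbone_backward
from .loop_remodel import RAMA_BINS
from .motif_search import MotifQuery
from .structio import (
    AtomRecord,
    BACKBONE_ATOMS,
    Residue,
    Structure,
    kabsch_superpose,
)

__all__ = [
    "BuilderParams",
    "SimTruth",
    "DockingScenario",
    "build_ideal_secondary",
    "coords_to_structure",
    "rgd_motif_query",
    "make_scaffold_library",
    "make_docking_scenario",
    "simulate_assay_data",
    "simulate_ssm_counts",
]

#: Canonical torsions of the ideal elements used to compose synthetic chains.
ELEMENT_TORSIONS = {"helix": (-57.0, -47.0), "strand": (-120.0, 130.0)}

#: Backbone shape standing in for the extended-turn binding motif: an
#: extended N-terminal stretch rolling into a single helical turn, the
#: conformation class of the RGDLGALA peptide bound to the integrin.
MOTIF_PHI = np.array([-120.0, -120.0, -120.0, -90.0, -60.0, -60.0, -60.0, -60.0])
MOTIF_PSI = np.array([130.0, 130.0, 130.0, 0.0, -40.0, -40.0, -40.0, -40.0])
MOTIF_SEQUENCE = ["ARG", "GLY", "ASP", "LEU", "GLY", "ALA", "LEU", "ALA"]


@dataclass
class BuilderParams:
    """Torsion recipe for an ideal backbone segment."""

    n_residues: int
    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        self.phi = np.broadcast_to(np.asarray(self.phi, float), (self.n_residues,)).copy()
        self.psi = np.broadcast_to(np.asarray(self.psi, float), (self.n_residues,)).copy()
        if self.omega is not None:
            self.omega = np.broadcast_to(np.asarray(self.omega, float), (self.n_residues,)).copy()


@dataclass
class SimTruth:
    """Generating parameters of a simulated dataset, kept next to the data."""

    model: str
    params: dict
    noise_sigma: float
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=float, sort_keys=True)


def coords_to_structure(
    coords: np.ndarray,
    structure_id: str = "synthetic",
    chain_id: str = "A",
    start_number: int = 1,
    names: list[str] | None = None,
) -> Structure:
    """Wrap an (n, 4, 3) backbone coordinate array as a Structure."""
    coords = np.asarray(coords, dtype=float)
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    s = Structure(id=structure_id)
    for i in range(coords.shape[0]):
        name = names[i] if names else "GLY"
        atoms = [
            AtomRecord(a, elements[a], coords[i, j].copy()) for j, a in enumerate(BACKBONE_ATOMS)
        ]
        s.add_residue(Residue(chain_id, start_number + i, "", name, atoms))
    return s


def build_ideal_secondary(params: BuilderParams, structure_id: str = "ideal") -> Structure:
    """Build a backbone from per-residue torsions with ideal internal coordinates."""
    coords = build_backbone(params.phi, params.psi, params.omega)
    return coords_to_structure(coords, structure_id=structure_id)


def rgd_motif_query(
    n_flank: int = 5, c_flank: int = 5, rmsd_threshold: float = 1.0
) -> MotifQuery:
    """The 8-residue extended-turn query motif with the RGDLGALA sequence."""
    coords = build_backbone(MOTIF_PHI, MOTIF_PSI)
    return MotifQuery(
        core_coords=coords,
        sequence=list(MOTIF_SEQUENCE),
        n_flank=n_flank,
        c_flank=c_flank,
        rmsd_threshold=rmsd_threshold,
    )


# ---------------------------------------------------------------------------
# structure generators
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _sample_bin_torsions(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    names = list(RAMA_BINS)
    probs = [RAMA_BINS[k]["p"] for k in names]
    phi = np.empty(n)
    psi = np.empty(n)
    for i in range(n):
        b = RAMA_BINS[names[int(rng.choice(len(names), p=probs))]]
        phi[i] = rng.uniform(*b["phi"])
        psi[i] = rng.uniform(*b["psi"])
    return phi, psi


def _random_composition_torsions(rng: np.random.Generator, total: int) -> tuple[np.ndarray, np.ndarray]:
    """Torsions of a random helix/strand/loop segment composition."""
    phi, psi = [], []
    while len(phi) < total:
        kind = ("helix", "strand", "loop")[int(rng.integers(3))]
        length = int(rng.integers(4, 9))
        if kind == "loop":
            p, q = _sample_bin_torsions(rng, length)
        else:
            p0, q0 = ELEMENT_TORSIONS[kind]
            p = np.full(length, p0) + rng.normal(0, 2.0, length)
            q = np.full(length, q0) + rng.normal(0, 2.0, length)
        phi.extend(p.tolist())
        psi.extend(q.tolist())
    return np.array(phi[:total]), np.array(psi[:total])


def _assemble_host(
    core_coords: np.ndarray, rng: np.random.Generator, n_flank: int, c_flank: int
) -> np.ndarray:
    """Embed a motif core between freshly grown flank segments."""
    parts = []
    if n_flank:
        phi_n, psi_n = _sample_bin_torsions(rng, n_flank)
        phi_anchor = float(rng.uniform(-130, -60))
        parts.append(extend_backbone_backward(core_coords[0, :3], phi_anchor, phi_n, psi_n))
    parts.append(core_coords.copy())
    if c_flank:
        phi_c, psi_c = _sample_bin_torsions(rng, c_flank)
        psi_anchor = float(rng.uniform(-60, 150))
        parts.append(extend_backbone(core_coords[-1, :3], psi_anchor, phi_c, psi_c))
    return np.concatenate(parts)


def _min_window_rmsd(coords: np.ndarray, query_flat: np.ndarray, length: int) -> float:
    """Brute-force sliding-window minimum RMSD (independent of the harvester)."""
    best = np.inf
    for i in range(coords.shape[0] - length + 1):
        win = coords[i : i + length].reshape(-1, 3)
        best = min(best, kabsch_superpose(query_flat, win).rmsd)
    return best


@dataclass
class DockingScenario:
    """A toy complex for exercising harvest -> dock -> clash filtering."""

    query: MotifQuery
    library: list[Structure]
    target: Structure
    planted_id: str
    clashing_id: str


def make_scaffold_library(
    query: MotifQuery,
    n_decoys: int,
    noise_sigma: float = 0.2,
    seed: int = 0,
    max_retries: int = 50,
) -> tuple[list[Structure], dict]:
    """A scaffold library with one planted motif copy among verified decoys.

    The planted structure embeds a rigidly transformed, noise-perturbed copy
    of the query core between grown flank segments; every decoy is a random
    helix/strand/loop composition verified by brute-force scan to contain no
    window within 1.5x the query threshold.  Returns the structures and a
    manifest recording where the motif was planted.
    """
    if n_decoys < 0:
        raise ValueError("n_decoys must be non-negative")
    rng = np.random.default_rng(seed)
    core_len = len(query)
    n_flank, c_flank = query.n_flank, query.c_flank
    for _ in range(max_retries):
        noisy_core = query.core_coords + rng.normal(0.0, noise_sigma, query.core_coords.shape)
        host = _assemble_host(noisy_core, rng, n_flank, c_flank)
        # the planted window must stay harvestable: peptide bonds intact
        # (no spurious chain break) and within the query threshold
        c_n = np.linalg.norm(host[1:, 0] - host[:-1, 2], axis=1)
        if c_n.max() <= 2.0 and kabsch_superpose(query.flat_core, noisy_core.reshape(-1, 3)).rmsd <= query.rmsd_threshold:
            break
    else:
        raise RuntimeError(f"could not plant a recoverable motif copy after {max_retries} tries")
    R = _random_rotation(rng)
    t = rng.uniform(-20.0, 20.0, 3)
    host = host @ R.T + t
    structures = [coords_to_structure(host, structure_id="planted")]
    total_len = host.shape[0]
    qflat = query.flat_core
    for d in range(n_decoys):
        for attempt in range(max_retries):
            length = total_len + int(rng.integers(0, 11))
            phi, psi = _random_composition_torsions(rng, length)
            coords = build_backbone(phi, psi)
            if _min_window_rmsd(coords, qflat, core_len) > 1.5 * query.rmsd_threshold:
                coords = coords @ _random_rotation(rng).T + rng.uniform(-20, 20, 3)
                structures.append(coords_to_structure(coords, structure_id=f"decoy_{d:03d}"))
                break
        else:
            raise RuntimeError(f"could not build a verified decoy after {max_retries} tries")
    manifest = {
        "planted_id": "planted",
        "chain_id": "A",
        "core_start_number": n_flank + 1,
        "core_end_number": n_flank + core_len,
        "noise_sigma": noise_sigma,
        "seed": seed,
        "n_structures": len(structures),
    }
    return structures, manifest


def make_docking_scenario(
    seed: int = 0,
    noise_sigma: float = 0.1,
    n_benign_decoys: int = 3,
    n_target_atoms: int = 12,
    clash_cutoff: float = 3.0,
) -> DockingScenario:
    """Construct a complex where clash filtering separates two scaffolds.

    Both the planted scaffold and a "clashing" scaffold contain the query
    core (so both are harvested and docked); target pseudo-atoms are then
    placed within clash range of the clashing scaffold's docked flanks but
    well clear of the planted scaffold, so the screen must retain one and
    discard the other.  Benign decoys contain no motif window at all.
    """
    rng = np.random.default_rng(seed)
    query = rgd_motif_query(rmsd_threshold=1.0)
    core = query.core_coords

    def _docked_host() -> np.ndarray:
        noisy = core + rng.normal(0.0, noise_sigma, core.shape)
        return _assemble_host(noisy, rng, query.n_flank, query.c_flank)

    planted = _docked_host()
    clashing = _docked_host()
    core_slice = slice(query.n_flank, query.n_flank + len(query))

    planted_all = planted.reshape(-1, 3)
    flank_idx = [i for i in range(clashing.shape[0]) if not (core_slice.start <= i < core_slice.stop)]
    target_points = []
    for i in rng.permutation(flank_idx):
        atom = clashing[i, 1]  # CA of a clashing-scaffold flank residue
        for _ in range(20):
            offset = rng.normal(size=3)
            offset *= (clash_cutoff - 1.0) / np.linalg.norm(offset)
            p = atom + offset
            if np.linalg.norm(planted_all - p, axis=1).min() > clash_cutoff + 1.0:
                target_points.append(p)
                break
        if len(target_points) >= n_target_atoms:
            break
    if len(target_points) < 3:
        raise RuntimeError("could not place target atoms discriminating the scaffolds")
    target = Structure(id="target")
    for k, p in enumerate(target_points):
        target.add_residue(
            Residue("T", k + 1, "", "GLY", [AtomRecord("CA", "C", np.array(p))])
        )
    library = [
        coords_to_structure(planted, structure_id="planted"),
        coords_to_structure(clashing, structure_id="clashing"),
    ]
    qflat = query.flat_core
    total_len = planted.shape[0]
    for d in range(n_benign_decoys):
        for _ in range(50):
            phi, psi = _random_composition_torsions(rng, total_len)
            coords = build_backbone(phi, psi)
            if _min_window_rmsd(coords, qflat, len(query)) > 1.5 * query.rmsd_threshold:
                library.append(coords_to_structure(coords, structure_id=f"decoy_{d:03d}"))
                break
        else:
            raise RuntimeError("could not build a verified benign decoy")
    return DockingScenario(
        query=query, library=library, target=target, planted_id="planted", clashing_id="clashing"
    )


# ---------------------------------------------------------------------------
# assay-data simulators
# ---------------------------------------------------------------------------


def _grid_around(center: float, n_each_side: int = 4, factor: float = 3.0) -> np.ndarray:
    return center * factor ** np.arange(-n_each_side, n_each_side + 1, dtype=float)


def simulate_assay_data(model: str, truth: SimTruth) -> dict[str, pd.DataFrame]:
    """Forward-simulate an assay dataset under a known truth.

    Supported models: ``one_site`` (params kd, bmax, background), ``four_pl``
    (ic50, top, bottom, hill), ``bli`` (kon, koff, rmax, concentrations,
    optionally t_assoc/t_dissoc/dt) and ``decay`` (t_half, c0, optionally
    times).  Additive Gaussian noise has sigma expressed as a fraction of
    the dynamic range (for ``decay``, of each concentration, mirroring the
    proportional error of ELISA-quantified profiles).
    """
    if model != truth.model:
        raise ValueError(f"truth describes model {truth.model!r}, not {model!r}")
    rng = np.random.default_rng(truth.seed)
    p = truth.params
    sig = truth.noise_sigma
    replicates = int(p.get("replicates", 3))  # titrations are run in triplicate
    if model == "one_site":
        grid = np.asarray(p.get("conc_grid", _grid_around(p["kd"])), dtype=float)
        conc = np.repeat(grid, replicates)
        y = p.get("background", 0.0) + p["bmax"] * conc / (p["kd"] + conc)
        y = y + rng.normal(0.0, sig * p["bmax"], len(conc)) if sig > 0 else y
        return {"titration": pd.DataFrame({"concentration": conc, "signal": y})}
    if model == "four_pl":
        grid = np.asarray(p.get("conc_grid", _grid_around(p["ic50"])), dtype=float)
        conc = np.repeat(grid, replicates)
        span = p["top"] - p["bottom"]
        y = p["bottom"] + span / (1.0 + (conc / p["ic50"]) ** p["hill"])
        y = y + rng.normal(0.0, sig * abs(span), len(conc)) if sig > 0 else y
        return {"response": pd.DataFrame({"concentration": conc, "signal": y})}
    if model == "bli":
        dt = float(p.get("dt", 5.0))
        ta = np.arange(0.0, float(p.get("t_assoc", 900.0)) + dt / 2, dt)
        td = np.arange(0.0, float(p.get("t_dissoc", 1200.0)) + dt / 2, dt)
        kon, koff, rmax = p["kon"], p["koff"], p["rmax"]
        tables = {}
        for c in p["concentrations"]:
            kobs = kon * c + koff
            req = rmax * kon * c / kobs
            ya = req * (1.0 - np.exp(-kobs * ta))
            y0 = req * (1.0 - np.exp(-kobs * ta[-1]))
            yd = y0 * np.exp(-koff * td)
            if sig > 0:
                ya = ya + rng.normal(0.0, sig * rmax, len(ta))
                yd = yd + rng.normal(0.0, sig * rmax, len(td))
            tables[f"assoc_{c:g}"] = pd.DataFrame({"time": ta, "signal": ya})
            tables[f"dissoc_{c:g}"] = pd.DataFrame({"time": td, "signal": yd})
        return tables
    if model == "decay":
        times = np.asarray(p.get("times", [5, 10, 15, 20, 30, 45, 60, 90]), dtype=float)
        c0 = p.get("c0", 100.0)
        lam = math.log(2.0) / p["t_half"]
        c = c0 * np.exp(-lam * times)
        if sig > 0:
            c = c * (1.0 + rng.normal(0.0, sig, len(times)))
        return {"profile": pd.DataFrame({"time": times, "concentration": c})}
    raise ValueError(f"unknown model {model!r}")


def simulate_ssm_counts(
    positions,
    alphabet,
    effects: dict | None,
    depth: int,
    seed: int,
) -> tuple[dict, dict, SimTruth]:
    """Simulate pre/post sorting counts for a site-saturation library.

    Variants are (position, substitution) pairs.  Pre-sort counts are
    multinomial over a uniform library; post-sort frequencies are the
    observed pre frequencies weighted by each variant's fold change
    (``effects``, default 1).  Both tables sum to ``depth``.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    variants = [(p, a) for p in positions for a in alphabet]
    effects = effects or {}
    n = len(variants)
    pre = rng.multinomial(depth, np.full(n, 1.0 / n))
    weights = pre.astype(float) * np.array([effects.get(v, 1.0) for v in variants])
    if weights.sum() <= 0:
        raise ValueError("post-sort pool is empty under the given effects")
    post = rng.multinomial(depth, weights / weights.sum())
    truth = SimTruth(
        model="ssm",
        params={"effects": {f"{p}:{a}": effects.get((p, a), 1.0) for p, a in variants}},
        noise_sigma=0.0,
        seed=seed,
    )
    pre_counts = {v: int(c) for v, c in zip(variants, pre)}
    post_counts = {v: int(c) for v, c in zip(variants, post)}
    return pre_counts, post_counts, truth
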