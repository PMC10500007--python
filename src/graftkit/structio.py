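"""Atomic structure data model, PDB/mmCIF I/O, selections and rigid-body geometry.

The hierarchy is deliberately small: a :class:`Structure` is an ordered
mapping of chain id to a list of :class:`Residue`, each holding ordered
:class:`AtomRecord` objects.  Author numbering (chain id, residue number,
insertion code) is the canonical residue key throughout the package, so that
residue labels printed in structural work on integrin complexes (e.g. E316 on
the beta-6 subunit, K304 on beta-8) can be addressed directly.

File reading and writing are backed by gemmi; alternate locations are
collapsed to a single conformer on read (highest occupancy, ties broken in
favour of altloc 'A').  Hydrogens are kept in the model but excluded from all
distance-based screens downstream.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "Structure",
    "SuperpositionResult",
    "TorsionSet",
    "StructureParseError",
    "StructureFormatError",
    "SelectionSyntaxError",
    "DegenerateGeometryError",
    "read_structure",
    "write_structure",
    "select",
    "kabsch_superpose",
    "measure_torsions",
    "neighbor_pairs",
    "backbone_coords",
    "dihedral",
]

#: Atom names that constitute the peptide backbone, in canonical order.
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Consecutive residues whose C--N distance exceeds this are a chain break (A).
CHAIN_BREAK_CN = 2.0

ResidueKey = tuple[str, int, str]


class StructureParseError(ValueError):
    """A coordinate file could not be parsed."""


class StructureFormatError(ValueError):
    """A Structure cannot be represented in the requested dialect."""


class SelectionSyntaxError(ValueError):
    """Malformed selection expression; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class DegenerateGeometryError(ValueError):
    """Point sets unsuitable for superposition (too few / collinear)."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class AtomRecord:
    """A single atom: name, element, Cartesian position in Angstrom."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    temperature_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """A residue under author numbering; atoms keep file order."""

    chain_id: str
    number: int
    insertion_code: str = ""
    name: str = "UNK"
    atoms: list[AtomRecord] = field(default_factory=list)
    polymer: bool = True

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.number, self.insertion_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def backbone_complete(self) -> bool:
        return all(self.atom(n) is not None for n in BACKBONE_ATOMS)

    def backbone(self) -> np.ndarray:
        """(4, 3) array of N, CA, C, O positions; requires a complete backbone."""
        if not self.backbone_complete:
            raise ValueError(f"residue {self.key} has an incomplete backbone")
        return np.array([self.atom(n).position for n in BACKBONE_ATOMS])

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def copy(self) -> "Residue":
        return Residue(
            self.chain_id,
            self.number,
            self.insertion_code,
            self.name,
            [
                AtomRecord(a.name, a.element, a.position.copy(), a.occupancy, a.altloc, a.temperature_factor)
                for a in self.atoms
            ],
            self.polymer,
        )


@dataclass
class Structure:
    """Ordered chains of residues, as read from (or destined for) a file."""

    id: str = ""
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    source_format: str = ""

    def add_residue(self, res: Residue) -> None:
        self.chains.setdefault(res.chain_id, []).append(res)

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")
        return self.chains[chain_id]

    def residues(self, chain_id: str | None = None) -> Iterator[Residue]:
        if chain_id is not None:
            yield from self.chains.get(chain_id, [])
        else:
            for residues in self.chains.values():
                yield from residues

    def atoms(self) -> Iterator[tuple[Residue, AtomRecord]]:
        for res in self.residues():
            for atom in res.atoms:
                yield res, atom

    def residue(self, key: ResidueKey) -> Residue:
        chain_id, number, icode = key
        for res in self.chains.get(chain_id, []):
            if res.number == number and res.insertion_code == icode:
                return res
        raise KeyError(f"no residue {key} in structure {self.id!r}")

    @property
    def n_atoms(self) -> int:
        return sum(len(res.atoms) for res in self.residues())

    def coordinates(self, heavy_only: bool = False) -> np.ndarray:
        pts = [
            a.position
            for _, a in self.atoms()
            if not (heavy_only and a.is_hydrogen)
        ]
        return np.array(pts).reshape(-1, 3)

    def copy(self) -> "Structure":
        out = Structure(self.id, {}, self.source_format)
        for cid, residues in self.chains.items():
            out.chains[cid] = [r.copy() for r in residues]
        return out

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly transformed copy (x -> R x + t)."""
        out = self.copy()
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for _, atom in out.atoms():
            atom.position = R @ atom.position + t
        return out


def backbone_coords(residues: Sequence[Residue]) -> np.ndarray:
    """Stacked (4 * len(residues), 3) N,CA,C,O coordinates of a residue run."""
    return np.concatenate([r.backbone() for r in residues]) if residues else np.empty((0, 3))


def chain_is_connected(prev: Residue, nxt: Residue) -> bool:
    """True when the peptide bond between two consecutive residues is intact."""
    c = prev.atom("C")
    n = nxt.atom("N")
    if c is None or n is None:
        return False
    return float(np.linalg.norm(c.position - n.position)) <= CHAIN_BREAK_CN


# ---------------------------------------------------------------------------
# file I/O (gemmi-backed)
# ---------------------------------------------------------------------------


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, tie -> altloc 'A'."""
    by_name: dict[str, list[AtomRecord]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.altloc != "A", a.altloc))
        kept.append(best)
    return kept


def read_structure(path: str | Path, dialect: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    All polymer atoms are loaded; heteroatoms (HETATM / non-polymer entities)
    are retained with ``polymer=False``.  Only the first model of a
    multi-model file is used.
    """
    path = Path(path)
    fmts = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif, "auto": gemmi.CoorFormat.Detect}
    if dialect not in fmts:
        raise StructureFormatError(f"unknown dialect {dialect!r}; expected pdb, mmcif or auto")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=fmts[dialect])
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    source = "mmcif" if st.input_format == gemmi.CoorFormat.Mmcif else "pdb"
    out = Structure(id=st.name or path.stem, source_format=source)
    if len(st) == 0:
        return out
    model = st[0]
    for chain in model:
        for res in chain:
            atoms = [
                AtomRecord(
                    name=a.name,
                    element=a.element.name,
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    altloc=a.altloc if a.altloc else "",
                    temperature_factor=a.b_iso,
                )
                for a in res
            ]
            atoms = _resolve_altlocs(atoms)
            out.add_residue(
                Residue(
                    chain_id=chain.name,
                    number=res.seqid.num,
                    insertion_code=res.seqid.icode.strip(),
                    name=res.name,
                    atoms=atoms,
                    polymer=res.het_flag != "H",
                )
            )
    return out


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.id or "model"
    model = gemmi.Model("1")
    for chain_id, residues in s.chains.items():
        chain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            gres.het_flag = "A" if res.polymer else "H"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.position)
                ga.occ = atom.occupancy
                ga.b_iso = atom.temperature_factor
                if atom.altloc:
                    ga.altloc = atom.altloc
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: Structure, path: str | Path, dialect: str = "auto") -> None:
    """Write a Structure as PDB (fixed-column, 3-decimal coordinates) or mmCIF."""
    path = Path(path)
    if dialect == "auto":
        dialect = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if dialect not in ("pdb", "mmcif"):
        raise StructureFormatError(f"unknown dialect {dialect!r}")
    if dialect == "pdb":
        for cid in s.chains:
            if len(cid) > 2:
                raise StructureFormatError(
                    f"chain id {cid!r} too long for the PDB dialect (max 2 characters)"
                )
    st = _to_gemmi(s)
    if dialect == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*([A-Za-z_][\w]*|[-+]?\d+|[(),]|\S)")


class _Selector:
    """Recursive-descent parser/evaluator for the small selection grammar.

    Grammar::

        expr    := term ('or' term)*
        term    := factor ('and' factor)*
        factor  := 'not' factor | '(' expr ')' | primary
        primary := 'chain' id_list | 'resi' range_list | 'resn' id_list
                 | 'name' id_list | 'backbone' | 'polymer' | 'het' | 'all'
    """

    KEYWORDS = {"and", "or", "not", "chain", "resi", "resn", "name", "backbone", "polymer", "het", "all"}

    def __init__(self, expr: str):
        self.expr = expr
        self.tokens: list[tuple[str, int]] = []
        pos = 0
        while pos < len(expr):
            m = _TOKEN_RE.match(expr, pos)
            if not m:
                break
            self.tokens.append((m.group(1), m.start(1)))
            pos = m.end()
        self.i = 0

    def _peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def _pos(self) -> int:
        return self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.expr)

    def _next(self) -> str:
        tok = self._peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression", len(self.expr))
        self.i += 1
        return tok

    def parse(self):
        pred = self._expr()
        if self._peek() is not None:
            raise SelectionSyntaxError(f"unexpected token {self._peek()!r}", self._pos())
        return pred

    def _expr(self):
        preds = [self._term()]
        while self._peek() == "or":
            self._next()
            preds.append(self._term())
        return lambda r, a: any(p(r, a) for p in preds)

    def _term(self):
        preds = [self._factor()]
        while self._peek() == "and":
            self._next()
            preds.append(self._factor())
        return lambda r, a: all(p(r, a) for p in preds)

    def _factor(self):
        tok = self._peek()
        if tok == "not":
            self._next()
            inner = self._factor()
            return lambda r, a: not inner(r, a)
        if tok == "(":
            self._next()
            inner = self._expr()
            if self._peek() != ")":
                raise SelectionSyntaxError("expected ')'", self._pos())
            self._next()
            return inner
        return self._primary()

    def _id_list(self) -> list[str]:
        items = [self._next()]
        while self._peek() == ",":
            self._next()
            items.append(self._next())
        return items

    def _range_list(self) -> list[tuple[int, int]]:
        ranges = []
        while True:
            pos = self._pos()
            tok = self._next()
            m = re.fullmatch(r"(-?\d+)(?:\s*)", tok)
            if not m:
                raise SelectionSyntaxError(f"expected residue number, got {tok!r}", pos)
            lo = int(tok)
            hi = lo
            nxt = self._peek()
            if nxt == "-":
                self._next()
                hi_tok = self._next()
                if not re.fullmatch(r"-?\d+", hi_tok):
                    raise SelectionSyntaxError(f"expected residue number, got {hi_tok!r}", self._pos())
                hi = int(hi_tok)
            elif nxt is not None and re.fullmatch(r"-\d+", nxt):
                # "180-190" lexes as "180", "-190": treat as a range end
                hi = int(self._next()[1:])
            ranges.append((lo, hi))
            if self._peek() == ",":
                self._next()
                continue
            return ranges

    def _primary(self):
        pos = self._pos()
        tok = self._next()
        if tok == "chain":
            ids = set(self._id_list())
            return lambda r, a: r.chain_id in ids
        if tok == "resi":
            ranges = self._range_list()
            return lambda r, a: any(lo <= r.number <= hi for lo, hi in ranges)
        if tok == "resn":
            names = {n.upper() for n in self._id_list()}
            return lambda r, a: r.name.upper() in names
        if tok == "name":
            names = {n.upper() for n in self._id_list()}
            return lambda r, a: a.name.upper() in names
        if tok == "backbone":
            return lambda r, a: a.name in BACKBONE_ATOMS
        if tok == "polymer":
            return lambda r, a: r.polymer
        if tok == "het":
            return lambda r, a: not r.polymer
        if tok == "all":
            return lambda r, a: True
        raise SelectionSyntaxError(f"unknown selection keyword {tok!r}", pos)


def select(s: Structure, expr: str) -> Structure:
    """Evaluate a selection expression, returning a filtered Structure view.

    Residue ordering within chains is preserved; residues losing all atoms
    are dropped.  An empty selection is a valid (empty) Structure.
    """
    pred = _Selector(expr).parse()
    out = Structure(id=s.id, source_format=s.source_format)
    for res in s.residues():
        kept = [a for a in res.atoms if pred(res, a)]
        if kept:
            view = Residue(res.chain_id, res.number, res.insertion_code, res.name, kept, res.polymer)
            out.add_residue(view)
    return out


# ---------------------------------------------------------------------------
# rigid-body geometry
# ---------------------------------------------------------------------------


@dataclass
class SuperpositionResult:
    """Optimal proper rigid transform of a mobile onto a fixed point set."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "rmsd": self.rmsd,
        }


def kabsch_superpose(fixed: np.ndarray, mobile: np.ndarray) -> SuperpositionResult:
    """Least-squares superposition of ``mobile`` onto ``fixed`` (Kabsch, SVD form).

    Returns the proper rotation (det = +1) and translation minimising the
    RMSD between the transformed mobile set and the fixed set.  Reflections
    are never returned; collinear or too-small point sets raise
    :class:`DegenerateGeometryError`.
    """
    fixed = np.asarray(fixed, dtype=float)
    mobile = np.asarray(mobile, dtype=float)
    if fixed.shape != mobile.shape:
        raise DegenerateGeometryError(
            f"point count mismatch: fixed {fixed.shape} vs mobile {mobile.shape}"
        )
    if fixed.ndim != 2 or fixed.shape[1] != 3 or fixed.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 points of dimension 3")
    cf = fixed.mean(axis=0)
    cm = mobile.mean(axis=0)
    f = fixed - cf
    m = mobile - cm
    # collinearity check: second singular value of either centered set ~ 0
    for pts in (f, m):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] <= 1e-8 * max(sv[0], 1.0):
            raise DegenerateGeometryError("point set is collinear (or coincident)")
    H = m.T @ f
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention, (-180, 180]."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


@dataclass
class TorsionSet:
    """Backbone torsions (phi, psi, omega in degrees) keyed by residue.

    Angles are ``None`` exactly where a flanking backbone atom is missing or
    the peptide bond is broken (C--N beyond the chain-break cutoff).
    """

    keys: list[ResidueKey]
    phi: list[float | None]
    psi: list[float | None]
    omega: list[float | None]

    def get(self, key: ResidueKey) -> tuple[float | None, float | None, float | None]:
        i = self.keys.index(key)
        return self.phi[i], self.psi[i], self.omega[i]

    def __len__(self) -> int:
        return len(self.keys)


def measure_torsions(s: Structure, chain_id: str) -> TorsionSet:
    """Measure phi/psi/omega along one chain.

    omega of residue i is defined from CA(i-1), C(i-1), N(i), CA(i); phi of
    residue i from C(i-1), N(i), CA(i), C(i); psi from N(i), CA(i), C(i),
    N(i+1).  Torsions adjacent to a chain break are undefined, never
    extrapolated.
    """
    residues = [r for r in s.residues(chain_id) if r.polymer]
    if len(residues) < 2:
        raise ValueError(f"chain {chain_id!r} needs at least 2 residues")
    keys, phis, psis, omegas = [], [], [], []
    for i, res in enumerate(residues):
        prev_res = residues[i - 1] if i > 0 else None
        next_res = residues[i + 1] if i + 1 < len(residues) else None
        prev_ok = prev_res is not None and chain_is_connected(prev_res, res)
        next_ok = next_res is not None and chain_is_connected(res, next_res)
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        phi = psi = omega = None
        if prev_ok and None not in (n, ca, c) and prev_res.atom("C") is not None:
            phi = dihedral(prev_res.atom("C").position, n.position, ca.position, c.position)
        if prev_ok and None not in (n, ca) and prev_res.atom("CA") is not None and prev_res.atom("C") is not None:
            omega = dihedral(
                prev_res.atom("CA").position, prev_res.atom("C").position, n.position, ca.position
            )
        if next_ok and None not in (n, ca, c) and next_res.atom("N") is not None:
            psi = dihedral(n.position, ca.position, c.position, next_res.atom("N").position)
        keys.append(res.key)
        phis.append(phi)
        psis.append(psi)
        omegas.append(omega)
    return TorsionSet(keys=keys, phi=phis, psi=psis, omega=omegas)


def neighbor_pairs(
    a: np.ndarray, b: np.ndarray, cutoff: float
) -> list[tuple[int, int, float]]:
    """All index pairs (i, j) with |a_i - b_j| <= cutoff, each reported once.

    Uses a k-d tree; empty inputs yield an empty list.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if len(a) == 0 or len(b) == 0:
        return []
    from scipy.spatial import cKDTree

    tree_a = cKDTree(a)
    tree_b = cKDTree(b)
    pairs = []
    for i, js in enumerate(tree_a.query_ball_tree(tree_b, r=cutoff)):
        for j in js:
            d = float(np.linalg.norm(a[i] - b[j]))
            pairs.append((i, j, d))
    return pairs
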