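"""Structure representation, PDB I/O, parameter assignment and
methionine-sulfoxide model building.

A :class:`Structure` is an ordered list of :class:`Atom` records mirroring
PDB order.  Coordinates are in angstrom; serials and residue ids are kept
exactly as read.  File I/O goes through biotite's PDB reader/writer with a
thin validation layer so that malformed records are reported with their
line number and multi-model files with inconsistent topology are rejected.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import biotite.structure as bts
import biotite.structure.io.pdb as btpdb

from .constants import (
    SULFOXIDE_GRID_COUNT,
    SULFOXIDE_GRID_STEP_DEG,
    SULFOXIDE_RESNAME,
    SULFOXIDE_SO_BOND,
)
from .errors import (
    GeometryError,
    IncompleteResidueError,
    ParameterizationError,
    PDBFormatError,
    PDBParseError,
    SelectionError,
    TopologyError,
)

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "AtomSet",
    "ParamTable",
    "read_pdb",
    "write_pdb",
    "assign_params",
    "build_sulfoxide",
]

# Bondi-like van der Waals radii used when atoms carry no assigned radius
# (clash scoring during sulfoxide building).
_ELEMENT_RADII = {"H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
                  "P": 1.80, "X": 1.70}


@dataclass
class Atom:
    """One atom record: identity, position and optional nonbonded
    parameters (radius A, charge e, LJ well depth kcal/mol, LJ r_min/2 A).
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: np.ndarray
    radius: float | None = None
    charge: float | None = None
    lj_epsilon: float | None = None
    lj_rmin_half: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise GeometryError(f"atom {self.serial}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise GeometryError(f"atom {self.serial}: non-finite position")
        if self.radius is not None and self.radius <= 0:
            raise ValueError(f"atom {self.serial}: radius must be positive")

    def copy(self) -> "Atom":
        return replace(self, position=self.position.copy())


@dataclass
class Structure:
    """An ordered collection of atoms (one PDB model)."""

    atoms: list[Atom]
    model_id: int = 1
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (a copy)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise GeometryError("coordinate array shape mismatch")
        for atom, pos in zip(self.atoms, xyz):
            atom.position = pos.copy()

    def radii(self) -> np.ndarray:
        """Per-atom radii; raises if any atom is unparameterized."""
        out = np.empty(len(self.atoms))
        for i, a in enumerate(self.atoms):
            if a.radius is None:
                raise ParameterizationError(
                    f"atom {a.serial} ({a.residue_name} {a.name}) has no radius"
                )
            out[i] = a.radius
        return out

    def residue_indices(self, residue_id: int, chain_id: str | None = None) -> list[int]:
        """Atom indices belonging to one residue (empty list if absent)."""
        return [
            i for i, a in enumerate(self.atoms)
            if a.residue_id == residue_id
            and (chain_id is None or a.chain_id == chain_id)
        ]

    def copy(self) -> "Structure":
        return Structure([a.copy() for a in self.atoms], self.model_id,
                         self.provenance)


@dataclass
class Trajectory:
    """Ordered frames sharing one topology, spaced ``frame_interval`` ps."""

    frames: list[Structure]
    frame_interval: float = 10.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.frames:
            ref = [(a.name, a.residue_id, a.chain_id) for a in self.frames[0].atoms]
            for k, fr in enumerate(self.frames[1:], start=2):
                got = [(a.name, a.residue_id, a.chain_id) for a in fr.atoms]
                if got != ref:
                    raise TopologyError(
                        f"frame {k} does not share the topology of frame 1"
                    )

    def __len__(self) -> int:
        return len(self.frames)

    def times(self) -> np.ndarray:
        return np.arange(len(self.frames)) * self.frame_interval


@dataclass(frozen=True)
class AtomSet:
    """A selection: atom indices into one Structure, plus a label."""

    indices: frozenset[int]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.indices:
            raise SelectionError(f"empty atom set ({self.label!r})")
        object.__setattr__(self, "indices", frozenset(int(i) for i in self.indices))

    def __len__(self) -> int:
        return len(self.indices)

    def __contains__(self, i: int) -> bool:
        return i in self.indices

    def sorted(self) -> list[int]:
        return sorted(self.indices)

    def validate(self, structure: Structure) -> None:
        if self.indices and max(self.indices) >= len(structure.atoms):
            raise SelectionError(f"atom set {self.label!r} exceeds structure bounds")


class ParamTable:
    """Nonbonded parameters keyed by (residue_name, atom_name).

    Lookup order: exact (residue, atom) -> wildcard residue ("*", atom)
    -> element fallback ("*", element symbol).  A lookup that falls through
    all three raises :class:`ParameterizationError`.
    """

    COLUMNS = ("residue_name", "atom_name", "radius_A", "charge_e",
               "lj_epsilon", "lj_rmin_half")

    def __init__(self, rows: dict[tuple[str, str], tuple[float, float, float, float]]):
        for (res, name), (rad, _q, eps, _rm) in rows.items():
            if rad <= 0:
                raise ValueError(f"({res},{name}): radius must be positive")
            if eps < 0:
                raise ValueError(f"({res},{name}): lj_epsilon must be >= 0")
        self._rows = dict(rows)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ParamTable":
        rows: dict[tuple[str, str], tuple[float, float, float, float]] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if tuple(header) != cls.COLUMNS:
                raise ValueError(f"bad ParamTable header: {header}")
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                res, name, rad, q, eps, rmin = line.split("\t")
                rows[(res, name)] = (float(rad), float(q), float(eps), float(rmin))
        return cls(rows)

    @classmethod
    def default(cls) -> "ParamTable":
        """The packaged generic table (Bondi-like radii, toy charges/LJ)."""
        path = Path(__file__).parent / "data" / "params.tsv"
        return cls.from_tsv(path)

    def lookup(self, residue_name: str, atom_name: str, element: str = ""
               ) -> tuple[float, float, float, float]:
        for key in ((residue_name, atom_name), ("*", atom_name), ("*", element)):
            if key in self._rows:
                return self._rows[key]
        raise ParameterizationError(
            f"no parameters for ({residue_name}, {atom_name}, element {element!r})"
        )

    def __len__(self) -> int:
        return len(self._rows)


# --------------------------------------------------------------------------
# PDB I/O
# --------------------------------------------------------------------------

def _validate_pdb_text(path: Path) -> None:
    """Cheap pre-scan: every ATOM/HETATM record must carry parseable
    fixed-column coordinates.  Reports the first offending line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PDBParseError(f"line {lineno}: truncated record")
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    int(line[22:26])
                except ValueError as exc:
                    raise PDBParseError(f"line {lineno}: {exc}") from exc


def _atoms_from_array(arr: "bts.AtomArray") -> list[Atom]:
    serials = (arr.get_annotation("atom_id") if "atom_id" in arr.get_annotation_categories()
               else np.arange(1, arr.array_length() + 1))
    atoms = []
    for i in range(arr.array_length()):
        atoms.append(Atom(
            serial=int(serials[i]),
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]),
            residue_name=str(arr.res_name[i]),
            residue_id=int(arr.res_id[i]),
            chain_id=str(arr.chain_id[i]),
            position=arr.coord[i],
        ))
    return atoms


def read_pdb(path: str | Path, multi_model: bool = False,
             frame_interval: float = 10.0) -> Structure | Trajectory:
    """Read a PDB file into a Structure, or a Trajectory if ``multi_model``.

    Raises :class:`PDBParseError` (with line number) on malformed records
    and :class:`TopologyError` if MODEL blocks disagree in atom count.
    """
    path = Path(path)
    _validate_pdb_text(path)
    pdb_file = btpdb.PDBFile.read(path)
    n_models = pdb_file.get_model_count()
    if not multi_model:
        arr = pdb_file.get_structure(model=1, extra_fields=["atom_id"])
        return Structure(_atoms_from_array(arr), model_id=1, provenance=str(path))
    try:
        stack = pdb_file.get_structure(model=None, extra_fields=["atom_id"])
    except Exception as exc:
        raise TopologyError(f"{path}: inconsistent MODEL blocks: {exc}") from exc
    frames = []
    for m in range(n_models):
        arr = stack[m]
        frames.append(Structure(_atoms_from_array(arr), model_id=m + 1,
                                provenance=str(path)))
    return Trajectory(frames, frame_interval=frame_interval)


def _array_from_structure(s: Structure) -> "bts.AtomArray":
    n = len(s.atoms)
    arr = bts.AtomArray(n)
    arr.add_annotation("atom_id", dtype=int)
    for i, a in enumerate(s.atoms):
        if not np.all(np.isfinite(a.position)):
            raise PDBFormatError(f"atom {a.serial}: non-finite coordinate")
        if a.serial > 99999 or a.serial < -9999:
            raise PDBFormatError(f"serial {a.serial} exceeds PDB field width")
        if a.residue_id > 9999 or a.residue_id < -999:
            raise PDBFormatError(f"residue id {a.residue_id} exceeds PDB field width")
        arr.coord[i] = a.position
        arr.atom_name[i] = a.name
        arr.element[i] = a.element or a.name[:1]
        arr.res_name[i] = a.residue_name
        arr.res_id[i] = a.residue_id
        arr.chain_id[i] = a.chain_id
        arr.atom_id[i] = a.serial
    arr.hetero[:] = False
    return arr


def write_pdb(obj: Structure | Trajectory, path: str | Path) -> Path:
    """Write a Structure (single model) or Trajectory (MODEL/ENDMDL blocks)."""
    path = Path(path)
    pdb_file = btpdb.PDBFile()
    if isinstance(obj, Structure):
        pdb_file.set_structure(_array_from_structure(obj))
    else:
        arrays = [_array_from_structure(fr) for fr in obj.frames]
        stack = bts.stack(arrays)
        pdb_file.set_structure(stack)
    pdb_file.write(path)
    return path


# --------------------------------------------------------------------------
# Parameter assignment
# --------------------------------------------------------------------------

def assign_params(structure: Structure, table: ParamTable) -> Structure:
    """Return a copy with radius/charge/LJ fields filled from ``table``.

    Collects every unresolvable atom before raising, so the error message
    lists all offending (residue, atom) pairs at once.
    """
    out = structure.copy()
    missing = []
    for atom in out.atoms:
        try:
            rad, q, eps, rmin = table.lookup(atom.residue_name, atom.name,
                                             atom.element)
        except ParameterizationError:
            missing.append((atom.residue_name, atom.name))
            continue
        atom.radius, atom.charge = rad, q
        atom.lj_epsilon, atom.lj_rmin_half = eps, rmin
    if missing:
        raise ParameterizationError(f"unresolvable atoms: {missing}")
    return out


# --------------------------------------------------------------------------
# Sulfoxide building
# --------------------------------------------------------------------------

def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = axis
    return np.array([
        [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
        [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
        [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
    ])


def _overlap_score(pos: np.ndarray, others: np.ndarray, other_radii: np.ndarray,
                   r_new: float) -> float:
    if len(others) == 0:
        return 0.0
    d = np.linalg.norm(others - pos, axis=1)
    pen = np.maximum(0.0, (other_radii + r_new) - d)
    return float(np.sum(pen ** 2))


def build_sulfoxide(structure: Structure, residue_id: int,
                    chain_id: str | None = None,
                    resname: str = SULFOXIDE_RESNAME) -> Structure:
    """Convert one methionine to methionine sulfoxide.

    A single oxygen (name OD) is bonded to SD at the packaged S=O length,
    initially along the negative bisector of the CG-SD-CE angle, then
    rotated about the CG-SD axis over a 24-point, 15-degree grid to the
    angle with the lowest steric-overlap score against all atoms outside
    the mutated residue.  Every other atom is left untouched, mimicking a
    fixed-environment relaxation of the mutated side chain only.
    """
    idx = structure.residue_indices(residue_id, chain_id)
    if not idx:
        raise SelectionError(f"no residue with id {residue_id}")
    res_atoms = [structure.atoms[i] for i in idx]
    res_name = res_atoms[0].residue_name
    if res_name != "MET":
        raise TypeError(f"residue {residue_id} is {res_name}, not MET")
    by_name = {a.name: i for a, i in zip(res_atoms, idx)}
    for needed in ("CG", "SD", "CE"):
        if needed not in by_name:
            raise IncompleteResidueError(
                f"MET {residue_id} lacks atom {needed}")

    out = structure.copy()
    cg = out.atoms[by_name["CG"]].position
    sd = out.atoms[by_name["SD"]].position
    ce = out.atoms[by_name["CE"]].position
    u_cg = (cg - sd) / np.linalg.norm(cg - sd)
    u_ce = (ce - sd) / np.linalg.norm(ce - sd)
    d0 = -(u_cg + u_ce)
    d0 /= np.linalg.norm(d0)
    axis = u_cg

    # environment = everything outside the mutated residue
    env_idx = [i for i in range(len(out.atoms)) if i not in set(idx)]
    env_pos = np.array([out.atoms[i].position for i in env_idx]).reshape(-1, 3)
    env_rad = np.array([
        out.atoms[i].radius if out.atoms[i].radius is not None
        else _ELEMENT_RADII.get(out.atoms[i].element, _ELEMENT_RADII["X"])
        for i in env_idx
    ])
    r_o = _ELEMENT_RADII["O"]

    best_pos, best_score = None, np.inf
    for k in range(SULFOXIDE_GRID_COUNT):
        ang = np.deg2rad(k * SULFOXIDE_GRID_STEP_DEG)
        direction = _rotation_matrix(axis, ang) @ d0
        cand = sd + SULFOXIDE_SO_BOND * direction
        score = _overlap_score(cand, env_pos, env_rad, r_o)
        if score < best_score - 1e-12:  # strict improvement; ties keep earlier angle
            best_pos, best_score = cand, score

    last = max(idx)
    new_serial = max(a.serial for a in out.atoms) + 1
    od = Atom(serial=new_serial, name="OD", element="O", residue_name=resname,
              residue_id=residue_id, chain_id=res_atoms[0].chain_id,
              position=best_pos)
    for i in idx:
        out.atoms[i].residue_name = resname
    out.atoms.insert(last + 1, od)
    out.provenance = (structure.provenance + f" +sulfoxide({residue_id})").strip()
    return out


def sulfoxide_overlap_score(structure: Structure, residue_id: int,
                            chain_id: str | None = None) -> float:
    """Steric-overlap score of an already-placed sulfoxide oxygen (OD)
    against all atoms outside its residue.  Diagnostic companion to
    :func:`build_sulfoxide`."""
    idx = structure.residue_indices(residue_id, chain_id)
    by_name = {structure.atoms[i].name: i for i in idx}
    if "OD" not in by_name:
        raise IncompleteResidueError(f"residue {residue_id} has no OD atom")
    pos = structure.atoms[by_name["OD"]].position
    env_idx = [i for i in range(len(structure.atoms)) if i not in set(idx)]
    env_pos = np.array([structure.atoms[i].position for i in env_idx]).reshape(-1, 3)
    env_rad = np.array([
        structure.atoms[i].radius if structure.atoms[i].radius is not None
        else _ELEMENT_RADII.get(structure.atoms[i].element, _ELEMENT_RADII["X"])
        for i in env_idx
    ])
    return _overlap_score(pos, env_pos, env_rad, _ELEMENT_RADII["O"])
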