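"""Per-frame and per-trajectory structural metrics.

Implements solvent accessible surface area (Shrake-Rupley sphere sampling
on a deterministic golden-section spiral), geometric hydrogen-bond
detection, switched Coulomb/Lennard-Jones group interaction energies, and
centered running averages of time series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import (
    COULOMB_KCAL,
    DEFAULT_PROBE_RADIUS,
    DEFAULT_SASA_POINTS,
)
from .errors import (
    DomainError,
    GeometryError,
    ParameterizationError,
    SelectionError,
)
from .structure import AtomSet, Structure, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "SASAResult", "HBondCriteria", "HBond", "HBondList", "EnergyPair",
    "Series", "golden_spiral_points", "sasa_frame", "sasa_series",
    "detect_hbonds_frame", "hbond_fraction", "interaction_energy",
    "switching_function", "running_average",
]


# --------------------------------------------------------------------------
# Time series container
# --------------------------------------------------------------------------

@dataclass
class Series:
    """A labelled time series (times in ps)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise DomainError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise DomainError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_tsv(self, path: str | Path) -> Path:
        pd.DataFrame({"time_ps": self.times, "value": self.values,
                      "label": self.label}).to_csv(path, sep="\t", index=False)
        return Path(path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Series":
        df = pd.read_csv(path, sep="\t")
        label = str(df["label"].iloc[0]) if "label" in df and len(df) else ""
        return cls(df["time_ps"].to_numpy(), df["value"].to_numpy(), label)


# --------------------------------------------------------------------------
# SASA
# --------------------------------------------------------------------------

@dataclass
class SASAResult:
    per_atom: dict[int, float]
    group_total: float
    probe_radius: float
    n_points: int


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit-sphere points on a golden-section spiral.

    Deterministic; the same point set is used for every atom, which makes
    the quadrature reproducible across runs and platforms.
    """
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa_frame(structure: Structure, group: AtomSet,
               probe: float = DEFAULT_PROBE_RADIUS,
               n_points: int = DEFAULT_SASA_POINTS) -> SASAResult:
    """Shrake-Rupley SASA of ``group`` atoms within the whole structure.

    Each group atom's sphere is expanded by the probe radius and sampled
    with the deterministic spiral point set; a point counts as accessible
    when it lies outside every *other* atom's expanded sphere (all atoms
    of the structure occlude, not only group members).
    """
    if n_points < 32:
        raise DomainError("n_points must be >= 32")
    group.validate(structure)
    coords = structure.coords()
    radii = structure.radii()
    expanded = radii + probe
    unit = golden_spiral_points(n_points)

    per_atom: dict[int, float] = {}
    for i in group.sorted():
        ri = expanded[i]
        pts = coords[i] + ri * unit
        # neighbour pruning: only atoms whose expanded sphere can reach
        d = np.linalg.norm(coords - coords[i], axis=1)
        neigh = np.where((d < ri + expanded) & (np.arange(len(d)) != i))[0]
        if len(neigh) == 0:
            frac = 1.0
        else:
            diff = pts[:, None, :] - coords[neigh][None, :, :]
            dist2 = np.einsum("ijk,ijk->ij", diff, diff)
            buried = np.any(dist2 < (expanded[neigh] ** 2)[None, :] - 1e-12,
                            axis=1)
            frac = 1.0 - buried.mean()
        per_atom[i] = 4.0 * np.pi * ri * ri * frac
    return SASAResult(per_atom=per_atom, group_total=float(sum(per_atom.values())),
                      probe_radius=probe, n_points=n_points)


def sasa_series(trajectory: Trajectory, group: AtomSet,
                probe: float = DEFAULT_PROBE_RADIUS,
                n_points: int = DEFAULT_SASA_POINTS,
                label: str = "sasa") -> Series:
    """Group SASA per frame, times taken from the frame interval."""
    if len(trajectory) == 0:
        raise DomainError("empty trajectory")
    values = [sasa_frame(fr, group, probe, n_points).group_total
              for fr in trajectory.frames]
    return Series(trajectory.times(), np.array(values), label=label)


# --------------------------------------------------------------------------
# Hydrogen bonds
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criteria: H...acceptor distance cutoff (A, inclusive) and
    donor-H...acceptor angle minimum (degrees, inclusive)."""

    max_h_acceptor_distance: float = 2.7
    min_donor_angle: float = 120.0

    def __post_init__(self) -> None:
        if self.max_h_acceptor_distance <= 0:
            raise DomainError("distance cutoff must be positive")
        if not (0 < self.min_donor_angle <= 180):
            raise DomainError("angle cutoff must be in (0, 180]")


@dataclass(frozen=True)
class HBond:
    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    distance: float
    angle: float


HBondList = list[HBond]

#: hydrogens are attached to a donor heavy atom by the name-prefix rule
#: (name starts with H) plus proximity
_H_ATTACH_DIST = 1.2


def _attached_hydrogens(structure: Structure, heavy_index: int) -> list[int]:
    heavy = structure.atoms[heavy_index]
    out = []
    for j, a in enumerate(structure.atoms):
        if j == heavy_index or not a.name.startswith("H"):
            continue
        if a.residue_id != heavy.residue_id or a.chain_id != heavy.chain_id:
            continue
        if np.linalg.norm(a.position - heavy.position) < _H_ATTACH_DIST:
            out.append(j)
    return out


def detect_hbonds_frame(structure: Structure, donors: AtomSet,
                        acceptors: AtomSet,
                        criteria: HBondCriteria = HBondCriteria()) -> HBondList:
    """Hydrogen bonds between donor heavy atoms and acceptors in one frame.

    A (donor, H, acceptor) triple qualifies iff the H...acceptor distance
    is <= the cutoff and the donor-H...acceptor angle (vertex at H) is >=
    the angle cutoff; both boundaries inclusive.  Donors without an
    attached hydrogen are skipped with a warning.
    """
    bonds: HBondList = []
    for d in donors.sorted():
        hydrogens = _attached_hydrogens(structure, d)
        if not hydrogens:
            logger.warning("donor atom %d (%s) has no attached hydrogen; skipped",
                           structure.atoms[d].serial, structure.atoms[d].name)
            continue
        dpos = structure.atoms[d].position
        for h in hydrogens:
            hpos = structure.atoms[h].position
            for a in acceptors.sorted():
                if a in (d, h):
                    continue
                apos = structure.atoms[a].position
                dist = float(np.linalg.norm(apos - hpos))
                if dist > criteria.max_h_acceptor_distance or dist == 0.0:
                    continue
                v1 = dpos - hpos
                v2 = apos - hpos
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                if angle + 1e-9 >= criteria.min_donor_angle:
                    bonds.append(HBond(d, h, a, dist, angle))
    return bonds


def hbond_fraction(trajectory: Trajectory, residue_group: AtomSet,
                   solvent_group: AtomSet,
                   criteria: HBondCriteria = HBondCriteria()) -> float:
    """Fraction of frames with >= 1 hydrogen bond between the groups.

    Both donor/acceptor role assignments are tried (residue as donor with
    solvent as acceptor, and vice versa), matching the hydration reading:
    a frame counts if any qualifying bond links the two groups.
    """
    if len(trajectory) == 0:
        raise DomainError("empty trajectory")
    n_bonded = 0
    for frame in trajectory.frames:
        bonds = detect_hbonds_frame(frame, residue_group, solvent_group, criteria)
        if not bonds:
            bonds = detect_hbonds_frame(frame, solvent_group, residue_group,
                                        criteria)
        if bonds:
            n_bonded += 1
    return n_bonded / len(trajectory)


# --------------------------------------------------------------------------
# Interaction energies
# --------------------------------------------------------------------------

@dataclass
class EnergyPair:
    electrostatic: float
    van_der_waals: float
    cutoff: float
    switch_on: float

    @property
    def total(self) -> float:
        return self.electrostatic + self.van_der_waals


def switching_function(r: np.ndarray, switch_on: float, cutoff: float) -> np.ndarray:
    """CHARMM-style C1-continuous switch: 1 below ``switch_on``, 0 beyond
    ``cutoff``, polynomial in between::

        S(r) = (roff^2 - r^2)^2 (roff^2 + 2 r^2 - 3 ron^2) / (roff^2 - ron^2)^3
    """
    r = np.asarray(r, dtype=float)
    ron2, roff2, r2 = switch_on ** 2, cutoff ** 2, r ** 2
    mid = ((roff2 - r2) ** 2 * (roff2 + 2 * r2 - 3 * ron2)
           / (roff2 - ron2) ** 3)
    return np.where(r <= switch_on, 1.0, np.where(r >= cutoff, 0.0, mid))


def interaction_energy(structure: Structure, group_a: AtomSet, group_b: AtomSet,
                       cutoff: float = 10.0, switch_on: float = 8.0) -> EnergyPair:
    """Switched pairwise Coulomb + Lennard-Jones energy between two groups.

    Parameters must have been assigned (charge, LJ epsilon/r_min per atom).
    Combination rules: geometric epsilon, arithmetic r_min.  Both energy
    terms are multiplied by the switching polynomial.
    """
    if group_a.indices & group_b.indices:
        raise SelectionError("interaction groups must be disjoint")
    ia, ib = group_a.sorted(), group_b.sorted()
    coords = structure.coords()
    for i in ia + ib:
        at = structure.atoms[i]
        if at.charge is None or at.lj_epsilon is None or at.lj_rmin_half is None:
            raise ParameterizationError(
                f"atom {at.serial} ({at.residue_name} {at.name}) lacks parameters")
    qa = np.array([structure.atoms[i].charge for i in ia])
    qb = np.array([structure.atoms[i].charge for i in ib])
    ea = np.array([structure.atoms[i].lj_epsilon for i in ia])
    eb = np.array([structure.atoms[i].lj_epsilon for i in ib])
    ra = np.array([structure.atoms[i].lj_rmin_half for i in ia])
    rb = np.array([structure.atoms[i].lj_rmin_half for i in ib])

    diff = coords[ia][:, None, :] - coords[ib][None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    if np.any(r == 0):
        raise GeometryError("coincident atoms across interaction groups")
    s = switching_function(r, switch_on, cutoff)
    within = r < cutoff

    elec = COULOMB_KCAL * np.outer(qa, qb) / r * s
    eps = np.sqrt(np.outer(ea, eb))
    rmin = ra[:, None] + rb[None, :]
    ratio6 = (rmin / r) ** 6
    vdw = eps * (ratio6 ** 2 - 2.0 * ratio6) * s
    return EnergyPair(
        electrostatic=float(np.sum(elec[within])),
        van_der_waals=float(np.sum(vdw[within])),
        cutoff=cutoff, switch_on=switch_on,
    )


# --------------------------------------------------------------------------
# Running averages
# --------------------------------------------------------------------------

def running_average(series: Series, window: float) -> Series:
    """Centered moving mean over all samples within +/- window/2, truncated
    at the edges; output times are unchanged."""
    t, v = series.times, series.values
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise DomainError("times must be strictly increasing")
    half = window / 2.0
    out = np.empty_like(v)
    for k in range(len(t)):
        mask = np.abs(t - t[k]) <= half + 1e-9
        out[k] = v[mask].mean()
    return Series(t.copy(), out, label=series.label)
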