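"""Coarse-grained constant-velocity pulling and rupture-force analysis.

The toy model is a Go-like bead chain arranged as a caged hydrophobic
core: a body block of beads forms a shell around a stack of core beads,
and a helix block (the C-terminal-helix analog) caps the core.  Native
contacts between the helix block and the rest of the model are marked
oxidizable; methionine oxidation is emulated by scaling their well depth
by a factor < 1, weakening core packing.  Pulling attaches a virtual
spring between a handle bead and a dummy point moving at constant
velocity; the applied force follows Hook's law F = k * dx.

Dynamics are Langevin (BAOAB splitting); with zero friction the
integrator reduces to velocity Verlet, which the energy-conservation
tests exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .constants import ACCEL_CONV, KB_KCAL, PN_PER_KCAL_PER_MOL_A
from .errors import DomainError, InstabilityError, TopologyError
from .metrics import Series, golden_spiral_points, sasa_frame
from .structure import Atom, AtomSet, Structure, Trajectory

__all__ = [
    "ToyModelSpec", "ToyModel", "PullParams", "PullingTrace", "RuptureEvent",
    "build_toy_model", "run_cv_pulling", "spring_force", "detect_rupture",
    "potential_energy", "kinetic_energy",
]


# --------------------------------------------------------------------------
# Model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyModelSpec:
    """Construction parameters for the two-block toy fold.

    The shell beads sit on a deterministic spiral sphere of radius
    ``d_shell`` around the core; the top ``n_helix`` beads (by z) form the
    separable helix block.  Contacts crossing the helix/body boundary are
    oxidizable; ``oxidation_factor`` scales their well depth (1.0 =
    unoxidized).
    """

    n_shell: int = 14
    n_helix: int = 3
    n_core: int = 3
    d_shell: float = 6.2
    core_spacing: float = 2.4
    bead_radius: float = 3.0
    mass: float = 50.0
    k_bond: float = 50.0
    eps_body: float = 6.0
    eps_helix: float = 4.0
    oxidation_factor: float = 1.0
    contact_cutoff: float = 8.0
    rep_epsilon: float = 2.0
    handle_offset: float = 4.0
    handle_lateral: float = 7.0
    jitter: float = 0.05


@dataclass
class ToyModel:
    positions: np.ndarray            # (n, 3) A
    bonds: np.ndarray                # (nb, 2) int
    bond_k: np.ndarray               # kcal/mol/A^2
    bond_r0: np.ndarray              # A
    contacts: np.ndarray             # (nc, 2) int
    contact_eps: np.ndarray          # kcal/mol
    contact_r0: np.ndarray           # A
    contact_oxidizable: np.ndarray   # bool
    core_set: AtomSet
    helix_set: AtomSet
    fixed_index: int
    pulled_index: int
    bead_radius: float
    mass: float
    rep_epsilon: float
    spec: ToyModelSpec

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def to_structure(self, positions: np.ndarray | None = None) -> Structure:
        pos = self.positions if positions is None else positions
        atoms = [
            Atom(serial=i + 1, name="BD", element="C", residue_name="BEA",
                 residue_id=i + 1, chain_id="T", position=pos[i],
                 radius=self.bead_radius)
            for i in range(len(pos))
        ]
        return Structure(atoms, provenance="toy pulling model")


def build_toy_model(spec: ToyModelSpec = ToyModelSpec(), seed: int = 0
                    ) -> ToyModel:
    """Deterministic toy fold for a given (spec, seed).

    The seed only jitters bead positions by ``spec.jitter`` A so replicate
    builds differ slightly, as replicate starting structures would.
    Changing only ``oxidation_factor`` changes only the oxidizable
    contacts' well depths.
    """
    rng = np.random.default_rng(seed)
    shell_unit = golden_spiral_points(spec.n_shell)
    order = np.argsort(shell_unit[:, 2])          # ascending z
    shell = shell_unit[order] * spec.d_shell
    n_body = spec.n_shell - spec.n_helix
    body = shell[:n_body]
    helix = shell[n_body:]

    core = np.array([[0.0, 0.0, k * spec.core_spacing]
                     for k in range(spec.n_core)])
    anchor = np.array([[0.0, 0.0, -(spec.d_shell + spec.handle_offset)]])
    # lateral handle offset tilts the pull axis so the undocked helix
    # block slides clear of the core instead of hovering above it
    handle = np.array([[spec.handle_lateral, 0.0,
                        spec.d_shell + spec.handle_offset]])

    # slack linker between the shell rim and the helix block: a zig-zag
    # of contact-free beads bulging radially outward, standing in for the
    # chain that pays out when the helix undocks, so the freed block can
    # be carried away without dragging the body
    rim = body[-1]
    helix_bottom = helix[0]
    linker = []
    for k, bulge in enumerate((6.0, 8.0, 6.0), start=1):
        base = rim + (helix_bottom - rim) * (k / 4.0)
        radial = base - np.array([0.0, 0.0, base[2]])
        radial = radial / max(np.linalg.norm(radial), 1e-6)
        linker.append(base + radial * bulge)
    linker = np.array(linker)

    # chain order: anchor, core, body (bottom-up), linker, helix
    # (bottom-up), handle
    pos = np.vstack([anchor, core, body, linker, helix, handle])
    pos = pos + rng.normal(0.0, spec.jitter, size=pos.shape)
    n = len(pos)
    n_linker = len(linker)
    first_linker = 1 + spec.n_core + n_body
    linker_ids = set(range(first_linker, first_linker + n_linker))
    helix_ids = set(range(first_linker + n_linker, n))  # helix beads + handle
    core_ids = set(range(1, 1 + spec.n_core))

    bonds = np.array([[i, i + 1] for i in range(n - 1)], dtype=np.int64)
    bond_r0 = np.array([np.linalg.norm(pos[i + 1] - pos[i])
                        for i in range(n - 1)])
    if np.any(bond_r0 > 2.5 * spec.d_shell):
        raise TopologyError("chain bonds too long; model disconnected")
    bond_k = np.full(n - 1, spec.k_bond)

    bonded = {(i, i + 1) for i in range(n - 1)}
    cpairs, ceps, cr0, coxi = [], [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in bonded:
                continue
            if i in linker_ids or j in linker_ids:
                continue  # linker beads form no native contacts
            d = float(np.linalg.norm(pos[j] - pos[i]))
            if d >= spec.contact_cutoff:
                continue
            oxidizable = (i in helix_ids) != (j in helix_ids)
            eps = spec.eps_helix if oxidizable else spec.eps_body
            if oxidizable:
                eps *= spec.oxidation_factor
            cpairs.append((i, j))
            ceps.append(eps)
            cr0.append(d)
            coxi.append(oxidizable)
    return ToyModel(
        positions=pos,
        bonds=bonds, bond_k=bond_k, bond_r0=bond_r0,
        contacts=np.array(cpairs, dtype=np.int64),
        contact_eps=np.array(ceps), contact_r0=np.array(cr0),
        contact_oxidizable=np.array(coxi, dtype=bool),
        core_set=AtomSet(frozenset(core_ids), "core"),
        helix_set=AtomSet(frozenset(helix_ids), "helix"),
        fixed_index=0, pulled_index=n - 1,
        bead_radius=spec.bead_radius, mass=spec.mass,
        rep_epsilon=spec.rep_epsilon,
        spec=spec,
    )


# --------------------------------------------------------------------------
# Pulling parameters and outputs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PullParams:
    """Constant-velocity protocol; defaults mirror the emulated all-atom setup
    (2 kcal/mol/A^2 spring pulled at 5 A/ns, 300 K, 2 fs steps, 10 ps
    recording cadence)."""

    spring_k: float = 2.0        # kcal/mol/A^2
    velocity: float = 5.0        # A/ns
    temperature: float = 300.0   # K
    friction: float = 0.5        # 1/ps
    dt: float = 2.0              # fs
    duration: float = 4.0        # ns
    record_interval: float = 10.0  # ps

    def __post_init__(self) -> None:
        if self.spring_k < 0 or self.velocity < 0 or self.dt <= 0:
            raise DomainError("spring_k/velocity must be >= 0 and dt > 0")


@dataclass
class PullingTrace:
    """Recorded pulling observables; force = spring_k * extension at every
    record by construction."""

    times: np.ndarray            # ps
    dummy_position: np.ndarray   # A, projection on pull axis
    pulled_position: np.ndarray  # A, projection on pull axis
    extension: np.ndarray        # A
    force: np.ndarray            # kcal/mol/A
    core_sasa: np.ndarray        # A^2
    potential_energy: np.ndarray | None = None  # kcal/mol (diagnostic)
    kinetic_energy: np.ndarray | None = None    # kcal/mol (diagnostic)

    @property
    def force_pn(self) -> np.ndarray:
        return self.force * PN_PER_KCAL_PER_MOL_A

    def force_series(self, unit: str = "kcal") -> Series:
        vals = self.force if unit == "kcal" else self.force_pn
        return Series(self.times, vals, label=f"force_{unit}")

    def sasa_series(self) -> Series:
        return Series(self.times, self.core_sasa, label="core_sasa")

    def to_tsv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({
            "time_ps": self.times, "dummy_A": self.dummy_position,
            "pulled_A": self.pulled_position, "extension_A": self.extension,
            "force_kcalmolA": self.force, "force_pN": self.force_pn,
            "core_sasa_A2": self.core_sasa,
        }).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PullingTrace":
        import pandas as pd
        df = pd.read_csv(path, sep="\t")
        return cls(df["time_ps"].to_numpy(), df["dummy_A"].to_numpy(),
                   df["pulled_A"].to_numpy(), df["extension_A"].to_numpy(),
                   df["force_kcalmolA"].to_numpy(),
                   df["core_sasa_A2"].to_numpy())


@dataclass
class RuptureEvent:
    crossing_time: float    # ps
    peak_time: float        # ps
    peak_force: float       # kcal/mol/A
    peak_force_pn: float    # pN
    window: float           # ps
    threshold: float        # A^2


# --------------------------------------------------------------------------
# Forces / integrator (numba kernels)
# --------------------------------------------------------------------------

@njit(cache=False)
def _forces(pos, bonds, bond_k, bond_r0, cpairs, ceps, cr0, excl,
            rep_eps, rep_sigma, out):
    n = pos.shape[0]
    out[:] = 0.0
    e = 0.0
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx0 = pos[j, 0] - pos[i, 0]
        dx1 = pos[j, 1] - pos[i, 1]
        dx2 = pos[j, 2] - pos[i, 2]
        r = math.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        e += 0.5 * bond_k[b] * (r - bond_r0[b]) ** 2
        fmag = bond_k[b] * (r - bond_r0[b]) / r
        out[i, 0] += fmag * dx0; out[i, 1] += fmag * dx1; out[i, 2] += fmag * dx2
        out[j, 0] -= fmag * dx0; out[j, 1] -= fmag * dx1; out[j, 2] -= fmag * dx2
    for c in range(cpairs.shape[0]):
        i, j = cpairs[c, 0], cpairs[c, 1]
        dx0 = pos[j, 0] - pos[i, 0]
        dx1 = pos[j, 1] - pos[i, 1]
        dx2 = pos[j, 2] - pos[i, 2]
        r = math.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        s = cr0[c] / r
        s10 = s ** 10
        s12 = s10 * s * s
        e += ceps[c] * (5.0 * s12 - 6.0 * s10)
        # dU/dr = -60 eps (s^12 - s^10) / r ; force on j along +dx
        fmag = 60.0 * ceps[c] * (s12 - s10) / (r * r)
        out[j, 0] += fmag * dx0; out[j, 1] += fmag * dx1; out[j, 2] += fmag * dx2
        out[i, 0] -= fmag * dx0; out[i, 1] -= fmag * dx1; out[i, 2] -= fmag * dx2
    sig2 = rep_sigma * rep_sigma
    for i in range(n):
        for j in range(i + 1, n):
            if excl[i, j] == 1:
                continue
            dx0 = pos[j, 0] - pos[i, 0]
            dx1 = pos[j, 1] - pos[i, 1]
            dx2 = pos[j, 2] - pos[i, 2]
            r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
            if r2 >= sig2:
                continue
            r = math.sqrt(r2)
            s12 = (rep_sigma / r) ** 12
            e += rep_eps * (s12 - 1.0)
            fmag = 12.0 * rep_eps * s12 / r2
            out[j, 0] += fmag * dx0; out[j, 1] += fmag * dx1; out[j, 2] += fmag * dx2
            out[i, 0] -= fmag * dx0; out[i, 1] -= fmag * dx1; out[i, 2] -= fmag * dx2
    return e


@njit(cache=False)
def _run_pulling(pos0, mass, bonds, bond_k, bond_r0, cpairs, ceps, cr0,
                 excl, rep_eps, rep_sigma, fixed_i, pulled_i, axis,
                 spring_k, v_aps, temperature, gamma, dt, n_steps,
                 record_every, seed):
    np.random.seed(seed)
    n = pos0.shape[0]
    pos = pos0.copy()
    vel = np.random.standard_normal((n, 3)) * math.sqrt(
        KB_KCAL * temperature * ACCEL_CONV / mass)
    vel[fixed_i] = 0.0
    f = np.zeros((n, 3))
    _forces(pos, bonds, bond_k, bond_r0, cpairs, ceps, cr0, excl,
            rep_eps, rep_sigma, f)
    origin = pos0[pulled_i].copy()

    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(KB_KCAL * temperature * ACCEL_CONV / mass * (1.0 - c1 * c1))
    conv = ACCEL_CONV / mass

    n_rec = n_steps // record_every + 1
    trace = np.zeros((n_rec, 5))       # dummy, pulled, extension, pe, ke
    frames = np.zeros((n_rec, n, 3))
    rec = 0
    status = 0

    # force at t = 0 (conservative + spring); reused across the step join
    pe = _forces(pos, bonds, bond_k, bond_r0, cpairs, ceps, cr0, excl,
                 rep_eps, rep_sigma, f)
    if spring_k > 0.0:
        f[pulled_i] += spring_k * (origin - pos[pulled_i])
    f[fixed_i] = 0.0

    for step in range(n_steps + 1):
        t = step * dt
        if step % record_every == 0:
            dummy = origin + axis * (v_aps * t)
            dproj = (dummy[0] * axis[0] + dummy[1] * axis[1]
                     + dummy[2] * axis[2])
            pproj = (pos[pulled_i, 0] * axis[0] + pos[pulled_i, 1] * axis[1]
                     + pos[pulled_i, 2] * axis[2])
            fpe = np.zeros((n, 3))
            pe = _forces(pos, bonds, bond_k, bond_r0, cpairs, ceps, cr0,
                         excl, rep_eps, rep_sigma, fpe)
            ke = 0.0
            for i in range(n):
                ke += (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
            trace[rec, 0] = dproj
            trace[rec, 1] = pproj
            trace[rec, 2] = dproj - pproj
            trace[rec, 3] = pe
            trace[rec, 4] = 0.5 * mass * ke / ACCEL_CONV
            frames[rec] = pos
            rec += 1
            for i in range(n):
                for d in range(3):
                    if abs(pos[i, d]) > 1.0e4:
                        status = 1
            if status == 1:
                break
        if step == n_steps:
            break
        # BAOAB step: B (half kick) A (half drift) O A B
        vel += 0.5 * dt * f * conv
        vel[fixed_i] = 0.0
        pos += 0.5 * dt * vel
        if gamma > 0.0:
            vel = c1 * vel + c2 * np.random.standard_normal((n, 3))
            vel[fixed_i] = 0.0
        pos += 0.5 * dt * vel
        _forces(pos, bonds, bond_k, bond_r0, cpairs, ceps, cr0, excl,
                rep_eps, rep_sigma, f)
        if spring_k > 0.0:
            t2 = (step + 1) * dt
            f[pulled_i, 0] += spring_k * (origin[0] + axis[0] * v_aps * t2
                                          - pos[pulled_i, 0])
            f[pulled_i, 1] += spring_k * (origin[1] + axis[1] * v_aps * t2
                                          - pos[pulled_i, 1])
            f[pulled_i, 2] += spring_k * (origin[2] + axis[2] * v_aps * t2
                                          - pos[pulled_i, 2])
        f[fixed_i] = 0.0
        vel += 0.5 * dt * f * conv
        vel[fixed_i] = 0.0
    return trace[:rec], frames[:rec], status


def _exclusion_matrix(model: ToyModel) -> np.ndarray:
    n = model.n_beads
    excl = np.zeros((n, n), dtype=np.int8)
    for i, j in model.bonds:
        excl[i, j] = excl[j, i] = 1
    for i, j in model.contacts:
        excl[i, j] = excl[j, i] = 1
    np.fill_diagonal(excl, 1)
    return excl


def potential_energy(model: ToyModel, positions: np.ndarray | None = None
                     ) -> float:
    """Bonded + contact + excluded-volume energy, kcal/mol."""
    pos = model.positions if positions is None else np.asarray(positions)
    f = np.zeros_like(pos)
    return float(_forces(pos, model.bonds, model.bond_k, model.bond_r0,
                         model.contacts, model.contact_eps, model.contact_r0,
                         _exclusion_matrix(model), model.rep_epsilon,
                         2.0 * model.bead_radius * 0.9, f))


def kinetic_energy(velocities: np.ndarray, mass: float) -> float:
    """Kinetic energy in kcal/mol for velocities in A/ps."""
    return float(0.5 * mass * np.sum(velocities ** 2) / ACCEL_CONV)


def run_cv_pulling(model: ToyModel, pull: PullParams = PullParams(),
                   seed: int = 0, compute_sasa: bool = True,
                   sasa_n_points: int = 480
                   ) -> tuple[PullingTrace, Trajectory]:
    """Langevin constant-velocity pulling of the toy model.

    The dummy moves from the pulled bead's initial position along the
    initial fixed->pulled axis.  The trace is recorded every
    ``record_interval`` ps; each recorded frame also yields the core
    group's SASA (beads occlude with their built radii).
    """
    if model.fixed_index == model.pulled_index:
        raise DomainError("fixed and pulled atoms must differ")
    axis = model.positions[model.pulled_index] - model.positions[model.fixed_index]
    axis = axis / np.linalg.norm(axis)
    dt_ps = pull.dt * 1e-3
    n_steps = int(round(pull.duration * 1000.0 / dt_ps))
    record_every = max(1, int(round(pull.record_interval / dt_ps)))
    v_aps = pull.velocity * 1e-3  # A/ns -> A/ps

    trace_arr, frames_arr, status = _run_pulling(
        model.positions.astype(np.float64), model.mass,
        model.bonds, model.bond_k, model.bond_r0,
        model.contacts, model.contact_eps, model.contact_r0,
        _exclusion_matrix(model), model.rep_epsilon,
        2.0 * model.bead_radius * 0.9,
        model.fixed_index, model.pulled_index, axis,
        pull.spring_k, v_aps, pull.temperature, pull.friction,
        dt_ps, n_steps, record_every, seed % (2 ** 31),
    )
    if status != 0:
        raise InstabilityError(
            "integrator blow-up (|coordinate| > 1e4 A); reduce dt")

    times = np.arange(len(trace_arr)) * record_every * dt_ps
    frames = [model.to_structure(frames_arr[k]) for k in range(len(frames_arr))]
    trajectory = Trajectory(frames, frame_interval=record_every * dt_ps)

    if compute_sasa:
        sasa = np.array([
            sasa_frame(fr, model.core_set, n_points=sasa_n_points).group_total
            for fr in frames
        ])
    else:
        sasa = np.full(len(frames), np.nan)
    return PullingTrace(
        times=times,
        dummy_position=trace_arr[:, 0],
        pulled_position=trace_arr[:, 1],
        extension=trace_arr[:, 2],
        force=pull.spring_k * trace_arr[:, 2],
        core_sasa=sasa,
        potential_energy=trace_arr[:, 3],
        kinetic_energy=trace_arr[:, 4],
    ), trajectory


def spring_force(dummy_position: np.ndarray, pulled_position: np.ndarray,
                 spring_k: float, axis: np.ndarray | None = None
                 ) -> tuple[float, float]:
    """Hook's-law applied force F = k * dx.

    dx is the signed projection of (dummy - pulled) onto the pull axis
    (the dummy-pulled direction itself if no axis is given).  Returns
    (force in kcal/mol/A, force in pN).
    """
    if spring_k < 0:
        raise DomainError("spring_k must be >= 0")
    diff = np.asarray(dummy_position, float) - np.asarray(pulled_position, float)
    if axis is None:
        dx = float(np.linalg.norm(diff))
    else:
        a = np.asarray(axis, float)
        dx = float(np.dot(diff, a / np.linalg.norm(a)))
    f = spring_k * dx
    return f, f * PN_PER_KCAL_PER_MOL_A


# --------------------------------------------------------------------------
# Rupture detection
# --------------------------------------------------------------------------

def detect_rupture(force_series: Series, sasa_series: Series,
                   threshold: float = 50.0, window: float = 400.0,
                   persistence: int = 2,
                   force_unit: str = "kcal") -> RuptureEvent | None:
    """Identify the rupture force peak from paired force/SASA series.

    The crossing time is the first record where SASA exceeds ``threshold``
    and stays above it for ``persistence`` consecutive records; the peak
    force is the maximum within a window of ``window`` ps centered on the
    crossing (earliest sample on ties).  Returns None when the SASA never
    crosses (no-event), and raises DomainError on empty input.  If the two
    series have different time bases the SASA is matched to force times by
    nearest time.
    """
    if len(force_series) == 0 or len(sasa_series) == 0:
        raise DomainError("empty series")
    t = force_series.times
    if (len(sasa_series) != len(t)
            or not np.allclose(sasa_series.times, t)):
        idx = np.abs(sasa_series.times[None, :] - t[:, None]).argmin(axis=1)
        sasa = sasa_series.values[idx]
    else:
        sasa = sasa_series.values

    above = sasa > threshold
    crossing_idx = None
    for k in range(len(above) - persistence + 1):
        if all(above[k:k + persistence]):
            crossing_idx = k
            break
    if crossing_idx is None:
        return None
    t_cross = t[crossing_idx]
    in_win = np.abs(t - t_cross) <= window / 2.0 + 1e-9
    forces = force_series.values[in_win]
    times_win = t[in_win]
    peak_pos = int(np.argmax(forces))  # argmax returns earliest maximum
    peak = float(forces[peak_pos])
    if force_unit == "kcal":
        f_kcal, f_pn = peak, peak * PN_PER_KCAL_PER_MOL_A
    else:
        f_kcal, f_pn = peak / PN_PER_KCAL_PER_MOL_A, peak
    return RuptureEvent(
        crossing_time=float(t_cross), peak_time=float(times_win[peak_pos]),
        peak_force=f_kcal, peak_force_pn=f_pn,
        window=window, threshold=threshold,
    )
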