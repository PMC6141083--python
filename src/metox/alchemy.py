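"""Alchemical free-energy machinery.

The transformation from methionine to methionine sulfoxide is modelled as
a coupling parameter lambda switched from 0 (unoxidized) to 1 (sulfoxide)
over a schedule of intermediate states; the per-window energy differences
collected in forward and backward passes feed the Zwanzig (EXP) and
Bennett acceptance ratio (BAR) estimators.  Paired folded/unfolded
estimates combine through the thermodynamic cycle into a ddG of folding:
positive ddG means oxidation destabilizes the fold.

All estimator math runs in reduced units (energies divided by k_B*T);
inputs and outputs are in kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Protocol

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, kbt
from .errors import DomainError, NonOverlapError, SamplerHealthError

__all__ = [
    "LambdaSchedule", "WorkData", "FreeEnergyEstimate", "DDGResult",
    "make_schedule", "softcore_potential", "ToyAlchemicalSystem",
    "HarmonicSwitchSystem", "SoftcoreSiteSystem", "buried_site_system",
    "exposed_site_system", "sample_windows", "exp_estimate", "bar_estimate",
    "run_alchemical", "ddg_cycle",
]


# --------------------------------------------------------------------------
# Schedule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LambdaSchedule:
    """Uniform lambda schedule: ``n_windows`` states from 0 to 1, each
    simulated for ``window_length`` ps with the first
    ``equilibration_fraction`` of the window discarded."""

    n_windows: int
    window_length: float
    equilibration_fraction: float
    lambdas: tuple[float, ...]

    @property
    def total_duration(self) -> float:
        return self.n_windows * self.window_length


def make_schedule(n_windows: int = 100, window_length: float = 100.0,
                  equilibration_fraction: float = 0.5) -> LambdaSchedule:
    """Default mirrors the emulated all-atom protocol: 100 states over a 10 ns
    sweep (0.1 ns per state), half equilibration / half collection."""
    if n_windows < 2:
        raise DomainError("need at least 2 lambda states")
    if not (0 <= equilibration_fraction < 1):
        raise DomainError("equilibration fraction must be in [0, 1)")
    if window_length <= 0:
        raise DomainError("window length must be positive")
    lambdas = tuple(np.linspace(0.0, 1.0, n_windows))
    return LambdaSchedule(n_windows, window_length, equilibration_fraction,
                          lambdas)


# --------------------------------------------------------------------------
# Work data
# --------------------------------------------------------------------------

@dataclass
class WorkData:
    """Per-window energy differences, kcal/mol.

    ``forward[i]`` holds u(lambda_{i+1}) - u(lambda_i) sampled at state i;
    ``backward[i]`` holds u(lambda_i) - u(lambda_{i+1}) sampled at state
    i+1.  Post-equilibration samples only.
    """

    lambdas: tuple[float, ...]
    forward: list[np.ndarray]
    backward: list[np.ndarray]
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise DomainError("temperature must be positive")
        n_win = len(self.lambdas) - 1
        if len(self.forward) != n_win or len(self.backward) != n_win:
            raise DomainError("window count mismatch with lambda schedule")

    @property
    def n_windows(self) -> int:
        return len(self.lambdas) - 1

    def to_tsv(self, path: str | Path) -> Path:
        rows = []
        for i in range(self.n_windows):
            for du in self.forward[i]:
                rows.append((i, self.lambdas[i], self.lambdas[i + 1], "F", du))
            for du in self.backward[i]:
                rows.append((i, self.lambdas[i], self.lambdas[i + 1], "B", du))
        df = pd.DataFrame(rows, columns=["window_index", "lambda_from",
                                         "lambda_to", "direction",
                                         "delta_u_kcalmol"])
        with open(path, "w") as fh:
            fh.write(f"# temperature_K = {self.temperature}\n")
            df.to_csv(fh, sep="\t", index=False)
        return Path(path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "WorkData":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# temperature_K"):
                raise DomainError("work TSV lacks temperature header")
            temperature = float(first.split("=")[1])
            df = pd.read_csv(fh, sep="\t")
        lambdas: list[float] = []
        forward, backward = [], []
        for w, grp in df.groupby("window_index", sort=True):
            lam_from = float(grp["lambda_from"].iloc[0])
            lam_to = float(grp["lambda_to"].iloc[0])
            if not lambdas:
                lambdas.append(lam_from)
            lambdas.append(lam_to)
            forward.append(grp.loc[grp.direction == "F",
                                   "delta_u_kcalmol"].to_numpy())
            backward.append(grp.loc[grp.direction == "B",
                                    "delta_u_kcalmol"].to_numpy())
        return cls(tuple(lambdas), forward, backward, temperature)


@dataclass
class FreeEnergyEstimate:
    delta_g: float
    standard_error: float
    method: str
    n_windows: int
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.standard_error < 0:
            raise DomainError("standard error must be >= 0")


@dataclass
class DDGResult:
    dg_folded: FreeEnergyEstimate
    dg_unfolded: FreeEnergyEstimate
    ddg: float
    standard_error: float


# --------------------------------------------------------------------------
# Soft-core potential
# --------------------------------------------------------------------------

def softcore_potential(r: float | np.ndarray, lam: float,
                       lj_epsilon: float, lj_rmin: float,
                       alpha: float = 0.5) -> float | np.ndarray:
    """Beutler-style soft-core Lennard-Jones, finite at r = 0 for lam < 1.

    V = lam * 4 eps * [ (1/(alpha(1-lam) + (r/sigma)^6))^2
                        - 1/(alpha(1-lam) + (r/sigma)^6) ]

    with sigma = r_min / 2^(1/6).  At lam = 1 this reduces to the standard
    12-6 Lennard-Jones potential; at lam = 0 it vanishes identically.
    """
    if alpha <= 0:
        raise DomainError("alpha must be positive")
    if not (0.0 <= lam <= 1.0):
        raise DomainError("lambda must lie in [0, 1]")
    sigma = lj_rmin / 2.0 ** (1.0 / 6.0)
    s6 = (np.asarray(r, dtype=float) / sigma) ** 6
    denom = alpha * (1.0 - lam) + s6
    with np.errstate(divide="ignore"):
        val = np.where(
            denom > 0.0,
            lam * 4.0 * lj_epsilon * (1.0 / np.maximum(denom, 1e-300) ** 2
                                      - 1.0 / np.maximum(denom, 1e-300)),
            np.inf,  # r = 0 at lam = 1: the bare LJ wall
        )
    if np.isscalar(r):
        return float(val)
    return val


# --------------------------------------------------------------------------
# Toy alchemical systems (1-D reaction coordinate)
# --------------------------------------------------------------------------

class ToyAlchemicalSystem(Protocol):
    """A one-dimensional system with a lambda-dependent potential."""

    step_size: float
    x0: float

    def energy(self, x: float, lam: float) -> float: ...


@dataclass
class HarmonicSwitchSystem:
    """Harmonic well whose stiffness interpolates linearly in lambda:
    U(x, lam) = 0.5 * ((1-lam) k0 + lam k1) x^2.

    The free-energy change has the closed form (k_B T / 2) ln(k1/k0),
    independent of the lambda path, which makes this the workhorse
    end-to-end oracle."""

    k0: float = 1.0
    k1: float = 4.0
    step_size: float = 1.0
    x0: float = 0.0

    def energy(self, x: float, lam: float) -> float:
        k = (1.0 - lam) * self.k0 + lam * self.k1
        return 0.5 * k * x * x

    def closed_form_dg(self, temperature: float = DEFAULT_TEMPERATURE) -> float:
        return 0.5 * kbt(temperature) * math.log(self.k1 / self.k0)


@dataclass
class SoftcoreSiteSystem:
    """A tethered site particle whose interaction with fixed environment
    neighbours is switched on through the soft-core potential.

    Emulates growing the sulfoxide oxygen at a methionine site: a buried
    site has close-packed neighbours and pays a large (positive) free
    energy to accommodate the new atom; a solvent-exposed site has distant
    neighbours and pays essentially nothing.
    """

    tether_k: float = 2.0
    neighbors: tuple[tuple[float, float, float], ...] = ()  # (pos A, eps, rmin)
    alpha: float = 0.5
    step_size: float = 0.6
    x0: float = 0.0

    def energy(self, x: float, lam: float) -> float:
        # scalar soft-core inlined: this runs in the Metropolis hot loop
        u = 0.5 * self.tether_k * x * x
        if lam == 0.0:
            return u
        a1 = self.alpha * (1.0 - lam)
        for pos, eps, rmin in self.neighbors:
            s6 = (x - pos) ** 6 / (rmin ** 6 / 2.0)  # (r/sigma)^6, sigma^6 = rmin^6/2
            denom = a1 + s6
            if denom <= 0.0:
                return math.inf  # on top of a neighbor at lam = 1
            u += lam * 4.0 * eps * (1.0 / (denom * denom) - 1.0 / denom)
        return u

    def exact_dg(self, temperature: float = DEFAULT_TEMPERATURE,
                 x_range: float = 12.0, n_grid: int = 20001) -> float:
        """Deterministic oracle: dG from direct Boltzmann integrals of the
        two endpoint potentials on a dense grid."""
        beta = 1.0 / kbt(temperature)
        x = np.linspace(-x_range, x_range, n_grid)
        u0 = np.array([self.energy(v, 0.0) for v in x])
        u1 = np.array([self.energy(v, 1.0) for v in x])
        # log of Z1/Z0 via shifted exponentials for stability
        log_z0 = logsumexp(-beta * u0)
        log_z1 = logsumexp(-beta * u1)
        return float(-(log_z1 - log_z0) / beta)


def buried_site_system() -> SoftcoreSiteSystem:
    """Site hemmed in by two close neighbours: alchemical growth is
    strongly coupled to the environment (folded, buried methionine).

    The neighbour spacing keeps the tether minimum the global minimum at
    every lambda, so the transformation stays ergodic for a local
    sampler while still costing several kcal/mol."""
    return SoftcoreSiteSystem(
        tether_k=2.0,
        neighbors=((3.0, 0.2, 4.0), (-3.0, 0.2, 4.0)),
    )


def exposed_site_system() -> SoftcoreSiteSystem:
    """Site with remote neighbours only: the transformation barely feels
    the environment (tripeptide-like, solvent-exposed methionine)."""
    return SoftcoreSiteSystem(
        tether_k=2.0,
        neighbors=((9.0, 0.2, 4.0), (-9.0, 0.2, 4.0)),
    )


# --------------------------------------------------------------------------
# Sampling
# --------------------------------------------------------------------------

def _metropolis(system: ToyAlchemicalSystem, lam: float, x: float,
                n_steps: int, n_collect: int, collect_lam: float | None,
                rng: np.random.Generator, beta: float
                ) -> tuple[float, np.ndarray, float]:
    """Metropolis chain at state ``lam``; during the last ``n_collect``
    steps records u(x, collect_lam) - u(x, lam).  Returns final x, the
    samples, and the acceptance rate."""
    delta = system.step_size
    u = system.energy(x, lam)
    samples = np.empty(n_collect)
    proposals = rng.uniform(-delta, delta, size=n_steps)
    accepts = rng.uniform(size=n_steps)
    n_acc = 0
    k = 0
    collect_from = n_steps - n_collect
    for step in range(n_steps):
        x_new = x + proposals[step]
        u_new = system.energy(x_new, lam)
        if u_new <= u or accepts[step] < math.exp(-beta * (u_new - u)):
            x, u = x_new, u_new
            n_acc += 1
        if step >= collect_from:
            samples[k] = system.energy(x, collect_lam) - u
            k += 1
    return x, samples, n_acc / n_steps


def sample_windows(system: ToyAlchemicalSystem, schedule: LambdaSchedule,
                   seed: int, steps_per_ps: float = 50.0,
                   temperature: float = DEFAULT_TEMPERATURE,
                   backward_from_forward: bool = True) -> WorkData:
    """Collect forward and backward per-window energy differences.

    The forward pass walks the lambda states 0 -> 1, carrying the
    configuration between windows; each window equilibrates for the
    schedule's equilibration fraction and then collects
    u(lambda_{i+1}) - u(lambda_i).  The backward pass starts from the
    final forward configuration (the chained convention;
    set ``backward_from_forward=False`` for an independently initialized
    diagnostic pass) and walks 1 -> 0 collecting the reverse differences.
    """
    beta = 1.0 / kbt(temperature)
    rng = np.random.default_rng(seed)
    n_steps = max(2, int(round(schedule.window_length * steps_per_ps)))
    n_eq = int(n_steps * schedule.equilibration_fraction)
    n_collect = n_steps - n_eq
    if n_collect < 1:
        raise DomainError("schedule leaves no collection phase")

    lam = schedule.lambdas
    n_win = len(lam) - 1
    forward: list[np.ndarray] = []
    x = system.x0
    for i in range(n_win):
        x, samples, acc = _metropolis(system, lam[i], x, n_steps, n_collect,
                                      lam[i + 1], rng, beta)
        if acc < 0.01:
            raise SamplerHealthError(
                f"window {i} (lambda={lam[i]:.3f}): acceptance {acc:.3%}")
        forward.append(samples)

    backward: list[np.ndarray] = [None] * n_win  # type: ignore[list-item]
    x = x if backward_from_forward else system.x0
    for i in reversed(range(n_win)):
        x, samples, acc = _metropolis(system, lam[i + 1], x, n_steps,
                                      n_collect, lam[i], rng, beta)
        if acc < 0.01:
            raise SamplerHealthError(
                f"window {i} backward (lambda={lam[i + 1]:.3f}): "
                f"acceptance {acc:.3%}")
        backward[i] = samples
    return WorkData(lam, forward, backward, temperature)


# --------------------------------------------------------------------------
# Estimators
# --------------------------------------------------------------------------

_BOOTSTRAP_BLOCKS = 20


def statistical_inefficiency(x: np.ndarray) -> float:
    """g = 1 + 2 * sum of the positive initial autocorrelations.

    Correlated Metropolis output carries fewer independent samples than
    its length; variances are scaled by g (n_eff = n / g).  The sum is
    truncated at the first non-positive autocorrelation (initial positive
    sequence rule)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        return 1.0
    dx = x - x.mean()
    var = float(np.dot(dx, dx)) / n
    if var <= 0:
        return 1.0
    g = 1.0
    for t in range(1, n // 2):
        rho = float(np.dot(dx[:-t], dx[t:])) / ((n - t) * var)
        if rho <= 0.0:
            break
        g += 2.0 * rho * (1.0 - t / n)
    return max(g, 1.0)


def _exp_window(du_reduced: np.ndarray) -> float:
    """Zwanzig estimate of beta*dG from reduced energy differences."""
    n = len(du_reduced)
    return -(logsumexp(-du_reduced) - math.log(n))


def _block_se(du_reduced: np.ndarray) -> float:
    """Block standard error of the per-window EXP estimate (reduced)."""
    n = len(du_reduced)
    n_blocks = min(_BOOTSTRAP_BLOCKS, n)
    if n_blocks < 2:
        return 0.0
    blocks = np.array_split(du_reduced, n_blocks)
    vals = np.array([_exp_window(b) for b in blocks])
    return float(vals.std(ddof=1) / math.sqrt(n_blocks))


def exp_estimate(work: WorkData,
                 direction: Literal["forward", "backward"] = "forward"
                 ) -> FreeEnergyEstimate:
    """One-directional exponential-average (Zwanzig) estimator.

    Forward uses the forward energy differences directly; backward uses
    the reverse differences with the sign flipped so both report the
    0 -> 1 free-energy change.  Standard error by per-window block
    averaging, windows combined in quadrature.
    """
    kt = kbt(work.temperature)
    total = 0.0
    var = 0.0
    for i in range(work.n_windows):
        du = work.forward[i] if direction == "forward" else work.backward[i]
        if len(du) == 0:
            raise DomainError(f"window {i}: no {direction} samples")
        du_red = du / kt
        g = _exp_window(du_red)
        if direction == "backward":
            g = -g
        total += g * kt
        var += (_block_se(du_red) * kt) ** 2
    return FreeEnergyEstimate(total, math.sqrt(var), f"EXP_{direction}",
                              work.n_windows, work.temperature)


def _fermi(x: np.ndarray) -> np.ndarray:
    # overflow-safe logistic 1/(1+exp(x))
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    return out


def _bar_window(wf: np.ndarray, wr: np.ndarray, tol: float
                ) -> tuple[float, float]:
    """Solve Bennett's self-consistent equation for one window.

    ``wf``/``wr`` are reduced forward/reverse energy differences.  Returns
    (dG, variance), both in reduced units.  The root of

        h(x) = sum f(M + wf - x) - sum f(-M + wr + x),   M = ln(nF/nR)

    is unique because h is monotone increasing; it is bracketed by
    doubling around the forward-EXP initial guess and refined by Brent's
    method.
    """
    nf, nr = len(wf), len(wr)
    m = math.log(nf / nr)

    def h(x: float) -> float:
        return float(_fermi(m + wf - x).sum() - _fermi(-m + wr + x).sum())

    x0 = _exp_window(wf)
    span = 1.0
    lo, hi = x0 - span, x0 + span
    for _ in range(64):
        if h(lo) < 0 < h(hi):
            break
        span *= 2.0
        lo, hi = x0 - span, x0 + span
    else:
        raise NonOverlapError(
            "Bennett equation has no bracketed root; forward and backward "
            "work distributions do not overlap — use more lambda windows")
    dg = brentq(h, lo, hi, xtol=tol)

    ff = _fermi(m + wf - dg)
    fr = _fermi(-m + wr + dg)
    # Bennett's asymptotic variance with effective sample sizes: the
    # Metropolis chains are autocorrelated, so n is deflated by the
    # statistical inefficiency of each direction's energy differences
    nf_eff = nf / statistical_inefficiency(wf)
    nr_eff = nr / statistical_inefficiency(wr)
    var = ((np.mean(ff ** 2) / np.mean(ff) ** 2 - 1.0) / nf_eff
           + (np.mean(fr ** 2) / np.mean(fr) ** 2 - 1.0) / nr_eff)
    return float(dg), max(var, 0.0)


def bar_estimate(work: WorkData, tolerance: float = 1e-8
                 ) -> FreeEnergyEstimate:
    """Bennett acceptance ratio estimate over all windows.

    Each window's dG solves the Bennett self-consistent equation to
    ``tolerance`` (in k_B T); window estimates are summed and Bennett's
    asymptotic variances added in quadrature.
    """
    kt = kbt(work.temperature)
    total = 0.0
    var = 0.0
    for i in range(work.n_windows):
        wf = np.asarray(work.forward[i]) / kt
        wr = np.asarray(work.backward[i]) / kt
        if len(wf) == 0 or len(wr) == 0:
            raise DomainError(f"window {i}: BAR needs samples in both directions")
        dg, v = _bar_window(wf, wr, tolerance)
        total += dg * kt
        var += v * kt * kt
    return FreeEnergyEstimate(total, math.sqrt(var), "BAR",
                              work.n_windows, work.temperature)


def run_alchemical(system: ToyAlchemicalSystem, schedule: LambdaSchedule,
                   seed: int, steps_per_ps: float = 50.0,
                   temperature: float = DEFAULT_TEMPERATURE
                   ) -> FreeEnergyEstimate:
    """Sample all windows and combine with BAR (the production pipeline)."""
    work = sample_windows(system, schedule, seed, steps_per_ps, temperature)
    return bar_estimate(work)


# --------------------------------------------------------------------------
# Thermodynamic cycle
# --------------------------------------------------------------------------

def ddg_cycle(folded: FreeEnergyEstimate,
              unfolded: FreeEnergyEstimate) -> DDGResult:
    """ddG of folding upon oxidation from the two alchemical legs.

    ddG = dG_alch(folded) - dG_alch(unfolded); positive values mean the
    oxidation is thermodynamically unfavorable for folding.  Standard
    errors combine in quadrature.
    """
    if abs(folded.temperature - unfolded.temperature) > 1e-9:
        raise DomainError("folded/unfolded estimates at different temperatures")
    ddg = folded.delta_g - unfolded.delta_g
    se = math.sqrt(folded.standard_error ** 2 + unfolded.standard_error ** 2)
    return DDGResult(folded, unfolded, ddg, se)
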