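"""SASA quadrature, hydrogen-bond criteria, switched interaction
energies and running averages, each against an independent oracle."""

import math

import numpy as np
import pytest

from metox.errors import DomainError, SelectionError
from metox.metrics import (
    HBondCriteria, Series, detect_hbonds_frame, hbond_fraction,
    golden_spiral_points, interaction_energy, running_average, sasa_frame,
    sasa_series, switching_function,
)
from metox.structure import Atom, AtomSet, Structure, Trajectory

from conftest import make_water


def bead(i, pos, radius=1.9, **kw):
    return Atom(i, "BD", "C", "BEA", i, "A", np.asarray(pos, float),
                radius=radius, **kw)


# ------------------------------------------------------------------ SASA

def test_sasa_isolated_sphere_matches_analytic():
    s = Structure([bead(1, [0, 0, 0])])
    r = sasa_frame(s, AtomSet(frozenset({0})), probe=1.4, n_points=960)
    analytic = 4 * math.pi * 3.3 ** 2
    assert r.group_total == pytest.approx(analytic, rel=0.02)


def test_sasa_disjoint_spheres_additive():
    s = Structure([bead(1, [0, 0, 0]), bead(2, [100, 0, 0])])
    both = sasa_frame(s, AtomSet(frozenset({0, 1})))
    one = sasa_frame(s, AtomSet(frozenset({0})))
    assert both.group_total == pytest.approx(2 * one.group_total, rel=1e-9)
    assert both.group_total == pytest.approx(
        sum(both.per_atom.values()), abs=1e-6)


def test_sasa_fully_buried_atom_is_zero():
    shell_dirs = golden_spiral_points(30)
    atoms = [bead(1, [0, 0, 0])]
    for k, d in enumerate(shell_dirs, start=2):
        atoms.append(bead(k, d * 2 * 1.9 * 0.9))
    s = Structure(atoms)
    r = sasa_frame(s, AtomSet(frozenset({0})))
    assert r.group_total == 0.0


def _mc_sasa(coords, radii, probe, n_mc, rng):
    """Monte-Carlo point-rejection oracle: uniform random points on each
    expanded sphere, accepted if outside all other expanded spheres."""
    expanded = radii + probe
    total = 0.0
    for i in range(len(coords)):
        pts = rng.normal(size=(n_mc, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts = coords[i] + expanded[i] * pts
        free = np.ones(n_mc, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            free &= d2 >= expanded[j] ** 2
        total += 4 * math.pi * expanded[i] ** 2 * free.mean()
    return total


def test_sasa_cluster_matches_monte_carlo_oracle():
    rng = np.random.default_rng(42)
    coords = rng.uniform(-4, 4, size=(20, 3))
    atoms = [bead(i + 1, c) for i, c in enumerate(coords)]
    s = Structure(atoms)
    group = AtomSet(frozenset(range(20)))
    mine = sasa_frame(s, group, n_points=960).group_total
    oracle = _mc_sasa(coords, np.full(20, 1.9), 1.4, 100_000, rng)
    assert mine == pytest.approx(oracle, rel=0.03)


def test_sasa_rigid_motion_invariance():
    rng = np.random.default_rng(7)
    coords = rng.uniform(-4, 4, size=(12, 3))
    s = Structure([bead(i + 1, c) for i, c in enumerate(coords)])
    group = AtomSet(frozenset(range(12)))
    base = sasa_frame(s, group).group_total
    # random rotation + translation
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    s2 = Structure([bead(i + 1, q @ c + np.array([5.0, -3.0, 2.0]))
                    for i, c in enumerate(coords)])
    moved = sasa_frame(s2, group).group_total
    assert moved == pytest.approx(base, rel=0.01)


def test_sasa_quadrature_convergence():
    rng = np.random.default_rng(3)
    coords = rng.uniform(-3, 3, size=(8, 3))
    s = Structure([bead(i + 1, c) for i, c in enumerate(coords)])
    group = AtomSet(frozenset(range(8)))
    a = sasa_frame(s, group, n_points=960).group_total
    b = sasa_frame(s, group, n_points=3840).group_total
    assert a == pytest.approx(b, rel=0.01)


def test_sasa_monotone_in_neighbors():
    atoms = [bead(1, [0, 0, 0])]
    s = Structure(atoms)
    prev = sasa_frame(s, AtomSet(frozenset({0}))).group_total
    for k, d in enumerate(golden_spiral_points(8), start=2):
        atoms = atoms + [bead(k, d * 3.5)]
        s = Structure(atoms)
        cur = sasa_frame(s, AtomSet(frozenset({0}))).group_total
        assert cur <= prev + 1e-9
        prev = cur


def test_sasa_series_shapes_and_trend():
    # group progressively buried over 3 frames -> strictly decreasing
    def frame(d):
        return Structure([bead(1, [0, 0, 0]), bead(2, [d, 0, 0])])

    traj = Trajectory([frame(8.0), frame(5.0), frame(3.0)], frame_interval=10)
    ser = sasa_series(traj, AtomSet(frozenset({0})))
    assert len(ser) == 3
    assert np.all(np.diff(ser.values) < 0)
    one = sasa_series(Trajectory([frame(5.0)]), AtomSet(frozenset({0})))
    assert one.values[0] == pytest.approx(
        sasa_frame(frame(5.0), AtomSet(frozenset({0}))).group_total)


def test_sasa_requires_radii():
    s = Structure([Atom(1, "N", "N", "ALA", 1, "A", np.zeros(3))])
    from metox.errors import ParameterizationError
    with pytest.raises(ParameterizationError):
        sasa_frame(s, AtomSet(frozenset({0})))


# --------------------------------------------------------------- H-bonds

def _posed_water_frame(dist, angle):
    """Acceptor O at origin; one water with its H at `dist` and the
    O-H...O angle at `angle` degrees."""
    h = np.array([dist, 0.0, 0.0])
    theta = math.radians(angle)
    ow = h + 0.9572 * np.array([-math.cos(theta), 0.0, math.sin(theta)])
    atoms = [Atom(1, "O", "O", "ACC", 1, "A", np.zeros(3)),
             Atom(2, "OH2", "O", "HOH", 2, "W", ow),
             Atom(3, "H1", "H", "HOH", 2, "W", h)]
    return Structure(atoms)


@pytest.mark.parametrize("dist,angle,expected", [
    (2.0, 180.0, 1),
    (3.0, 180.0, 0),      # beyond the 2.7 A distance cutoff
    (2.70, 120.0, 1),     # inclusive boundaries
    (2.70, 119.0, 0),
    (2.71, 180.0, 0),
    (1.8, 125.0, 1),
])
def test_hbond_criteria_boundaries(dist, angle, expected):
    s = _posed_water_frame(dist, angle)
    bonds = detect_hbonds_frame(s, AtomSet(frozenset({1})),
                                AtomSet(frozenset({0})), HBondCriteria())
    assert len(bonds) == expected
    if expected:
        assert bonds[0].distance == pytest.approx(dist)
        assert bonds[0].angle == pytest.approx(angle, abs=1e-6)


def test_hbond_donor_without_hydrogen_skipped(caplog):
    atoms = [Atom(1, "O", "O", "ACC", 1, "A", np.zeros(3)),
             Atom(2, "OH2", "O", "HOH", 2, "W", np.array([2.5, 0, 0]))]
    s = Structure(atoms)
    bonds = detect_hbonds_frame(s, AtomSet(frozenset({1})),
                                AtomSet(frozenset({0})))
    assert bonds == []


def test_hbond_rigid_motion_invariance():
    s = _posed_water_frame(2.2, 150.0)
    rng = np.random.default_rng(11)
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    moved = s.copy()
    moved.set_coords(s.coords() @ q.T + np.array([3.0, 4.0, -2.0]))
    for frame in (s, moved):
        bonds = detect_hbonds_frame(frame, AtomSet(frozenset({1})),
                                    AtomSet(frozenset({0})))
        assert len(bonds) == 1


def test_hbond_fraction_counts_frames():
    good = _posed_water_frame(2.0, 180.0)
    bad = _posed_water_frame(3.5, 180.0)
    frames = [good, good, bad, good, bad, bad, good, bad, bad, bad]
    traj = Trajectory([f.copy() for f in frames], frame_interval=10)
    frac = hbond_fraction(traj, AtomSet(frozenset({1})),
                          AtomSet(frozenset({0})))
    assert frac == pytest.approx(0.4)
    all_good = Trajectory([good.copy() for _ in range(5)])
    assert hbond_fraction(all_good, AtomSet(frozenset({1})),
                          AtomSet(frozenset({0}))) == 1.0
    none = Trajectory([bad.copy() for _ in range(5)])
    assert hbond_fraction(none, AtomSet(frozenset({1})),
                          AtomSet(frozenset({0}))) == 0.0


# ------------------------------------------------------ interaction energy

def charged(i, pos, q, eps=0.0, rmin_half=1.0):
    return Atom(i, "Q", "C", "ION", i, "A", np.asarray(pos, float),
                radius=1.7, charge=q, lj_epsilon=eps, lj_rmin_half=rmin_half)


def test_coulomb_closed_form_below_switch():
    s = Structure([charged(1, [0, 0, 0], 1.0), charged(2, [4, 0, 0], -1.0)])
    e = interaction_energy(s, AtomSet(frozenset({0})), AtomSet(frozenset({1})))
    assert e.electrostatic == pytest.approx(-332.0636 / 4.0)
    assert e.van_der_waals == 0.0


def test_energy_zero_beyond_cutoff():
    s = Structure([charged(1, [0, 0, 0], 1.0), charged(2, [12, 0, 0], -1.0)])
    e = interaction_energy(s, AtomSet(frozenset({0})), AtomSet(frozenset({1})))
    assert e.electrostatic == 0.0 and e.van_der_waals == 0.0


def test_energy_in_switch_region_matches_polynomial():
    s = Structure([charged(1, [0, 0, 0], 1.0), charged(2, [9, 0, 0], -1.0)])
    e = interaction_energy(s, AtomSet(frozenset({0})), AtomSet(frozenset({1})))
    ron2, roff2, r2 = 64.0, 100.0, 81.0
    s9 = (roff2 - r2) ** 2 * (roff2 + 2 * r2 - 3 * ron2) / (roff2 - ron2) ** 3
    assert e.electrostatic == pytest.approx(-332.0636 / 9.0 * s9)
    assert switching_function(8.0, 8.0, 10.0) == pytest.approx(1.0)
    assert switching_function(10.0, 8.0, 10.0) == pytest.approx(0.0)
    # C1 continuity at the joins
    eps = 1e-6
    assert switching_function(8.0 + eps, 8.0, 10.0) == pytest.approx(1.0, abs=1e-5)
    assert switching_function(10.0 - eps, 8.0, 10.0) == pytest.approx(0.0, abs=1e-5)


def test_lj_minimum_and_combination_rules():
    # identical atoms at r = rmin_i/2 + rmin_j/2 sit at the combined minimum
    a = charged(1, [0, 0, 0], 0.0, eps=0.2, rmin_half=1.9)
    b = charged(2, [3.8, 0, 0], 0.0, eps=0.8, rmin_half=1.9)
    s = Structure([a, b])
    e = interaction_energy(s, AtomSet(frozenset({0})), AtomSet(frozenset({1})))
    assert e.van_der_waals == pytest.approx(-math.sqrt(0.2 * 0.8))


def test_energy_symmetry_linearity_additivity():
    rng = np.random.default_rng(5)
    atoms = [charged(i + 1, rng.uniform(0, 6, 3), rng.uniform(-1, 1),
                     eps=0.1, rmin_half=1.5) for i in range(6)]
    s = Structure(atoms)
    a, b = AtomSet(frozenset({0, 1})), AtomSet(frozenset({2, 3, 4, 5}))
    e_ab = interaction_energy(s, a, b)
    e_ba = interaction_energy(s, b, a)
    assert e_ab.electrostatic == pytest.approx(e_ba.electrostatic)
    assert e_ab.van_der_waals == pytest.approx(e_ba.van_der_waals)
    # additivity over a partition of b
    b1, b2 = AtomSet(frozenset({2, 3})), AtomSet(frozenset({4, 5}))
    assert (interaction_energy(s, a, b1).electrostatic
            + interaction_energy(s, a, b2).electrostatic
            ) == pytest.approx(e_ab.electrostatic)
    # electrostatics linear in one group's charges
    s2 = s.copy()
    for i in (0, 1):
        s2.atoms[i].charge *= 3.0
    assert interaction_energy(s2, a, b).electrostatic == pytest.approx(
        3.0 * e_ab.electrostatic)


def test_energy_overlapping_groups_rejected():
    s = Structure([charged(1, [0, 0, 0], 1.0), charged(2, [4, 0, 0], -1.0)])
    with pytest.raises(SelectionError):
        interaction_energy(s, AtomSet(frozenset({0, 1})),
                           AtomSet(frozenset({1})))


# --------------------------------------------------------- running average

def _brute_running_average(t, v, window):
    out = np.empty_like(v)
    for k in range(len(t)):
        sel = np.abs(t - t[k]) <= window / 2 + 1e-9
        out[k] = v[sel].mean()
    return out


def test_running_average_constant_identity():
    s = Series(np.arange(10.0), np.full(10, 3.3))
    out = running_average(s, 30.0)
    assert np.allclose(out.values, 3.3)
    assert np.array_equal(out.times, s.times)


def test_running_average_alternating_matches_brute_force():
    t = np.arange(0.0, 100.0, 10.0)
    v = np.where(np.arange(10) % 2 == 0, 1.0, -1.0)
    out = running_average(Series(t, v), 20.0)
    expected = _brute_running_average(t, v, 20.0)
    assert np.allclose(out.values, expected)
    # centered inclusive 20 ps window: interior averages 3 samples
    assert np.allclose(np.abs(out.values[1:-1]), 1.0 / 3.0)
    assert out.values[0] == pytest.approx(0.0)


def test_running_average_window_below_spacing_is_identity():
    t = np.arange(0.0, 50.0, 10.0)
    v = np.array([5.0, -2.0, 7.0, 0.0, 1.0])
    out = running_average(Series(t, v), 5.0)
    assert np.allclose(out.values, v)


def test_running_average_commutes_with_constant_shift():
    rng = np.random.default_rng(2)
    t = np.arange(0.0, 200.0, 10.0)
    v = rng.normal(size=len(t))
    a = running_average(Series(t, v + 7.0), 40.0).values
    b = running_average(Series(t, v), 40.0).values + 7.0
    assert np.allclose(a, b)


def test_series_tsv_round_trip(tmp_path):
    s = Series(np.arange(5.0), np.array([1.0, 2.0, 3.0, 2.0, 1.0]), "force")
    p = tmp_path / "s.tsv"
    s.to_tsv(p)
    back = Series.from_tsv(p)
    assert np.allclose(back.times, s.times)
    assert np.allclose(back.values, s.values)
    assert back.label == "force"


def test_series_requires_increasing_times():
    with pytest.raises(DomainError):
        Series(np.array([0.0, 0.0, 1.0]), np.zeros(3))
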