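"""Free-energy machinery: schedules, soft-core potential, samplers and
the EXP/BAR estimators against closed forms and independent oracles."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from metox.alchemy import (
    HarmonicSwitchSystem, SoftcoreSiteSystem, WorkData, bar_estimate,
    buried_site_system, ddg_cycle, exp_estimate, exposed_site_system,
    FreeEnergyEstimate, make_schedule, run_alchemical, sample_windows,
    softcore_potential, statistical_inefficiency,
)
from metox.constants import kbt
from metox.errors import DomainError
from metox.synth import gen_crooks_samples

KT = kbt(300.0)


# -------------------------------------------------------------- schedule

def test_schedule_production_shape():
    s = make_schedule(100, 100.0, 0.5)
    assert len(s.lambdas) == 100
    assert s.lambdas[0] == 0.0 and s.lambdas[-1] == 1.0
    assert np.allclose(np.diff(s.lambdas), 1.0 / 99.0)
    assert s.total_duration == pytest.approx(10_000.0)  # 10 ns


def test_schedule_degenerate_and_errors():
    s = make_schedule(2, 1.0, 0.5)
    assert s.lambdas == (0.0, 1.0)
    with pytest.raises(DomainError):
        make_schedule(1, 1.0, 0.5)
    with pytest.raises(DomainError):
        make_schedule(10, 1.0, 1.0)  # no collection phase


# -------------------------------------------------------------- softcore

def test_softcore_endpoints_and_finiteness():
    eps, rmin = 0.3, 3.5
    assert softcore_potential(2.0, 0.0, eps, rmin) == 0.0
    assert softcore_potential(0.5, 0.0, eps, rmin) == 0.0
    # lam = 1 at r = rmin reduces to the bare LJ minimum
    assert softcore_potential(rmin, 1.0, eps, rmin) == pytest.approx(-eps)
    # finite at r = 0 for lam < 1; matches direct evaluation
    lam, alpha = 0.5, 0.5
    direct = lam * 4 * eps * (1 / (alpha * (1 - lam)) ** 2
                              - 1 / (alpha * (1 - lam)))
    assert softcore_potential(0.0, lam, eps, rmin, alpha) == pytest.approx(direct)
    assert math.isfinite(softcore_potential(0.0, 0.999, eps, rmin))


def test_softcore_matches_bare_lj_at_lam_one():
    eps, rmin = 0.2, 4.0
    sigma = rmin / 2 ** (1 / 6)
    for r in (2.5, 3.0, 4.0, 6.0):
        bare = 4 * eps * ((sigma / r) ** 12 - (sigma / r) ** 6)
        assert softcore_potential(r, 1.0, eps, rmin) == pytest.approx(bare)


# -------------------------------------------------------------- sampler

def test_identity_transformation_gives_zero_work():
    system = HarmonicSwitchSystem(2.0, 2.0)
    sched = make_schedule(5, 10.0, 0.5)
    work = sample_windows(system, sched, seed=0)
    assert all(np.allclose(w, 0.0) for w in work.forward)
    assert all(np.allclose(w, 0.0) for w in work.backward)
    assert bar_estimate(work).delta_g == pytest.approx(0.0, abs=1e-12)
    assert exp_estimate(work, "forward").delta_g == pytest.approx(0.0, abs=1e-12)


def test_stiffening_gives_positive_mean_forward_work():
    system = HarmonicSwitchSystem(1.0, 4.0)
    work = sample_windows(system, make_schedule(10, 50.0, 0.5), seed=1)
    assert np.mean(np.concatenate(work.forward)) > 0


def test_sampler_is_deterministic_per_seed():
    system = HarmonicSwitchSystem(1.0, 4.0)
    sched = make_schedule(5, 20.0, 0.5)
    w1 = sample_windows(system, sched, seed=9)
    w2 = sample_windows(system, sched, seed=9)
    for a, b in zip(w1.forward + w1.backward, w2.forward + w2.backward):
        assert np.array_equal(a, b)


# ------------------------------------------------------------ estimators

def test_exp_on_delta_distribution():
    lambdas = (0.0, 0.5, 1.0)
    c = 0.7
    work = WorkData(lambdas, [np.full(50, c)] * 2, [np.full(50, -c)] * 2)
    assert exp_estimate(work, "forward").delta_g == pytest.approx(2 * c)
    assert exp_estimate(work, "backward").delta_g == pytest.approx(2 * c)
    assert bar_estimate(work).delta_g == pytest.approx(2 * c, abs=1e-7)


def test_exp_gaussian_analytic_limit():
    # for Normal(mu, sigma^2) work, EXP converges to mu - sigma^2/(2 kT)
    rng = np.random.default_rng(12)
    mu, sigma = 1.0, 0.3  # kcal/mol
    n = 10_000
    du = rng.normal(mu, sigma, n)
    work = WorkData((0.0, 1.0), [du], [np.zeros(1)])
    est = exp_estimate(work, "forward")
    expected = mu - sigma ** 2 / (2 * KT)
    assert est.delta_g == pytest.approx(expected, abs=3 * max(est.standard_error,
                                                              1e-4))


def test_exp_brackets_truth_in_expectation():
    # bias-dominated regime: forward EXP overestimates, backward EXP
    # underestimates the true value on average across seeds
    f_vals, b_vals = [], []
    for seed in range(50):
        work, _ = gen_crooks_samples(3.0, 2.5, 1000, 1000, seed)
        f_vals.append(exp_estimate(work, "forward").delta_g / KT)
        b_vals.append(exp_estimate(work, "backward").delta_g / KT)
    assert np.mean(f_vals) > 3.0
    assert np.mean(b_vals) < 3.0


def test_bar_exact_on_consistent_deltas():
    w0 = 1.3
    work = WorkData((0.0, 1.0), [np.full(100, w0)], [np.full(100, -w0)])
    est = bar_estimate(work)
    assert est.delta_g == pytest.approx(w0, abs=1e-7)


def test_bar_matches_independent_mle_route():
    # the Bennett root must agree with the logistic maximum-likelihood
    # formulation solved by a generic optimizer
    work, _ = gen_crooks_samples(3.0, 2.0, 2000, 2000, 4)
    wf = work.forward[0] / KT
    wr = work.backward[0] / KT

    def nll(x):
        return (np.log1p(np.exp(-(wf - x))).sum()
                + np.log1p(np.exp(-(wr + x))).sum())

    mle = minimize_scalar(nll, bracket=(0.0, 6.0)).x
    assert bar_estimate(work).delta_g / KT == pytest.approx(mle, abs=1e-6)


def test_bar_gauge_invariance():
    # shifting one window's endpoint potential by a constant shifts that
    # window's forward work by +c, backward by -c, and the dG by exactly +c
    work, _ = gen_crooks_samples(2.0, 1.0, 500, 500, 3, n_windows=3)
    base = bar_estimate(work).delta_g
    c = 0.8  # kcal/mol
    work.forward[1] = work.forward[1] + c
    work.backward[1] = work.backward[1] - c
    assert bar_estimate(work).delta_g == pytest.approx(base + c, abs=1e-9)


def test_window_splitting_consistency():
    system = HarmonicSwitchSystem(1.0, 4.0)
    coarse = run_alchemical(system, make_schedule(25, 40.0, 0.5), seed=21)
    fine = run_alchemical(system, make_schedule(50, 40.0, 0.5), seed=22)
    se = math.hypot(coarse.standard_error, fine.standard_error)
    assert abs(coarse.delta_g - fine.delta_g) < 2 * se


def test_statistical_inefficiency_sane():
    rng = np.random.default_rng(0)
    iid = rng.normal(size=4000)
    assert statistical_inefficiency(iid) < 1.5
    # AR(1) with rho = 0.9 has g ~ (1+rho)/(1-rho) = 19
    x = np.empty(40_000)
    x[0] = 0.0
    eps = rng.normal(size=40_000)
    for i in range(1, len(x)):
        x[i] = 0.9 * x[i - 1] + eps[i]
    assert statistical_inefficiency(x) == pytest.approx(19.0, rel=0.35)


# ------------------------------------------------------------- end-to-end

def test_harmonic_pipeline_recovers_closed_form():
    system = HarmonicSwitchSystem(1.0, 4.0)
    est = run_alchemical(system, make_schedule(100, 100.0, 0.5), seed=5)
    true = system.closed_form_dg()
    assert true == pytest.approx(0.4132, abs=5e-4)
    assert abs(est.delta_g - true) < 2 * est.standard_error


def test_softcore_toy_matches_quadrature_oracle():
    system = buried_site_system()
    est = run_alchemical(system, make_schedule(100, 100.0, 0.5), seed=8)
    exact = system.exact_dg()
    assert abs(est.delta_g - exact) < 2 * est.standard_error + 0.02


def test_backward_modes_agree():
    system = HarmonicSwitchSystem(1.0, 4.0)
    sched = make_schedule(40, 50.0, 0.5)
    chained = bar_estimate(sample_windows(system, sched, seed=2))
    fresh = bar_estimate(sample_windows(system, sched, seed=2,
                                        backward_from_forward=False))
    se = math.hypot(chained.standard_error, fresh.standard_error)
    assert abs(chained.delta_g - fresh.delta_g) < 3 * se


# ----------------------------------------------------------------- cycle

def test_ddg_cycle_arithmetic_and_quadrature():
    f = FreeEnergyEstimate(5.0, 0.3, "BAR", 10)
    u = FreeEnergyEstimate(2.0, 0.4, "BAR", 10)
    res = ddg_cycle(f, u)
    assert res.ddg == pytest.approx(3.0)
    assert res.standard_error == pytest.approx(0.5)


def test_ddg_cycle_closure_and_antisymmetry():
    f = FreeEnergyEstimate(1.234, 0.1, "BAR", 10)
    assert ddg_cycle(f, f).ddg == 0.0
    u = FreeEnergyEstimate(0.9, 0.2, "BAR", 10)
    assert ddg_cycle(f, u).ddg == -ddg_cycle(u, f).ddg


def test_ddg_cycle_temperature_mismatch():
    f = FreeEnergyEstimate(1.0, 0.1, "BAR", 10, temperature=300.0)
    u = FreeEnergyEstimate(1.0, 0.1, "BAR", 10, temperature=310.0)
    with pytest.raises(DomainError):
        ddg_cycle(f, u)


def test_buried_site_costs_more_than_exposed():
    sched = make_schedule(50, 40.0, 0.5)
    dg_b = run_alchemical(buried_site_system(), sched, seed=1)
    dg_e = run_alchemical(exposed_site_system(), sched, seed=2)
    res = ddg_cycle(dg_b, dg_e)
    assert res.ddg > 2 * res.standard_error
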