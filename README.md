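# metox

Desk-scale analysis of how methionine oxidation destabilizes a
force-sensing protein domain — the scenario of the von Willebrand factor
A2 domain, whose unfolding under tension exposes a cleavage site, and
whose methionines are oxidized to methionine sulfoxide, Met(O), by
inflammatory oxidants. The package rebuilds the two analysis tracks of
that problem as tested, seeded, fully synthetic pipelines for method
development and teaching:

* **Alchemical ΔΔG of folding.** A coupling parameter λ converts Met
  (λ = 0) into Met(O) (λ = 1) over a schedule of intermediate states
  (default 100 states × 0.1 ns, half equilibration / half collection).
  Forward and backward per-window energy differences feed the Zwanzig
  (EXP) and Bennett acceptance-ratio (BAR) estimators; a Beutler-style
  soft core keeps appearing atoms finite at r = 0. The thermodynamic
  cycle then gives the change in folding free energy,

      ΔΔG = ΔG_alch(folded) − ΔG_alch(unfolded),

  with ΔΔG > 0 meaning oxidation disfavors folding. The unfolded state
  is proxied by a fully exposed site (the Ala-Met-Ala tripeptide
  picture).

* **Constant-velocity pulling and rupture forces.** A Gō-like two-block
  bead model (a shell body caging a hydrophobic core, capped by a
  separable helix block) is pulled through a virtual spring
  (k = 2 kcal/mol/Å², v = 5 Å/ns, F = k·Δx) under BAOAB Langevin
  dynamics. Oxidation scales the helix–core contact strengths by a
  factor < 1. The rupture force is read off by an exposure-anchored rule: the
  force maximum within a 400 ps window around the moment the core's
  solvent-accessible surface area (SASA) first exceeds 50 Å²
  (20 ps running averages, 2-record persistence).

Supporting layers: PDB I/O and an atom-selection mini-grammar,
Shrake–Rupley SASA on a deterministic spiral quadrature, geometric
hydrogen bonds (H⋯O ≤ 2.7 Å, ∠O–H⋯O ≥ 120°), switched Coulomb/LJ group
energies, methionine-sulfoxide model building, seeded synthetic-data
generators with ground-truth sidecars, and replicate statistics
(mean ± SEM, one-tailed Student t-tests with 0.05/0.10 significance
tiers).

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

```python
import numpy as np
from metox import (HarmonicSwitchSystem, make_schedule, run_alchemical,
                   buried_site_system, exposed_site_system, ddg_cycle,
                   build_toy_model, run_cv_pulling, PullParams,
                   ToyModelSpec, detect_rupture, running_average)

# 1. closed-form check: harmonic well stiffened 1 -> 4 kcal/mol/A^2
sched = make_schedule(100, 100.0, 0.5)          # 100 states, 10 ns total
est = run_alchemical(HarmonicSwitchSystem(1.0, 4.0), sched, seed=7)
print(f"dG = {est.delta_g:.4f} +/- {est.standard_error:.4f} kcal/mol")
# dG = 0.4135 +/- 0.0022 kcal/mol   (exact: (kT/2) ln 4 = 0.4132)

# 2. ddG of folding: buried site vs tripeptide-like unfolded proxy
ddg = ddg_cycle(run_alchemical(buried_site_system(), sched, seed=3),
                run_alchemical(exposed_site_system(), sched, seed=4))
print(f"ddG = {ddg.ddg:.3f} +/- {ddg.standard_error:.3f} kcal/mol")
# ddG = 9.511 +/- 0.008 kcal/mol    (> 0: oxidation destabilizes)

# 3. pulling: unoxidized vs oxidized rupture force, one seed each
for label, factor in (("unoxidized", 1.0), ("oxidized", 0.5)):
    model = build_toy_model(ToyModelSpec(oxidation_factor=factor), seed=1)
    trace, _ = run_cv_pulling(model, PullParams(), seed=1)
    ev = detect_rupture(running_average(trace.force_series(), 20.0),
                        running_average(trace.sasa_series(), 20.0))
    print(f"{label}: {ev.peak_force_pn:.0f} pN at {ev.peak_time:.0f} ps")
# unoxidized: 573 pN at 2250 ps
# oxidized: 291 pN at 1850 ps
```

The numbers say: the estimator reproduces the analytic free energy
within its error bar; growing the sulfoxide oxygen at a tightly packed
site costs ~9.5 kcal/mol more than at an exposed one (a destabilizing
ΔΔG); and halving the helix–core contact strength roughly halves the
force needed to undock the helix cap — the mechanical signature of
oxidation. Over 10 seeds per condition the means are ≈ 550 pN vs
≈ 260 pN with a one-tailed p ≪ 0.05.

A CLI mirrors the pipeline stages
(`metox sasa|hbonds|energy|pull|rupture|fep-sample|fep-bar|ddg|gen|report`);
run `metox --help`.

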