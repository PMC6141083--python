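# Methods

`metox` re-creates, at desk scale and on fully synthetic systems, the two
analysis tracks used to study how methionine oxidation destabilizes a
force-sensing protein domain (the VWF A2 fold is the motivating case):

1. **thermodynamic** — the change in folding free energy upon converting
   a methionine to methionine sulfoxide, estimated from alchemical
   free-energy calculations combined through a thermodynamic cycle, and
2. **mechanical** — the rupture force needed to undock a C-terminal
   helix under constant-velocity pulling, detected from the moment the
   hydrophobic core it shields becomes solvent exposed.

All-atom molecular dynamics is out of scope; every input is produced by
a seeded generator with a ground-truth sidecar, so each downstream
operation can be scored against known answers.

## Units and constants

Energies kcal/mol, lengths Å, times ps, masses amu, charges e.
k_B = 0.0019872041 kcal/mol/K, default T = 300 K (k_BT = 0.59616
kcal/mol). Force unit kcal/mol/Å with a pN mirror (1 kcal/mol/Å =
69.4786 pN). Accelerations use 1 (kcal/mol/Å)/amu = 418.4 Å/ps².

## Structural metrics

**SASA** is Shrake–Rupley sphere sampling: each atom's sphere, inflated
by the probe radius (default 1.4 Å), is covered with a deterministic
golden-section spiral point set (default 960 points); a point is
accessible when outside every other atom's inflated sphere. The spiral
lattice makes the quadrature exactly reproducible; accuracy is ~1–2 %
against the closed form for a lone sphere and ~3 % against a 10⁵-point
Monte-Carlo oracle on clusters. The probe radius and point density are
package defaults.

**Hydrogen bonds** use the geometric criterion: H⋯acceptor distance
≤ 2.7 Å and donor–H⋯acceptor angle (vertex at the hydrogen) ≥ 120°,
both boundaries inclusive. Hydrogens attach to a donor heavy atom by
name prefix plus proximity (< 1.2 Å, same residue) because the PDB
fixtures carry no bond table. "Hydration" of a residue is the fraction
of trajectory frames with at least one qualifying bond between the
residue group and the solvent group.

**Interaction energies** are pairwise Coulomb (k_e = 332.0636
kcal·Å/mol/e²) plus 12-6 Lennard-Jones (geometric ε, arithmetic r_min
combination), both multiplied by the CHARMM-style C¹ switching
polynomial S(r) = (r_off²−r²)²(r_off²+2r²−3r_on²)/(r_off²−r_on²)³ with
r_on = 8 Å, r_off = 10 Å by default. No Ewald summation: these are
short-range group decompositions, not total system energies.

**Running averages** are centered moving means over all samples within
± window/2 (inclusive), truncated at the series edges. For an
alternating ±1 series at 10 ps spacing with a 20 ps window this gives
interior values ±1/3 and edge values 0.

## Sulfoxide model building

`build_sulfoxide` adds one oxygen (OD) to the SD sulphur at 1.50 Å,
initially along the negative bisector of the CG–SD–CE angle, then
rotated about the CG–SD axis over a 24 × 15° grid to the angle with the
lowest quadratic overlap score against all atoms outside the mutated
residue (Bondi-like radii when atoms are unparameterized; ties keep the
earlier angle). All other atoms stay fixed, mimicking a fixed-environment
relaxation of the mutated side chain. This geometric clash relief
replaces force-field minimization, which is out of scope; the S=O length
and grid are package conventions, not measured values. The residue is
renamed MSX (configurable).

## Alchemical free energies

The Met→Met(O) conversion is abstracted to a coupling parameter λ ∈
[0, 1] on toy one-dimensional systems. The default schedule mirrors the
emulated all-atom protocol: 100 uniformly spaced λ states, 0.1 ns per state
(10 ns total), first half of each window equilibration, second half
collection. Metropolis sampling maps "time" to moves at 50 steps/ps;
the forward pass carries the configuration from state to state, and the
backward pass starts from the final forward configuration (an
independently initialized backward pass is available behind a flag).

Estimators (all internal math in reduced units ΔU/k_BT):

* **EXP (Zwanzig)**: ΔG = −k_BT ln⟨e^{−ΔU/k_BT}⟩ per window, summed;
  standard error by per-window block averaging (20 blocks) combined in
  quadrature. Forward EXP is biased high, backward EXP biased low, in
  expectation — the pair brackets the truth on average, not per seed.
* **BAR (Bennett)**: per window, the self-consistent equation
  Σ_F f(M + w_F − x) = Σ_R f(−M + w_R + x) (f the Fermi function,
  M = ln n_F/n_R) solved by bracket expansion around the forward-EXP
  guess plus Brent refinement to 10⁻⁸ k_BT. The estimate is identical
  to the logistic maximum-likelihood formulation, which the tests solve
  independently as a cross-check. Bennett's asymptotic variance is
  evaluated with effective sample sizes n/g, where g is the statistical
  inefficiency of each window's ΔU series (initial-positive-sequence
  autocorrelation sum); without this correction the within-run SE
  understates the seed-to-seed spread of the estimate several-fold.
  Window variances add in quadrature, with no cross-window covariance
  term — a documented simplification; replicate-level SEM is the
  faithful error bar for multi-run comparisons.

**Soft core.** Appearing particles interact through the Beutler-style
form V = λ·4ε[(α(1−λ) + (r/σ)⁶)⁻² − (α(1−λ) + (r/σ)⁶)⁻¹] with α = 0.5
and σ = r_min/2^{1/6}; finite at r = 0 for λ < 1 and exactly the bare
Lennard-Jones at λ = 1. Electrostatics, where present, would scale
linearly in λ; the packaged toys are vdW-only. The functional form and
α are package conventions.

**Toy systems.**

* `HarmonicSwitchSystem` interpolates a harmonic stiffness k₀→k₁;
  ΔG = (k_BT/2) ln(k₁/k₀) in closed form (0.4132 kcal/mol for 1→4
  kcal/mol/Å² at 300 K) — the end-to-end oracle.
* `SoftcoreSiteSystem` tethers a site particle (k = 2 kcal/mol/Å²) and
  switches on soft-core interactions with fixed neighbours. The buried
  variant (neighbours at ±3.0 Å, ε = 0.2, r_min = 4.0 Å) keeps the
  tether minimum global at every λ, so a local sampler stays ergodic
  while the transformation costs ≈ 9.5 kcal/mol (matched by a dense-grid
  Boltzmann-integral oracle). The exposed variant (neighbours at ±9 Å)
  costs ≈ −0.007 kcal/mol. Earlier, tighter neighbour spacings created a
  λ-dependent escape over a wall — a genuine quasi-nonergodicity failure
  mode of FEP — and were rejected for the packaged defaults.

**Thermodynamic cycle.** ΔΔG = ΔG_alch(folded) − ΔG_alch(unfolded);
positive means oxidation destabilizes the fold. The unfolded leg uses
the exposed (tripeptide-like) system: a fully solvent-exposed site and
the unfolded proxy are the same weak-coupling limit, which is why the
exposed-site ΔΔG vanishes within noise. SE combines in quadrature.

## Coarse-grained pulling

The toy fold is a Gō-like bead model (radius 3 Å, mass 50 amu): a
14-bead shell (golden-spiral sphere, radius 6.2 Å) cages a 3-bead core
stack; the top 3 shell beads plus a pull handle form the separable
helix block. Chain bonds (k = 50 kcal/mol/Å², native lengths) run
anchor → core → body → linker → helix → handle; three contact-free
linker beads bulge outward as slack chain so the undocked helix can be
carried away without dragging the body. Native contacts (12-10 form,
minimum ε at the built distance) connect all non-bonded pairs within
8 Å: body/core contacts at ε = 6 kcal/mol, helix–body/core contacts at
ε = 4 kcal/mol and flagged oxidizable — oxidation scales exactly these
by `oxidation_factor` (experiments use 0.5), emulating sulfoxide
hydrophilicity disrupting core packing. Non-contact pairs repel through
a truncated r⁻¹² wall.

Dynamics are BAOAB Langevin (friction 0.5 ps⁻¹, dt = 2 fs), reducing to
velocity Verlet at zero friction (energy drift < 1 % over 10⁵ steps;
kinetic energy per mobile bead within 1 % of 3/2 k_BT over 3 ns). The
pulling protocol mirrors the emulated all-atom setup: the bottom anchor bead is
fixed, a virtual spring (k = 2 kcal/mol/Å²) connects the handle to a
dummy moving at 5 Å/ns along the initial fixed→pulled axis, F = k·Δx
with Δx the axis projection, records every 10 ps for 4 ns. The handle
sits 7 Å off-axis so the freed helix block slides clear of the core
instead of hovering over it — with a purely axial pull the solvent
exposure lags the force peak by over a nanosecond and the detection rule
cannot couple them.

**Rupture detection** anchors the force peak to core exposure: smooth force and core
SASA with 20 ps running averages, find the first record where SASA
exceeds 50 Å² and stays above for 2 consecutive records (persistence
guards single-frame noise), then report the maximum force within a
400 ps window centered on that crossing (earliest sample on ties). Centering the window on the crossing is a package convention. A trace whose SASA never crosses yields a no-event
result, distinct from an error.

Under these defaults (10 seeds per condition) the unoxidized model
ruptures near 550 pN and the half-strength-contact model near 250 pN,
with a one-tailed pooled t-test far below 0.05.

**Loading-rate dependence.** The monotone increase of rupture force
with pulling velocity (1/5/25 Å/ns) is verified with a symmetric axial
pull and 2 ps recording. Two measurement effects matter: the default
tilted handle peels contacts sequentially at high velocity (stress
localization lowers the peak — a loading-geometry effect, not a
loading-rate one), and 10 ps records quantize the sharp high-velocity
peaks by ~0.5 kcal/mol/Å. With collective loading the trend is
13.4 → 13.7 → 13.8 kcal/mol/Å across 10 rupture-verified seeds.

## Synthetic data and what passing tests show

Generators are pure functions of (spec, seed) and write GroundTruth
sidecars. `gen_crooks_samples` draws forward work from
N(ΔG + σ²/2, σ²) and reverse work from N(−ΔG + σ²/2, σ²) in reduced
units, which satisfies the Crooks relation exactly, so ΔG is the exact
answer for any consistent estimator. The pulling fixture is a logistic
SASA step (40 ps width, so the persistence rule always has two
qualifying records) plus a triangular force peak (30 ps half-width:
sharp enough that after 20 ps smoothing the apex clears its neighbours
by ≈ 4 σ at 5 %-of-peak noise, keeping "exact peak-time recovery" well
defined). Hydrogen-bond frames pose rigid waters at exact
distance/angle geometries.

None of these emulate real solvent structure, force-field energetics,
or the real domain's topology. Passing tests therefore demonstrate that
the estimators, detection rules and statistics are implemented
correctly and are calibrated on systems with known answers — not that
the toy models predict the magnitudes real simulations would give. The
directional conclusions (buried-site oxidation destabilizes; weakened
core contacts lower the rupture force) are reproduced by construction
of the toys, as designed.

## Statistics

Replicate reporting is mean ± SEM (n−1 denominator). Comparisons use
the one-tailed two-sample Student t-test with pooled variance (Welch
available behind a flag); degenerate zero-variance input returns p =
0.5 on equal means, else 0/1 by direction. Tiers: p < 0.05 significant,
0.05 ≤ p < 0.10 marginal, else not significant (half-open boundaries).
No multiple-testing correction is applied. Type-I error at nominal 0.05
is within [0.04, 0.06] under a 10⁴-trial null simulation with n = 3 per
group.

## Problem sizes

The packaged defaults keep every stage desk-scale: estimator
calibration uses 50 seeded fixtures of 5000 samples/side; alchemical
runs use 100 windows × 5000 Metropolis steps (≈ 1 s each); pulling runs
integrate 2·10⁶ steps (≈ 13 s each with per-record SASA); the pulling
comparison uses 10 seeds per condition; the t-test null uses 10⁴
trials.

## Known limitations

* Within-run BAR errors ignore cross-window covariance from the chained
  sampler; replicate SEM is the faithful error bar.
* The toy pulling model has a single rupture pathway; real domains
  unfold through intermediates, and the helix-block clearance kinetics
  (hence the force-peak/SASA-crossing coupling) are geometry-tuned.
* The selection grammar covers residue/name/chain predicates and set
  algebra only; no distance-based selections.
* PDB I/O handles ATOM/HETATM/MODEL records through biotite; no
  insertion codes, altlocs or crystallographic symmetry.
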