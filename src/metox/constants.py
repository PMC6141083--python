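"""Physical constants and unit conversions used throughout the package.

Internal unit system (AKMA-like): energy kcal/mol, length A (angstrom),
mass amu, time ps, charge e.  Forces are kcal/mol/A with a pN mirror
where experimentally relevant.
"""

#: Boltzmann constant, kcal/mol/K.
KB_KCAL: float = 0.0019872041

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE: float = 300.0

#: Coulomb constant for charges in e and distances in A, kcal*A/mol/e^2.
COULOMB_KCAL: float = 332.0636

#: 1 kcal/mol/A expressed in piconewton.
PN_PER_KCAL_PER_MOL_A: float = 69.4786

#: Converts (kcal/mol/A) / amu into A/ps^2 (acceleration).
#: 1 kcal/mol/A / amu = 4184 J/mol / 1e-10 m / (1e-3 kg/mol) = 4.184e16 m/s^2
#: = 418.4 A/ps^2.
ACCEL_CONV: float = 418.4

#: Water-probe radius for solvent accessible surface area, A.
DEFAULT_PROBE_RADIUS: float = 1.4

#: Default Shrake-Rupley quadrature density (points per atomic sphere).
DEFAULT_SASA_POINTS: int = 960

#: S=O bond length used when building a methionine-sulfoxide model, A.
SULFOXIDE_SO_BOND: float = 1.50

#: Clash-relief grid for sulfoxide oxygen placement: 24 rotations of 15 deg
#: about the CG-SD axis.
SULFOXIDE_GRID_STEP_DEG: float = 15.0
SULFOXIDE_GRID_COUNT: int = 24

#: Residue name given to methionine sulfoxide in output structures.
SULFOXIDE_RESNAME: str = "MSX"

def kbt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return KB_KCAL * temperature
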