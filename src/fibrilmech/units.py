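"""Unit system and conversion constants.

The simulator works in LAMMPS "real"-style units: length in Å, energy in
kcal/mol, time in fs, mass in g/mol.  Derived quantities:

* force:  kcal/mol/Å
* stress: kcal/mol/Å³  (converted to MPa for reporting)
* velocity: Å/fs (1e-4 Å/fs = 10 m/s, the pulling speed of the reference
  tensile protocol)
"""

from __future__ import annotations

#: Avogadro constant, 1/mol
AVOGADRO = 6.02214076e23

#: 1 kcal in J
KCAL_IN_J = 4184.0

#: Boltzmann constant in kcal/mol/K
KB_KCAL_MOL_K = 0.0019872041

#: 1 kcal/mol/Å³ expressed in Pa (energy density -> pressure)
KCAL_MOL_A3_IN_PA = KCAL_IN_J / AVOGADRO / 1e-30  # ≈ 6.9477e9 Pa

#: 1 kcal/mol/Å³ in MPa
KCAL_MOL_A3_IN_MPA = KCAL_MOL_A3_IN_PA / 1e6

#: 1 Å/fs in m/s
A_PER_FS_IN_M_PER_S = 1e5

#: acceleration prefactor: a [Å/fs²] = MVV2E * F[kcal/mol/Å] / m[g/mol]
#: (4184 J/mol per kcal/mol, 1 Å = 1e-10 m, 1 fs = 1e-15 s)
FORCE_MASS_TO_ACCEL = 4.184e-4


def stress_to_mpa(stress_kcal_mol_a3: float) -> float:
    """Convert an engineering stress from kcal/mol/Å³ to MPa."""
    return stress_kcal_mol_a3 * KCAL_MOL_A3_IN_MPA


def velocity_to_m_per_s(velocity_a_fs: float) -> float:
    """Convert a pulling velocity from Å/fs to m/s."""
    return velocity_a_fs * A_PER_FS_IN_M_PER_S
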