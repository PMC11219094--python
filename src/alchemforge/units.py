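"""Internal unit system and physical constants.

All engine internals run in reduced units: the unit of energy is kT at the
reference temperature T0 = 300 K, lengths are in nanometres, masses are 1,
and charges are in elementary charge units.  Reduced potentials handed to
MBAR are therefore just energies.  Conversion helpers translate free
energies to kcal/mol for reports.
"""

from __future__ import annotations

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_PER_MOL_K = 0.0019872041

#: Reference temperature defining the reduced energy unit (K).
T_REFERENCE = 300.0

#: One reduced energy unit (kT at 300 K) in kcal/mol.
KT_IN_KCAL_PER_MOL = KB_KCAL_PER_MOL_K * T_REFERENCE

#: Coulomb constant in kcal*Angstrom/(mol e^2); the familiar 332.06 value.
_COULOMB_KCAL_A = 332.0637

#: Coulomb constant in reduced energy * nm / e^2 at T0 = 300 K.
COULOMB_CONSTANT_REDUCED = _COULOMB_KCAL_A / 10.0 / KT_IN_KCAL_PER_MOL


def kt_to_kcal_per_mol(x: float, temperature: float = T_REFERENCE) -> float:
    """Convert an energy in kT units at ``temperature`` to kcal/mol."""
    return x * KB_KCAL_PER_MOL_K * temperature


def kcal_per_mol_to_kt(x: float, temperature: float = T_REFERENCE) -> float:
    """Convert an energy in kcal/mol to kT units at ``temperature``."""
    return x / (KB_KCAL_PER_MOL_K * temperature)
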