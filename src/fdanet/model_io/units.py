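"""Unit handling for forces, energies and lengths.

Internal conventions: lengths in nm, energies in kJ/mol, forces in
kJ/mol/nm.  Reported forces are in pN; angles are reported in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

AVOGADRO = 6.02214076e23  # 1/mol (exact, SI 2019)

#: 1 kJ/mol/nm expressed in piconewton per molecule:
#:   1e3 J/mol / (N_A * 1e-9 m) * 1e12 pN/N
KJ_MOL_NM_TO_PN = 1.0e3 / (AVOGADRO * 1.0e-9) * 1.0e12

#: Coulomb prefactor in MD units: f = 1/(4 pi eps0) in kJ mol^-1 nm e^-2
COULOMB_CONSTANT = 138.935458

ANGSTROM_PER_NM = 10.0

_FORCE_UNITS = ("kJ/mol/nm", "pN")


class UnknownUnitError(ValueError):
    pass


@dataclass(frozen=True)
class ForceUnit:
    """A force unit together with its conversion factor to kJ/mol/nm."""

    unit: str

    def __post_init__(self) -> None:
        if self.unit not in _FORCE_UNITS:
            raise UnknownUnitError(
                f"unknown force unit {self.unit!r}; expected one of {_FORCE_UNITS}"
            )

    @property
    def to_internal(self) -> float:
        """Multiplicative factor converting this unit to kJ/mol/nm."""
        return 1.0 if self.unit == "kJ/mol/nm" else 1.0 / KJ_MOL_NM_TO_PN


def convert_force(x, from_unit: str, to_unit: str):
    """Linearly convert a force value (scalar or array) between units.

    Supported units: ``kJ/mol/nm`` and ``pN``.
    """
    f = ForceUnit(from_unit)
    t = ForceUnit(to_unit)
    return x * (f.to_internal / t.to_internal)
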