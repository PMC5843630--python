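"""Physical constants in the package unit system (kJ/mol, nm, ps, e, u).

In these units 1 u (nm/ps)^2 = 1 kJ/mol, so kinetic energies computed from
atomic masses in u and velocities in nm/ps need no conversion factor.
"""

from dataclasses import dataclass
import math

#: Boltzmann constant, kJ/(mol K).
KB: float = 8.31446261815324e-3

#: Coulomb prefactor 1/(4 pi eps0), kJ/mol * nm / e^2. Two +1e charges at
#: 1 nm separation have electrostatic energy of exactly this many kJ/mol.
COULOMB_FACTOR: float = 138.935458


@dataclass(frozen=True)
class PhysicalConstants:
    """Electrostatic constants for the kJ/mol, nm, ps, e unit system."""

    coulomb_factor: float = COULOMB_FACTOR

    @property
    def vacuum_permittivity(self) -> float:
        """eps0 in e^2 / (kJ/mol * nm); equals 1/(4 pi coulomb_factor)."""
        return 1.0 / (4.0 * math.pi * self.coulomb_factor)


CONSTANTS = PhysicalConstants()
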