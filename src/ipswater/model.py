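"""Water model parameters and periodic configurations.

Atoms are stored molecule-contiguously in O, H, H order, so atom ``3*m`` is
the oxygen of molecule ``m``. All quantities use the kJ/mol, nm, ps, e, u
unit system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np


@dataclass(frozen=True)
class WaterModel:
    """Rigid three-site water model (defaults: SPC/E).

    The extended simple point charge model places the negative charge on the
    oxygen site and constrains the two O-H bonds and the H-O-H angle, so each
    molecule is a rigid, charge-neutral unit with a permanent dipole along
    the H-H bisector.
    """

    name: str = "SPC/E"
    r_oh: float = 0.1  # nm
    hoh_angle_deg: float = 109.47
    q_o: float = -0.8476  # e
    q_h: float = +0.4238
    sigma_oo: float = 0.3166  # nm
    epsilon_oo: float = 0.650  # kJ/mol
    mass_o: float = 15.9994  # u
    mass_h: float = 1.008

    @property
    def r_hh(self) -> float:
        """H-H distance implied by the rigid bond length and angle (nm)."""
        return 2.0 * self.r_oh * math.sin(math.radians(self.hoh_angle_deg) / 2.0)

    @property
    def net_charge(self) -> float:
        return self.q_o + 2.0 * self.q_h

    @property
    def mass(self) -> float:
        """Molecular mass (u)."""
        return self.mass_o + 2.0 * self.mass_h

    @property
    def c6(self) -> float:
        """Dispersion coefficient 4*eps*sigma^6 for the O-O pair."""
        return 4.0 * self.epsilon_oo * self.sigma_oo**6

    @property
    def c12(self) -> float:
        """Repulsion coefficient 4*eps*sigma^12 for the O-O pair."""
        return 4.0 * self.epsilon_oo * self.sigma_oo**12

    def atom_charges(self, n_molecules: int) -> np.ndarray:
        return np.tile([self.q_o, self.q_h, self.q_h], n_molecules)

    def atom_masses(self, n_molecules: int) -> np.ndarray:
        return np.tile([self.mass_o, self.mass_h, self.mass_h], n_molecules)

    def site_offsets(self) -> np.ndarray:
        """O, H, H site positions relative to O for a reference orientation.

        The dipole (H-H bisector from O) points along +z.
        """
        half = math.radians(self.hoh_angle_deg) / 2.0
        return np.array(
            [
                [0.0, 0.0, 0.0],
                [self.r_oh * math.sin(half), 0.0, self.r_oh * math.cos(half)],
                [-self.r_oh * math.sin(half), 0.0, self.r_oh * math.cos(half)],
            ]
        )


#: The SPC/E parameter set used throughout.
SPCE = WaterModel()


@dataclass
class Configuration:
    """Periodic box of rigid waters: positions, velocities and index maps."""

    box: np.ndarray  # (3,) orthorhombic edges, nm
    positions: np.ndarray  # (n_atoms, 3), nm
    velocities: np.ndarray = None  # (n_atoms, 3), nm/ps
    model: WaterModel = field(default_factory=lambda: SPCE)

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        if self.positions.shape[0] % 3 != 0:
            raise ValueError("atom count must be a multiple of 3 (O,H,H waters)")
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)
        else:
            self.velocities = np.asarray(self.velocities, dtype=float)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.n_atoms // 3

    @property
    def molecule_index(self) -> np.ndarray:
        """Molecule id of each atom."""
        return np.repeat(np.arange(self.n_molecules), 3)

    @property
    def charge_group_index(self) -> np.ndarray:
        """Charge-group id of each atom; one group per water molecule."""
        return self.molecule_index

    @property
    def charges(self) -> np.ndarray:
        return self.model.atom_charges(self.n_molecules)

    @property
    def masses(self) -> np.ndarray:
        return self.model.atom_masses(self.n_molecules)

    def copy(self) -> "Configuration":
        return Configuration(
            box=self.box.copy(),
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            model=self.model,
        )

    def oxygen_positions(self) -> np.ndarray:
        return self.positions[0::3]

    def dipole_unit_vectors(self) -> np.ndarray:
        """Unit molecular dipole vectors (along the H-H bisector from O)."""
        pos = self.positions.reshape(self.n_molecules, 3, 3)
        # H positions relative to O; minimum-image safe for intact molecules
        d = pos[:, 1:, :] - pos[:, :1, :]
        d -= self.box * np.round(d / self.box)
        bisector = d.sum(axis=1)
        norm = np.linalg.norm(bisector, axis=1, keepdims=True)
        return bisector / norm

    def wrapped_positions(self) -> np.ndarray:
        return self.positions - self.box * np.floor(self.positions / self.box)


def minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    return disp - box * np.round(disp / box)
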