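"""Velocity-Verlet molecular dynamics of rigid SPC/E water.

Rigid geometry is maintained with SHAKE (positions) and RATTLE (velocities)
on the three intramolecular distances of each water; temperature control is
a single-chain Nose-Hoover thermostat updated every step. All waters are
integrated together, so SHAKE iterations are vectorised across molecules.

Degrees of freedom: 6 per molecule (3 translational + 3 rotational for a
rigid non-linear body) minus 3 for the removed centre-of-mass motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .constants import KB
from .model import Configuration, SPCE
from .cutoff_engine import build_pairlist, nonbonded_energy_forces
from .ips_potentials import PairPotentialTable

DEFAULT_DT = 0.002  # ps (2 fs)
SHAKE_TOL = 1e-6  # relative
SHAKE_MAX_ITER = 500


@dataclass
class ThermostatState:
    """Single-chain Nose-Hoover state.

    The thermostat mass is Q = g kB T tau^2 with g the number of degrees of
    freedom and tau the coupling time constant.
    """

    target_temperature: float  # K
    tau: float = 0.04  # ps
    xi: float = 0.0  # friction variable, 1/ps

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("coupling time constant must be positive")


@dataclass
class Trajectory:
    """Frames of an MD run: times (ps), positions, velocities, energy log."""

    times: np.ndarray
    positions: np.ndarray  # (n_frames, n_atoms, 3)
    velocities: np.ndarray
    box: np.ndarray
    log: dict = field(default_factory=dict)  # per-step series

    @property
    def n_frames(self) -> int:
        return len(self.times)


def constraint_targets(model=SPCE) -> np.ndarray:
    """Rigid distances (O-H1, O-H2, H1-H2) in nm."""
    return np.array([model.r_oh, model.r_oh, model.r_hh])


_CONSTRAINT_PAIRS = np.array([[0, 1], [0, 2], [1, 2]])


def _coupling_matrix(inv_m: np.ndarray) -> np.ndarray:
    """S[c,c']: how unit multiplier on constraint c' moves bond vector c.

    A multiplier correction on constraint c' = (a', b') displaces
    x_a' by -w_a' lam r_c' and x_b' by +w_b' lam r_c'; S collects the
    resulting coefficient on bond vector c = (a, b).
    """
    n = len(_CONSTRAINT_PAIRS)
    s = np.zeros((n, n))
    for c, (a, b) in enumerate(_CONSTRAINT_PAIRS):
        for cp, (ap, bp) in enumerate(_CONSTRAINT_PAIRS):
            s[c, cp] = (
                -inv_m[ap] * (a == ap)
                + inv_m[bp] * (a == bp)
                + inv_m[ap] * (b == ap)
                - inv_m[bp] * (b == bp)
            )
    return s


def apply_shake(
    positions_before: np.ndarray,
    positions_after: np.ndarray,
    masses: np.ndarray,
    targets: np.ndarray | None = None,
    rel_tol: float = SHAKE_TOL,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Project drifted positions back onto the rigid-water constraints.

    SHAKE with a coupled (matrix) Newton update: corrections act along the
    pre-drift bond directions, mass-weighted so each molecule's centre of
    mass is unchanged; the three multipliers per molecule are solved jointly
    from the linearised constraint equations, vectorised over molecules, and
    iterated until every distance satisfies ``|r - d| / d <= rel_tol``.

    Returns (corrected positions, displacement applied, iterations used).

    Raises
    ------
    RuntimeError
        On non-convergence, reporting the worst constraint violation.
    """
    if targets is None:
        targets = constraint_targets()
    n_mol = positions_after.shape[0] // 3
    old = positions_before.reshape(n_mol, 3, 3)
    new = positions_after.reshape(n_mol, 3, 3).copy()
    inv_m = 1.0 / masses.reshape(n_mol, 3)[0]  # per-site: O, H, H
    s = _coupling_matrix(inv_m)
    d2 = targets**2

    ca, cb = _CONSTRAINT_PAIRS[:, 0], _CONSTRAINT_PAIRS[:, 1]
    r_old = old[:, ca] - old[:, cb]  # (n_mol, 3 constraints, 3)
    worst = np.inf
    for iteration in range(1, SHAKE_MAX_ITER + 1):
        r_new = new[:, ca] - new[:, cb]
        g = np.einsum("mci,mci->mc", r_new, r_new) - d2
        worst = float(np.max(np.abs(np.sqrt(g + d2) - targets) / targets))
        if worst <= rel_tol:
            corrected = new.reshape(-1, 3)
            return corrected, corrected - positions_after, iteration - 1
        # dg_c/dlam_c' = 2 S[c,c'] (r_new_c . r_old_c')
        jac = 2.0 * s[None, :, :] * np.einsum("mci,mdi->mcd", r_new, r_old)
        lam = np.linalg.solve(jac, -g[..., None])[..., 0]
        corr = lam[:, :, None] * r_old  # (n_mol, constraint, 3)
        for c, (a, b) in enumerate(_CONSTRAINT_PAIRS):
            new[:, a] -= inv_m[a] * corr[:, c]
            new[:, b] += inv_m[b] * corr[:, c]
    raise RuntimeError(
        f"SHAKE failed to converge in {SHAKE_MAX_ITER} iterations; "
        f"worst relative violation {worst:.3e}"
    )


def apply_rattle(
    positions: np.ndarray, velocities: np.ndarray, masses: np.ndarray
) -> np.ndarray:
    """Project velocities onto the constraint manifold (RATTLE).

    The velocity constraints r_ab . v_ab = 0 are linear in the three
    multipliers per molecule, so one batched 3x3 solve removes the
    bond-stretching velocity components exactly.
    """
    n_mol = positions.shape[0] // 3
    pos = positions.reshape(n_mol, 3, 3)
    vel = velocities.reshape(n_mol, 3, 3).copy()
    inv_m = 1.0 / masses.reshape(n_mol, 3)[0]
    s = _coupling_matrix(inv_m)
    ca, cb = _CONSTRAINT_PAIRS[:, 0], _CONSTRAINT_PAIRS[:, 1]
    rab = pos[:, ca] - pos[:, cb]
    vab = vel[:, ca] - vel[:, cb]
    b = np.einsum("mci,mci->mc", rab, vab)
    jac = s[None, :, :] * np.einsum("mci,mdi->mcd", rab, rab)
    k = np.linalg.solve(jac, -b[..., None])[..., 0]
    corr = k[:, :, None] * rab
    for c, (a, bidx) in enumerate(_CONSTRAINT_PAIRS):
        vel[:, a] -= inv_m[a] * corr[:, c]
        vel[:, bidx] += inv_m[bidx] * corr[:, c]
    return vel.reshape(-1, 3)


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    return 0.5 * float(np.sum(masses[:, None] * velocities**2))


def degrees_of_freedom(n_molecules: int) -> int:
    """6 per rigid non-linear molecule, minus 3 for fixed total momentum."""
    return 6 * n_molecules - 3


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray, dof: int) -> float:
    return 2.0 * kinetic_energy(velocities, masses) / (dof * KB)


def nose_hoover_update(
    state: ThermostatState, kinetic: float, dof: int, dt: float
) -> tuple[ThermostatState, float]:
    """Half-step single-chain Nose-Hoover propagation.

    Returns the updated state and the velocity scale factor exp(-xi dt/2).
    The friction velocity obeys d(xi)/dt = (2K - g kB T)/Q with
    Q = g kB T tau^2; at the fixed point (K at target) xi is stationary, and
    the scale factor is exactly 1 when xi = 0.
    """
    g_kt = dof * KB * state.target_temperature
    q = g_kt * state.tau**2
    xi = state.xi + 0.25 * dt * (2.0 * kinetic - g_kt) / q
    scale = np.exp(-0.5 * dt * xi)
    kinetic_scaled = kinetic * scale**2
    xi = xi + 0.25 * dt * (2.0 * kinetic_scaled - g_kt) / q
    return ThermostatState(state.target_temperature, state.tau, xi), float(scale)


def maxwell_boltzmann_velocities(
    config: Configuration, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw velocities at temperature T, remove COM drift, constrain, rescale."""
    masses = config.masses
    sigma = np.sqrt(KB * temperature / masses)
    vel = rng.normal(size=(config.n_atoms, 3)) * sigma[:, None]
    vel -= np.average(vel, axis=0, weights=masses)
    vel = apply_rattle(config.positions, vel, masses)
    dof = degrees_of_freedom(config.n_molecules)
    t_now = kinetic_temperature(vel, masses, dof)
    return vel * np.sqrt(temperature / t_now)


class ForceField:
    """Force provider built from a pair list scheme and a potential table."""

    def __init__(
        self,
        table: PairPotentialTable,
        scheme: str = "group",
        list_radius: float | None = None,
    ) -> None:
        self.table = table
        self.scheme = scheme
        self.list_radius = (
            list_radius if list_radius is not None else table.list_radius
        )

    def __call__(self, config: Configuration):
        pairlist = build_pairlist(config, self.list_radius, scheme=self.scheme, sort=False)
        e_elec, e_lj, forces = nonbonded_energy_forces(config, pairlist, self.table)
        return e_elec + e_lj, forces


class EwaldForceField:
    """Force provider using the direct Ewald reference (plus truncated LJ)."""

    def __init__(self, params, lj_table: PairPotentialTable, lj_radius: float):
        from .ewald_reference import ewald_energy_forces
        import copy

        self._ewald = ewald_energy_forces
        self.params = params
        # electrostatics comes from the Ewald sum; zero the table's Coulomb
        # columns so only the LJ columns contribute here
        self.lj_table = copy.deepcopy(lj_table)
        self.lj_table.f = np.zeros_like(self.lj_table.f)
        self.lj_table.minus_fprime = np.zeros_like(self.lj_table.minus_fprime)
        self.lj_radius = lj_radius

    def __call__(self, config: Configuration):
        e_es, f_es = self._ewald(config, self.params)
        pairlist = build_pairlist(config, self.lj_radius, scheme="group")
        _, e_lj, f_lj = nonbonded_energy_forces(config, pairlist, self.lj_table)
        return e_es + e_lj, f_es + f_lj


def velocity_verlet_step(
    config: Configuration,
    forces: np.ndarray,
    force_fn: Callable,
    dt: float = DEFAULT_DT,
    thermostat: ThermostatState | None = None,
) -> tuple[Configuration, np.ndarray, float, ThermostatState | None]:
    """One velocity-Verlet step with SHAKE/RATTLE and optional NVT coupling.

    Sequence: (thermostat half) -> half kick -> drift -> SHAKE -> force
    recompute -> half kick -> RATTLE -> (thermostat half). Returns the new
    configuration, forces, potential energy and thermostat state.
    """
    masses = config.masses
    vel = config.velocities
    dof = degrees_of_freedom(config.n_molecules)

    if thermostat is not None:
        thermostat, scale = nose_hoover_update(
            thermostat, kinetic_energy(vel, masses), dof, dt
        )
        vel = vel * scale

    vel = vel + 0.5 * dt * forces / masses[:, None]
    new_pos = config.positions + dt * vel
    new_pos, shift, _ = apply_shake(config.positions, new_pos, masses)
    # SHAKE position correction feeds back into the half-step velocity
    vel = vel + shift / dt

    new_config = Configuration(config.box, new_pos, vel, model=config.model)
    e_pot, new_forces = force_fn(new_config)

    vel = vel + 0.5 * dt * new_forces / masses[:, None]
    vel = apply_rattle(new_pos, vel, masses)

    if thermostat is not None:
        thermostat, scale = nose_hoover_update(
            thermostat, kinetic_energy(vel, masses), dof, dt
        )
        vel = vel * scale

    new_config.velocities = vel
    return new_config, new_forces, e_pot, thermostat


def run_simulation(
    config: Configuration,
    force_fn: Callable,
    n_steps: int,
    dt: float = DEFAULT_DT,
    ensemble: str = "nve",
    temperature: float = 298.15,
    tau: float = 0.04,
    stride: int = 10,
    seed: int | None = None,
    blowup_energy: float = 1e7,
) -> Trajectory:
    """Integrate an MD trajectory; deterministic for a fixed seed.

    If ``seed`` is given, initial velocities are (re)drawn from a
    Maxwell-Boltzmann distribution at ``temperature``; otherwise the
    configuration's velocities are used as-is. Frames (including the initial
    state) are stored every ``stride`` steps; the log records per-step
    potential/kinetic energy, temperature and conserved-quantity series.

    Raises
    ------
    RuntimeError
        If the potential energy exceeds ``blowup_energy`` (overlap blow-up).
    """
    config = config.copy()
    if seed is not None:
        rng = np.random.default_rng(seed)
        config.velocities = maxwell_boltzmann_velocities(config, temperature, rng)

    thermostat = (
        ThermostatState(target_temperature=temperature, tau=tau)
        if ensemble.lower() == "nvt"
        else None
    )
    masses = config.masses
    dof = degrees_of_freedom(config.n_molecules)

    e_pot, forces = force_fn(config)
    times, frames_x, frames_v = [0.0], [config.positions.copy()], [
        config.velocities.copy()
    ]
    log = {"time": [0.0], "potential": [e_pot],
           "kinetic": [kinetic_energy(config.velocities, masses)],
           "temperature": [kinetic_temperature(config.velocities, masses, dof)],
           "xi": [0.0]}

    for step in range(1, n_steps + 1):
        config, forces, e_pot, thermostat = velocity_verlet_step(
            config, forces, force_fn, dt=dt, thermostat=thermostat
        )
        if not np.isfinite(e_pot) or abs(e_pot) > blowup_energy:
            raise RuntimeError(
                f"simulation blow-up at step {step}: potential energy {e_pot:.3e}"
            )
        log["time"].append(step * dt)
        log["potential"].append(e_pot)
        log["kinetic"].append(kinetic_energy(config.velocities, masses))
        log["temperature"].append(
            kinetic_temperature(config.velocities, masses, dof)
        )
        log["xi"].append(thermostat.xi if thermostat is not None else 0.0)
        if step % stride == 0:
            times.append(step * dt)
            frames_x.append(config.positions.copy())
            frames_v.append(config.velocities.copy())

    return Trajectory(
        times=np.array(times),
        positions=np.array(frames_x),
        velocities=np.array(frames_v),
        box=config.box.copy(),
        log={k: np.array(v) for k, v in log.items()},
    )
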