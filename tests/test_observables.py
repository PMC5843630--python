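"""Observable estimators against closed forms and O(N^2) brute force."""

import numpy as np
import pytest

from ipswater import Configuration, SystemRecipe, build_bulk
from ipswater.constants import CONSTANTS
from ipswater.model import SPCE, minimum_image
from ipswater import observables as obs
from ipswater.observables import ObservableSeries
from ipswater.system_builder import _place_molecules
from ipswater.water_md import Trajectory


def make_traj(frames, box, dt=0.1):
    frames = np.asarray(frames, float)
    return Trajectory(
        times=dt * np.arange(len(frames)),
        positions=frames,
        velocities=np.zeros_like(frames),
        box=np.asarray(box, float),
    )


def random_water_frame(n, box, rng, align=None):
    """n waters at uniform positions; optionally all dipoles aligned."""
    sites = rng.uniform(0, box, size=(n, 3))
    pos = _place_molecules(sites, rng, SPCE)
    if align is not None:
        # rebuild every molecule in the reference orientation (dipole +z)
        offsets = SPCE.site_offsets()
        pos = (sites[:, None, :] + offsets[None]).reshape(-1, 3)
    return pos


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_gk(positions, box, dr, nbins):
    """O(N^2) Kirkwood factor, self term included, value at bin upper edge."""
    n = positions.shape[0] // 3
    oxy = positions[0::3]
    u = obs._frame_dipoles(positions, box)
    out = np.zeros(nbins)
    for b in range(nbins):
        edge = (b + 1) * dr
        total = 0.0
        for i in range(n):
            acc = u[i].copy()  # j = i self term
            for j in range(n):
                if j == i:
                    continue
                d = oxy[i] - oxy[j]
                d = d - box * np.round(d / box)
                if np.dot(d, d) < edge * edge:
                    acc = acc + u[j]
            total += float(np.dot(u[i], acc))
        out[b] = total / n
    return out


def brute_cos_shell(positions, box, dr, nbins):
    """O(N^2) shell-wise <cos theta>, equal weight per reference molecule."""
    n = positions.shape[0] // 3
    oxy = positions[0::3]
    u = obs._frame_dipoles(positions, box)
    out = np.zeros(nbins)
    counts = np.zeros(nbins)
    for b in range(nbins):
        per_i = []
        for i in range(n):
            dots, cnt = 0.0, 0
            for j in range(n):
                if j == i:
                    continue
                d = oxy[i] - oxy[j]
                d = d - box * np.round(d / box)
                r = np.sqrt(np.dot(d, d))
                if b * dr <= r < (b + 1) * dr:
                    dots += float(np.dot(u[i], u[j]))
                    cnt += 1
            per_i.append(dots / cnt if cnt else 0.0)
            counts[b] += cnt
        out[b] = np.mean(per_i)
    return out, counts


def brute_rdf(positions, box, dr, nbins):
    n = positions.shape[0] // 3
    oxy = positions[0::3]
    hist = np.zeros(nbins)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = oxy[i] - oxy[j]
            d = d - box * np.round(d / box)
            r = np.sqrt(np.dot(d, d))
            b = int(r / dr)
            if b < nbins:
                hist[b] += 1
    centers = (np.arange(nbins) + 0.5) * dr
    vol = float(np.prod(box))
    return hist * vol / (4 * np.pi * centers**2 * dr * n * (n - 1))


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

class TestSelfDiffusion:
    def test_frozen_trajectory_gives_zero(self):
        frame = build_bulk(SystemRecipe(20, seed=1)).positions
        traj = make_traj([frame] * 50, build_bulk(SystemRecipe(20, seed=1)).box)
        res = obs.self_diffusion(traj, fit_window=2.0)
        assert res.d == pytest.approx(0.0, abs=1e-12)

    def test_brownian_recovery_within_5_percent(self):
        """Synthetic random walk with known D0 = 2.5e-3 nm^2/ps."""
        rng = np.random.default_rng(77)
        d0 = 2.5e-3
        dt = 0.1
        n_part, n_frames = 200, 1500
        steps = rng.normal(
            scale=np.sqrt(2 * d0 * dt), size=(n_frames - 1, n_part, 3)
        )
        oxy = np.concatenate(
            [np.zeros((1, n_part, 3)), np.cumsum(steps, axis=0)], axis=0
        )
        # inflate to O,H,H layout (H sites ride along; MSD uses oxygens)
        pos = np.repeat(oxy, 3, axis=1)
        traj = make_traj(pos, box=[1e6, 1e6, 1e6], dt=dt)
        res = obs.self_diffusion(traj, fit_window=20.0)
        assert res.diffusive
        assert res.d == pytest.approx(d0, rel=0.05)

    def test_ballistic_regime_flagged(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(30, 3))
        t = np.arange(100) * 0.1
        oxy = t[:, None, None] * v[None]
        pos = np.repeat(oxy, 3, axis=1)
        traj = make_traj(pos, box=[1e6] * 3, dt=0.1)
        res = obs.self_diffusion(traj, fit_window=5.0)
        assert not res.diffusive
        assert res.exponent > 1.5

    def test_window_longer_than_trajectory_raises(self):
        pos = np.zeros((10, 6, 3))
        traj = make_traj(pos, box=[5, 5, 5], dt=0.1)
        with pytest.raises(ValueError, match="window"):
            obs.self_diffusion(traj, fit_window=5.0)

    def test_unwrap_accumulates_minimum_image_steps(self):
        box = np.array([1.0, 1.0, 1.0])
        # particle drifting +x at 0.3/frame, wrapped into [0, 1)
        x = (0.1 + 0.3 * np.arange(10)) % 1.0
        pos = np.zeros((10, 1, 3))
        pos[:, 0, 0] = x
        out = obs.unwrap_trajectory(pos, box)
        np.testing.assert_allclose(
            out[:, 0, 0], 0.1 + 0.3 * np.arange(10), atol=1e-12
        )


# ---------------------------------------------------------------------------
# radial structure
# ---------------------------------------------------------------------------

class TestRdf:
    def test_uniform_gas_is_unity(self, rng):
        box = np.array([4.0, 4.0, 4.0])
        frames = [random_water_frame(200, box, rng) for _ in range(8)]
        series = obs.rdf(make_traj(frames, box), dr=0.1)
        sel = series.bin_centers > 0.4
        noise = 3.0 / np.sqrt(np.maximum(series.counts[sel], 1))
        assert np.all(np.abs(series.values[sel] - 1.0) < np.maximum(3 * noise, 0.25))

    def test_two_particles_closed_form(self):
        """For N = 2 at distance d the single occupied bin equals the Eq.-3
        normalisation V / (4 pi r^2 dr N (N-1)) x 2 ordered pairs."""
        box = np.array([3.0, 3.0, 3.0])
        d = 0.73
        pos = np.zeros((6, 3))
        pos[3:, 0] = d  # second molecule's O displaced along x
        series = obs.rdf(make_traj([pos], box), dr=0.02)
        b = int(d / 0.02)
        centre = (b + 0.5) * 0.02
        expected = 27.0 / (4 * np.pi * centre**2 * 0.02 * 2 * 1) * 2
        assert series.values[b] == pytest.approx(expected)
        others = np.delete(series.values, b)
        assert np.all(others == 0)

    def test_neighbour_count_integral(self, rng):
        box = np.array([3.0, 3.0, 3.0])
        frames = [random_water_frame(100, box, rng) for _ in range(4)]
        series = obs.rdf(make_traj(frames, box), dr=0.05)
        n_density = 100 / 27.0
        integral = np.sum(
            series.values * n_density * 4 * np.pi * series.bin_centers**2 * 0.05
        )
        # expected neighbours within r < L/2 for an ideal gas
        expected = n_density * 4 / 3 * np.pi * 1.5**3 * (99 / 100)
        assert integral == pytest.approx(expected, rel=0.05)

    def test_matches_brute_force(self, rng):
        box = np.array([2.0, 2.0, 2.0])
        pos = random_water_frame(30, box, rng)
        series = obs.rdf(make_traj([pos], box), dr=0.05)
        np.testing.assert_allclose(
            series.values, brute_rdf(pos, box, 0.05, len(series.values)),
            atol=1e-10,
        )


class TestKirkwood:
    def test_parallel_dipoles(self, rng):
        """All dipoles parallel: G_k(r) = 1 + mean neighbour count within r."""
        box = np.array([3.0, 3.0, 3.0])
        pos = random_water_frame(40, box, rng, align=True)
        series = obs.kirkwood_gk(make_traj([pos], box), dr=0.05)
        oxy = pos[0::3]
        ii, jj = np.triu_indices(40, k=1)
        r = np.linalg.norm(minimum_image(oxy[ii] - oxy[jj], box), axis=1)
        for b in (5, 15, 25):
            edge = (b + 1) * 0.05
            count = 2 * np.sum(r < edge) / 40
            assert series.values[b] == pytest.approx(1 + count, abs=1e-9)

    def test_random_orientations_near_unity(self, rng):
        box = np.array([4.0, 4.0, 4.0])
        frames = [random_water_frame(150, box, rng) for _ in range(12)]
        series = obs.kirkwood_gk(make_traj(frames, box), dr=0.1)
        # sum of ~n kT-free random dot products: sd ~ sqrt(2 n_pairs)/N/frames
        assert np.all(np.abs(series.values - 1.0) < 0.6)

    def test_matches_brute_force(self, rng):
        box = np.array([2.0, 2.0, 2.0])
        pos = random_water_frame(30, box, rng)
        series = obs.kirkwood_gk(make_traj([pos], box), dr=0.1)
        np.testing.assert_allclose(
            series.values, brute_gk(pos, box, 0.1, len(series.values)),
            atol=1e-10,
        )

    def test_two_parallel_dipoles_sign_convention(self):
        box = np.array([3.0, 3.0, 3.0])
        offsets = SPCE.site_offsets()
        pos = np.concatenate([offsets + [1, 1, 1], offsets + [1.6, 1, 1]])
        series = obs.kirkwood_gk(make_traj([pos], box), dr=0.1)
        assert series.values[-1] == pytest.approx(2.0)


class TestDipoleOrdering:
    def test_random_orientations_near_zero(self, rng):
        box = np.array([4.0, 4.0, 4.0])
        frames = [random_water_frame(150, box, rng) for _ in range(10)]
        series = obs.dipole_ordering_hoo(make_traj(frames, box), dr=0.1)
        sel = series.bin_centers > 0.5
        assert np.abs(series.values[sel]).max() < 0.25

    def test_parallel_equals_three_g(self, rng):
        """All parallel dipoles: h_OO = 3 g_OO wherever every molecule's
        shell is occupied (empty shells contribute 0 to <cos theta>, so the
        identity weakens to h_OO <= 3 g_OO on sparse bins)."""
        box = np.array([3.0, 3.0, 3.0])
        pos = random_water_frame(60, box, rng, align=True)
        traj = make_traj([pos], box)
        hoo = obs.dipole_ordering_hoo(traj, dr=0.05)
        g = obs.rdf(traj, dr=0.05)
        # occupancy: how many of the 60 molecules have >= 1 shell neighbour
        oxy = pos[0::3]
        ii, jj = np.triu_indices(60, k=1)
        r = np.linalg.norm(minimum_image(oxy[ii] - oxy[jj], box), axis=1)
        nbins = len(hoo.values)
        occupancy = np.zeros(nbins)
        for b in range(nbins):
            shell = (r >= b * 0.05) & (r < (b + 1) * 0.05)
            occupancy[b] = len(set(ii[shell]) | set(jj[shell]))
        full = occupancy == 60
        np.testing.assert_allclose(hoo.values[full], 3 * g.values[full], atol=1e-9)
        assert np.all(hoo.values <= 3 * g.values + 1e-9)

    def test_matches_brute_force(self, rng):
        box = np.array([2.0, 2.0, 2.0])
        pos = random_water_frame(30, box, rng)
        series = obs.dipole_ordering_hoo(make_traj([pos], box), dr=0.1)
        nbins = len(series.values)
        cos_shell, _ = brute_cos_shell(pos, box, 0.1, nbins)
        g = brute_rdf(pos, box, 0.1, nbins)
        np.testing.assert_allclose(series.values, 3 * g * cos_shell, atol=1e-9)


# ---------------------------------------------------------------------------
# slab profiles and electrostatic potential
# ---------------------------------------------------------------------------

class TestProfiles:
    def test_bulk_profile_flat_at_global_density(self, rng):
        # bins aligned with the 6x6x6 builder lattice so each holds one plane
        config = build_bulk(SystemRecipe(216, seed=9))
        traj = make_traj([config.positions], config.box)
        rho_m, rho_c = obs.density_profiles(traj, dz=config.box[2] / 6)
        assert np.all(np.abs(rho_m.values / 0.997 - 1) < 0.25)

    def test_total_charge_integral_zero(self, rng):
        config = build_bulk(SystemRecipe(64, seed=2))
        traj = make_traj([config.positions], config.box)
        _, rho_c = obs.density_profiles(traj, dz=0.05)
        area = config.box[0] * config.box[1]
        total = rho_c.values.sum() * rho_c.bin_width * area
        assert abs(total) < 1e-10

    def test_hand_placed_molecules_counted_per_bin(self):
        box = np.array([2.0, 2.0, 4.0])
        offsets = SPCE.site_offsets() * 0.0  # collapse sites onto O for count
        z_values = [0.5, 0.5, 2.5]
        pos = np.concatenate([offsets + [1, 1, z] for z in z_values])
        traj = make_traj([pos], box)
        rho_m, _ = obs.density_profiles(traj, dz=1.0)
        bin_volume = 2.0 * 2.0 * 1.0
        expected_mass = SPCE.mass * 1.66053906660e-3 / bin_volume
        assert rho_m.values[0] == pytest.approx(2 * expected_mass)
        assert rho_m.values[2] == pytest.approx(1 * expected_mass)
        assert rho_m.values[1] == 0 and rho_m.values[3] == 0

    def test_psi_zero_for_zero_charge(self):
        z = np.linspace(0.05, 4.95, 50)
        series = ObservableSeries(z, np.zeros(50), 0.1, observable_id="rho_charge")
        psi = obs.electrostatic_potential_profile(series)
        assert np.all(psi.values == 0)

    def test_parallel_plate_capacitor_step(self):
        """Two opposite charge sheets: potential step sigma*d/eps0."""
        dz = 0.01
        z = (np.arange(600) + 0.5) * dz
        rho = np.zeros_like(z)
        sheet = 0.5  # e/nm^3 over one bin -> sigma_s = 0.005 e/nm^2
        i1, i2 = 200, 400
        rho[i1] = sheet
        rho[i2] = -sheet
        series = ObservableSeries(z, rho, dz, observable_id="rho_charge")
        psi = obs.electrostatic_potential_profile(series)
        sigma_s = sheet * dz
        d = (i2 - i1) * dz
        expected = sigma_s * d / CONSTANTS.vacuum_permittivity
        step = psi.values[-1] - psi.values[0]
        assert step == pytest.approx(-expected, rel=0.02)

    def test_psi_convergence_second_order(self):
        """Trapezoid double integration converges ~O(dz^2) to the closed
        form for rho_c = sin(k z)."""
        k = 3.0
        eps0 = CONSTANTS.vacuum_permittivity

        def max_error(dz):
            z = (np.arange(int(6 / dz)) + 0.5) * dz
            s = ObservableSeries(z, np.sin(k * z), dz, observable_id="rho_charge")
            psi = obs.electrostatic_potential_profile(s).values
            z0 = z[0]
            # psi(z) = -(1/eps0) int_z0^z int_z0^z' sin(k z'') dz'' dz'
            exact = -(
                (z - z0) * np.cos(k * z0) / k
                - (np.sin(k * z) - np.sin(k * z0)) / k**2
            ) / eps0
            return np.abs(psi - exact).max()

        e1, e2 = max_error(0.02), max_error(0.01)
        assert e1 / e2 > 3.0

    def test_anchor_at_vacuum_bin(self):
        z = (np.arange(100) + 0.5) * 0.1
        rho_c = np.where((z > 4) & (z < 6), np.sin(z), 0.0)
        mass = np.where((z > 4) & (z < 6), 1.0, 0.0)
        charge = ObservableSeries(z, rho_c, 0.1, observable_id="rho_charge")
        massp = ObservableSeries(z, mass, 0.1, observable_id="rho_mass")
        psi = obs.electrostatic_potential_profile(charge, massp)
        anchor = int(np.argmin(mass))
        assert psi.values[anchor] == 0.0

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        z = (np.arange(10) + 0.5) * 0.2
        s = ObservableSeries(z, np.sin(z), 0.2, observable_id="demo",
                             metadata={"frames": 3})
        s.to_csv(tmp_path / "demo.csv")
        back = pd.read_csv(tmp_path / "demo.csv", comment="#")
        np.testing.assert_allclose(back["value"].to_numpy(), np.sin(z))
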