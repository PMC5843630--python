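"""Construct bulk-water boxes and water-vapour slabs for simulation.

Initial structures are jittered cubic lattices of randomly oriented rigid
waters; equilibration burns in the liquid structure. The builders guarantee
the exact target mass density (bulk), a minimum intermolecular O-O
separation, and determinism under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Configuration, SPCE, WaterModel

#: Avogadro scaling: mass density (g/cm^3) = AMU_PER_NM3_TO_G_PER_CM3 * (u/nm^3)
AMU_PER_NM3_TO_G_PER_CM3 = 1.66053906660e-24 / 1e-21

MIN_OO_DISTANCE = 0.25  # nm


@dataclass(frozen=True)
class SystemRecipe:
    """What to build: molecule count, density or box, geometry, seed."""

    n_molecules: int
    density: float | None = 0.997  # g/cm^3 (bulk) or slab liquid density
    box: tuple | None = None  # explicit edges (nm) overrides density for slabs
    geometry: str = "bulk"  # "bulk" | "slab"
    slab_axis: int = 2
    jitter: float = 0.02  # nm, uniform lattice perturbation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("bulk", "slab"):
            raise ValueError("geometry must be 'bulk' or 'slab'")
        if self.geometry == "bulk" and self.box is None and (
            self.density is None or self.density <= 0
        ):
            raise ValueError("bulk recipes need a positive density or explicit box")
        if self.geometry == "slab" and self.box is None:
            raise ValueError("slab recipes need explicit box edges")


def _random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrices (quaternion method)."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack(
        [
            np.stack([1 - 2 * (y**2 + z**2), 2 * (x * y - w * z), 2 * (x * z + w * y)], -1),
            np.stack([2 * (x * y + w * z), 1 - 2 * (x**2 + z**2), 2 * (y * z - w * x)], -1),
            np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x**2 + y**2)], -1),
        ],
        axis=1,
    )


def _place_molecules(
    oxygen_sites: np.ndarray, rng: np.random.Generator, model: WaterModel
) -> np.ndarray:
    """Expand O sites into full O,H,H coordinates with random orientations."""
    n = len(oxygen_sites)
    rot = _random_rotations(n, rng)
    offsets = model.site_offsets()  # (3 sites, 3)
    sites = np.einsum("nij,sj->nsi", rot, offsets) + oxygen_sites[:, None, :]
    return sites.reshape(-1, 3)


def _lattice_sites(n: int, box: np.ndarray, region_lo, region_hi, jitter, rng):
    """n jittered sites on the smallest cubic-ish lattice filling a region."""
    lo = np.asarray(region_lo, float)
    hi = np.asarray(region_hi, float)
    extent = hi - lo
    # choose per-axis counts proportional to extent so cells stay near-cubic
    m = int(np.ceil(n ** (1.0 / 3.0)))
    counts = np.maximum(np.round(extent / extent.prod() ** (1 / 3) * m), 1).astype(int)
    while counts.prod() < n:
        counts[np.argmin(counts * 1.0)] += 1
    cell = extent / counts
    idx = np.stack(
        np.meshgrid(*[np.arange(c) for c in counts], indexing="ij"), -1
    ).reshape(-1, 3)
    sites = lo + (idx + 0.5) * cell
    chosen = sites[: n] if len(sites) == n else sites[
        rng.choice(len(sites), size=n, replace=False)
    ]
    max_jitter = min(jitter, float(cell.min()) / 2 - MIN_OO_DISTANCE / 2)
    if max_jitter > 0:
        chosen = chosen + rng.uniform(-max_jitter, max_jitter, size=chosen.shape)
    return chosen, cell


def build_bulk(recipe: SystemRecipe, model: WaterModel = SPCE) -> Configuration:
    """Bulk water at an exact target mass density.

    The cubic box edge follows from L^3 = n m_w / rho; molecules sit on a
    jittered lattice with random orientations, guaranteeing no O-O pair
    closer than 0.25 nm.
    """
    n = recipe.n_molecules
    rng = np.random.default_rng(recipe.seed)
    if recipe.box is not None:
        box = np.asarray(recipe.box, float)
    else:
        volume = n * model.mass * AMU_PER_NM3_TO_G_PER_CM3 / recipe.density
        box = np.full(3, volume ** (1.0 / 3.0))
    if n == 0:
        return Configuration(box, np.zeros((0, 3)), model=model)
    sites, cell = _lattice_sites(n, box, (0, 0, 0), box, recipe.jitter, rng)
    if cell.min() < MIN_OO_DISTANCE:
        raise ValueError(
            f"density too high: lattice cell {cell.min():.3f} nm cannot keep "
            f"O-O separations above {MIN_OO_DISTANCE} nm"
        )
    positions = _place_molecules(sites, rng, model)
    return Configuration(box, positions, model=model)


def build_slab(recipe: SystemRecipe, model: WaterModel = SPCE) -> Configuration:
    """A liquid slab centred along the slab axis with vacuum on both sides.

    The slab thickness follows from the molecule count and the liquid
    density (recipe.density); the remaining box length along the slab axis
    is empty vapour.
    """
    box = np.asarray(recipe.box, float)
    n = recipe.n_molecules
    rng = np.random.default_rng(recipe.seed)
    if n == 0:
        return Configuration(box, np.zeros((0, 3)), model=model)
    axis = recipe.slab_axis
    density = recipe.density if recipe.density else 0.997
    volume = n * model.mass * AMU_PER_NM3_TO_G_PER_CM3 / density
    tangential = [i for i in range(3) if i != axis]
    area = box[tangential[0]] * box[tangential[1]]
    thickness = volume / area
    if thickness >= box[axis]:
        raise ValueError("slab thickness exceeds the box; no vacuum would remain")
    lo = np.zeros(3)
    hi = box.copy()
    lo[axis] = (box[axis] - thickness) / 2.0
    hi[axis] = (box[axis] + thickness) / 2.0
    sites, cell = _lattice_sites(n, box, lo, hi, recipe.jitter, rng)
    if cell.min() < MIN_OO_DISTANCE:
        raise ValueError("slab too dense for the overlap guarantee")
    positions = _place_molecules(sites, rng, model)
    return Configuration(box, positions, model=model)


def mass_density(config: Configuration) -> float:
    """Mass density of a configuration in g/cm^3."""
    total_mass = config.n_molecules * config.model.mass
    return total_mass * AMU_PER_NM3_TO_G_PER_CM3 / float(np.prod(config.box))
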