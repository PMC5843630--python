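"""Text I/O: GRO/XYZ coordinate dialects and YAML recipes.

GRO is the fixed-column coordinate format (nm, optional nm/ps velocities);
XYZ frames carry the box on the comment line. Both are exact-width writers
and tolerant readers for the three-site water systems this package builds.
"""

from __future__ import annotations

import numpy as np
import yaml

from .model import Configuration, SPCE

_ATOM_NAMES = ("OW", "HW1", "HW2")


def write_gro(config: Configuration, path, title: str = "SPC/E water") -> None:
    with open(path, "w") as fh:
        fh.write(f"{title}\n{config.n_atoms:5d}\n")
        vel = config.velocities
        has_vel = np.any(vel)
        for a in range(config.n_atoms):
            mol = a // 3
            name = _ATOM_NAMES[a % 3]
            x, y, z = config.positions[a]
            line = f"{(mol % 99999) + 1:5d}{'SOL':<5s}{name:>5s}{(a % 99999) + 1:5d}" \
                   f"{x:8.3f}{y:8.3f}{z:8.3f}"
            if has_vel:
                vx, vy, vz = vel[a]
                line += f"{vx:8.4f}{vy:8.4f}{vz:8.4f}"
            fh.write(line + "\n")
        fh.write("{:10.5f}{:10.5f}{:10.5f}\n".format(*config.box))


def read_gro(path) -> Configuration:
    with open(path) as fh:
        lines = fh.read().splitlines()
    n_atoms = int(lines[1])
    positions = np.empty((n_atoms, 3))
    velocities = np.zeros((n_atoms, 3))
    for a in range(n_atoms):
        line = lines[2 + a]
        positions[a] = [float(line[20 + 8 * k:28 + 8 * k]) for k in range(3)]
        if len(line.rstrip()) >= 68:
            velocities[a] = [float(line[44 + 8 * k:52 + 8 * k]) for k in range(3)]
    box = np.array([float(tok) for tok in lines[2 + n_atoms].split()[:3]])
    return Configuration(box, positions, velocities, model=SPCE)


def write_xyz_frames(positions_frames, box, path, comment: str = "") -> None:
    """Multi-frame XYZ; the box edges ride on each comment line."""
    positions_frames = np.asarray(positions_frames)
    if positions_frames.ndim == 2:
        positions_frames = positions_frames[None]
    with open(path, "w") as fh:
        for frame in positions_frames:
            fh.write(f"{len(frame)}\n")
            fh.write(f"box {box[0]:.6f} {box[1]:.6f} {box[2]:.6f} {comment}\n")
            for a, (x, y, z) in enumerate(frame):
                fh.write(f"{_ATOM_NAMES[a % 3]:<4s} {x: .6f} {y: .6f} {z: .6f}\n")


def read_xyz_frames(path):
    """Return (frames array, box) from an XYZ file written by this package."""
    frames = []
    box = None
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline().split()
            if comment and comment[0] == "box":
                box = np.array([float(v) for v in comment[1:4]])
            frame = np.empty((n, 3))
            for a in range(n):
                frame[a] = [float(tok) for tok in fh.readline().split()[1:4]]
            frames.append(frame)
    return np.array(frames), box


def save_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
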