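"""Text-based trajectory/topology readers and writers.

Formats: XYZ (visualization), LAMMPS data files (topology export with three
bond types: 1 = collagen, 2 = AGE, 3 = strengthened), LAMMPS-style text dumps
(per-frame positions), and tidy CSV curve tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from fibrilmech.geometry import (
    FAMILY_AGE,
    FAMILY_COLLAGEN,
    FAMILY_STRENGTHENED,
    FibrilTopology,
)
from fibrilmech.tensile import Trajectory

_BOND_TYPE = {FAMILY_COLLAGEN: 1, FAMILY_AGE: 2, FAMILY_STRENGTHENED: 3}


def write_xyz(path: str | Path, positions: np.ndarray, symbols=None, comment: str = "") -> None:
    """Write one XYZ frame (symbols default to 'C')."""
    positions = np.asarray(positions)
    n = len(positions)
    if symbols is None:
        symbols = ["C"] * n
    with open(path, "w") as fh:
        fh.write(f"{n}\n{comment}\n")
        for s, (x, y, z) in zip(symbols, positions):
            fh.write(f"{s} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read one XYZ frame: (symbols, positions)."""
    with open(path) as fh:
        n = int(fh.readline())
        fh.readline()
        symbols, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            symbols.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    return symbols, np.array(rows)


def write_lammps_data(path: str | Path, topo: FibrilTopology) -> None:
    """Export the topology as a LAMMPS data file (atom_style full).

    Atom type 1 = molecular bead, 2 = grip-extension bead; bond types
    1 = collagen, 2 = AGE cross-link, 3 = strengthened.
    """
    pos = topo.positions
    n = len(pos)
    bonds = [
        (i, j, _BOND_TYPE[int(f)])
        for i, j, f in zip(topo.bond_i, topo.bond_j, topo.bond_family)
    ] + [(i, j, _BOND_TYPE[FAMILY_AGE]) for i, j in topo.crosslinks]
    lo = pos.min(axis=0) - 50.0
    hi = pos.max(axis=0) + 50.0
    with open(path, "w") as fh:
        fh.write("fibrilmech topology export\n\n")
        fh.write(f"{n} atoms\n{len(bonds)} bonds\n\n")
        fh.write("2 atom types\n3 bond types\n\n")
        fh.write(f"{lo[0]:.4f} {hi[0]:.4f} xlo xhi\n")
        fh.write(f"{lo[1]:.4f} {hi[1]:.4f} ylo yhi\n")
        fh.write(f"{lo[2]:.4f} {hi[2]:.4f} zlo zhi\n\n")
        fh.write("Atoms # full\n\n")
        for k in range(n):
            atype = 2 if topo.is_extension[k] else 1
            mol = int(topo.chain_index[k]) + 1
            x, y, z = pos[k]
            fh.write(f"{k + 1} {mol} {atype} 0.0 {x:.6f} {y:.6f} {z:.6f}\n")
        fh.write("\nBonds\n\n")
        for b, (i, j, t) in enumerate(bonds, start=1):
            fh.write(f"{b} {t} {int(i) + 1} {int(j) + 1}\n")


def write_lammps_dump(path: str | Path, frames: list[np.ndarray],
                      timesteps: list[int] | None = None) -> None:
    """Write a multi-frame LAMMPS-style text dump (id x y z)."""
    with open(path, "w") as fh:
        for f, pos in enumerate(frames):
            ts = timesteps[f] if timesteps else f
            n = len(pos)
            lo = pos.min(axis=0) - 1.0
            hi = pos.max(axis=0) + 1.0
            fh.write(f"ITEM: TIMESTEP\n{ts}\n")
            fh.write(f"ITEM: NUMBER OF ATOMS\n{n}\n")
            fh.write("ITEM: BOX BOUNDS ff ff ff\n")
            for d in range(3):
                fh.write(f"{lo[d]:.6f} {hi[d]:.6f}\n")
            fh.write("ITEM: ATOMS id x y z\n")
            for k, (x, y, z) in enumerate(pos, start=1):
                fh.write(f"{k} {x:.6f} {y:.6f} {z:.6f}\n")


def read_lammps_dump(path: str | Path) -> tuple[list[int], list[np.ndarray]]:
    """Read a text dump written by :func:`write_lammps_dump` (or LAMMPS with
    'id x y z' columns).  Returns (timesteps, position frames)."""
    timesteps, frames = [], []
    with open(path) as fh:
        line = fh.readline()
        while line:
            assert line.startswith("ITEM: TIMESTEP")
            timesteps.append(int(fh.readline()))
            assert fh.readline().startswith("ITEM: NUMBER OF ATOMS")
            n = int(fh.readline())
            assert fh.readline().startswith("ITEM: BOX")
            for _ in range(3):
                fh.readline()
            header = fh.readline().split()[2:]
            ix = header.index("id")
            cx, cy, cz = header.index("x"), header.index("y"), header.index("z")
            pos = np.empty((n, 3))
            for _ in range(n):
                parts = fh.readline().split()
                k = int(parts[ix]) - 1
                pos[k] = [float(parts[cx]), float(parts[cy]), float(parts[cz])]
            frames.append(pos)
            line = fh.readline()
    return timesteps, frames


def trajectory_to_csv(path: str | Path, traj: Trajectory) -> None:
    """Write the per-frame scalar table of a trajectory."""
    traj.to_frame().to_csv(path, index=False)


def trajectory_table_from_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
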