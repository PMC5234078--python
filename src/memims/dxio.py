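"""OpenDX text-format export/import for regular 3-D scalar grids."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_dx", "read_dx"]


def write_dx(values: np.ndarray, origin, spacing, path: str | Path,
             comment: str = "") -> None:
    """Write a regular grid (values indexed [ix, iy, iz]) as OpenDX text.

    ``origin`` and ``spacing`` are in the coordinate units of the grid
    (A here); the scalar values keep whatever unit they carry.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("values must be a 3-D array")
    nx, ny, nz = values.shape
    ox, oy, oz = origin
    if np.isscalar(spacing):
        dx = dy = dz = float(spacing)
    else:
        dx, dy, dz = spacing
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6g} {oy:.6g} {oz:.6g}\n")
        fh.write(f"delta {dx:.6g} 0 0\n")
        fh.write(f"delta 0 {dy:.6g} 0\n")
        fh.write(f"delta 0 0 {dz:.6g}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {values.size} "
            f"data follows\n"
        )
        flat = values.ravel(order="C")  # z fastest, the DX convention
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.8e}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


def read_dx(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an OpenDX grid; returns (values[ix,iy,iz], origin, spacing)."""
    counts = origin = None
    deltas = []
    data: list[float] = []
    n_items = None
    reading = False
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s.startswith("object 1"):
                counts = tuple(int(x) for x in s.split()[-3:])
            elif s.startswith("origin"):
                origin = np.array([float(x) for x in s.split()[1:4]])
            elif s.startswith("delta"):
                deltas.append([float(x) for x in s.split()[1:4]])
            elif "data follows" in s:
                n_items = int(s.split("items")[1].split()[0])
                reading = True
            elif reading and len(data) < (n_items or 0):
                try:
                    data.extend(float(x) for x in s.split())
                except ValueError:
                    reading = False
    if counts is None or origin is None or n_items is None:
        raise ValueError(f"not a parsable DX grid: {path}")
    values = np.array(data[:n_items]).reshape(counts, order="C")
    spacing = np.array([deltas[0][0], deltas[1][1], deltas[2][2]])
    return values, origin, spacing
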