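"""Plain-text exports: legacy-ASCII VTK structured grids and mask images.

The VTK writers emit the legacy STRUCTURED_POINTS format by hand (no VTK
dependency), which ParaView and pyvista both read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .flow_solver import FlowField
from .geometry import ComputationalGrid

__all__ = ["write_vtk_mask", "write_vtk_field", "write_mask_png"]


def _header(f, grid: ComputationalGrid, title: str) -> None:
    h = grid.spacing
    f.write("# vtk DataFile Version 3.0\n")
    f.write(f"{title}\n")
    f.write("ASCII\n")
    f.write("DATASET STRUCTURED_POINTS\n")
    # cell data on an (nx x ny) cell grid needs (nx+1 x ny+1) points
    f.write(f"DIMENSIONS {grid.nx + 1} {grid.ny + 1} 1\n")
    f.write("ORIGIN 0 0 0\n")
    f.write(f"SPACING {h} {h} {h}\n")
    f.write(f"CELL_DATA {grid.nx * grid.ny}\n")


def _write_scalars(f, name: str, values: np.ndarray, fmt: str) -> None:
    f.write(f"SCALARS {name} {'int' if fmt == 'd' else 'float'} 1\n")
    f.write("LOOKUP_TABLE default\n")
    # VTK cell ordering: x fastest
    flat = values.T.ravel()
    f.write("\n".join(format(val, fmt) for val in flat))
    f.write("\n")


def write_vtk_mask(path: str | Path, grid: ComputationalGrid) -> Path:
    """Export the cell-label mask for inspection."""
    path = Path(path)
    with path.open("w") as f:
        _header(f, grid, "domain mask")
        _write_scalars(f, "cell_mask", grid.cell_mask.astype(int), "d")
    return path


def write_vtk_field(path: str | Path, grid: ComputationalGrid,
                    field: FlowField) -> Path:
    """Export cell-centered speed, pressure and velocity components."""
    path = Path(path)
    uc = 0.5 * (field.u[:-1, :] + field.u[1:, :])
    vc = 0.5 * (field.v[:, :-1] + field.v[:, 1:])
    with path.open("w") as f:
        _header(f, grid, f"flow field t={field.time:.6g}s")
        _write_scalars(f, "pressure", field.p, ".6e")
        _write_scalars(f, "u", uc, ".6e")
        _write_scalars(f, "v", vc, ".6e")
        _write_scalars(f, "speed", np.hypot(uc, vc), ".6e")
    return path


def write_mask_png(path: str | Path, mask: np.ndarray) -> Path:
    """Save a boolean metal mask (or cell mask) as a grayscale PNG."""
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib import image as mpimg

    path = Path(path)
    mpimg.imsave(path, np.asarray(mask, dtype=float).T[::-1, :],
                 cmap="gray", vmin=0, vmax=1)
    return path
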