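"""Legacy-ASCII VTK export of grids and fields for external inspection.

Writes the STRUCTURED_POINTS (image-data) dialect, readable by ParaView
and VisIt: cell data for tissue labels and |E|, point data for the nodal
potential.
"""

from __future__ import annotations

import numpy as np

from .grid import LabeledGrid


def write_vtk_image(
    path,
    grid: LabeledGrid,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    spec = grid.spec
    nxn, nyn, nzn = spec.node_shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("tchannel grid export\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nxn} {nyn} {nzn}\n")
        fh.write(f"ORIGIN {spec.origin[0]} {spec.origin[1]} {spec.origin[2]}\n")
        fh.write(f"SPACING {spec.spacing} {spec.spacing} {spec.spacing}\n")

        cell_data = {"tissue_label": grid.labels, **(cell_data or {})}
        fh.write(f"CELL_DATA {spec.n_cells}\n")
        for name, arr in cell_data.items():
            a = np.asarray(arr)
            if a.shape != tuple(spec.shape):
                raise ValueError(f"cell array {name!r} has shape {a.shape}")
            kind = "int" if np.issubdtype(a.dtype, np.integer) else "float"
            fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
            # VTK expects x fastest; our arrays are (x, y, z) C-order
            np.savetxt(fh, a.transpose(2, 1, 0).reshape(-1, 1), fmt="%.9g")

        if point_data:
            fh.write(f"POINT_DATA {spec.n_nodes}\n")
            for name, arr in point_data.items():
                a = np.asarray(arr)
                if a.shape != tuple(spec.node_shape):
                    raise ValueError(f"point array {name!r} has shape {a.shape}")
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, a.transpose(2, 1, 0).reshape(-1, 1), fmt="%.9g")
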