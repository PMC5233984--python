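"""Structured voxel grids with per-cell tissue labels.

The head (or sphere phantom) lives on a regular, isotropic hexahedral grid.
Cell ``(i, j, k)`` occupies the half-open box
``[origin + i*h, origin + (i+1)*h)`` per axis (0-based), with ``h`` the
spacing in mm.  Potentials are nodal, fields and labels are per-cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np


class TissueLabel(IntEnum):
    """Tissue / material labels.  AIR is the exterior complement."""

    AIR = 0
    SCALP = 1
    SKULL = 2
    DURA = 3
    CSF = 4
    GM = 5
    WM = 6
    GEL = 7
    ELECTRODE = 8
    CHANNEL = 9


#: Default isotropic conductivities in S/m.  The transcranial channel is
#: titanium; the electrode is a metal disc.  AIR carries zero conductivity
#: and is excluded from the conduction problem.
DEFAULT_CONDUCTIVITY: dict[TissueLabel, float] = {
    TissueLabel.SCALP: 0.465,
    TissueLabel.SKULL: 0.01,
    TissueLabel.DURA: 0.065,
    TissueLabel.CSF: 1.65,
    TissueLabel.GM: 0.276,
    TissueLabel.WM: 0.126,
    TissueLabel.GEL: 0.30,
    TissueLabel.ELECTRODE: 5.80e7,
    TissueLabel.CHANNEL: 7.40e5,
}


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular voxel grid.

    Parameters
    ----------
    origin : (3,) array-like
        Coordinates of the grid corner in mm.
    spacing : float
        Isotropic cell edge length in mm (> 0).
    shape : (3,) ints
        Number of cells per axis (each >= 2).
    """

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        if len(self.shape) != 3 or any(int(n) < 2 for n in self.shape):
            raise ValueError(f"shape must be 3 ints >= 2, got {self.shape}")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def node_shape(self) -> tuple[int, int, int]:
        return tuple(n + 1 for n in self.shape)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.node_shape))

    @property
    def extent(self) -> np.ndarray:
        """Physical edge lengths (mm) per axis."""
        return np.asarray(self.shape, float) * self.spacing

    def axis_cell_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing

    def axis_nodes(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n + 1) * self.spacing

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid (ij-indexed) of cell-center coordinates, mm."""
        return np.meshgrid(
            self.axis_cell_centers(0),
            self.axis_cell_centers(1),
            self.axis_cell_centers(2),
            indexing="ij",
        )

    def node_index(self, i, j, k):
        """Flat C-order index of node (i, j, k)."""
        _, ny, nz = self.node_shape
        return (np.asarray(i) * ny + np.asarray(j)) * nz + np.asarray(k)

    def cell_volume_mm3(self) -> float:
        return float(self.spacing**3)


@dataclass
class LabeledGrid:
    """A GridSpec plus an int8 label array of shape ``spec.shape``."""

    spec: GridSpec
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != tuple(self.spec.shape):
            raise ValueError(
                f"label array shape {self.labels.shape} != grid shape {self.spec.shape}"
            )

    def copy(self) -> "LabeledGrid":
        return LabeledGrid(self.spec, self.labels.copy())

    def count(self, label: TissueLabel) -> int:
        return int(np.count_nonzero(self.labels == int(label)))

    def mask(self, *labels: TissueLabel) -> np.ndarray:
        out = np.zeros(self.labels.shape, bool)
        for lab in labels:
            out |= self.labels == int(lab)
        return out


@dataclass
class ConductivityMap:
    """Mapping TissueLabel -> conductivity (S/m); AIR is fixed at 0."""

    values: dict[TissueLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDUCTIVITY)
    )

    def __post_init__(self) -> None:
        vals = dict(DEFAULT_CONDUCTIVITY)
        vals.update({TissueLabel(k): float(v) for k, v in self.values.items()})
        vals.pop(TissueLabel.AIR, None)
        for lab, sig in vals.items():
            if sig <= 0:
                raise ValueError(f"conductivity for {lab.name} must be > 0, got {sig}")
        self.values = vals

    def __getitem__(self, label: TissueLabel) -> float:
        if TissueLabel(label) == TissueLabel.AIR:
            return 0.0
        return self.values[TissueLabel(label)]

    def as_array(self) -> np.ndarray:
        """Per-label sigma indexed by label integer value (AIR -> 0)."""
        arr = np.zeros(max(int(l) for l in TissueLabel) + 1)
        for lab, sig in self.values.items():
            arr[int(lab)] = sig
        return arr

    def cell_sigma(self, grid: LabeledGrid) -> np.ndarray:
        """Per-cell conductivity array (S/m), shape = grid.spec.shape."""
        return self.as_array()[grid.labels]
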