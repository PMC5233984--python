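"""Parametric synthetic head and phantom geometries.

Generates the labeled voxel models the pipeline operates on:

* a layered head (scalp / skull / dura / CSF / GM / WM stacked along z) with
  a single sinusoidal gyral crown — a "hand-knob-like" ridge — centered
  under the electrode montage;
* a concentric-shell sphere phantom used as the analytic validation target;
* the transcranial channel (I- or T-shaped titanium implant) carved through
  the full skull thickness;
* the 4x1 HD-tDCS montage (center active electrode + 4 returns on a ring),
  each electrode a metal disc on a gel pad, with the boundary-face node sets
  the solver needs for its current/ground conditions.

All lengths are mm.  z is the scalp-normal axis; the scalp surface is flat
and the gyral fold lives on the CSF/GM interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec, LabeledGrid, TissueLabel


class ConfigurationError(ValueError):
    """A geometry/config parameter set that cannot be realised."""


@dataclass
class HeadParams:
    """Layer thicknesses and gyral-fold shape of the synthetic head.

    Thicknesses are mm.  ``csf`` is the CSF thickness at the fold crown;
    in the troughs the CSF is thicker by ``fold_amplitude``.  ``wm`` is the
    minimum white-matter depth below the GM at the crown.  ``top_clearance``
    reserves air above the scalp for the gel + electrode stack.
    """

    scalp: float = 5.0
    skull: float = 7.0
    dura: float = 0.5
    csf: float = 2.0
    gm: float = 2.5
    wm: float = 8.0
    fold_amplitude: float = 3.0
    fold_wavelength: float = 20.0
    #: scalar, or (x, y) pair — the displacement experiment extends x so
    #: the displaced return ring stays on the scalp
    lateral_extent: float | tuple[float, float] = 84.0
    top_clearance: float = 4.0

    def __post_init__(self) -> None:
        for name in ("scalp", "skull", "dura", "csf", "gm", "wm"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"layer '{name}' thickness must be >= 0")
        if self.fold_amplitude < 0 or self.fold_wavelength <= 0:
            raise ConfigurationError("fold amplitude must be >= 0 and wavelength > 0")

    @property
    def stack_height(self) -> float:
        """Total z extent needed: all layers plus fold depth and clearance."""
        return (
            self.top_clearance
            + self.scalp
            + self.skull
            + self.dura
            + self.csf
            + self.fold_amplitude
            + self.gm
            + self.wm
        )


def default_grid(head: HeadParams, spacing: float = 0.5) -> GridSpec:
    """Grid just large enough for ``head``, centered laterally on x=y=0."""
    ext = head.lateral_extent
    ex, ey = (ext, ext) if np.isscalar(ext) else ext
    nx = int(math.ceil(ex / spacing))
    ny = int(math.ceil(ey / spacing))
    nz = int(math.ceil(head.stack_height / spacing))
    return GridSpec(
        origin=(-nx * spacing / 2.0, -ny * spacing / 2.0, 0.0),
        spacing=spacing,
        shape=(nx, ny, nz),
    )


def fold_height(x: np.ndarray, head: HeadParams) -> np.ndarray:
    """Gyral bump height b(x) in [0, amplitude]; crown (max) at x = 0."""
    x = np.asarray(x, float)
    lam = head.fold_wavelength
    b = 0.5 * head.fold_amplitude * (1.0 + np.cos(2.0 * np.pi * x / lam))
    return np.where(np.abs(x) <= lam / 2.0, b, 0.0)


def head_interfaces(grid: GridSpec, head: HeadParams) -> dict[str, float]:
    """z coordinates (mm) of the flat interfaces, measured in grid frame."""
    z_top = grid.origin[2] + grid.extent[2]
    scalp_top = z_top - head.top_clearance
    skull_top = scalp_top - head.scalp
    dura_top = skull_top - head.skull
    csf_top = dura_top - head.dura
    gm_top_crown = csf_top - head.csf
    return {
        "scalp_top": scalp_top,
        "skull_top": skull_top,
        "dura_top": dura_top,
        "csf_top": csf_top,
        "gm_top_crown": gm_top_crown,
    }


def crown_surface_point(grid: GridSpec, head: HeadParams) -> np.ndarray:
    """The CSF/GM crown apex (mm) — the stimulation target."""
    z = head_interfaces(grid, head)["gm_top_crown"]
    return np.array([0.0, 0.0, z])


def build_head_model(grid: GridSpec, head: HeadParams) -> LabeledGrid:
    """Label the grid with the layered head; every cell gets exactly one label.

    Layers are stacked along z (scalp outermost); the CSF/GM interface
    follows the configured sinusoidal fold, with the crown apex at x = 0
    directly beneath the undisplaced montage center.  The fold carries
    through to the GM/WM interface, so the GM band has constant thickness.
    """
    if head.stack_height > grid.extent[2] + 1e-9:
        # locate the first layer that no longer fits, walking from the top
        names = ["top_clearance", "scalp", "skull", "dura", "csf",
                 "fold_amplitude", "gm", "wm"]
        cum = 0.0
        for name in names:
            cum += getattr(head, name)
            if cum > grid.extent[2] + 1e-9:
                raise ConfigurationError(
                    f"layer '{name}' exceeds the grid z extent "
                    f"({grid.extent[2]:.3f} mm available, "
                    f"{head.stack_height:.3f} mm required)"
                )
    zi = head_interfaces(grid, head)
    xc = grid.axis_cell_centers(0)
    zc = grid.axis_cell_centers(2)
    gm_top = zi["gm_top_crown"] - head.fold_amplitude + fold_height(xc, head)

    nx, ny, nz = grid.shape
    lab2d = np.full((nx, nz), int(TissueLabel.AIR), np.int8)
    z = np.broadcast_to(zc[None, :], (nx, nz))
    g = gm_top[:, None]
    lab2d[(z < zi["scalp_top"]) & (z >= zi["skull_top"])] = int(TissueLabel.SCALP)
    lab2d[(z < zi["skull_top"]) & (z >= zi["dura_top"])] = int(TissueLabel.SKULL)
    lab2d[(z < zi["dura_top"]) & (z >= zi["csf_top"])] = int(TissueLabel.DURA)
    lab2d[(z < zi["csf_top"]) & (z >= g)] = int(TissueLabel.CSF)
    lab2d[(z < g) & (z >= g - head.gm)] = int(TissueLabel.GM)
    lab2d[z < g - head.gm] = int(TissueLabel.WM)

    labels = np.broadcast_to(lab2d[:, None, :], (nx, ny, nz)).copy()
    return LabeledGrid(grid, labels)


@dataclass
class SphereParams:
    """Concentric-shell phantom: radii strictly decreasing, one label each."""

    radii: tuple[float, ...]
    layer_labels: tuple[TissueLabel, ...]
    center: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, float)
        if r.size < 1 or np.any(np.diff(r) >= 0):
            raise ConfigurationError("sphere radii must be strictly decreasing")
        if len(self.layer_labels) != r.size:
            raise ConfigurationError("need one label per sphere layer")


def build_sphere_phantom(grid: GridSpec, sphere: SphereParams) -> LabeledGrid:
    """Voxelize concentric spherical shells by cell-center membership."""
    center = np.asarray(
        sphere.center
        if sphere.center is not None
        else np.asarray(grid.origin) + grid.extent / 2.0,
        float,
    )
    lo = center - sphere.radii[0]
    hi = center + sphere.radii[0]
    if np.any(lo < np.asarray(grid.origin) - 1e-9) or np.any(
        hi > np.asarray(grid.origin) + grid.extent + 1e-9
    ):
        raise ConfigurationError(
            f"outer radius {sphere.radii[0]} mm does not fit inside the grid"
        )
    X, Y, Z = grid.cell_centers()
    r = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2)
    labels = np.full(grid.shape, int(TissueLabel.AIR), np.int8)
    for radius, lab in zip(sphere.radii, sphere.layer_labels):
        labels[r <= radius] = int(lab)
    return LabeledGrid(grid, labels)


def outer_surface_nodes(grid: LabeledGrid) -> tuple[np.ndarray, np.ndarray]:
    """Nodes on the conductor/air interface.

    Returns flat node indices and their coordinates (mm) for every node
    touching at least one non-AIR cell but fewer than eight (i.e. on the
    outer surface of the conductor, including the grid boundary).
    """
    spec = grid.spec
    lab = grid.labels != int(TissueLabel.AIR)
    nshape = spec.node_shape
    cover = np.zeros(nshape, np.int8)
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                pad = np.zeros(nshape, bool)
                pad[di:nshape[0] - 1 + di, dj:nshape[1] - 1 + dj,
                    dk:nshape[2] - 1 + dk] = lab
                cover += pad
    surf = (cover >= 1) & (cover < 8)
    idx = np.argwhere(surf)
    pos = idx * spec.spacing + np.asarray(spec.origin)
    return np.ravel_multi_index(idx.T, nshape), pos


@dataclass
class ChannelSpec:
    """Transcranial channel: a conductive shaft through the skull.

    ``shape`` is "I" (shaft only), "T" (shaft + hat disc at one skull
    table), or "NONE".  The hat diameter defaults to shaft + 1 mm.  The hat
    sits at the outer (scalp-side) skull table by default, like the head
    of an epidural screw: there it collects current over its wider face
    and funnels it down the shaft, which is what makes the T shape
    slightly more effective than the I shape.  Set ``hat_side`` to
    "inner" for a hat against the dural table.
    """

    shape: str = "T"
    shaft_diameter: float = 7.0
    hat_diameter: float | None = None
    hat_thickness: float = 1.0
    hat_side: str = "outer"
    axis: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.shape = self.shape.upper()
        if self.shape not in ("I", "T", "NONE"):
            raise ConfigurationError(f"unknown channel shape {self.shape!r}")
        if self.shape != "NONE" and self.shaft_diameter <= 0:
            raise ConfigurationError("shaft diameter must be > 0")
        if self.hat_diameter is None:
            self.hat_diameter = self.shaft_diameter + 1.0
        if self.hat_side not in ("inner", "outer"):
            raise ConfigurationError(f"hat_side must be inner/outer, got {self.hat_side!r}")


def carve_channel(grid: LabeledGrid, chan: ChannelSpec) -> LabeledGrid:
    """Relabel skull cells inside the channel to CHANNEL (titanium).

    Only SKULL cells are touched, so the implant spans exactly the full
    skull thickness and carving conserves skull+channel cell count.
    """
    if chan.shape == "NONE":
        return grid
    spec = grid.spec
    X, Y, _ = spec.cell_centers()
    r2 = (X - chan.axis[0]) ** 2 + (Y - chan.axis[1]) ** 2
    skull = grid.labels == int(TissueLabel.SKULL)
    shaft = skull & (r2 <= (chan.shaft_diameter / 2.0) ** 2)
    if not shaft.any():
        raise ConfigurationError("channel axis does not intersect the skull layer")
    out = grid.copy()
    out.labels[shaft] = int(TissueLabel.CHANNEL)
    if chan.shape == "T":
        zc = spec.axis_cell_centers(2)
        kk = np.where(skull.any(axis=(0, 1)))[0]
        if chan.hat_side == "inner":
            zlo = zc[kk.min()] - spec.spacing / 2.0
            in_hat_z = zc < zlo + chan.hat_thickness
        else:
            zhi = zc[kk.max()] + spec.spacing / 2.0
            in_hat_z = zc >= zhi - chan.hat_thickness
        hat = skull & (r2 <= (chan.hat_diameter / 2.0) ** 2) & in_hat_z[None, None, :]
        out.labels[hat] = int(TissueLabel.CHANNEL)
    return out


@dataclass
class MontageSpec:
    """4x1 HD-tDCS montage: one active center electrode + 4 returns.

    Disc electrodes (height 1 mm, radius 4 mm) sit on gel pads (height
    2 mm, radius 4 mm) on the scalp.  The returns sit on a ring of
    ``ring_radius`` around the center.  ``displacement`` translates the
    whole five-electrode assembly rigidly in the scalp plane; the channel
    (if any) stays put.
    """

    center: tuple[float, float] = (0.0, 0.0)
    ring_radius: float = 35.0
    electrode_height: float = 1.0
    electrode_radius: float = 4.0
    gel_height: float = 2.0
    gel_radius: float = 4.0
    current_mA: float = 1.0
    displacement: tuple[float, float] = (0.0, 0.0)

    def positions(self) -> np.ndarray:
        """(5, 2) electrode axis positions; row 0 is the active electrode."""
        cx = self.center[0] + self.displacement[0]
        cy = self.center[1] + self.displacement[1]
        ring = [(self.ring_radius, 0), (-self.ring_radius, 0),
                (0, self.ring_radius), (0, -self.ring_radius)]
        return np.array([(cx, cy)] + [(cx + dx, cy + dy) for dx, dy in ring])


@dataclass
class MontageFaces:
    """Exposed top-face node sets of the placed electrodes.

    ``active_nodes`` / ``return_nodes`` are flat node indices;
    ``active_weights`` are per-node face-area weights (mm^2, summing to the
    exposed active area) used to spread the injected current uniformly.
    """

    active_nodes: np.ndarray
    active_weights: np.ndarray
    return_nodes: np.ndarray
    current_mA: float

    def active_centroid(self, grid: GridSpec) -> np.ndarray:
        nxn, nyn, nzn = grid.node_shape
        idx = self.active_nodes
        i, rem = np.divmod(idx, nyn * nzn)
        j, k = np.divmod(rem, nzn)
        pts = np.stack([i, j, k], axis=1) * grid.spacing + np.asarray(grid.origin)
        w = self.active_weights[:, None]
        return (pts * w).sum(axis=0) / w.sum()


def place_montage(
    grid: LabeledGrid, montage: MontageSpec
) -> tuple[LabeledGrid, MontageFaces]:
    """Stamp the five gel+electrode stacks onto the scalp surface.

    Returns the augmented grid and the boundary node sets: the active
    electrode's exposed top faces (Neumann current injection) and the four
    return electrodes' top faces (Dirichlet ground).
    """
    spec = grid.spec
    h = spec.spacing
    xc = spec.axis_cell_centers(0)
    yc = spec.axis_cell_centers(1)
    out = grid.copy()

    # flat scalp: topmost non-air cell index, from any head column
    nonair = (grid.labels != int(TissueLabel.AIR)).any(axis=(0, 1))
    if not nonair.any():
        raise ConfigurationError("grid contains no tissue to mount electrodes on")
    k_scalp_top = int(np.where(nonair)[0].max())

    n_gel = max(1, int(round(montage.gel_height / h)))
    n_el = max(1, int(round(montage.electrode_height / h)))
    k_gel = np.arange(k_scalp_top + 1, k_scalp_top + 1 + n_gel)
    k_el = np.arange(k_gel[-1] + 1, k_gel[-1] + 1 + n_el)
    if k_el[-1] >= spec.shape[2]:
        raise ConfigurationError("electrode stack exceeds the grid top")

    face_cells: list[np.ndarray] = []
    for ex, ey in montage.positions():
        gel_fp = (xc[:, None] - ex) ** 2 + (yc[None, :] - ey) ** 2 <= montage.gel_radius**2
        el_fp = (xc[:, None] - ex) ** 2 + (yc[None, :] - ey) ** 2 <= montage.electrode_radius**2
        if not el_fp.any():
            raise ConfigurationError(
                f"electrode footprint at ({ex:.1f}, {ey:.1f}) mm lies off the grid"
            )
        ii, jj = np.where(gel_fp)
        if ii.min() == 0 or jj.min() == 0 or ii.max() == spec.shape[0] - 1 or jj.max() == spec.shape[1] - 1:
            raise ConfigurationError(
                f"electrode footprint at ({ex:.1f}, {ey:.1f}) mm touches the grid edge"
            )
        for k in k_gel:
            out.labels[gel_fp, k] = int(TissueLabel.GEL)
        for k in k_el:
            out.labels[el_fp, k] = int(TissueLabel.ELECTRODE)
        face_cells.append(np.stack(np.where(el_fp), axis=1))

    # top faces of the electrode discs live on node plane k_el[-1] + 1
    k_node = int(k_el[-1] + 1)

    def face_nodes(cells_ij: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        acc: dict[int, float] = {}
        q = h * h / 4.0
        for i, j in cells_ij:
            for di in (0, 1):
                for dj in (0, 1):
                    idx = int(spec.node_index(i + di, j + dj, k_node))
                    acc[idx] = acc.get(idx, 0.0) + q
        nodes = np.fromiter(acc.keys(), dtype=np.int64)
        order = np.argsort(nodes)
        weights = np.fromiter(acc.values(), dtype=float)
        return nodes[order], weights[order]

    a_nodes, a_weights = face_nodes(face_cells[0])
    r_nodes = np.concatenate([face_nodes(fc)[0] for fc in face_cells[1:]])
    faces = MontageFaces(
        active_nodes=a_nodes,
        active_weights=a_weights,
        return_nodes=np.unique(r_nodes),
        current_mA=montage.current_mA,
    )
    return out, faces
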