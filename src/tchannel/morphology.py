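"""Parametric pyramidal-neuron morphologies, SWC I/O, and cortical placement.

Two compartmental stand-in morphologies are generated:

* **L5**: a deep pyramidal cell — apical trunk with a small tuft reaching
  layer 1, two basal dendrites, axon initial segment, and a myelinated-like
  axon that crosses the GM/WM boundary (landmark ``b1``), bends (``b2``)
  and runs horizontally in the white matter to ``terminal``.
* **L3**: a superficial pyramidal cell whose axon remains inside the gray
  matter (landmarks ``mid`` and ``terminal``).

Probe landmarks follow the convention: ``d2`` is the apical tip, ``d1`` a
tuft side branch, ``d3`` the apical mid-trunk (L5) or basal tip (L3),
``d4`` the L5 basal tip.

Placement aligns the local apical axis (+z) with the outward cortical
normal, puts the soma at a configurable fractional GM depth, stretches the
apical trunk so the tuft reaches the layer-1 band, and stretches the L5
axon so ``b1`` lands on the GM/WM boundary.  Established reconstructions
can be substituted through the SWC importer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np

from .grid import LabeledGrid, TissueLabel


class Part(IntEnum):
    """Compartment part tags; values 1-4 follow the SWC convention."""

    SOMA = 1
    AXON = 2
    BASAL = 3
    APICAL = 4
    ISEG = 5


L5_LANDMARKS = frozenset({"d1", "d2", "d3", "d4", "soma", "iseg", "b1", "b2", "terminal"})
L3_LANDMARKS = frozenset({"d1", "d2", "d3", "soma", "iseg", "mid", "terminal"})


@dataclass
class Morphology:
    """Compartmental tree.  Node 0 is the soma root (parent -1).

    Compartment ``i > 0`` is the cylinder from ``pos[parent[i]]`` to
    ``pos[i]`` with diameter ``diam_um[i]``; the root soma is modeled as a
    cylinder of length equal to its diameter (same membrane area as the
    equivalent sphere).  Coordinates are mm; in the local build frame the
    soma sits at the origin with +z toward the pia.
    """

    pos: np.ndarray          # (n, 3) mm
    parent: np.ndarray       # (n,) int, -1 for root
    part: np.ndarray         # (n,) Part values
    diam_um: np.ndarray      # (n,)
    landmarks: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, float).reshape(-1, 3)
        self.parent = np.asarray(self.parent, np.int64)
        self.part = np.asarray(self.part, np.int8)
        self.diam_um = np.asarray(self.diam_um, float)
        n = len(self.pos)
        if n == 0:
            raise ValueError("empty morphology")
        if self.parent[0] != -1 or np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValueError("parents must precede children with a single root at 0")
        if np.count_nonzero(self.parent == -1) != 1:
            raise ValueError("exactly one root compartment expected")
        if np.any(self.diam_um <= 0):
            raise ValueError("diameters must be > 0")
        for name, idx in self.landmarks.items():
            if not 0 <= idx < n:
                raise ValueError(f"landmark {name!r} points at missing compartment {idx}")

    @property
    def n_comp(self) -> int:
        return len(self.pos)

    def lengths_mm(self) -> np.ndarray:
        """Per-compartment cylinder length; soma length = soma diameter."""
        out = np.empty(self.n_comp)
        out[0] = self.diam_um[0] * 1e-3
        d = self.pos[1:] - self.pos[self.parent[1:]]
        out[1:] = np.linalg.norm(d, axis=1)
        return out

    def centers_mm(self) -> np.ndarray:
        """Compartment center points (segment midpoints; soma position)."""
        out = np.empty_like(self.pos)
        out[0] = self.pos[0]
        out[1:] = 0.5 * (self.pos[1:] + self.pos[self.parent[1:]])
        return out

    def copy(self) -> "Morphology":
        return Morphology(
            self.pos.copy(), self.parent.copy(), self.part.copy(),
            self.diam_um.copy(), dict(self.landmarks),
        )


@dataclass
class MorphParams:
    """Shape parameters (mm unless noted) of the parametric pyramidal cells."""

    soma_diam_um: float = 20.0
    trunk_diam_um: float = 3.0
    tuft_diam_um: float = 1.5
    basal_diam_um: float = 2.0
    iseg_diam_um: float = 1.8
    axon_diam_um: float = 1.2
    apical_trunk_mm: float | None = None   # kind default: L5 1.5, L3 0.8
    tuft_len_mm: float = 0.25
    basal_radius_mm: float = 0.3
    iseg_len_mm: float = 0.05
    axon_below_mm: float | None = None     # kind default: L5 1.0, L3 0.35
    axon_run_mm: float = 0.5
    flatness: float = 1.0                  # < 1 compresses the apical extent
    step_mm: float = 0.05                  # build-time segment length

    def __post_init__(self) -> None:
        for name in ("soma_diam_um", "trunk_diam_um", "tuft_diam_um",
                     "basal_diam_um", "iseg_diam_um", "axon_diam_um",
                     "tuft_len_mm", "basal_radius_mm", "iseg_len_mm",
                     "axon_run_mm", "flatness", "step_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def type23_variant() -> MorphParams:
    """Parameters emulating the flat, thick-trunked L5 reference cells.

    The alternative L5 morphologies used for the sensitivity comparison
    are vertically compressed ("flat dendritic trees") but carry a much
    thicker apical trunk and tuft.  Both features matter: in a uniform
    field, pure vertical compression of a passive cable strictly reduces
    somatic polarization (polarization scales with extent along the field
    while the length constant is unchanged), whereas trunk thickening
    raises the length constant (lambda ~ sqrt(d)) and with it the somatic
    drive.  The combination reproduces the reference behaviour: a flatter
    cell with larger somatic depolarization.
    """
    return MorphParams(flatness=0.6, trunk_diam_um=10.0, tuft_diam_um=4.0)


class _Builder:
    def __init__(self, soma_diam: float):
        self.pos = [np.zeros(3)]
        self.parent = [-1]
        self.part = [int(Part.SOMA)]
        self.diam = [soma_diam]

    def chain(self, start: int, end_point, part: Part, diam: float, step: float) -> int:
        """Append a straight run from node ``start`` to ``end_point``."""
        p0 = self.pos[start]
        p1 = np.asarray(end_point, float)
        length = float(np.linalg.norm(p1 - p0))
        nseg = max(1, int(np.ceil(length / step)))
        prev = start
        for s in range(1, nseg + 1):
            self.pos.append(p0 + (p1 - p0) * (s / nseg))
            self.parent.append(prev)
            self.part.append(int(part))
            self.diam.append(diam)
            prev = len(self.pos) - 1
        return prev

    def done(self, landmarks: dict[str, int]) -> Morphology:
        return Morphology(
            np.array(self.pos), np.array(self.parent), np.array(self.part),
            np.array(self.diam), landmarks,
        )


def build_pn(kind: str, params: MorphParams | None = None) -> Morphology:
    """Deterministic parametric L5 or L3 pyramidal-cell morphology."""
    kind = kind.upper()
    if kind not in ("L5", "L3"):
        raise ValueError(f"unknown pyramidal-neuron kind {kind!r}")
    p = params or MorphParams()
    trunk = p.apical_trunk_mm if p.apical_trunk_mm is not None else (1.5 if kind == "L5" else 0.8)
    axon_below = p.axon_below_mm if p.axon_below_mm is not None else (1.0 if kind == "L5" else 0.35)
    f = p.flatness
    b = _Builder(p.soma_diam_um)
    lm: dict[str, int] = {"soma": 0}

    # apical trunk + tuft (z extents scaled by the flatness factor)
    mid = b.chain(0, (0, 0, 0.5 * trunk * f), Part.APICAL, p.trunk_diam_um, p.step_mm)
    lm["d3" if kind == "L5" else "_trunk_mid"] = mid
    top = b.chain(mid, (0, 0, trunk * f), Part.APICAL, p.trunk_diam_um, p.step_mm)
    lm["d2"] = b.chain(top, (0, 0, (trunk + p.tuft_len_mm) * f),
                       Part.APICAL, p.tuft_diam_um, p.step_mm)
    lm["d1"] = b.chain(top, (0.8 * p.tuft_len_mm, 0, (trunk + 0.4 * p.tuft_len_mm) * f),
                       Part.APICAL, p.tuft_diam_um, p.step_mm)

    # basal dendrites
    tip = b.chain(0, (p.basal_radius_mm, 0, -0.5 * p.basal_radius_mm),
                  Part.BASAL, p.basal_diam_um, p.step_mm)
    b.chain(0, (-p.basal_radius_mm, 0, -0.5 * p.basal_radius_mm),
            Part.BASAL, p.basal_diam_um, p.step_mm)
    lm["d4" if kind == "L5" else "d3"] = tip

    # initial segment + axon
    iseg = b.chain(0, (0, 0, -p.iseg_len_mm), Part.ISEG, p.iseg_diam_um, p.step_mm)
    lm["iseg"] = iseg
    z_b1 = -p.iseg_len_mm - axon_below
    if kind == "L5":
        b1 = b.chain(iseg, (0, 0, z_b1), Part.AXON, p.axon_diam_um, p.step_mm)
        lm["b1"] = b1
        b2 = b.chain(b1, (0.1, 0, z_b1 - 0.15), Part.AXON, p.axon_diam_um, p.step_mm)
        lm["b2"] = b2
        lm["terminal"] = b.chain(b2, (0.1 + p.axon_run_mm, 0, z_b1 - 0.15),
                                 Part.AXON, p.axon_diam_um, p.step_mm)
    else:
        midax = b.chain(iseg, (0, 0, -p.iseg_len_mm - 0.5 * axon_below),
                        Part.AXON, p.axon_diam_um, p.step_mm)
        lm["mid"] = midax
        lm["terminal"] = b.chain(midax, (0, 0, z_b1), Part.AXON, p.axon_diam_um, p.step_mm)
    lm.pop("_trunk_mid", None)
    m = b.done(lm)
    expect = L5_LANDMARKS if kind == "L5" else L3_LANDMARKS
    assert set(m.landmarks) == expect
    return m


# ---------------------------------------------------------------------------
# SWC I/O (standard 7-column records; type 5 is used for the initial segment)

def write_swc(m: Morphology, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent (mm, radius um/2 scaled to um)\n")
        for i in range(m.n_comp):
            x, y, z = m.pos[i]
            fh.write(
                f"{i + 1} {int(m.part[i])} {x:.9g} {y:.9g} {z:.9g} "
                f"{m.diam_um[i] / 2.0:.9g} {m.parent[i] + 1 if m.parent[i] >= 0 else -1}\n"
            )


def read_swc(path) -> Morphology:
    """Parse a 7-column SWC file (1 soma, 2 axon, 3 basal, 4 apical, 5 iseg)."""
    recs: dict[int, tuple] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if len(tok) != 7:
                raise ValueError(f"{path}: line {ln}: expected 7 columns, got {len(tok)}")
            try:
                sid, typ = int(tok[0]), int(tok[1])
                x, y, z, r = (float(t) for t in tok[2:6])
                par = int(tok[6])
            except ValueError as exc:
                raise ValueError(f"{path}: line {ln}: {exc}") from None
            recs[sid] = (typ, x, y, z, r, par, ln)
    if not recs:
        raise ValueError(f"{path}: no SWC records")
    order = sorted(recs)
    remap = {sid: i for i, sid in enumerate(order)}
    pos, parent, part, diam = [], [], [], []
    for sid in order:
        typ, x, y, z, r, par, ln = recs[sid]
        if par == -1:
            parent.append(-1)
        else:
            if par not in remap:
                raise ValueError(f"{path}: line {ln}: parent id {par} does not exist")
            pi = remap[par]
            if pi >= remap[sid]:
                raise ValueError(f"{path}: line {ln}: parent {par} does not precede sample {sid}")
            parent.append(pi)
        pos.append((x, y, z))
        part.append(typ if typ in set(int(p) for p in Part) else int(Part.BASAL))
        diam.append(2.0 * r)
    return Morphology(np.array(pos), np.array(parent), np.array(part), np.array(diam))


# ---------------------------------------------------------------------------
# placement

@dataclass
class PlacedNeuron:
    """A morphology transformed into grid coordinates."""

    morphology: Morphology
    kind: str
    surface_point: np.ndarray
    normal_out: np.ndarray
    depth_mm: float
    scale_factors: dict[str, float]

    def landmark_positions(self) -> dict[str, np.ndarray]:
        return {k: self.morphology.pos[i] for k, i in self.morphology.landmarks.items()}


DEPTH_FRACTION = {"L5": 0.75, "L3": 0.4}
LAYER1_FRACTION = 0.05  # apical tip target depth as a fraction of GM thickness


def _rotation_to(n_out: np.ndarray) -> np.ndarray:
    """Rotation matrix taking local +z onto the unit vector ``n_out``."""
    n = np.asarray(n_out, float)
    n = n / np.linalg.norm(n)
    ez = np.array([0.0, 0.0, 1.0])
    v = np.cross(ez, n)
    c = float(np.dot(ez, n))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def place_neuron(
    m: Morphology,
    kind: str,
    surface_point,
    normal_out,
    gm_thickness_mm: float,
    depth_fraction: float | None = None,
) -> PlacedNeuron:
    """Place a neuron perpendicular to the cortical surface.

    The soma goes to ``depth_fraction * gm_thickness`` below the CSF/GM
    surface along the inward normal; the apical extent is stretched so the
    tip reaches the layer-1 band; for L5 the descending axon is stretched
    so ``b1`` lands on the GM/WM boundary.
    """
    kind = kind.upper()
    frac = depth_fraction if depth_fraction is not None else DEPTH_FRACTION[kind]
    T = float(gm_thickness_mm)
    depth = frac * T
    if T <= depth * 0.999 or depth <= 0:
        raise ValueError(
            f"gray matter {T:.2f} mm too thin for soma depth {depth:.2f} mm"
        )
    out = m.copy()
    scales: dict[str, float] = {}

    apical = out.part == int(Part.APICAL)
    z_tip = out.pos[apical, 2].max()
    target_extent = (frac - LAYER1_FRACTION) * T
    s_ap = target_extent / z_tip
    out.pos[apical, 2] *= s_ap
    scales["apical"] = float(s_ap)

    if kind == "L5":
        b1 = out.landmarks["b1"]
        z_b1 = out.pos[b1, 2]
        z_i = out.pos[out.landmarks["iseg"], 2]
        target_b1 = -(T - depth)
        s_ax = (target_b1 - z_i) / (z_b1 - z_i)
        axon = out.part == int(Part.AXON)
        descend = axon & (np.arange(out.n_comp) <= b1)
        beyond = axon & (np.arange(out.n_comp) > b1)
        out.pos[descend, 2] = z_i + (out.pos[descend, 2] - z_i) * s_ax
        out.pos[beyond, 2] += target_b1 - z_b1
        scales["axon"] = float(s_ax)

    R = _rotation_to(normal_out)
    soma_global = np.asarray(surface_point, float) - np.asarray(normal_out, float) * depth
    out.pos = soma_global + out.pos @ R.T
    return PlacedNeuron(out, kind, np.asarray(surface_point, float),
                        np.asarray(normal_out, float), depth, scales)


@dataclass
class ROISpec:
    """Disc-shaped region of interest on the CSF/GM crown.

    ``spacing`` is the surface lattice pitch; 0.84 mm fills the default
    5 mm-radius disc with ~112 neurons, matching the reference population
    density.
    """

    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 5.0
    spacing: float = 0.84

    def __post_init__(self) -> None:
        if self.radius < 0 or self.spacing <= 0:
            raise ValueError("ROI radius must be >= 0 and spacing > 0")


def surface_columns(grid: LabeledGrid) -> dict[tuple[int, int], tuple[float, float]]:
    """Per (i, j) column: (surface z of the CSF/GM interface, GM thickness)."""
    gm = grid.labels == int(TissueLabel.GM)
    any_gm = gm.any(axis=2)
    h = grid.spec.spacing
    z0 = grid.spec.origin[2]
    out: dict[tuple[int, int], tuple[float, float]] = {}
    for i, j in zip(*np.where(any_gm)):
        kk = np.where(gm[i, j])[0]
        out[(int(i), int(j))] = (z0 + (kk.max() + 1) * h, len(kk) * h)
    return out


def populate_roi(
    grid: LabeledGrid,
    roi: ROISpec,
    kind: str,
    params: MorphParams | None = None,
    normals_lookup=None,
    depth_fraction: float | None = None,
) -> list[PlacedNeuron]:
    """Deterministic row-major lattice of placed neurons inside the ROI disc.

    ``normals_lookup`` maps a column index (i, j) to the outward cortical
    normal there; if omitted, normals are taken from the smoothed-label
    field (see :mod:`tchannel.metrics`).
    """
    from .metrics import column_normals

    template = build_pn(kind, params)
    cols = surface_columns(grid)
    if normals_lookup is None:
        normals_lookup = column_normals(grid)
    spec = grid.spec
    h = spec.spacing
    n_steps = int(np.floor(roi.radius / roi.spacing)) if roi.radius > 0 else 0
    placed: list[PlacedNeuron] = []
    for ix in range(-n_steps, n_steps + 1):
        for iy in range(-n_steps, n_steps + 1):
            dx, dy = ix * roi.spacing, iy * roi.spacing
            if dx * dx + dy * dy > roi.radius**2 + 1e-9:
                continue
            x = roi.center[0] + dx
            y = roi.center[1] + dy
            i = int(np.floor((x - spec.origin[0]) / h))
            j = int(np.floor((y - spec.origin[1]) / h))
            if (i, j) not in cols:
                continue
            z_surf, thick = cols[(i, j)]
            n_out = normals_lookup.get((i, j), np.array([0.0, 0.0, 1.0]))
            placed.append(
                place_neuron(template, kind, (x, y, z_surf), n_out, thick,
                             depth_fraction)
            )
    if not placed:
        raise ValueError("ROI produced zero neuron placements")
    return placed
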