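"""Shared fixtures.

The full-resolution sweeps are expensive (one conduction solve per
configuration), so they are computed once per session and shared by every
test that inspects them.
"""

from __future__ import annotations

import numpy as np
import pytest

import tchannel as tc
from tchannel.config import Scenario
from tchannel.pipeline import (
    build_population,
    diameter_sweep,
    displacement_sweep,
    run_sweep,
)


@pytest.fixture(scope="session")
def default_scenario() -> Scenario:
    return Scenario()


@pytest.fixture(scope="session")
def small_scenario() -> Scenario:
    """A coarse, laterally trimmed head for fast solver-level tests."""
    return Scenario(
        spacing=1.0,
        head=tc.HeadParams(lateral_extent=30.0, wm=4.0),
        montage=tc.MontageSpec(ring_radius=10.0, electrode_radius=2.0, gel_radius=2.0),
    )


@pytest.fixture(scope="session")
def roi_populations(default_scenario):
    """ROI neuron populations on the pristine default head (built once)."""
    spec = default_scenario.grid_spec()
    head_grid = tc.build_head_model(spec, default_scenario.head)
    return build_population(head_grid, default_scenario, ("L5", "L3"))


@pytest.fixture(scope="session")
def diameter_sweep_result(default_scenario, roi_populations):
    """Full channel experiment: NONE + I/T at shaft diameters 1..9 mm."""
    cfg = diameter_sweep(default_scenario)
    return run_sweep(cfg, populations=roi_populations)


@pytest.fixture(scope="session")
def displacement_sweep_result(default_scenario, roi_populations):
    """T-shaped 7 mm channel fixed on target; montage displaced 0..20 mm.

    The head is extended along x so the return ring stays on the scalp at
    the largest displacement.  The crown geometry is unchanged, so the
    ROI population built on the default head carries over verbatim.
    """
    base = Scenario(
        spacing=default_scenario.spacing,
        head=tc.HeadParams(lateral_extent=(132.0, 84.0)),
        channel=tc.ChannelSpec(shape="T", shaft_diameter=7.0),
        montage=default_scenario.montage,
    )
    cfg = displacement_sweep(base)
    return run_sweep(cfg, populations=roi_populations)


@pytest.fixture(scope="session")
def head_solution(default_scenario):
    """One full-resolution conduction solve (T7 channel) with its grid."""
    spec = default_scenario.grid_spec()
    g = tc.build_head_model(spec, default_scenario.head)
    g = tc.carve_channel(g, tc.ChannelSpec(shape="T", shaft_diameter=7.0))
    g, faces = tc.place_montage(g, default_scenario.montage)
    phi = tc.solve_potential(g, default_scenario.conductivity, faces,
                             default_scenario.solver)
    return g, faces, phi


# ---------------------------------------------------------------------------
# sphere-phantom oracle harness (independent closed form lives here)

SPHERE_RADIUS_MM = 20.0
SPHERE_SIGMA = 0.33
CAP_DEG = 14.0


def sphere_point_source_potential(p_eval_mm, p_src_mm, current_A, radius_mm, sigma):
    """Closed-form potential of a point current source on a conducting sphere.

    Interior solution of the insulated homogeneous sphere,
    ``V = I/(4 pi sigma R) * (2/g + ln(2/(1 - t cos(gamma) + g)))`` with
    ``t = r/R`` and ``g = sqrt(1 - 2 t cos(gamma) + t^2)`` (the constant
    n=0 term is irrelevant for potential differences).
    """
    p = np.atleast_2d(p_eval_mm)
    ps = np.asarray(p_src_mm, float)
    ps = ps / np.linalg.norm(ps) * radius_mm
    r = np.linalg.norm(p, axis=1)
    t = r / radius_mm
    cosg = (p @ ps) / (r * radius_mm)
    g = np.sqrt(np.maximum(1.0 - 2.0 * t * cosg + t * t, 0.0))
    R_m = radius_mm * 1e-3
    return current_A / (4 * np.pi * sigma * R_m) * (
        2.0 / g + np.log(2.0 / (1.0 - t * cosg + g))
    )


@pytest.fixture(scope="session")
def sphere_solution():
    """Homogeneous sphere with a polar source/sink electrode pair at 1 mm.

    Returns (grid, conductivity, phi, surface sample data) for the analytic
    comparisons.  Injection is spread over small polar caps and the analytic
    reference superposes the closed form over the actual injection nodes.
    """
    R = SPHERE_RADIUS_MM
    spec = tc.GridSpec(origin=(-22, -22, -22), spacing=1.0, shape=(44, 44, 44))
    g = tc.build_sphere_phantom(
        spec,
        tc.SphereParams(radii=(R,), layer_labels=(tc.TissueLabel.GM,), center=(0, 0, 0)),
    )
    cm = tc.ConductivityMap({tc.TissueLabel.GM: SPHERE_SIGMA})
    flat, pos = tc.outer_surface_nodes(g)
    r = np.linalg.norm(pos, axis=1)
    ang = np.arccos(np.clip(pos[:, 2] / r, -1, 1))
    cap = np.deg2rad(CAP_DEG)
    src = ang < cap
    snk = ang > np.pi - cap
    current = 1e-3
    source_nodes = np.concatenate([flat[src], flat[snk]])
    source_cur = np.concatenate(
        [np.full(src.sum(), current / src.sum()),
         np.full(snk.sum(), -current / snk.sum())]
    )
    pin = flat[np.argmin(np.abs(pos[:, 2]))]  # equator reference node
    bc = tc.BoundaryConditions(
        dirichlet_nodes=np.array([pin]),
        source_nodes=source_nodes,
        source_currents_A=source_cur,
    )
    phi = tc.solve_potential(g, cm, bc, tc.SolverConfig())
    return {
        "grid": g,
        "conductivity": cm,
        "phi": phi,
        "surface_flat": flat,
        "surface_pos": pos,
        "surface_ang": ang,
        "src_mask": src,
        "snk_mask": snk,
        "source_pos": np.concatenate([pos[src], pos[snk]]),
        "source_cur": source_cur,
        "cap_rad": cap,
    }
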