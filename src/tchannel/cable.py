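"""Steady-state sub-threshold membrane polarization of compartmental neurons.

For weak extracellular fields the sub-threshold response of a passive
cable is linear, so the steady-state transmembrane deviation ``v`` (mV,
depolarization positive) solves

    (G_axial + G_membrane) v = -G_axial e

where ``e`` is the extracellular potential at the compartment centers
(mV), ``G_axial`` is the tree Laplacian of axial conductances (series
half-compartment resistances, ``R = 4 R_a l / (pi d^2)`` per half), and
``G_membrane`` is diagonal with ``pi d l / R_m``.  Sealed ends are the
natural boundary condition of the tree Laplacian.  Only spatial *gradients*
of ``e`` polarize the membrane: a constant offset is annihilated by
``G_axial``.

A backward-Euler time integrator is included for verification; at 10
membrane time constants it reproduces the linear steady state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .morphology import Morphology, Part, PlacedNeuron


@dataclass
class MembraneParams:
    """Passive membrane constants (neuroscience CGS conventions).

    ``r_m``: specific membrane resistance, Ohm cm^2; ``r_a``: axial
    resistivity, Ohm cm; ``c_m``: specific capacitance, uF/cm^2 (only used
    by the time-domain mode).  ``part_r_m`` optionally overrides ``r_m``
    per compartment part (e.g. a leakier initial segment).
    """

    r_m: float = 30000.0
    r_a: float = 150.0
    c_m: float = 0.75
    part_r_m: dict[Part, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.r_m <= 0 or self.r_a <= 0 or self.c_m <= 0:
            raise ValueError("membrane parameters must be > 0")

    def lambda_mm(self, diam_um: np.ndarray | float) -> np.ndarray | float:
        """Length constant sqrt(d r_m / (4 r_a)) in mm."""
        d_cm = np.asarray(diam_um, float) * 1e-4
        return 10.0 * np.sqrt(d_cm * self.r_m / (4.0 * self.r_a))

    def tau_s(self) -> float:
        return self.r_m * self.c_m * 1e-6


@dataclass
class PolarizationProfile:
    """Per-compartment steady-state transmembrane deviation, mV."""

    morphology: Morphology
    dv_mV: np.ndarray

    def landmark_values(self) -> dict[str, float]:
        return {k: float(self.dv_mV[i]) for k, i in self.morphology.landmarks.items()}

    @property
    def soma_mV(self) -> float:
        return float(self.dv_mV[self.morphology.landmarks.get("soma", 0)])


@dataclass
class CouplingResult:
    """Somatic coupling constant: soma polarization per unit local field.

    ``k_mm = dV_soma (mV) / E_local (mV/mm)``; note 1 mV/mm = 1 V/m, so the
    field magnitude can be passed in V/m unchanged.
    """

    k_mm: float
    local_E_V_per_m: float


def refine(m: Morphology, params: MembraneParams, max_frac: float = 0.1) -> Morphology:
    """Subdivide compartments to l <= max_frac * lambda(d).

    Landmarks are remapped onto the preserved segment endpoints.
    """
    lam = np.asarray(params.lambda_mm(m.diam_um), float)
    pos = [m.pos[0]]
    parent = [-1]
    part = [int(m.part[0])]
    diam = [m.diam_um[0]]
    newidx = {0: 0}
    for i in range(1, m.n_comp):
        p0 = m.pos[m.parent[i]]
        p1 = m.pos[i]
        length = float(np.linalg.norm(p1 - p0))
        nseg = max(1, int(np.ceil(length / (max_frac * lam[i]))))
        prev = newidx[int(m.parent[i])]
        for s in range(1, nseg + 1):
            pos.append(p0 + (p1 - p0) * (s / nseg))
            parent.append(prev)
            part.append(int(m.part[i]))
            diam.append(m.diam_um[i])
            prev = len(pos) - 1
        newidx[i] = prev
    lms = {k: newidx[v] for k, v in m.landmarks.items()}
    return Morphology(np.array(pos), np.array(parent), np.array(part),
                      np.array(diam), lms)


def _conductances(m: Morphology, p: MembraneParams):
    """(G_axial tree Laplacian, g_membrane diagonal), both in siemens."""
    l_cm = m.lengths_mm() * 0.1
    d_cm = m.diam_um * 1e-4
    area = np.pi * d_cm * l_cm
    rm = np.array([p.part_r_m.get(Part(t), p.r_m) for t in m.part])
    g_m = area / rm

    child = np.arange(1, m.n_comp)
    par = m.parent[child]
    half = lambda i: (l_cm[i] / 2.0) * 4.0 * p.r_a / (np.pi * d_cm[i] ** 2)
    g_ax = 1.0 / (half(child) + half(par))

    n = m.n_comp
    rows = np.concatenate([child, par, child, par])
    cols = np.concatenate([child, par, par, child])
    vals = np.concatenate([g_ax, g_ax, -g_ax, -g_ax])
    L = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return L, g_m


def steady_state_polarization(
    neuron: Morphology | PlacedNeuron,
    e_mV: np.ndarray,
    params: MembraneParams | None = None,
) -> PolarizationProfile:
    """Solve the passive steady-state compartmental system.

    ``e_mV`` holds the extracellular potential at each compartment center
    (one value per compartment, mV).  Sealed ends; direct sparse solve.
    """
    m = neuron.morphology if isinstance(neuron, PlacedNeuron) else neuron
    p = params or MembraneParams()
    e = np.asarray(e_mV, float)
    if e.shape != (m.n_comp,):
        raise ValueError(f"need {m.n_comp} extracellular values, got {e.shape}")
    L, g_m = _conductances(m, p)
    A = (L + sp.diags(g_m)).tocsc()
    rhs = -(L @ e)
    dv = spla.spsolve(A, rhs)
    if not np.all(np.isfinite(dv)):
        raise RuntimeError("singular compartmental system (disconnected tree?)")
    return PolarizationProfile(m, dv)


def uniform_field_polarization(
    neuron: Morphology | PlacedNeuron,
    E_V_per_m,
    params: MembraneParams | None = None,
) -> PolarizationProfile:
    """Polarization under a spatially uniform field E (V/m).

    Synthesizes ``e = -E . x`` at the compartment centers; with x in mm and
    E in V/m the product is directly in mV.
    """
    m = neuron.morphology if isinstance(neuron, PlacedNeuron) else neuron
    e_mV = -(m.centers_mm() @ np.asarray(E_V_per_m, float))
    return steady_state_polarization(m, e_mV, params)


def time_domain_polarization(
    neuron: Morphology | PlacedNeuron,
    e_mV: np.ndarray,
    params: MembraneParams | None = None,
    n_tau: float = 10.0,
    steps_per_tau: int = 50,
) -> PolarizationProfile:
    """Backward-Euler integration from rest; verification mode only.

    Integrates ``C dv/dt = -(G_ax + G_m) v - G_ax e`` for ``n_tau``
    membrane time constants and returns the final state.
    """
    m = neuron.morphology if isinstance(neuron, PlacedNeuron) else neuron
    p = params or MembraneParams()
    e = np.asarray(e_mV, float)
    L, g_m = _conductances(m, p)
    l_cm = m.lengths_mm() * 0.1
    d_cm = m.diam_um * 1e-4
    C = p.c_m * 1e-6 * np.pi * d_cm * l_cm  # farads
    tau = p.tau_s()
    dt = tau / steps_per_tau
    A = (sp.diags(C / dt) + L + sp.diags(g_m)).tocsc()
    lu = spla.splu(A)
    drive = -(L @ e)
    v = np.zeros(m.n_comp)
    for _ in range(int(n_tau * steps_per_tau)):
        v = lu.solve(C / dt * v + drive)
    return PolarizationProfile(m, v)


def coupling_constant(profile: PolarizationProfile, local_E_V_per_m: float) -> CouplingResult:
    """Somatic coupling constant k (mm) = soma dV (mV) / local field (mV/mm)."""
    if local_E_V_per_m <= 0:
        raise ValueError("local field magnitude must be > 0")
    return CouplingResult(
        k_mm=profile.soma_mV / local_E_V_per_m,
        local_E_V_per_m=float(local_E_V_per_m),
    )


def coupling_summary(results: list[CouplingResult]) -> tuple[float, float]:
    """Population mean and SD of the coupling constant."""
    ks = np.array([r.k_mm for r in results])
    return float(ks.mean()), float(ks.std(ddof=1)) if len(ks) > 1 else 0.0
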