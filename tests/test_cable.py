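"""Passive cable solver: closed forms, superposition, morphology effects."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tchannel as tc
from tchannel.cable import (
    MembraneParams,
    coupling_constant,
    refine,
    steady_state_polarization,
    time_domain_polarization,
    uniform_field_polarization,
)
from tchannel.morphology import Morphology, Part


def symmetric_fiber(diam_um=2.0, length_mm=1.0, nseg_per_arm=100):
    """Uniform straight fiber along x with the root at its midpoint."""
    arm = (length_mm - diam_um * 1e-3) / 2
    pos = [np.zeros(3)]
    parent = [-1]
    part = [int(Part.SOMA)]
    diam = [diam_um]
    for sgn in (1, -1):
        prev = 0
        for s in range(1, nseg_per_arm + 1):
            x = sgn * (diam_um * 1e-3 / 2 + arm * s / nseg_per_arm)
            pos.append(np.array([x, 0.0, 0.0]))
            parent.append(prev)
            part.append(int(Part.AXON))
            diam.append(diam_um)
            prev = len(pos) - 1
    return Morphology(np.array(pos), np.array(parent), np.array(part),
                      np.array(diam), {"soma": 0})


def random_tree(rng, n):
    """Random branching passive tree with mm-scale segments."""
    pos = [np.zeros(3)]
    parent = [-1]
    part = [int(Part.SOMA)]
    diam = [rng.uniform(5, 20)]
    for i in range(1, n):
        p = int(rng.integers(0, i))
        step = rng.normal(scale=0.05, size=3)
        pos.append(pos[p] + step)
        parent.append(p)
        part.append(int(rng.choice([2, 3, 4])))
        diam.append(rng.uniform(0.5, 4.0))
    return Morphology(np.array(pos), np.array(parent), np.array(part),
                      np.array(diam), {"soma": 0})


def dense_steady_state(m, e_mV, p):
    """Independent dense-matrix reference solve of the same physics."""
    n = m.n_comp
    l_cm = m.lengths_mm() * 0.1
    d_cm = m.diam_um * 1e-4
    G = np.zeros((n, n))
    for i in range(1, n):
        j = m.parent[i]
        r = (l_cm[i] / 2) * 4 * p.r_a / (np.pi * d_cm[i] ** 2) \
            + (l_cm[j] / 2) * 4 * p.r_a / (np.pi * d_cm[j] ** 2)
        g = 1.0 / r
        G[i, i] += g
        G[j, j] += g
        G[i, j] -= g
        G[j, i] -= g
    rhs = -G @ np.asarray(e_mV)
    G_m = np.diag(np.pi * d_cm * l_cm / p.r_m)
    return np.linalg.solve(G + G_m, rhs)


class TestSteadyState:
    def test_constant_extracellular_potential_gives_zero(self):
        m = tc.build_pn("L5")
        prof = steady_state_polarization(m, np.full(m.n_comp, 42.0))
        assert np.allclose(prof.dv_mV, 0.0, atol=1e-9)

    def test_zero_drive_gives_zero(self):
        m = tc.build_pn("L3")
        prof = steady_state_polarization(m, np.zeros(m.n_comp))
        assert np.allclose(prof.dv_mV, 0.0)

    def test_sealed_end_fiber_matches_cable_closed_form(self):
        # end polarization E*lambda*tanh(L/2 lambda); midpoint exactly zero
        d, L = 2.0, 1.0
        p = MembraneParams()
        lam = float(p.lambda_mm(d))
        m = symmetric_fiber(d, L, nseg_per_arm=100)  # 201 compartments
        prof = uniform_field_polarization(m, (1.0, 0.0, 0.0), p)
        x = m.centers_mm()[:, 0]
        v_end = prof.dv_mV[np.argmax(x)]
        exact = 1.0 * lam * np.tanh(L / (2 * lam))
        assert v_end == pytest.approx(exact, rel=0.01)
        assert abs(prof.dv_mV[0]) < 1e-9  # midpoint (root) compartment

    def test_fiber_polarization_is_antisymmetric(self):
        m = symmetric_fiber()
        prof = uniform_field_polarization(m, (2.0, 0.0, 0.0))
        x = m.centers_mm()[:, 0]
        order = np.argsort(x)
        v = prof.dv_mV[order]
        assert np.allclose(v, -v[::-1], atol=1e-9)

    def test_wrong_drive_length_raises(self):
        m = tc.build_pn("L3")
        with pytest.raises(ValueError, match="extracellular"):
            steady_state_polarization(m, np.zeros(3))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_sparse_solve_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        m = random_tree(rng, n)
        e = rng.normal(scale=5.0, size=n)
        p = MembraneParams()
        sparse = steady_state_polarization(m, e, p).dv_mV
        dense = dense_steady_state(m, e, p)
        scale = max(np.abs(dense).max(), 1e-12)
        assert np.abs(sparse - dense).max() / scale < 1e-10

    @settings(max_examples=10, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_superposition_in_extracellular_drive(self, seed):
        rng = np.random.default_rng(seed)
        m = random_tree(rng, int(rng.integers(5, 40)))
        e1 = rng.normal(size=m.n_comp)
        e2 = rng.normal(size=m.n_comp)
        p = MembraneParams()
        v1 = steady_state_polarization(m, e1, p).dv_mV
        v2 = steady_state_polarization(m, e2, p).dv_mV
        v12 = steady_state_polarization(m, e1 + 2.0 * e2, p).dv_mV
        assert np.allclose(v12, v1 + 2.0 * v2, atol=1e-12)


class TestUniformField:
    def test_zero_field_gives_zero_profile(self):
        m = tc.build_pn("L5")
        prof = uniform_field_polarization(m, (0.0, 0.0, 0.0))
        assert np.allclose(prof.dv_mV, 0.0)

    def test_inward_field_hyperpolarizes_apex_depolarizes_soma(self):
        # inward = toward the white matter = -z in the local frame
        m = refine(tc.build_pn("L5"), MembraneParams())
        prof = uniform_field_polarization(m, (0.0, 0.0, -1.0))
        lv = prof.landmark_values()
        assert lv["d2"] < 0           # apical tip hyperpolarized
        assert lv["soma"] > 0         # soma depolarized
        assert lv["iseg"] > 0

    def test_soma_diameter_increase_reduces_somatic_polarization(self):
        p = MembraneParams()
        vals = []
        for d in (10.0, 20.0, 30.0, 40.0):
            m = refine(tc.build_pn("L5", tc.MorphParams(soma_diam_um=d)), p)
            prof = uniform_field_polarization(m, (0.0, 0.0, -1.0), p)
            vals.append(abs(prof.soma_mV))
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_flat_thick_trunk_variant_boosts_somatic_depolarization(self):
        # the alternative L5 cells are vertically compressed but carry a
        # thicker apical trunk; the variant must be flatter yet more
        # strongly depolarized at the soma than the default tall cell
        from tchannel.morphology import type23_variant

        p = MembraneParams()
        tall = refine(tc.build_pn("L5"), p)
        flat = refine(tc.build_pn("L5", type23_variant()), p)
        tip = lambda m: m.pos[m.landmarks["d2"], 2]  # noqa: E731
        assert tip(flat) < tip(tall)
        v_tall = uniform_field_polarization(tall, (0, 0, -1.0), p).soma_mV
        v_flat = uniform_field_polarization(flat, (0, 0, -1.0), p).soma_mV
        assert v_flat > v_tall > 0

    def test_pure_compression_alone_reduces_polarization(self):
        # scaling law: compressing a passive cable along the field shrinks
        # the extracellular drive while lambda is unchanged
        p = MembraneParams()
        tall = refine(tc.build_pn("L5", tc.MorphParams(flatness=1.0)), p)
        flat = refine(tc.build_pn("L5", tc.MorphParams(flatness=0.5)), p)
        v_tall = uniform_field_polarization(tall, (0, 0, -1.0), p).soma_mV
        v_flat = uniform_field_polarization(flat, (0, 0, -1.0), p).soma_mV
        assert 0 < v_flat < v_tall


class TestTimeDomain:
    def test_backward_euler_reaches_steady_state(self):
        m = symmetric_fiber(nseg_per_arm=30)
        p = MembraneParams()
        e = -(m.centers_mm() @ np.array([1.0, 0, 0]))
        ss = steady_state_polarization(m, e, p).dv_mV
        td = time_domain_polarization(m, e, p, n_tau=10.0).dv_mV
        denom = np.abs(ss).max()
        assert np.abs(td - ss).max() / denom < 1e-3


class TestCoupling:
    def test_definitional_unit_check(self):
        m = tc.build_pn("L3")
        prof = steady_state_polarization(m, np.zeros(m.n_comp))
        prof.dv_mV[m.landmarks["soma"]] = 0.0784
        assert coupling_constant(prof, 1.0).k_mm == pytest.approx(0.0784)

    def test_zero_polarization_gives_zero_constant(self):
        m = tc.build_pn("L3")
        prof = steady_state_polarization(m, np.zeros(m.n_comp))
        assert coupling_constant(prof, 2.5).k_mm == 0.0

    def test_scale_invariance(self):
        m = refine(tc.build_pn("L5"), MembraneParams())
        p1 = uniform_field_polarization(m, (0, 0, -1.0))
        p2 = uniform_field_polarization(m, (0, 0, -2.0))
        k1 = coupling_constant(p1, 1.0).k_mm
        k2 = coupling_constant(p2, 2.0).k_mm
        assert k1 == pytest.approx(k2, rel=1e-9)

    def test_zero_field_rejected(self):
        m = tc.build_pn("L3")
        prof = steady_state_polarization(m, np.zeros(m.n_comp))
        with pytest.raises(ValueError):
            coupling_constant(prof, 0.0)


class TestRefine:
    def test_segments_below_tenth_of_length_constant(self):
        p = MembraneParams()
        m = refine(tc.build_pn("L5"), p)
        lam = np.asarray(p.lambda_mm(m.diam_um))
        lengths = m.lengths_mm()
        assert np.all(lengths[1:] <= 0.1 * lam[1:] + 1e-9)

    def test_landmarks_survive_refinement(self):
        m = tc.build_pn("L5")
        r = refine(m, MembraneParams())
        for name, idx in m.landmarks.items():
            assert np.allclose(r.pos[r.landmarks[name]], m.pos[idx], atol=1e-12)
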