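"""Parametric morphologies, SWC round-trips, cortical placement, ROI lattice."""

import numpy as np
import pytest

import tchannel as tc
from tchannel.grid import TissueLabel
from tchannel.morphology import (
    L3_LANDMARKS,
    L5_LANDMARKS,
    Part,
    ROISpec,
    place_neuron,
    populate_roi,
    surface_columns,
)


class TestBuildPn:
    @pytest.mark.parametrize("kind,expected", [("L5", L5_LANDMARKS),
                                               ("L3", L3_LANDMARKS)])
    def test_landmark_sets(self, kind, expected):
        m = tc.build_pn(kind)
        assert set(m.landmarks) == set(expected)

    @pytest.mark.parametrize("kind", ["L5", "L3"])
    def test_is_a_tree(self, kind):
        m = tc.build_pn(kind)
        assert np.count_nonzero(m.parent == -1) == 1
        assert np.count_nonzero(m.parent >= 0) == m.n_comp - 1
        assert np.all(m.parent[1:] < np.arange(1, m.n_comp))

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError, match="kind"):
            tc.build_pn("L9")

    def test_apical_tip_is_d2_and_above_soma(self):
        m = tc.build_pn("L5")
        apical_z = m.pos[m.part == int(Part.APICAL), 2]
        assert m.pos[m.landmarks["d2"], 2] == pytest.approx(apical_z.max())

    def test_flatness_compresses_apical_extent(self):
        tall = tc.build_pn("L5", tc.MorphParams(flatness=1.0))
        flat = tc.build_pn("L5", tc.MorphParams(flatness=0.5))
        assert flat.pos[flat.landmarks["d2"], 2] == pytest.approx(
            0.5 * tall.pos[tall.landmarks["d2"], 2])


class TestSwcIO:
    def test_minimal_three_point_file(self, tmp_path):
        p = tmp_path / "tiny.swc"
        p.write_text(
            "# comment\n"
            "1 1 0 0 0 5 -1\n"
            "2 3 1 0 0 1 1\n"
            "3 4 0 0 1 1 1\n"
        )
        m = tc.read_swc(p)
        assert m.n_comp == 3
        assert list(m.parent) == [-1, 0, 0]
        assert m.diam_um[0] == 10.0
        assert int(m.part[2]) == int(Part.APICAL)

    @pytest.mark.parametrize("kind", ["L5", "L3"])
    def test_round_trip_preserves_landmark_coordinates(self, kind, tmp_path):
        m = tc.build_pn(kind)
        path = tmp_path / "pn.swc"
        tc.write_swc(m, path)
        back = tc.read_swc(path)
        assert back.n_comp == m.n_comp
        for name, idx in m.landmarks.items():
            assert np.allclose(back.pos[idx], m.pos[idx], atol=1e-6), name
        assert np.array_equal(back.part, m.part)

    def test_missing_parent_reports_line(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 1 0 0 1 9\n")
        with pytest.raises(ValueError, match="line 2"):
            tc.read_swc(p)

    def test_wrong_column_count_reports_line(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5\n")
        with pytest.raises(ValueError, match="line 1"):
            tc.read_swc(p)


class TestPlacement:
    def test_flat_placement_is_translation_plus_scaling(self):
        m = tc.build_pn("L5")
        pn = place_neuron(m, "L5", (1.0, 2.0, 10.0), (0, 0, 1.0), 2.5)
        # x/y coordinates are rigidly translated (no rotation about z)
        assert np.allclose(pn.morphology.pos[:, 0] - 1.0, m.pos[:, 0], atol=1e-9)
        assert np.allclose(pn.morphology.pos[:, 1] - 2.0, m.pos[:, 1], atol=1e-9)
        assert pn.depth_mm == pytest.approx(0.75 * 2.5)
        assert "apical" in pn.scale_factors and "axon" in pn.scale_factors

    def test_apical_tip_reaches_layer_one_band(self):
        pn = place_neuron(tc.build_pn("L5"), "L5", (0, 0, 10.0), (0, 0, 1.0), 2.5)
        tip_depth = 10.0 - pn.morphology.pos[pn.morphology.landmarks["d2"], 2]
        assert tip_depth <= 0.1 * 2.5 + 1e-9  # within the top 10% of GM

    def test_l5_b1_lands_on_gm_wm_boundary(self, default_scenario):
        spec = default_scenario.grid_spec()
        g = tc.build_head_model(spec, default_scenario.head)
        cols = surface_columns(g)
        (i, j) = min(cols, key=lambda ij: abs(spec.axis_cell_centers(0)[ij[0]])
                     + abs(spec.axis_cell_centers(1)[ij[1]]))
        z_surf, thick = cols[(i, j)]
        pn = place_neuron(tc.build_pn("L5"), "L5",
                          (spec.axis_cell_centers(0)[i],
                           spec.axis_cell_centers(1)[j], z_surf),
                          (0, 0, 1.0), thick)
        b1 = pn.morphology.pos[pn.morphology.landmarks["b1"]]
        gm_wm_z = z_surf - thick
        assert abs(b1[2] - gm_wm_z) <= spec.spacing

    def test_l3_stays_inside_gray_matter(self, default_scenario):
        spec = default_scenario.grid_spec()
        g = tc.build_head_model(spec, default_scenario.head)
        cols = surface_columns(g)
        (i, j) = min(cols, key=lambda ij: abs(spec.axis_cell_centers(0)[ij[0]])
                     + abs(spec.axis_cell_centers(1)[ij[1]]))
        z_surf, thick = cols[(i, j)]
        pn = place_neuron(tc.build_pn("L3"), "L3",
                          (spec.axis_cell_centers(0)[i],
                           spec.axis_cell_centers(1)[j], z_surf),
                          (0, 0, 1.0), thick)
        h = spec.spacing
        for pos in pn.morphology.pos:
            idx = np.floor((pos - np.asarray(spec.origin)) / h).astype(int)
            assert g.labels[tuple(idx)] == int(TissueLabel.GM)

    def test_too_thin_cortex_raises(self):
        with pytest.raises(ValueError, match="thin"):
            place_neuron(tc.build_pn("L5"), "L5", (0, 0, 10.0), (0, 0, 1.0), 0.0)


class TestPopulateRoi:
    def test_default_lattice_holds_about_112_neurons(self, roi_populations):
        # 0.84 mm pitch on the 5 mm disc emulates the reference density
        for kind in ("L5", "L3"):
            assert len(roi_populations[kind]) == pytest.approx(112, rel=0.05)

    def test_zero_radius_places_single_neuron(self, default_scenario):
        spec = default_scenario.grid_spec()
        g = tc.build_head_model(spec, default_scenario.head)
        placed = populate_roi(g, ROISpec(radius=0.0), "L3")
        assert len(placed) == 1
        assert np.allclose(placed[0].surface_point[:2], 0.0)

    def test_doubling_spacing_reduces_count(self, default_scenario):
        spec = default_scenario.grid_spec()
        g = tc.build_head_model(spec, default_scenario.head)
        a = populate_roi(g, ROISpec(spacing=1.2), "L3")
        b = populate_roi(g, ROISpec(spacing=2.4), "L3")
        assert len(b) < len(a)

    def test_deterministic_ordering(self, default_scenario):
        spec = default_scenario.grid_spec()
        g = tc.build_head_model(spec, default_scenario.head)
        a = populate_roi(g, ROISpec(spacing=1.5), "L5")
        b = populate_roi(g, ROISpec(spacing=1.5), "L5")
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.morphology.pos, pb.morphology.pos)
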