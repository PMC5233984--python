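"""Synthetic head, sphere phantom, channel carving, montage placement."""

import numpy as np
import pytest

import tchannel as tc
from tchannel.geometry import ConfigurationError, head_interfaces


def small_head(spacing=0.5, **kw):
    head = tc.HeadParams(lateral_extent=20.0, wm=3.0, **kw)
    return head, tc.default_grid(head, spacing)


class TestGridSpec:
    def test_rejects_bad_spacing_and_shape(self):
        with pytest.raises(ValueError):
            tc.GridSpec(origin=(0, 0, 0), spacing=0.0, shape=(4, 4, 4))
        with pytest.raises(ValueError):
            tc.GridSpec(origin=(0, 0, 0), spacing=0.5, shape=(4, 1, 4))

    def test_cell_centers_half_open_convention(self):
        spec = tc.GridSpec(origin=(1.0, 0, 0), spacing=0.5, shape=(4, 2, 2))
        assert spec.axis_cell_centers(0)[0] == pytest.approx(1.25)
        assert spec.axis_nodes(0)[-1] == pytest.approx(3.0)


class TestHeadModel:
    def test_dura_layer_is_half_millimetre_at_crown(self):
        head, spec = small_head()
        g = tc.build_head_model(spec, head)
        i = g.labels.shape[0] // 2
        col = g.labels[i, g.labels.shape[1] // 2, :]
        n_dura = np.count_nonzero(col == int(tc.TissueLabel.DURA))
        assert n_dura * spec.spacing == pytest.approx(0.5)

    def test_zero_amplitude_gives_flat_slabs(self):
        head, spec = small_head(fold_amplitude=0.0)
        g = tc.build_head_model(spec, head)
        gm = g.labels == int(tc.TissueLabel.GM)
        # GM occupancy is identical in every column: a flat slab
        ref = gm[0, 0, :]
        assert np.all(gm == ref[None, None, :])

    def test_every_cell_labelled_partition(self):
        head, spec = small_head()
        g = tc.build_head_model(spec, head)
        counts = sum(g.count(lab) for lab in tc.TissueLabel)
        assert counts == spec.n_cells

    def test_layers_exceeding_grid_name_the_layer(self):
        head = tc.HeadParams(lateral_extent=20.0, wm=50.0)
        spec = tc.GridSpec(origin=(-10, -10, 0), spacing=0.5, shape=(40, 40, 80))
        with pytest.raises(ConfigurationError, match="wm"):
            tc.build_head_model(spec, head)

    def test_crown_apex_is_under_origin(self):
        head, spec = small_head()
        g = tc.build_head_model(spec, head)
        gm = g.labels == int(tc.TissueLabel.GM)
        top_k = np.array([
            np.max(np.where(gm[i, gm.shape[1] // 2])[0]) if gm[i, gm.shape[1] // 2].any() else -1
            for i in range(gm.shape[0])
        ])
        xc = spec.axis_cell_centers(0)
        assert abs(xc[np.argmax(top_k)]) <= head.fold_wavelength / 4

    def test_labeling_is_deterministic(self):
        head, spec = small_head()
        a = tc.build_head_model(spec, head)
        b = tc.build_head_model(spec, head)
        assert np.array_equal(a.labels, b.labels)


class TestSpherePhantom:
    def test_homogeneous_single_layer(self):
        spec = tc.GridSpec(origin=(-6, -6, -6), spacing=1.0, shape=(12, 12, 12))
        g = tc.build_sphere_phantom(
            spec, tc.SphereParams(radii=(5.0,), layer_labels=(tc.TissueLabel.GM,))
        )
        assert g.count(tc.TissueLabel.GM) > 0
        assert set(np.unique(g.labels)) == {0, int(tc.TissueLabel.GM)}

    def test_shell_volumes_match_analytic(self):
        radii = (20.0, 16.0, 14.0, 10.0)
        labels = (tc.TissueLabel.SCALP, tc.TissueLabel.SKULL,
                  tc.TissueLabel.CSF, tc.TissueLabel.GM)
        spec = tc.GridSpec(origin=(-22, -22, -22), spacing=1.0, shape=(44, 44, 44))
        g = tc.build_sphere_phantom(spec, tc.SphereParams(radii=radii, layer_labels=labels))
        bounds = list(radii) + [0.0]
        for lab, r_out, r_in in zip(labels, bounds[:-1], bounds[1:]):
            vol = g.count(lab) * spec.cell_volume_mm3()
            exact = 4 * np.pi / 3 * (r_out**3 - r_in**3)
            assert vol == pytest.approx(exact, rel=0.05)

    def test_radius_exceeding_grid_raises(self):
        spec = tc.GridSpec(origin=(-5, -5, -5), spacing=1.0, shape=(10, 10, 10))
        with pytest.raises(ConfigurationError):
            tc.build_sphere_phantom(
                spec, tc.SphereParams(radii=(9.0,), layer_labels=(tc.TissueLabel.GM,))
            )

    def test_non_decreasing_radii_rejected(self):
        with pytest.raises(ConfigurationError):
            tc.SphereParams(radii=(5.0, 5.0),
                            layer_labels=(tc.TissueLabel.CSF, tc.TissueLabel.GM))


class TestChannel:
    def test_hat_diameter_default_is_shaft_plus_one(self):
        assert tc.ChannelSpec(shape="T", shaft_diameter=7.0).hat_diameter == 8.0

    def test_i_shape_spans_full_skull_thickness(self):
        head, spec = small_head()
        g = tc.build_head_model(spec, head)
        out = tc.carve_channel(g, tc.ChannelSpec(shape="I", shaft_diameter=7.0))
        skull_k = np.where((g.labels == int(tc.TissueLabel.SKULL)).any(axis=(0, 1)))[0]
        chan = out.labels == int(tc.TissueLabel.CHANNEL)
        assert chan[:, :, skull_k.min()].any() and chan[:, :, skull_k.max()].any()

    def test_none_shape_returns_input_unchanged(self):
        head, spec = small_head()
        g = tc.build_head_model(spec, head)
        out = tc.carve_channel(g, tc.ChannelSpec(shape="NONE"))
        assert np.array_equal(out.labels, g.labels)

    @pytest.mark.parametrize("shape", ["I", "T"])
    def test_carving_confined_to_skull_and_conserves_cells(self, shape):
        head, spec = small_head()
        g = tc.build_head_model(spec, head)
        out = tc.carve_channel(g, tc.ChannelSpec(shape=shape, shaft_diameter=5.0))
        changed = out.labels != g.labels
        assert np.all(g.labels[changed] == int(tc.TissueLabel.SKULL))
        assert np.all(out.labels[changed] == int(tc.TissueLabel.CHANNEL))
        before = g.count(tc.TissueLabel.SKULL)
        after = out.count(tc.TissueLabel.SKULL) + out.count(tc.TissueLabel.CHANNEL)
        assert before == after

    def test_axis_missing_skull_raises(self):
        head, spec = small_head()
        g = tc.build_head_model(spec, head)
        with pytest.raises(ConfigurationError, match="skull"):
            tc.carve_channel(g, tc.ChannelSpec(shape="I", shaft_diameter=1.0,
                                               axis=(500.0, 0.0)))


class TestMontage:
    def montage(self, **kw):
        return tc.MontageSpec(ring_radius=6.0, electrode_radius=1.5,
                              gel_radius=1.5, **kw)

    def test_five_assemblies_with_standard_dimensions(self):
        head, spec = small_head()
        g = tc.build_head_model(spec, head)
        out, faces = tc.place_montage(g, self.montage())
        h = spec.spacing
        n_el_cells = out.count(tc.TissueLabel.ELECTRODE)
        n_gel_cells = out.count(tc.TissueLabel.GEL)
        footprint = np.count_nonzero(
            (spec.axis_cell_centers(0)[:, None] ** 2
             + spec.axis_cell_centers(1)[None, :] ** 2) <= 1.5**2
        )
        assert n_el_cells == 5 * footprint * round(1.0 / h)   # 1 mm tall discs
        assert n_gel_cells == 5 * footprint * round(2.0 / h)  # on 2 mm gel

    def test_zero_displacement_centroid_on_axis(self):
        head, spec = small_head()
        g = tc.build_head_model(spec, head)
        _, faces = tc.place_montage(g, self.montage())
        cx, cy, _ = faces.active_centroid(spec)
        assert abs(cx) < 1e-9 and abs(cy) < 1e-9

    def test_displacement_shifts_centroid_rigidly(self):
        head, spec = small_head()
        g = tc.build_head_model(spec, head)
        _, f0 = tc.place_montage(g, self.montage())
        _, f5 = tc.place_montage(g, self.montage(displacement=(2.0, 0.0)))
        d = f5.active_centroid(spec) - f0.active_centroid(spec)
        assert d[0] == pytest.approx(2.0, abs=1e-9)
        assert d[1] == pytest.approx(0.0, abs=1e-9)
        assert d[2] == pytest.approx(0.0, abs=1e-9)

    def test_off_grid_footprint_raises(self):
        head, spec = small_head()
        g = tc.build_head_model(spec, head)
        with pytest.raises(ConfigurationError, match="footprint"):
            tc.place_montage(g, self.montage(center=(100.0, 0.0)))
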