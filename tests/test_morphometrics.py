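"""Layer occupancy, proximal statistics, radial traces, curvature."""

import numpy as np
import pytest
from scipy import ndimage

import tomolink as tl
from tomolink.morphometrics import RadialTrace


def build_membrane_vesicle(gap_nm, voxel=3.2, shape=(48, 32, 32), radius_nm=20.0):
    """Flat membrane slab (label 1) plus one spherical vesicle (label 2)
    whose surface sits gap_nm above the slab."""
    data = np.zeros(shape, np.float32)
    labels = np.zeros(shape, np.int32)
    n_slab = 2
    labels[:n_slab] = 1
    top = n_slab * voxel
    center = np.array([top + gap_nm + radius_nm,
                       shape[1] * voxel / 2, shape[2] * voxel / 2])
    mask = tl.render_sphere_shell(center, 0, radius_nm, -2.0, data, voxel)
    labels[mask] = 2
    catalog = {1: tl.Boundary(1, "plasma_membrane"),
               2: tl.Boundary(2, "vesicle", center, radius_nm, "sv")}
    return tl.LabelVolume(labels, catalog, voxel), center


class TestLayerOccupancy:
    def test_no_vesicles_zero_everywhere(self):
        lv, _ = build_membrane_vesicle(30.0)
        prof = tl.layer_occupancy(lv, 1, [], max_distance_nm=100)
        assert (prof["occupancy"] == 0).all()

    def test_occupancy_nonzero_exactly_over_vesicle_extent(self):
        voxel = 3.2
        lv, center = build_membrane_vesicle(30.0, voxel)  # near 30, far 70 nm
        prof = tl.layer_occupancy(lv, 1, [2], max_distance_nm=120)
        occupied = prof[prof["occupancy"] > 0]
        # voxel-count oracle: layers holding vesicle voxels span [30, 70] nm
        # of distance, up to one voxel of digitisation
        assert occupied["distance_nm"].min() == pytest.approx(30, abs=2 * voxel)
        assert occupied["distance_nm"].max() == pytest.approx(70, abs=2 * voxel)

    def test_bounds_and_conservation(self):
        voxel = 3.2
        lv, _ = build_membrane_vesicle(20.0, voxel)
        max_nm = 96.0
        prof = tl.layer_occupancy(lv, 1, [2], max_distance_nm=max_nm)
        assert ((prof["occupancy"] >= 0) & (prof["occupancy"] <= 1)).all()
        # conservation: layer counts sum to all non-membrane voxels in range
        dist = ndimage.distance_transform_edt(lv.labels != 1, sampling=voxel)
        k = int(np.floor(max_nm / voxel))
        expected = int(((dist > 0) & (dist <= k * voxel)).sum())
        assert prof["layer_voxel_count"].sum() == expected

    def test_full_layer_occupancy_one(self):
        # a "vesicle" that is a full slab parallel to the membrane fills its
        # layers completely
        voxel = 2.0
        shape = (24, 8, 8)
        labels = np.zeros(shape, np.int32)
        labels[:2] = 1
        labels[6:8] = 2
        lv = tl.LabelVolume(labels, {1: tl.Boundary(1, "plasma_membrane"),
                                     2: tl.Boundary(2, "vesicle")}, voxel)
        prof = tl.layer_occupancy(lv, 1, [2], max_distance_nm=30)
        full = prof[prof["occupancy"] == 1.0]
        assert len(full) == 2  # the two slab layers

    def test_empty_membrane_rejected(self):
        lv, _ = build_membrane_vesicle(20.0)
        with pytest.raises(ValueError):
            tl.layer_occupancy(lv, 99, [2], 50)


class TestProximalStats:
    @pytest.mark.parametrize("gap,expected", [(20.0, 1), (50.0, 0)])
    def test_proximal_cut_at_45nm(self, gap, expected):
        lv, _ = build_membrane_vesicle(gap)
        out = tl.proximal_stats(lv, 1, [2], proximal_nm=45.0)
        assert out["n_proximal"] == expected

    def test_density_is_count_over_area(self):
        lv, _ = build_membrane_vesicle(20.0)
        out = tl.proximal_stats(lv, 1, [2], proximal_nm=45.0,
                                area_window_nm=250.0)
        assert out["membrane_area_um2"] > 0
        assert out["density_per_um2"] == pytest.approx(
            out["n_proximal"] / out["membrane_area_um2"])

    def test_area_counts_cytosol_facing_faces(self):
        # flat slab at the volume floor: included area = one face per column
        voxel = 3.2
        lv, _ = build_membrane_vesicle(20.0, voxel, shape=(48, 16, 16))
        out = tl.proximal_stats(lv, 1, [2], area_window_nm=1e6)
        expected_um2 = 16 * 16 * voxel ** 2 / 1e6
        assert out["membrane_area_um2"] == pytest.approx(expected_um2, rel=1e-6)


def radial_oracle(volume, center, radius, n_shells, supersample=10):
    """Direct radial shell averaging on a supersampled grid with linear
    interpolation - the independent reference for radial_trace."""
    voxel = volume.voxel_size_nm
    step = voxel / supersample
    reach = radius + (n_shells + 0.5) * voxel
    offs = np.arange(-reach, reach + step / 2, step)
    zz = (center[0] + offs) / voxel - 0.5
    yy = (center[1] + offs) / voxel - 0.5
    xx = (center[2] + offs) / voxel - 0.5
    grid = np.meshgrid(zz, yy, xx, indexing="ij")
    fine = ndimage.map_coordinates(volume.data.astype(float), np.array(grid),
                                   order=1, mode="nearest")
    r = np.sqrt(offs[:, None, None] ** 2 + offs[None, :, None] ** 2
                + offs[None, None, :] ** 2)
    shell = np.round((r - radius) / voxel).astype(int)
    means = []
    for k in range(-n_shells, n_shells + 1):
        sel = shell == k
        means.append(fine[sel].mean())
    return np.array(means)


class TestRadialTrace:
    def _vesicle_volume(self, kind="sv", voxel=3.2, radius=40.0):
        shape = (48, 48, 48)
        data = np.zeros(shape, np.float32)
        center = np.array(shape) * voxel / 2
        tl.render_sphere_shell(center, 0, radius, -2.0, data, voxel)
        if kind == "dcv_halo":
            tl.render_sphere_shell(center, 0, radius - 4.8, 0.0, data, voxel)
            tl.render_sphere_shell(center, 0, radius - 4.8 - 8.0, -1.5, data, voxel)
        elif kind == "dcv_nohalo":
            tl.render_sphere_shell(center, 0, radius - 4.8, -1.5, data, voxel)
        else:
            tl.render_sphere_shell(center, 0, radius - 4.8, -1.0, data, voxel)
        return tl.DensityVolume(data, voxel), center, radius

    def test_membrane_minimum_and_plateau_values(self):
        vol, center, radius = self._vesicle_volume("sv")
        trace = tl.radial_trace(vol, center, radius, n_shells_each_side=5)
        assert abs(trace.membrane_min_shell) <= 1
        assert trace.shell_value(-4) == pytest.approx(-1.0, abs=0.15)
        assert trace.shell_value(4) == pytest.approx(0.0, abs=0.1)

    def test_constant_volume_flat_trace(self):
        vol = tl.DensityVolume(np.full((40, 40, 40), -0.7, np.float32), 3.2)
        trace = tl.radial_trace(vol, np.full(3, 64.0), 30.0, 4)
        assert trace.mean_density == pytest.approx(-0.7, abs=1e-3)

    def test_halo_shows_as_local_maximum_between_membrane_and_core(self):
        vol, center, radius = self._vesicle_volume("dcv_halo")
        trace = tl.radial_trace(vol, center, radius, n_shells_each_side=8)
        m0 = trace.membrane_min_shell
        lumen = trace.shell_index < m0
        core_shell = trace.shell_index[lumen][np.argmin(trace.mean_density[lumen])]
        between = (trace.shell_index > core_shell) & (trace.shell_index < m0)
        assert trace.mean_density[between].max() > \
            trace.shell_value(int(core_shell)) + 0.5

    def test_agrees_with_supersampled_oracle(self):
        # band-limited volume (as after denoising): spline and supersampled
        # linear averaging must agree; at a hard density step the two
        # interpolants legitimately differ, so the profile is smoothed first
        raw, center, radius = self._vesicle_volume("dcv_nohalo")
        vol = tl.smooth_stand_in(raw, raw.voxel_size_nm)
        n = 6
        trace = tl.radial_trace(vol, center, radius, n_shells_each_side=n)
        oracle = radial_oracle(vol, center, radius, n)
        span = oracle.max() - oracle.min()
        assert np.max(np.abs(trace.mean_density - oracle)) < 0.05 * span

    def test_shells_must_fit_in_volume(self):
        vol = tl.DensityVolume(np.zeros((20, 20, 20), np.float32), 3.2)
        with pytest.raises(ValueError, match="bounds"):
            tl.radial_trace(vol, [32.0, 32.0, 32.0], 25.0, 5)


class TestClassifyLumen:
    def _trace(self, values):
        idx = np.arange(-(len(values) // 2), len(values) // 2 + 1)
        return RadialTrace(idx, np.asarray(values, float), 3.2)

    def test_lumen_at_cytoplasm_mean_is_light(self):
        trace = self._trace([0, 0, 0, 0, -2, 0, 0, 0, 0])
        assert tl.classify_lumen(trace, 0.0, 0.2) == "light"

    def test_deep_core_no_intermediate_is_dense_nohalo(self):
        trace = self._trace([-0.6, -0.6, -0.6, -0.7, -2, 0, 0, 0, 0])
        assert tl.classify_lumen(trace, 0.0, 0.2) == "dense_nohalo"

    def test_core_with_shell_at_cytoplasm_level_is_dense_halo(self):
        trace = self._trace([-1.0, -1.0, -0.9, 0.0, -2, 0, 0, 0, 0])
        assert tl.classify_lumen(trace, 0.0, 0.2) == "dense_halo"

    def test_degenerate_flat_trace_is_light(self):
        trace = self._trace([0.0] * 9)
        assert tl.classify_lumen(trace, 0.0, 0.0) == "light"

    def test_needs_three_lumen_shells(self):
        trace = self._trace([-2, 0, 0])
        with pytest.raises(ValueError):
            tl.classify_lumen(trace, 0.0, 0.1)

    def test_phantom_dcv_kinds_recovered(self):
        spec = tl.PhantomSpec(
            volume_shape=(96, 96, 96), rng_seed=6,
            vesicles=[
                tl.VesicleSpec(kind="dcv_halo", diameter_nm=80,
                               centers_nm=[[80, 80, 80]]),
                tl.VesicleSpec(kind="dcv_nohalo", diameter_nm=80,
                               centers_nm=[[80, 220, 80]]),
                tl.VesicleSpec(kind="light_medium", diameter_nm=80,
                               centers_nm=[[80, 80, 220]]),
            ])
        density, labels, truth = tl.generate_phantom(spec)
        got = {}
        for row in truth.vesicles.to_dict("records"):
            center = [row["center_z_nm"], row["center_y_nm"], row["center_x_nm"]]
            trace = tl.radial_trace(density, center, row["diameter_nm"] / 2, 8)
            got[row["kind"]] = tl.classify_lumen(trace, 0.0, 0.1)
        assert got == {"dcv_halo": "dense_halo", "dcv_nohalo": "dense_nohalo",
                       "light_medium": "light"}


class TestSelectDCV:
    def test_selection_rule(self):
        import pandas as pd
        table = pd.DataFrame({
            "lumen_class": ["dense_nohalo", "dense_halo", "dense_nohalo", "light"],
            "diameter_nm": [80.0, 70.0, 95.0, 80.0],
        })
        out = tl.select_dcv(table)
        assert out["diameter_nm"].tolist() == [80.0, 70.0]


class TestDistanceToMicrotubule:
    def _mt_volume(self, sphere_center, voxel=3.2):
        shape = (64, 64, 96)
        # straight tube along y at z=100, x=100 nm
        spec = tl.PhantomSpec(volume_shape=shape, voxel_size_nm=voxel,
                              microtubules=[tl.MicrotubuleSpec(
                                  points_nm=[[100, 8, 100], [100, 196, 100]])])
        density, lv, _ = tl.generate_phantom(spec)
        mask = tl.render_sphere_shell(np.asarray(sphere_center, float), 0, 40.0,
                                      -2.0, density.data, voxel)
        labels = lv.labels.copy()
        labels[mask] = 99
        catalog = dict(lv.catalog)
        catalog[99] = tl.Boundary(99, "vesicle", np.asarray(sphere_center, float),
                                  40.0, "light_medium")
        return tl.LabelVolume(labels, catalog, voxel)

    def test_known_geometry(self):
        # sphere r=40 centered 100 nm from the tube axis, outer radius 12.5
        # -> surface-to-surface 47.5 nm
        lv = self._mt_volume([100.0, 102.4, 200.0])
        d = tl.distance_to_microtubule(lv, 99)
        assert d == pytest.approx(47.5, abs=3.2)

    def test_touching_gives_zero(self):
        lv = self._mt_volume([100.0, 102.4, 152.5])  # gap 0
        assert tl.distance_to_microtubule(lv, 99) == pytest.approx(0.0, abs=3.3)

    def test_no_microtubules_missing(self):
        labels = np.zeros((8, 8, 8), np.int32)
        labels[2, 2, 2] = 1
        lv = tl.LabelVolume(labels, {1: tl.Boundary(1, "vesicle")}, 3.2)
        assert tl.distance_to_microtubule(lv, 1) is None


class TestCurvature:
    def test_straight_line_zero(self):
        pts = np.stack([np.zeros(20), np.zeros(20), np.linspace(0, 4000, 20)], axis=1)
        cm = tl.polyline_curvature(pts, 0.5)
        assert cm.kappa_per_um == 0.0
        assert cm.angular_per_um == 0.0

    def test_cocircular_points_exact_inverse_radius(self):
        # points on a circle spaced so successive chords are exactly 0.5 um:
        # the circumscribed circle is recovered exactly
        R = 0.53  # um, i.e. a 530-nm radius arc
        d = 0.5
        theta = 2 * np.arcsin(d / (2 * R))
        ang = np.arange(8) * theta
        pts_nm = 1000 * np.stack([np.zeros_like(ang), R * np.sin(ang),
                                  R * np.cos(ang)], axis=1)
        cm = tl.polyline_curvature(pts_nm, d)
        assert cm.kappa_per_um == pytest.approx(1 / R, rel=1e-9)
        # the printed magnitude: ~1.9 per um for a 530 nm arc radius
        assert round(cm.kappa_per_um, 1) == 1.9

    def test_resampled_circle_within_two_percent(self):
        # dense samples on a circle with R >= 5 d, resampled at spacing d
        R, d = 2.6, 0.5
        ang = np.linspace(0, np.pi, 400)
        pts_nm = 1000 * np.stack([np.zeros_like(ang), R * np.sin(ang),
                                  R * np.cos(ang)], axis=1)
        cm = tl.polyline_curvature(pts_nm, d)
        assert cm.kappa_per_um == pytest.approx(1 / R, rel=0.02)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            tl.polyline_curvature(np.zeros((2, 3)), 0.5)


class TestCurvatureToAngular:
    def test_zero_maps_to_zero(self):
        assert tl.curvature_to_angular(0.0, 0.5) == 0.0

    def test_printed_conversion_pairs(self):
        # 1.8 1/um at 0.5 um spacing -> 1.867, printed as 1.9 rad/um
        assert tl.curvature_to_angular(1.8, 0.5) == pytest.approx(1.8671, abs=1e-3)
        assert round(tl.curvature_to_angular(1.8, 0.5), 1) == 1.9

    def test_small_curvature_limit(self):
        for kappa in (0.01, 0.1, 0.5):
            out = tl.curvature_to_angular(kappa, 0.5)  # kappa d < 0.3
            assert out == pytest.approx(kappa, rel=0.01)

    def test_always_at_least_kappa(self):
        for kappa in np.linspace(0.1, 3.9, 20):
            assert tl.curvature_to_angular(kappa, 0.5) >= kappa

    def test_domain_error_when_chord_exceeds_diameter(self):
        with pytest.raises(ValueError):
            tl.curvature_to_angular(5.0, 0.5)  # kappa d / 2 > 1
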