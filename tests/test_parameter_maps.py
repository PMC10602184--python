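import numpy as np
import pytest

import roctscan as r
from roctscan.geometry import BScan, PixelResolution
from roctscan.lumen_segmentation import LumenMeasurement, MaskVolume
from roctscan.oct_simulation import make_layered_kidney, synthesize_bscan
from roctscan.parameter_maps import (
    ParameterMap,
    build_atcm,
    build_depm,
    build_diam,
    diameter_grid,
    extract_surface_depth,
    fit_extinction,
    stitch,
)

from conftest import downward_pose

RES = PixelResolution(lateral=0.05, axial=0.01, elevational=0.03)


def surface_bscan(rows_by_column, height_px=300, pose=None):
    """Zero background, intensity 1 from the given surface row downward."""
    W = len(rows_by_column)
    img = np.zeros((height_px, W))
    for j, row in enumerate(rows_by_column):
        if row is not None:
            img[row:, j] = 1.0
    return BScan(pixels=img, alpha_res=RES, pose=pose or downward_pose(z=5.0))


class TestExtractSurfaceDepth:
    def test_flat_surface_uniform_depth(self):
        b = surface_bscan([100] * 8)
        depth, valid = extract_surface_depth(b, threshold=0.5)
        assert valid.all()
        assert np.allclose(depth, 1.0)  # 100 px * 0.01 mm

    def test_step_edge_two_valued(self):
        b = surface_bscan([100] * 4 + [200] * 4)
        depth, valid = extract_surface_depth(b, threshold=0.5)
        assert valid.all()
        assert np.allclose(depth[:4], 1.0)
        assert np.allclose(depth[4:], 2.0)
        assert np.count_nonzero(np.abs(np.diff(depth)) > 1e-12) == 1

    def test_all_background_invalid(self):
        b = surface_bscan([None] * 8)
        depth, valid = extract_surface_depth(b, threshold=0.5)
        assert not valid.any()
        assert np.all(np.isnan(depth))


class TestFitExtinction:
    def make_column(self, mu, n=300, i0=0.9, alpha=0.01, surface=20):
        k = np.arange(n)
        col = np.zeros(n)
        col[surface:] = i0 * np.exp(-2 * mu * (k[surface:] - surface) * alpha)
        return col

    def test_noiseless_recovery(self):
        col = self.make_column(2.0)
        fit = fit_extinction(col, 20, 1.0, 0.01)
        assert fit.valid
        assert fit.mu_t == pytest.approx(2.0, abs=1e-6)

    def test_constant_intensity_zero_mu(self):
        col = np.full(300, 0.4)
        fit = fit_extinction(col, 20, 1.0, 0.01)
        assert fit.valid
        assert fit.mu_t == 0.0

    def test_scale_invariance(self):
        col = self.make_column(1.7)
        f1 = fit_extinction(col, 20, 1.0, 0.01)
        f2 = fit_extinction(col * 123.4, 20, 1.0, 0.01)
        assert f1.mu_t == pytest.approx(f2.mu_t, abs=1e-12)

    def test_gamma_speckle_recovery_within_ten_percent(self):
        rng = np.random.default_rng(0)
        mu = 2.0
        errs = []
        for _ in range(1000):
            col = self.make_column(mu) * rng.gamma(16.0, 1 / 16.0, 300)
            fit = fit_extinction(col, 20, 1.0, 0.01)
            errs.append(fit.mu_t - mu)
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse <= 0.1 * mu

    def test_window_outside_image_invalid(self):
        col = self.make_column(2.0, n=50)
        fit = fit_extinction(col, 48, 1.0, 0.01)
        assert not fit.valid

    def test_growing_intensity_clamped_and_flagged(self):
        col = np.exp(np.linspace(0, 3, 300))
        fit = fit_extinction(col, 20, 1.0, 0.01)
        assert fit.mu_t == 0.0
        assert not fit.valid


class TestBuildDepm:
    def test_phantom_glyph_height_and_width(self, phantom_scan):
        sample, plan, probe = (
            phantom_scan["sample"],
            phantom_scan["plan"],
            phantom_scan["probe"],
        )
        depm = build_depm(phantom_scan["log"])
        vals = depm.grid[depm.validity]
        height = vals.max() - vals.min()
        truth_h = sample.truth["extrusion_height"]
        assert abs(height - truth_h) <= probe.alpha_res.axial  # 1 axial voxel

        # glyph bbox recovered from the half-height mask
        mask = depm.validity & (depm.grid > vals.min() + truth_h / 2)
        rows = np.nonzero(mask.any(axis=1))[0]
        cols = np.nonzero(mask.any(axis=0))[0]
        x0 = depm.origin[0] + rows[0] * depm.res[0]
        x1 = depm.origin[0] + (rows[-1] + 1) * depm.res[0]
        y0 = depm.origin[1] + cols[0] * depm.res[1]
        y1 = depm.origin[1] + (cols[-1] + 1) * depm.res[1]
        (tx0, ty0, tx1, ty1) = sample.truth["glyph_bboxes"][0]
        pitch = sample.truth["pitch"]
        # elevational extent within 1 elevational pixel (+ raster pitch)
        assert abs((x1 - x0) - (tx1 - tx0)) <= depm.res[0] + 2 * pitch
        # lateral extent within 1 lateral pixel (+ raster pitch)
        assert abs((y1 - y0) - (ty1 - ty0)) <= depm.res[1] + 2 * pitch

    def test_wavy_trajectory_is_compensated(self, probe):
        sample = make_layered_kidney((20, 20), 0.0, [(5.0, 1.5)])
        frames = []
        for i in range(60):
            z = 1.2 + 0.4 * np.sin(i / 6.0)  # deliberately wavy altitude
            pose = downward_pose(x=2 + 0.03 * i, y=5.0, z=z, timestamp=i / 20)
            frames.append(
                synthesize_bscan(sample, pose, probe.width_px, probe.height_px, probe.alpha_res)
            )
        depm = build_depm(frames)
        vals = depm.grid[depm.validity]
        assert np.ptp(vals) <= probe.alpha_res.axial  # flat within one axial voxel

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            build_depm([])


class TestBuildAtcm:
    def test_two_region_sample(self, probe):
        sample = make_layered_kidney((20, 20), 0.0, [(10.0, 1.0)])
        y_edge = 5.0

        def mu(x, y, z):
            return np.where(np.asarray(y) < y_edge, 1.0, 3.0)

        sample.extinction_field = mu
        frames = [
            synthesize_bscan(
                sample,
                downward_pose(x=2 + 0.03 * i, y=5.0, z=0.5, timestamp=i / 20),
                probe.width_px,
                probe.height_px,
                probe.alpha_res,
            )
            for i in range(20)
        ]
        atcm = build_atcm(frames)
        vals = atcm.grid[atcm.validity]
        lo, hi = vals.min(), vals.max()
        assert lo == pytest.approx(1.0, abs=1e-6)
        assert hi == pytest.approx(3.0, abs=1e-6)
        # boundary within one lateral pixel of ground truth
        row = atcm.grid[0]
        ys = atcm.origin[1] + np.arange(atcm.shape[1]) * atcm.res[1]
        crossing = ys[np.nonzero(row > 2.0)[0][0]]
        assert abs(crossing - y_edge) <= atcm.res[1]

    def test_low_attenuation_tube_streak(self, probe):
        iso = PixelResolution(lateral=0.05, axial=0.02, elevational=0.03)
        radius, depth, y_c = 0.3, 0.5, 5.0
        sample = make_layered_kidney((20, 20), 0.0, [(10.0, 2.0)])

        def mu(x, y, z):
            inside = (np.asarray(y) - y_c) ** 2 + (np.asarray(z) + depth) ** 2 <= radius**2
            return np.where(inside, 0.2, 2.0)

        sample.extinction_field = mu
        frames = [
            synthesize_bscan(
                sample,
                downward_pose(x=2 + 0.03 * i, y=5.0, z=0.4, timestamp=i / 20),
                probe.width_px,
                probe.height_px,
                iso,
            )
            for i in range(10)
        ]
        atcm = build_atcm(frames, window_mm=1.0)
        low = atcm.validity & (atcm.grid < 2.0 - 0.05)
        ys = atcm.origin[1] + np.arange(atcm.shape[1]) * atcm.res[1]
        footprint = np.abs(ys - y_c) <= radius
        # streak spans every frame row and matches the footprint within 1 px dilation
        assert low.any(axis=1).all()
        for i in range(atcm.shape[0]):
            got = low[i]
            assert not np.any(got & ~np.convolve(footprint, [1, 1, 1], "same").astype(bool))
            inner = np.abs(ys - y_c) <= radius - atcm.res[1]
            assert np.all(got[inner])

    def test_uniform_sample_low_cv(self, flat_sample, probe):
        frames = [
            synthesize_bscan(
                flat_sample,
                downward_pose(x=2 + 0.03 * i, y=5.0, z=0.5, timestamp=i / 20),
                probe.width_px,
                probe.height_px,
                probe.alpha_res,
            )
            for i in range(10)
        ]
        atcm = build_atcm(frames)
        vals = atcm.grid[atcm.validity]
        assert vals.std() / vals.mean() < 0.01


def const_map(value, shape=(20, 30), origin=(0.0, 0.0), kind="DEPM", res=(0.1, 0.1)):
    return ParameterMap(
        kind=kind,
        grid=np.full(shape, float(value)),
        res=res,
        origin=origin,
        validity=np.ones(shape, dtype=bool),
    )


class TestStitch:
    def test_overlap_of_constant_maps_is_mean(self):
        a = const_map(2.0, origin=(0.0, 0.0))
        b = const_map(6.0, origin=(0.0, 2.0))  # 10-col overlap at 0.1 mm/px
        s = stitch([a, b])
        assert s.shape == (20, 50)
        assert np.allclose(s.grid[:, :20], 2.0)
        assert np.allclose(s.grid[:, 20:30], 4.0)
        assert np.allclose(s.grid[:, 30:], 6.0)

    def test_identical_maps_idempotent(self):
        a = const_map(3.3)
        s = stitch([a, const_map(3.3)])
        assert np.allclose(s.grid, 3.3)
        assert s.shape == a.shape

    def test_order_free(self):
        maps = [
            const_map(1.0, origin=(0.0, 0.0)),
            const_map(2.0, origin=(0.0, 1.5)),
            const_map(5.0, origin=(0.0, 3.0)),
        ]
        s1 = stitch(maps)
        s2 = stitch(maps[::-1])
        assert np.allclose(s1.grid, s2.grid)
        assert s1.origin == s2.origin

    def test_kind_mismatch_rejected(self):
        with pytest.raises(ValueError):
            stitch([const_map(1.0), const_map(1.0, kind="ATCM")])

    def test_res_mismatch_rejected(self):
        with pytest.raises(ValueError):
            stitch([const_map(1.0), const_map(1.0, res=(0.2, 0.1))])

    def test_validity_union_and_invalid_gap(self):
        a = const_map(1.0, shape=(5, 5), origin=(0.0, 0.0))
        b = const_map(2.0, shape=(5, 5), origin=(0.0, 1.0))  # 5-px gap
        s = stitch([a, b])
        assert s.validity[:, :5].all() and s.validity[:, 10:].all()
        assert not s.validity[:, 5:10].any()

    def test_three_scanline_footprint_width(self, phantom_scan):
        plan = phantom_scan["plan"]
        probe = phantom_scan["probe"]
        depm = build_depm(phantom_scan["log"])
        width = depm.shape[1] * depm.res[1]
        expected = probe.lateral_fov + 2 * (plan.W_OCT - plan.W_ol)
        assert abs(width - expected) <= depm.res[1]


def measurement(x, y, d_um):
    return LumenMeasurement(
        slice_index=0, component_id=1, diameter_um=d_um, centerline_px=1, centroid=(x, y, 0.0)
    )


def empty_mask_volume(shape=(40, 40, 10), res=0.1):
    return MaskVolume(
        voxels=np.zeros(shape, dtype=bool),
        voxel_size=np.array([res, res, res]),
        origin=np.zeros(3),
    )


class TestBuildDiam:
    def test_single_lumen_constant_field(self):
        vol = empty_mask_volume()
        meas = [measurement(2.0, 2.0, 25.0)]
        pm = build_diam(vol, meas, k=4)
        assert np.allclose(pm.grid[pm.validity], 25.0)

    def test_two_lumens_in_one_cell_averaged(self):
        vol = empty_mask_volume()
        meas = [measurement(0.5, 0.5, 10.0), measurement(0.6, 0.6, 30.0)]
        grid, valid = diameter_grid(meas, (40, 40), (0.1, 0.1), (0.0, 0.0), k=4)
        assert valid[0, 0]
        assert grid[0, 0] == pytest.approx(20.0)
        assert valid.sum() == 1

    def test_grid_matches_brute_force_cell_averages(self):
        rng = np.random.default_rng(1)
        k = 10
        meas = [
            measurement(rng.uniform(0, 4), rng.uniform(0, 4), rng.uniform(15, 30))
            for _ in range(50)
        ]
        grid, valid = diameter_grid(meas, (40, 40), (0.1, 0.1), (0.0, 0.0), k=k)
        # brute-force double loop over cells
        for gx in range(k):
            for gy in range(k):
                vals = [
                    m.diameter_um
                    for m in meas
                    if gx == min(int(m.centroid[0] / 0.1 / 40 * k), k - 1)
                    and gy == min(int(m.centroid[1] / 0.1 / 40 * k), k - 1)
                ]
                if vals:
                    assert valid[gx, gy]
                    assert grid[gx, gy] == pytest.approx(np.mean(vals))
                else:
                    assert not valid[gx, gy]

    def test_upsampled_shape_and_invalid_cells_masked(self):
        vol = empty_mask_volume()
        meas = [measurement(0.5, 0.5, 20.0)]
        pm = build_diam(vol, meas, k=4)
        assert pm.shape == (40, 40)
        assert pm.validity[0, 0]
        assert not pm.validity[-1, -1]

    def test_k_larger_than_projection_rejected(self):
        vol = empty_mask_volume(shape=(8, 8, 4))
        with pytest.raises(ValueError):
            build_diam(vol, [measurement(0.1, 0.1, 20.0)], k=10)
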