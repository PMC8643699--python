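"""Aerial trait extraction: segmentation, ground plane, canopy metrics,
vegetation indices."""

import numpy as np
import pytest

from hempkite.uas import (
    PlantROI,
    Scene,
    canopy_metrics,
    excess_green,
    locate_plants,
    otsu_threshold,
    ransac_ground_plane,
    read_scene,
    vegetation_indices,
    write_scene,
)

GT = (0.0, 0.02, 0.0, 10.0, 0.0, -0.02)       # 2 cm pixels, origin top-left


def otsu_exhaustive(img, nbins=256):
    """Oracle: argmax of between-class variance over every histogram cut."""
    hist, edges = np.histogram(img.ravel(), bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()
    best, best_t = -1.0, None
    for i in range(1, nbins):
        w0, w1 = p[:i].sum(), p[i:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (p[:i] * centers[:i]).sum() / w0
        m1 = (p[i:] * centers[i:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best:
            best, best_t = v, centers[i - 1]
    return best_t


class TestExcessGreen:
    def test_pure_green(self):
        img = np.zeros((1, 1, 3))
        img[0, 0] = (0, 1, 0)
        assert excess_green(img)[0, 0] == pytest.approx(2.0)

    def test_gray(self):
        assert excess_green(np.full((2, 2, 3), 0.3))[0, 0] == pytest.approx(0.0)

    def test_arithmetic(self):
        img = np.zeros((1, 1, 3))
        img[0, 0] = (0.2, 0.5, 0.1)
        assert excess_green(img)[0, 0] == pytest.approx(0.7)

    def test_wrong_band_count(self):
        with pytest.raises(ValueError):
            excess_green(np.zeros((2, 2, 4)))


class TestOtsu:
    @pytest.mark.parametrize("seedcase", range(4))
    def test_matches_exhaustive_oracle(self, seedcase):
        rng = np.random.default_rng(seedcase)
        if seedcase == 0:      # two-level map 60/40
            img = np.where(rng.uniform(size=(50, 50)) < 0.6, 0.0, 200.0)
        elif seedcase == 1:    # symmetric bimodal Gaussians
            img = np.concatenate([rng.normal(-2, 0.5, 2000),
                                  rng.normal(2, 0.5, 2000)])
        elif seedcase == 2:    # skewed mixture
            img = np.concatenate([rng.normal(0, 1, 3000),
                                  rng.normal(6, 2, 500)])
        else:                  # uniform noise
            img = rng.uniform(0, 1, 2500)
        got = otsu_threshold(img)
        want = otsu_exhaustive(np.asarray(img, dtype=float))
        rng_span = np.ptp(img)
        assert abs(got - want) <= rng_span / 256 * 1.5

    def test_two_level_separates(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.uniform(size=(40, 40)) < 0.6, 0.0, 200.0)
        t = otsu_threshold(img)
        assert 0.0 < t < 200.0

    def test_bimodal_near_midpoint(self):
        rng = np.random.default_rng(1)
        img = np.concatenate([rng.normal(-2, 0.5, 5000),
                              rng.normal(2, 0.5, 5000)])
        assert abs(otsu_threshold(img)) < 0.15

    def test_single_foreground_pixel(self):
        img = np.zeros((10, 10))
        img[5, 5] = 1.0
        t = otsu_threshold(img)
        assert 0.0 < t < 1.0

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.ones((5, 5)))


class TestLocatePlants:
    def test_single_square_blob_centroid(self):
        binary = np.zeros((100, 100), dtype=bool)
        binary[10:20, 30:40] = True
        centers = locate_plants(binary, GT, min_blob_px=10)
        assert centers.shape == (1, 2)
        # centroid row 14.5, col 34.5 -> ground
        assert centers[0, 0] == pytest.approx(0.0 + 35.0 * 0.02, abs=1e-9)
        assert centers[0, 1] == pytest.approx(10.0 - 15.0 * 0.02, abs=1e-9)

    def test_two_blobs_two_centers(self):
        binary = np.zeros((100, 100), dtype=bool)
        binary[10:20, 10:20] = True
        binary[60:70, 60:70] = True
        centers = locate_plants(binary, GT, min_blob_px=10)
        assert centers.shape == (2, 2)

    def test_small_blob_filtered(self):
        binary = np.zeros((50, 50), dtype=bool)
        binary[0:2, 0:2] = True
        with pytest.warns(UserWarning):
            centers = locate_plants(binary, GT, min_blob_px=50)
        assert centers.shape == (0, 2)

    def test_touching_blobs_merge(self):
        binary = np.zeros((50, 50), dtype=bool)
        binary[10:20, 10:20] = True
        binary[20:30, 20:30] = True      # diagonal touch: 8-connected merge
        centers = locate_plants(binary, GT, min_blob_px=10)
        assert centers.shape == (1, 2)


class TestRansac:
    def test_flat_plane_exact(self, rng):
        pts = np.column_stack([rng.uniform(0, 5, 300),
                               rng.uniform(0, 5, 300),
                               np.zeros(300)])
        plane, ground = ransac_ground_plane(pts, seed=0)
        assert abs(plane[2]) == pytest.approx(1.0, abs=1e-9)
        assert abs(plane[3]) < 1e-9
        assert ground.all()

    def test_ground_plus_canopy_classification(self, rng):
        ground = np.column_stack([rng.uniform(0, 3, 1000),
                                  rng.uniform(0, 3, 1000),
                                  rng.normal(0, 0.005, 1000)])
        canopy = np.column_stack([rng.uniform(1, 2, 300),
                                  rng.uniform(1, 2, 300),
                                  rng.uniform(0.2, 1.5, 300)])
        pts = np.vstack([ground, canopy])
        plane, is_ground = ransac_ground_plane(pts, seed=1)
        normal = np.array(plane[:3])
        angle = np.degrees(np.arccos(abs(normal[2])))
        assert angle < 1.0
        assert (~is_ground[1000:]).mean() >= 0.99

    def test_infinite_threshold_everything_inlier(self, rng):
        pts = rng.normal(size=(100, 3))
        _, is_ground = ransac_ground_plane(pts, dist_thresh=np.inf, seed=2)
        assert is_ground.all()

    def test_collinear_rejected(self):
        t = np.linspace(0, 1, 50)
        pts = np.column_stack([t, 2 * t, 3 * t])
        with pytest.raises(ValueError):
            ransac_ground_plane(pts, seed=3)


class TestCanopyMetrics:
    def test_unit_cuboid(self, rng):
        n = 20000
        pts = np.column_stack([rng.uniform(0, 1, n), rng.uniform(0, 1, n),
                               rng.uniform(0, 1, n)])
        roi = PlantROI(center=(0.5, 0.5), box=(1.0, 1.0))
        cm = canopy_metrics(pts, (0, 0, 1, 0), roi, grid_res=0.05)
        assert cm.height == pytest.approx(1.0, rel=0.05)
        assert cm.projected_area == pytest.approx(1.0, rel=0.05)
        assert cm.volume == pytest.approx(1.0, rel=0.05)

    def test_cone_volume(self, rng):
        n = 40000
        h, r = 1.2, 0.5
        frac = rng.uniform(0, 1, n) ** (1 / 3)
        z = h * (1 - frac)
        rad = r * frac * np.sqrt(rng.uniform(0, 1, n))
        th = rng.uniform(0, 2 * np.pi, n)
        pts = np.column_stack([rad * np.cos(th), rad * np.sin(th), z])
        roi = PlantROI(center=(0.0, 0.0), box=(1.2, 1.2))
        cm = canopy_metrics(pts, (0, 0, 1, 0), roi, grid_res=0.02)
        assert cm.volume == pytest.approx(np.pi * r**2 * h / 3, rel=0.10)

    def test_empty_roi_zeros_flagged(self):
        cm = canopy_metrics(np.empty((0, 3)), (0, 0, 1, 0),
                            PlantROI(center=(0, 0)))
        assert cm.empty and cm.height == 0.0 and cm.volume == 0.0


class TestVegetationIndices:
    def _uniform_scene(self, b, g, r, re, nir):
        msp = np.empty((50, 50, 5))
        for i, v in enumerate((b, g, r, re, nir)):
            msp[..., i] = v
        return msp

    def test_ndvi_zero_when_nir_equals_red(self):
        msp = self._uniform_scene(0.1, 0.1, 0.4, 0.4, 0.4)
        out = vegetation_indices(msp, GT, center=(0.5, 9.5))
        assert out["NDVI"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_nir08_r02(self):
        msp = self._uniform_scene(0.1, 0.4, 0.2, 0.5, 0.8)
        out = vegetation_indices(msp, GT, center=(0.5, 9.5))
        assert out["NDVI"] == pytest.approx(0.6)
        assert out["MSAVI2"] == pytest.approx(0.6)
        assert out["OSAVI"] == pytest.approx(0.6 / 1.16, abs=1e-9)
        assert out["GCI"] == pytest.approx(1.0)
        assert out["GNDVI"] == pytest.approx(1.0 / 3.0)

    def test_ratio_indices_scale_invariant(self):
        m1 = self._uniform_scene(0.1, 0.3, 0.2, 0.5, 0.7)
        m2 = 2.0 * m1
        o1 = vegetation_indices(m1, GT, center=(0.5, 9.5))
        o2 = vegetation_indices(m2, GT, center=(0.5, 9.5))
        for idx in ("NDVI", "GNDVI", "GCI"):
            assert o2[idx] == pytest.approx(o1[idx], rel=1e-9)
        assert o2["OSAVI"] != pytest.approx(o1["OSAVI"], rel=1e-3)

    def test_circle_outside_raster_rejected(self):
        msp = self._uniform_scene(0.1, 0.2, 0.3, 0.4, 0.5)
        with pytest.raises(ValueError, match="outside"):
            vegetation_indices(msp, GT, center=(100.0, 100.0))


def test_scene_roundtrip(tmp_path, rng):
    scene = Scene(
        rgb=rng.uniform(0, 1, (8, 9, 3)),
        msp=rng.uniform(0, 1, (8, 9, 5)),
        cloud=rng.uniform(0, 1, (20, 6)),
        geotransform=GT,
    )
    write_scene(scene, tmp_path / "s")
    back = read_scene(tmp_path / "s")
    np.testing.assert_allclose(back.rgb, scene.rgb, atol=1e-6)
    np.testing.assert_allclose(back.cloud, scene.cloud, atol=1e-5)
    assert back.geotransform == GT
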