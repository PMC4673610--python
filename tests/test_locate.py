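import math

import numpy as np
import pytest

from conftest import random_pattern, render_disks

from clemalign.errors import (
    DegenerateGeometryError,
    InsufficientCorrespondenceError,
)
from clemalign.locate import (
    Keypoint,
    detect_keypoints,
    estimate_similarity,
    locate_roi,
    match_descriptors,
    voronoi_augment,
)
from clemalign.raster_io import SimilarityTransform
from clemalign.segmentation import Island, IslandTable, label_islands


class TestDetectKeypoints:
    def test_blank_image_empty(self):
        assert detect_keypoints(np.zeros((64, 64))) == []

    def test_descriptors_unit_norm(self, pattern_512):
        kps = detect_keypoints(pattern_512.astype(float))
        assert kps
        for kp in kps[:50]:
            assert np.linalg.norm(kp.descriptor) == pytest.approx(1.0, abs=1e-6)
            assert kp.scale > 0

    def test_disk_center_and_scale_proportionality(self):
        def disk_kp(radius, side, tol):
            # large-sigma detections run on the reduced pyramid level, so
            # their positions are quantized to its 4-px grid
            img = render_disks([(side / 2, side / 2)], [radius], (side, side))
            kps = detect_keypoints(img.astype(float))
            near = [
                k for k in kps
                if math.hypot(k.x - side / 2, k.y - side / 2) <= tol
            ]
            assert near
            return max(near, key=lambda k: k.scale)

        k20 = disk_kp(20, 200, tol=2)
        k40 = disk_kp(40, 400, tol=4)
        ratio = k40.scale / k20.scale
        assert 1.6 <= ratio <= 2.4  # 2 +/- 20%

    def test_rotation_90_equivariance(self, pattern_512):
        kps = detect_keypoints(pattern_512.astype(float))
        rot = np.rot90(pattern_512, k=-1)  # (x, y) -> (N-1-y, x)
        kps_rot = detect_keypoints(rot.astype(float))
        n = pattern_512.shape[0]
        # map rotated keypoints back: x = y', y = N-1-x'
        mapped = {(round(k.y), round(n - 1 - k.x)) for k in kps_rot}
        positions = {(round(k.x), round(k.y)) for k in kps}
        hits = sum(
            1 for (xr, yr) in mapped
            if any(abs(xr - x) <= 1 and abs(yr - y) <= 1 for x, y in positions)
        )
        assert hits >= 0.8 * len(mapped)


class TestMatchDescriptors:
    def test_empty_sets_rejected(self, pattern_512):
        kps = detect_keypoints(pattern_512.astype(float))
        with pytest.raises(ValueError):
            match_descriptors([], kps)
        with pytest.raises(ValueError):
            match_descriptors(kps, [])

    def test_identical_sets_self_match(self, pattern_512):
        kps = detect_keypoints(pattern_512.astype(float))[:60]
        matches = match_descriptors(kps, kps, ratio=0.999)
        by_q = {qi: ri for qi, ri, _ in matches}
        same_pos = sum(
            1 for qi, ri in by_q.items()
            if (round(kps[qi].x), round(kps[qi].y))
            == (round(kps[ri].x), round(kps[ri].y))
        )
        assert same_pos == len(by_q) > 0
        assert all(d == pytest.approx(0.0, abs=1e-9) for _, _, d in matches)

    def test_shuffled_bijection_recovered(self, rng):
        # 50 synthetic keypoints with random descriptors; oracle: the
        # identity bijection found by exhaustive nearest-neighbour search
        descs = rng.random((50, 48))
        descs /= np.linalg.norm(descs, axis=1, keepdims=True)
        ref = [
            Keypoint(10.0 * i, 5.0 * i, 2.0, 0.0, d) for i, d in enumerate(descs)
        ]
        perm = rng.permutation(50)
        query = [ref[i] for i in perm]
        matches = match_descriptors(query, ref, ratio=0.9)
        assert len(matches) == 50
        for qi, ri, d in matches:
            assert ri == perm[qi]
            assert d == pytest.approx(0.0, abs=1e-12)

    def test_identical_twin_disks_rejected(self):
        # two identical isolated disks: d1 ~ d2 so the ratio test fires
        img = render_disks([(60, 64), (196, 64)], [15, 15], (128, 256))
        kps = detect_keypoints(img.astype(float))
        centers = [
            k for k in kps
            if min(math.hypot(k.x - 60, k.y - 64), math.hypot(k.x - 196, k.y - 64)) < 3
            and k.scale > 5
        ]
        if len(centers) >= 2:
            matches = match_descriptors(centers, centers, ratio=0.8)
            # self-distance 0 always survives; cross-disk matches must not
            for qi, ri, d in matches:
                assert d < 1e-9


class TestEstimateSimilarity:
    def test_identity_exact(self, rng):
        pts = rng.uniform(0, 100, (20, 2))
        tf, inliers = estimate_similarity(pts, pts)
        assert inliers.all()
        assert tf.scale == pytest.approx(1.0, abs=1e-9)
        assert tf.rotation_deg % 360 == pytest.approx(0.0, abs=1e-9)

    def test_two_point_closed_form(self):
        # analytic oracle: the unique similarity through two points
        src = np.array([[0.0, 0.0], [1.0, 0.0]])
        t = SimilarityTransform(2.0, 30.0, 5.0, -2.0)
        dst = t.apply(src)
        est, inliers = estimate_similarity(src, dst)
        assert inliers.all()
        assert est.scale == pytest.approx(2.0, rel=1e-12)
        assert est.rotation_deg == pytest.approx(30.0, abs=1e-9)
        assert est.tx == pytest.approx(5.0, abs=1e-9)
        assert est.ty == pytest.approx(-2.0, abs=1e-9)

    def test_planted_transform_with_outliers(self, rng):
        truth = SimilarityTransform(2.0, 15.0, 40.0, -7.0)
        src_in = rng.uniform(0, 200, (20, 2))
        dst_in = truth.apply(src_in) + rng.normal(0, 0.2, (20, 2))
        src_out = rng.uniform(0, 200, (9, 2))   # 30% outliers
        dst_out = rng.uniform(0, 400, (9, 2))
        src = np.vstack([src_in, src_out])
        dst = np.vstack([dst_in, dst_out])
        est, inliers = estimate_similarity(src, dst, seed=1)
        # oracle: least squares on the known inlier subset
        z = src_in[:, 0] + 1j * src_in[:, 1]
        w = dst_in[:, 0] + 1j * dst_in[:, 1]
        zc, wc = z - z.mean(), w - w.mean()
        m = np.vdot(zc, wc) / np.vdot(zc, zc).real
        assert est.scale == pytest.approx(abs(m), rel=0.01)
        assert est.scale == pytest.approx(2.0, rel=0.01)
        assert abs((est.rotation_deg - 15.0 + 180) % 360 - 180) < 0.5
        assert math.hypot(est.tx - 40.0, est.ty + 7.0) < 0.5

    def test_too_few_matches(self):
        with pytest.raises(InsufficientCorrespondenceError):
            estimate_similarity(np.zeros((1, 2)), np.zeros((1, 2)))

    def test_coincident_points_degenerate(self):
        src = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(DegenerateGeometryError):
            estimate_similarity(src, src)


class TestLocateRoi:
    def test_exact_crop(self):
        mask, _, _ = random_pattern(21, shape=(700, 700), n=40, rmin=6, rmax=22)
        roi = mask[260:460, 180:380].astype(float)
        res = locate_roi(roi, mask.astype(float), seed=0)
        assert res.status == "located"
        assert res.inlier_count >= 8
        assert res.transform.scale == pytest.approx(1.0, abs=0.005)
        assert abs(res.transform.rotation_deg) < 0.5
        assert res.transform.tx == pytest.approx(180, abs=1.0)
        assert res.transform.ty == pytest.approx(260, abs=1.0)

    def test_planted_similarity_with_island_loss(self):
        rng = np.random.default_rng(400)
        centers = np.column_stack(
            [rng.uniform(0, 900, 60), rng.uniform(0, 900, 60)]
        )
        radii = rng.uniform(5, 25, 60)
        mmask = render_disks(centers, radii, (900, 900))
        sc, th = 0.7, 123.0
        roi_size = int(round(512 / sc))
        rc = np.array([(roi_size - 1) / 2.0] * 2)
        anchor = np.array([430.0, 470.0])
        t0 = SimilarityTransform(sc, th, 0, 0)
        t = anchor - t0.apply(rc[None, :])[0]
        truth = SimilarityTransform(sc, th, t[0], t[1])
        keep = rng.random(60) > 0.05  # 5% island deletion
        roi = render_disks(
            truth.inverse().apply(centers[keep]), radii[keep] / sc,
            (roi_size, roi_size),
        )
        res = locate_roi(roi.astype(float), mmask.astype(float), seed=0)
        assert res.status == "located"
        est = res.transform
        assert abs(est.scale - sc) / sc < 0.01
        assert abs((est.rotation_deg - th + 180) % 360 - 180) < 1.0
        assert np.linalg.norm(est.apply(rc[None, :])[0] - anchor) < 2.0

    def test_unrelated_pattern_fails(self):
        mask, _, _ = random_pattern(31, shape=(700, 700), n=40, rmin=6, rmax=22)
        alien, _, _ = random_pattern(99, shape=(256, 256), n=15, rmin=5, rmax=15)
        res = locate_roi(alien.astype(float), mask.astype(float), seed=0)
        assert res.status != "located"
        assert res.transform is None


class TestVoronoiAugment:
    def _table(self, centroids):
        islands = [
            Island(i + 1, 10, 1.0, 12.0, 0.9, float(x), float(y))
            for i, (x, y) in enumerate(centroids)
        ]
        return IslandTable(islands)

    def test_single_site_no_edges(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[20:26, 20:26] = True
        table = label_islands(mask, 65.0, min_area_px=0)
        edges, aug = voronoi_augment(table, (50, 50))
        assert edges == []
        assert np.array_equal(aug, mask)

    def test_two_sites_perpendicular_bisector(self):
        table = self._table([(20.0, 30.0), (60.0, 70.0)])
        edges, aug = voronoi_augment(table, (100, 100))
        assert len(edges) == 1
        (x1, y1), (x2, y2) = edges[0]
        # oracle: analytic bisector -> endpoints equidistant from both sites
        for px, py in ((x1, y1), (x2, y2), ((x1 + x2) / 2, (y1 + y2) / 2)):
            d1 = math.hypot(px - 20, py - 30)
            d2 = math.hypot(px - 60, py - 70)
            assert d1 == pytest.approx(d2, abs=1e-6)

    def test_coincident_sites_degenerate(self):
        table = self._table([(5.0, 5.0), (5.0, 5.0), (5.0, 5.0)])
        with pytest.raises(DegenerateGeometryError):
            voronoi_augment(table, (50, 50))

    def test_collinear_sites(self):
        table = self._table([(10.0, 10.0), (30.0, 30.0), (50.0, 50.0)])
        edges, _ = voronoi_augment(table, (80, 80))
        assert len(edges) == 2

    def test_brute_force_nearest_site_labeling(self, rng):
        sites = np.column_stack(
            [rng.uniform(10, 190, 25), rng.uniform(10, 190, 25)]
        )
        table = self._table([tuple(p) for p in sites])
        edges, aug = voronoi_augment(table, (200, 200))
        assert len(edges) >= 25
        # oracle: flood-label the cells cut out by the rasterized edges and
        # check each connected region is nearest to exactly one site
        from skimage.measure import label as cc_label

        cells = cc_label(~aug, connectivity=1)
        ys, xs = np.mgrid[0:200, 0:200]
        nearest = np.argmin(
            (xs[..., None] - sites[:, 0]) ** 2 + (ys[..., None] - sites[:, 1]) ** 2,
            axis=-1,
        )
        checked = 0
        for cid in range(1, cells.max() + 1):
            sel = cells == cid
            if sel.sum() < 12:
                continue
            # erode the cell interior so 1-px rasterization slack is ignored
            from scipy.ndimage import binary_erosion

            interior = binary_erosion(sel, iterations=2)
            if interior.sum() < 4:
                continue
            labels = np.unique(nearest[interior])
            assert len(labels) == 1
            checked += 1
        assert checked >= 10

    def test_augmentation_increases_keypoints(self):
        mask, _, _ = random_pattern(11, shape=(300, 300), n=8, rmin=6, rmax=14)
        table = label_islands(mask, 65.0)
        assert len(table) >= 3
        _, aug = voronoi_augment(table, (300, 300))
        k_before = len(detect_keypoints(mask.astype(float)))
        k_after = len(detect_keypoints(aug.astype(float)))
        assert k_after > k_before
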