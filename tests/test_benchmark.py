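import numpy as np
import pytest

from clemalign.benchmark import (
    MAGNIFICATION_SCALING,
    MATRIX_PIXEL_SIZE_NM,
    STANDARD_DIAMETERS,
    DegradationConfig,
    DotMatrixSpec,
    crop_pairs,
    degrade,
    downscale_shape,
    estimate_pair_shift,
    generate_dot_matrix,
    run_accuracy,
    run_efficiency,
    simulate_island_loss,
)
from clemalign.errors import GeometryError
from clemalign.segmentation import label_islands


class TestDotMatrixSpec:
    def test_random_token_expands_to_standard_set(self):
        assert DotMatrixSpec().diameters() == STANDARD_DIAMETERS

    def test_diameter_floor(self):
        with pytest.raises(ValueError):
            DotMatrixSpec(dot_diameters_px=1)

    def test_coverage_bounds(self):
        with pytest.raises(ValueError):
            DotMatrixSpec(target_coverage=1.0)

    def test_physical_diameter_at_100x(self):
        # a 20 px dot at the 65 nm matrix pixel is 1.3 um across
        assert 20 * MATRIX_PIXEL_SIZE_NM / 1000 == pytest.approx(1.3)

    def test_magnification_scaling_invariants(self):
        assert MAGNIFICATION_SCALING[100] == 1.0
        mags = sorted(MAGNIFICATION_SCALING, reverse=True)
        factors = [MAGNIFICATION_SCALING[m] for m in mags]
        assert all(a < b for a, b in zip(factors, factors[1:]))


class TestGenerateDotMatrix:
    def test_zero_coverage_blank(self):
        spec = DotMatrixSpec(200, 200, 10, 0.0, seed=0)
        matrix, truth = generate_dot_matrix(spec)
        assert not matrix.pixels.any()
        assert len(truth) == 0

    def test_coverage_within_one_percent(self):
        spec = DotMatrixSpec(1000, 1000, 20, 0.10, seed=7)
        matrix, truth = generate_dot_matrix(spec)
        # oracle: direct pixel count
        coverage = (matrix.pixels > 0).mean()
        assert 0.09 <= coverage <= 0.11
        assert len(truth) > 0

    def test_binary_output_and_metadata(self):
        spec = DotMatrixSpec(300, 300, 12, 0.05, seed=1)
        matrix, _ = generate_dot_matrix(spec)
        assert matrix.modality == "binary"
        assert matrix.pixel_size_nm == 65.0
        assert set(np.unique(matrix.pixels)) <= {0, 255}

    def test_mixed_sizes_cycled_equally(self):
        spec = DotMatrixSpec(800, 800, [6, 12], 0.05, seed=3)
        _, truth = generate_dot_matrix(spec)
        counts = truth["diameter_px"].value_counts()
        assert abs(counts[6] - counts[12]) <= 1

    def test_deterministic_for_seed(self):
        spec = DotMatrixSpec(300, 300, 14, 0.08, seed=5)
        m1, t1 = generate_dot_matrix(spec)
        m2, t2 = generate_dot_matrix(spec)
        assert np.array_equal(m1.pixels, m2.pixels)
        assert t1.equals(t2)


class TestCropPairs:
    @pytest.fixture(scope="class")
    def matrix(self):
        spec = DotMatrixSpec(1200, 1200, 16, 0.08, seed=2)
        m, _ = generate_dot_matrix(spec)
        return m

    def test_full_overlap(self, matrix):
        pairs = crop_pairs(matrix, 3, overlap=1.0, seed=0, tile=256)
        for a, b, spec in pairs:
            assert (spec.true_dx, spec.true_dy) == (0, 0)
            assert np.array_equal(a, b)

    def test_axis_mode_magnitude(self, matrix):
        pairs = crop_pairs(matrix, 8, overlap=0.90, shift_mode="axis",
                           seed=1, tile=500)
        for _, _, spec in pairs:
            # one axis carries round(0.10 * 500) = 50 px, the other zero
            assert sorted(map(abs, (spec.true_dx, spec.true_dy))) == [0, 50]

    def test_bookkeeping_oracle(self, matrix):
        # ground truth equals the coordinate difference of the crops: the
        # overlap strips must agree pixel-for-pixel
        pairs = crop_pairs(matrix, 5, overlap=0.9, shift_mode="free",
                           seed=3, tile=300)
        for a, b, spec in pairs:
            dx, dy = spec.true_dx, spec.true_dy
            ax0, ay0 = max(0, dx), max(0, dy)
            bx0, by0 = max(0, -dx), max(0, -dy)
            w = 300 - abs(dx)
            h = 300 - abs(dy)
            assert np.array_equal(
                a[ay0:ay0 + h, ax0:ax0 + w], b[by0:by0 + h, bx0:bx0 + w]
            )

    def test_tile_too_large(self, matrix):
        with pytest.raises(GeometryError):
            crop_pairs(matrix, 1, tile=5000)

    def test_estimate_matches_truth_without_degradation(self, matrix):
        pairs = crop_pairs(matrix, 4, overlap=0.9, shift_mode="free",
                           seed=4, tile=300)
        for a, b, spec in pairs:
            dx, dy, _ = estimate_pair_shift(a, b)
            assert (dx, dy) == (spec.true_dx, spec.true_dy)


class TestDegrade:
    def test_identity_settings(self):
        rng = np.random.default_rng(0)
        binary = ((rng.random((64, 64)) > 0.5) * 255).astype(np.uint8)
        cfg = DegradationConfig(down_factor=1.0, noise_fraction=0.0,
                                blur_sigma_px=0.0, binarize_threshold=100)
        out = degrade(binary, cfg)
        assert np.array_equal(out.pixels, binary)

    def test_paper_downscale_shape_floor(self):
        # 2,048 / 3.846 -> 532 per side before restoration
        assert downscale_shape((2048, 2048), 3.846) == (532, 532)

    def test_output_binary_and_restored(self):
        rng = np.random.default_rng(1)
        img = ((rng.random((256, 256)) > 0.7) * 255).astype(np.uint8)
        out = degrade(img, DegradationConfig(), seed=3)
        assert out.pixels.shape == (256, 256)
        assert set(np.unique(out.pixels)) <= {0, 255}

    def test_area_preserved_for_large_dots(self):
        spec = DotMatrixSpec(512, 512, 20, 0.10, seed=9)
        matrix, _ = generate_dot_matrix(spec)
        out = degrade(matrix.pixels, DegradationConfig(), seed=11)
        before = (matrix.pixels > 0).mean()
        after = (out.pixels > 0).mean()
        # oracle: pixel counts before/after; dots >= 20 px survive the
        # paper's degradation with <10% relative area change
        assert abs(after - before) / before < 0.10

    def test_validation(self):
        with pytest.raises(ValueError):
            DegradationConfig(down_factor=0.5)
        with pytest.raises(ValueError):
            DegradationConfig(noise_fraction=0.7)
        with pytest.raises(ValueError):
            DegradationConfig(binarize_threshold=300)


class TestSimulateIslandLoss:
    @pytest.fixture(scope="class")
    def forty_islands(self):
        rng = np.random.default_rng(6)
        from skimage.draw import disk as draw_disk

        mask = np.zeros((600, 600), dtype=np.uint8)
        # disjoint grid placement: exactly 40 islands
        spots = [(40 + 90 * (i % 7) + int(rng.integers(-9, 9)),
                  40 + 90 * (i // 7) + int(rng.integers(-9, 9)))
                 for i in range(40)]
        for x, y in spots:
            rr, cc = draw_disk((y, x), 11, shape=mask.shape)
            mask[rr, cc] = 255
        table = label_islands(mask > 0, 65.0)
        assert len(table) == 40
        return mask

    def test_noop_at_zero(self, forty_islands):
        out, deleted = simulate_island_loss(forty_islands, 0.0, seed=1)
        assert deleted == []
        assert np.array_equal(out, forty_islands)

    def test_five_percent_removes_two(self, forty_islands):
        out, deleted = simulate_island_loss(forty_islands, 0.05, seed=2)
        # oracle: component counts before and after
        assert len(deleted) == 2
        before = len(label_islands(forty_islands > 0, 65.0))
        after = len(label_islands(out > 0, 65.0))
        assert before - after == 2

    def test_fraction_validation(self, forty_islands):
        with pytest.raises(ValueError):
            simulate_island_loss(forty_islands, 1.0)

    def test_deterministic(self, forty_islands):
        out1, d1 = simulate_island_loss(forty_islands, 0.2, seed=5)
        out2, d2 = simulate_island_loss(forty_islands, 0.2, seed=5)
        assert d1 == d2
        assert np.array_equal(out1, out2)


class TestRunAccuracy:
    def test_exact_recovery_without_degradation_integer_shifts(self):
        spec = DotMatrixSpec(1500, 1500, [10, 25, 60], 0.08, seed=4)
        report = run_accuracy(
            spec, n_base_pairs=4, n_scale_factors=2, scale_range=(1.0, 1.0),
            seed=4, tile=400, degradation=None,
        )
        # scale factor 1 keeps true shifts integer -> exact recovery
        assert report.mean_deviation == 0.0
        assert report.n_failed == 0

    def test_reports_are_reproducible(self):
        spec = DotMatrixSpec(1200, 1200, [10, 30], 0.08, seed=8)
        kwargs = dict(n_base_pairs=3, n_scale_factors=2, seed=8, tile=300,
                      degradation=None)
        r1 = run_accuracy(spec, **kwargs)
        r2 = run_accuracy(spec, **kwargs)
        assert r1.records.equals(r2.records)
        assert r1.mean_deviation == r2.mean_deviation

    def test_scale_factors_in_range(self):
        spec = DotMatrixSpec(1200, 1200, [10, 30], 0.08, seed=8)
        report = run_accuracy(spec, 2, 5, scale_range=(1.0, 4.0), seed=8,
                              tile=300, degradation=None)
        factors = report.records["scale_factor"].unique()
        assert ((factors > 1.0) & (factors <= 4.0)).all()

    def test_accuracy_nm_conversion(self):
        spec = DotMatrixSpec(1500, 1500, [10, 25, 60], 0.08, seed=4)
        report = run_accuracy(spec, 2, 2, scale_range=(1.0, 1.0), seed=4,
                              tile=400, degradation=None)
        assert report.accuracy_nm(200.0) == 0.0


class TestRunEfficiency:
    def test_blank_matrices_zero_efficiency(self):
        specs = [DotMatrixSpec(600, 600, 10, 0.0, seed=0)]
        report = run_efficiency(specs, [100, 20], n_pairs=3, seed=0, tile=200)
        assert (report["efficiency"] == 0.0).all()

    def test_grid_shape_and_bounds(self):
        specs = [DotMatrixSpec(800, 800, d, 0.08, seed=3 + i)
                 for i, d in enumerate((10, 24))]
        report = run_efficiency(specs, [100, 40], n_pairs=4, seed=1, tile=256)
        assert len(report) == 4
        assert report["efficiency"].between(0, 1).all()
        assert set(report["dot_spec"]) == {"10", "24"}
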