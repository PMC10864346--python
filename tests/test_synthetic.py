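"""Synthetic generator, pseudo-degradations, tiling and fold splitting."""

import numpy as np
import pytest
from scipy import ndimage

from aepseg.datatypes import DegradeSpec, Image2D, LabelMask, SyntheticSpec
from aepseg.synthetic import (
    SizingError,
    crop_tiles,
    degrade,
    gaussian_kernel_sigma,
    generate_dataset,
    generate_field,
    noise_field,
    split_kfold,
    _sample_centers,
    _voronoi_regions,
)


class TestGenerateDataset:
    def test_deterministic_under_fixed_seed(self):
        spec = SyntheticSpec(num_classes=3, image_size=(64, 64), seed=7)
        (img1, m1), = generate_dataset(spec)
        (img2, m2), = generate_dataset(spec)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert np.array_equal(m1.labels, m2.labels)

    def test_two_class_mask_values(self):
        spec = SyntheticSpec(num_classes=2, image_size=(64, 64), seed=3)
        (_, mask), = generate_dataset(spec)
        assert set(np.unique(mask.labels)) <= {0, 1}

    def test_all_classes_present_and_exhaustive(self):
        spec = SyntheticSpec(num_classes=3, image_size=(64, 64), seed=11)
        (img, mask), = generate_dataset(spec)
        assert set(np.unique(mask.labels)) == {0, 1, 2}
        assert img.shape == mask.shape

    def test_membrane_fraction_matches_boundary_tracing(self):
        """Membrane pixels equal a brute-force neighborhood scan for
        inter-cell borders on the underlying tessellation."""
        spec = SyntheticSpec(
            num_classes=3, image_size=(128, 128), cell_count_range=(4, 8), seed=1
        )
        (_, mask), = generate_dataset(spec)
        rng = np.random.default_rng(spec.seed)
        centers = _sample_centers(rng, spec)
        regions = _voronoi_regions(centers, spec.image_size)
        h, w = spec.image_size
        size = spec.membrane_thickness + 1
        lo, hi = size // 2, size - 1 - size // 2
        expected = np.zeros((h, w), dtype=bool)
        for i in range(h):
            for j in range(w):
                win = regions[
                    max(0, i - lo) : min(h, i + hi + 1), max(0, j - lo) : min(w, j + hi + 1)
                ]
                expected[i, j] = win.min() != win.max()
        assert np.array_equal(mask.labels == 1, expected)

    def test_nuclei_strictly_inside_cells(self):
        spec = SyntheticSpec(num_classes=3, image_size=(96, 96), seed=5)
        (_, mask), = generate_dataset(spec)
        nucleus = mask.labels == 2
        # every nucleus pixel is surrounded by non-membrane in its 4-neighborhood
        dilated = ndimage.binary_dilation(nucleus)
        assert not (dilated & (mask.labels == 1)).any()

    def test_sizing_error(self):
        spec = SyntheticSpec(num_classes=3, image_size=(8, 8), cell_count_range=(6, 6), seed=0)
        with pytest.raises(SizingError):
            generate_field(spec)

    def test_many_fields_are_distinct_but_reproducible(self):
        spec = SyntheticSpec(num_classes=3, image_size=(64, 64), seed=9)
        a = generate_dataset(spec, n=3)
        b = generate_dataset(spec, n=3)
        for (ia, ma), (ib, mb) in zip(a, b):
            assert np.array_equal(ia.pixels, ib.pixels)
        assert not np.array_equal(a[0][1].labels, a[1][1].labels)


class TestDegrade:
    def test_noise_statistics_match_spec(self):
        """The additive Gaussian field (mu=0, sigma=100) has sample mean
        within +/-1.5 and SD within +/-2.5 of nominal on a 256x256 draw, and
        the degraded image equals clip(x + field)."""
        spec = DegradeSpec(kind="noise", mu=0, sigma=100, seed=5)
        field = noise_field(spec, (256, 256))
        assert abs(field.mean()) < 1.5
        assert abs(field.std() - 100.0) < 2.5
        img = Image2D(np.full((256, 256), 128.0), "raw8")
        out = degrade(img, spec)
        assert np.array_equal(out.pixels, np.clip(128.0 + field, 0, 255))

    def test_contrast_shift_is_exact_clipped_subtraction(self):
        rng = np.random.default_rng(0)
        x = np.round(rng.uniform(0, 255, (32, 32)))
        out = degrade(Image2D(x, "raw8"), DegradeSpec(kind="contrast", mu=-100, sigma=0))
        assert np.array_equal(out.pixels, np.maximum(0.0, x - 100.0))

    def test_blur_of_constant_is_identity(self):
        img = Image2D(np.full((32, 32), 77.0), "raw8")
        out = degrade(img, DegradeSpec(kind="blur", kernel_size=5))
        np.testing.assert_allclose(out.pixels, 77.0, atol=1e-9)

    def test_blur_matches_bruteforce_mirror_convolution(self):
        """Blur equals an explicit normalized-Gaussian window sum with
        mirrored (reflect-101) border indexing."""
        rng = np.random.default_rng(1)
        x = rng.uniform(50, 200, (16, 16))
        k = 5
        out = degrade(Image2D(x, "raw8"), DegradeSpec(kind="blur", kernel_size=k))
        sigma = gaussian_kernel_sigma(k)
        r = k // 2
        off = np.arange(-r, r + 1)
        k1 = np.exp(-(off**2) / (2 * sigma**2))
        kern = np.outer(k1, k1) / np.outer(k1, k1).sum()

        def mirror(i, n):  # reflect about the edge pixel
            if i < 0:
                return -i
            if i >= n:
                return 2 * n - 2 - i
            return i

        expected = np.zeros_like(x)
        for i in range(16):
            for j in range(16):
                acc = 0.0
                for di in off:
                    for dj in off:
                        acc += (
                            kern[di + r, dj + r]
                            * x[mirror(i + di, 16), mirror(j + dj, 16)]
                        )
                expected[i, j] = acc
        np.testing.assert_allclose(out.pixels, expected, atol=1e-9)

    def test_blur_interior_mean_drift_is_small(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(50, 200, (64, 64))
        out = degrade(Image2D(x, "raw8"), DegradeSpec(kind="blur", kernel_size=5))
        assert abs(out.pixels[2:-2, 2:-2].mean() - x[2:-2, 2:-2].mean()) < 0.5

    def test_unit_range_image_rejected(self):
        img = Image2D(np.full((16, 16), 0.5), "unit")
        with pytest.raises(ValueError, match="raw 0-255"):
            degrade(img, DegradeSpec(kind="noise", sigma=10))

    def test_noise_deterministic_under_seed(self):
        img = Image2D(np.full((16, 16), 100.0), "raw8")
        spec = DegradeSpec(kind="noise", mu=0, sigma=20, seed=3)
        assert np.array_equal(degrade(img, spec).pixels, degrade(img, spec).pixels)


class TestCropTiles:
    def test_512_to_256_yields_four_tiles(self):
        x = np.arange(512 * 512, dtype=np.float64).reshape(512, 512) % 256
        img = Image2D(x, "raw8")
        mask = LabelMask((x > 128).astype(np.int64), 2)
        tiles = crop_tiles(img, mask, (256, 256))
        assert len(tiles) == 4

    def test_identity_tile(self):
        x = np.random.default_rng(0).uniform(0, 255, (256, 256))
        img = Image2D(x, "raw8")
        mask = LabelMask(np.zeros((256, 256), dtype=np.int64) , 2)
        tiles = crop_tiles(img, mask, (256, 256))
        assert len(tiles) == 1
        assert np.array_equal(tiles[0][0].pixels, x)

    def test_tiles_equal_direct_slicing_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 255, (64, 96))
        y = rng.integers(0, 3, (64, 96))
        tiles = crop_tiles(Image2D(x, "raw8"), LabelMask(y, 3), (32, 32))
        k = 0
        for i in range(2):
            for j in range(3):
                sl = (slice(32 * i, 32 * (i + 1)), slice(32 * j, 32 * (j + 1)))
                assert np.array_equal(tiles[k][0].pixels, x[sl])
                assert np.array_equal(tiles[k][1].labels, y[sl])
                k += 1

    def test_non_divisible_raises(self):
        img = Image2D(np.zeros((100, 100)), "raw8")
        mask = LabelMask(np.zeros((100, 100), dtype=np.int64), 2)
        with pytest.raises(ValueError, match="not divisible"):
            crop_tiles(img, mask, (64, 64))


class TestSplitKfold:
    @pytest.mark.parametrize(
        "N,k,sizes",
        [(50, 5, {10}), (10, 10, {1}), (11, 3, {4, 3})],
    )
    def test_fold_sizes(self, N, k, sizes):
        split = split_kfold(N, k, seed=0)
        counts = np.bincount(split.assignments, minlength=k)
        assert set(counts.tolist()) == sizes
        assert counts.sum() == N

    def test_partition_and_determinism(self):
        a = split_kfold(23, 4, seed=9)
        b = split_kfold(23, 4, seed=9)
        assert np.array_equal(a.assignments, b.assignments)
        assert a.content_hash() == b.content_hash()
        for f in range(4):
            tr, va = a.train_indices(f), a.fold_indices(f)
            assert np.array_equal(np.sort(np.concatenate([tr, va])), np.arange(23))

    def test_k_greater_than_n_raises(self):
        with pytest.raises(ValueError):
            split_kfold(3, 5, seed=0)
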