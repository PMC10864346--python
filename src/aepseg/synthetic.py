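"""Synthetic cell-field generator and pseudo-degradations.

The generator emulates multi-cell microscopy fields: a seeded Voronoi-like
tessellation produces closed membranes between touching cells, with nuclei
strictly inside cells (3-class mode) or a membrane/background field (2-class
mode).  Images are renderings of the mask (per-class base intensities plus
texture noise) on the 8-bit scale, so that the three pseudo-degradations —
additive Gaussian noise, a constant contrast shift, and Gaussian blur —
operate on the 0–255 scale on which their parameters are defined.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .datatypes import DegradeSpec, FoldSplit, Image2D, LabelMask, SyntheticSpec

__all__ = [
    "SizingError",
    "generate_dataset",
    "degrade",
    "crop_tiles",
    "split_kfold",
    "gaussian_kernel_sigma",
]

# Per-class base intensities on the 8-bit scale; chosen so classes are
# separable by intensity before degradation (cf. bright nuclei / dark
# membranes in stained micrographs).
_BASE_INTENSITY_3CLASS = {0: 160.0, 1: 70.0, 2: 230.0}  # cytoplasm/membrane/nucleus
_BASE_INTENSITY_2CLASS = {0: 170.0, 1: 60.0}  # background/membrane


class SizingError(ValueError):
    """Image too small to host the requested number of cells."""


def _sample_centers(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    h, w = spec.image_size
    lo, hi = spec.cell_count_range
    n = int(rng.integers(lo, hi + 1))
    # Each cell needs room for a membrane ring plus an interior; require a
    # ~6x6 px budget per cell and keep centers apart by a Poisson-disk rule.
    if n * 36 > h * w:
        raise SizingError(
            f"image_size {h}x{w} too small for up to {hi} cells "
            f"(need >= {n * 36} pixels for {n} cells)"
        )
    min_sep = 0.5 * np.sqrt(h * w / n)
    centers: list[tuple[float, float]] = []
    for _ in range(10_000):
        if len(centers) == n:
            break
        cand = (rng.uniform(0, h), rng.uniform(0, w))
        if all((cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 >= min_sep**2 for c in centers):
            centers.append(cand)
    if len(centers) < n:
        raise SizingError(
            f"could not place {n} separated cell centers in a {h}x{w} image"
        )
    return np.asarray(centers)


def _voronoi_regions(centers: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy[..., None] - centers[:, 0]) ** 2 + (xx[..., None] - centers[:, 1]) ** 2
    return np.argmin(d2, axis=-1)


def _membrane_from_regions(regions: np.ndarray, thickness: int) -> np.ndarray:
    """Pixels whose (thickness+1)-sized neighborhood spans >= 2 regions."""
    size = thickness + 1
    hi = ndimage.maximum_filter(regions, size=size, mode="nearest")
    lo = ndimage.minimum_filter(regions, size=size, mode="nearest")
    return hi != lo


def generate_dataset(spec: SyntheticSpec, n: int = 1) -> list[tuple[Image2D, LabelMask]]:
    """Generate n synthetic fields; deterministic under spec.seed.

    Per-field seeds are spawned from spec.seed so fields are independent but
    the whole dataset is reproducible bitwise.
    """
    if n == 1:
        return [generate_field(spec)]
    return generate_many(spec, n)


def generate_field(spec: SyntheticSpec) -> tuple[Image2D, LabelMask]:
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    centers = _sample_centers(rng, spec)
    regions = _voronoi_regions(centers, (h, w))
    membrane = _membrane_from_regions(regions, spec.membrane_thickness)

    labels = np.zeros((h, w), dtype=np.int64)
    labels[membrane] = 1

    if spec.num_classes == 3:
        # nucleus radius per cell: a fraction of the center's clearance from
        # the membrane so every nucleus sits strictly inside its cell
        clearance = ndimage.distance_transform_edt(~membrane)
        yy, xx = np.mgrid[0:h, 0:w]
        for i, (cy, cx) in enumerate(centers):
            iy, ix = int(round(cy)), int(round(cx))
            iy = min(max(iy, 0), h - 1)
            ix = min(max(ix, 0), w - 1)
            radius = max(1.0, spec.nucleus_radius_fraction * clearance[iy, ix])
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
            labels[disk & (regions == i) & (labels == 0)] = 2
        if not (labels == 2).any():  # degenerate fallback: seed pixel nuclei
            for cy, cx in centers:
                iy = min(max(int(round(cy)), 0), h - 1)
                ix = min(max(int(round(cx)), 0), w - 1)
                if labels[iy, ix] == 0:
                    labels[iy, ix] = 2

    base = _BASE_INTENSITY_3CLASS if spec.num_classes == 3 else _BASE_INTENSITY_2CLASS
    pixels = np.zeros((h, w), dtype=np.float64)
    for cls, val in base.items():
        pixels[labels == cls] = val
    if spec.texture_noise_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.texture_noise_sd, size=(h, w))
    pixels = np.clip(pixels, 0.0, 255.0)

    return Image2D(pixels, "raw8"), LabelMask(labels, spec.num_classes)


def generate_many(spec: SyntheticSpec, n: int) -> list[tuple[Image2D, LabelMask]]:
    """n independent fields with per-field seeds spawned from spec.seed."""
    seeds = np.random.SeedSequence(spec.seed).generate_state(n) % (2**31)
    out = []
    for s in seeds:
        sub = SyntheticSpec(
            num_classes=spec.num_classes,
            image_size=spec.image_size,
            cell_count_range=spec.cell_count_range,
            membrane_thickness=spec.membrane_thickness,
            nucleus_radius_fraction=spec.nucleus_radius_fraction,
            texture_noise_sd=spec.texture_noise_sd,
            seed=int(s),
        )
        out.append(generate_field(sub))
    return out


def gaussian_kernel_sigma(kernel_size: int) -> float:
    """Default blur sigma for a given kernel size (common CV convention)."""
    return 0.3 * ((kernel_size - 1) * 0.5 - 1) + 0.8


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    r = (size - 1) // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    k1 = np.exp(-(x**2) / (2 * sigma**2))
    k2 = np.outer(k1, k1)
    return k2 / k2.sum()


def noise_field(spec: DegradeSpec, shape: tuple[int, int]) -> np.ndarray:
    """The additive Gaussian sample field a noise/contrast degradation adds.

    Exposed separately because the clipped output image no longer carries the
    nominal (mu, sigma) statistics — clipping a sigma=100 field at the 8-bit
    bounds shrinks the observed SD substantially — so statistical checks of
    the degradation are made on this pre-clip field.
    """
    if spec.kind == "blur":
        raise ValueError("blur adds no noise field")
    rng = np.random.default_rng(spec.seed)
    if spec.sigma > 0:
        return rng.normal(spec.mu, spec.sigma, size=shape)
    return np.full(shape, float(spec.mu))


def degrade(image: Image2D, spec: DegradeSpec) -> Image2D:
    """Apply one pseudo-degradation on the 8-bit scale; output clipped."""
    if image.value_range != "raw8":
        raise ValueError(
            "degrade operates on the raw 0-255 scale; normalize to unit range "
            "only after degradation"
        )
    x = image.pixels
    if spec.kind in ("noise", "contrast"):
        out = x + noise_field(spec, x.shape)
    else:  # blur
        sigma = gaussian_kernel_sigma(spec.kernel_size)
        kernel = _gaussian_kernel(spec.kernel_size, sigma)
        out = ndimage.convolve(x, kernel, mode="mirror")
    return Image2D(np.clip(out, 0.0, 255.0), "raw8")


def crop_tiles(
    image: Image2D, mask: LabelMask, tile: tuple[int, int]
) -> list[tuple[Image2D, LabelMask]]:
    """Non-overlapping row-major tiles exactly covering the image."""
    th, tw = tile
    h, w = image.shape
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} disagree")
    if h % th or w % tw:
        raise ValueError(
            f"image {h}x{w} not divisible by tile {th}x{tw}; pad or pick a "
            "divisor tile size"
        )
    out = []
    for i in range(h // th):
        for j in range(w // tw):
            sl = (slice(i * th, (i + 1) * th), slice(j * tw, (j + 1) * tw))
            out.append(
                (
                    Image2D(image.pixels[sl], image.value_range),
                    LabelMask(mask.labels[sl], mask.num_classes),
                )
            )
    return out


def split_kfold(N: int, k: int, seed: int) -> FoldSplit:
    """Seeded permutation then contiguous chunking into k near-equal folds."""
    if k > N:
        raise ValueError(f"k={k} exceeds N={N}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    assignments = np.empty(N, dtype=np.int64)
    for fold, chunk in enumerate(np.array_split(perm, k)):
        assignments[chunk] = fold
    return FoldSplit(k=k, assignments=assignments, N=N)
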