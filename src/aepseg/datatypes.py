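"""Core value types shared across the pipeline.

Images are single-channel 2-D arrays with a declared value range:
``"raw8"`` means pixel values live on the 8-bit [0, 255] scale (the scale on
which the pseudo-degradations are defined), ``"unit"`` means [0, 1] (the
scale the networks consume).  Label masks are integer class-id arrays paired
with an image of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

ValueRange = Literal["raw8", "unit"]

_RANGE_BOUNDS: dict[str, tuple[float, float]] = {
    "raw8": (0.0, 255.0),
    "unit": (0.0, 1.0),
}


@dataclass
class Image2D:
    """Single-channel image with a declared value domain."""

    pixels: np.ndarray
    value_range: ValueRange = "unit"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"Image2D expects a 2-D array, got shape {self.pixels.shape}")
        h, w = self.pixels.shape
        if h < 8 or w < 8:
            raise ValueError(f"Image2D requires H, W >= 8, got {h}x{w}")
        if self.value_range not in _RANGE_BOUNDS:
            raise ValueError(f"unknown value_range {self.value_range!r}")
        lo, hi = _RANGE_BOUNDS[self.value_range]
        if not np.isfinite(self.pixels).all():
            raise ValueError("Image2D pixels must be finite")
        if self.pixels.min() < lo - 1e-9 or self.pixels.max() > hi + 1e-9:
            raise ValueError(
                f"pixels outside declared range {self.value_range} "
                f"[{lo}, {hi}]: observed [{self.pixels.min()}, {self.pixels.max()}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def to_unit(self) -> "Image2D":
        """Normalize to [0, 1] (training-time convention: divide by 255)."""
        if self.value_range == "unit":
            return self
        return Image2D(self.pixels / 255.0, "unit")


@dataclass
class LabelMask:
    """Per-pixel integer class ids in [0, num_classes)."""

    labels: np.ndarray
    num_classes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMask labels must be integers")
        self.labels = self.labels.astype(np.int64)
        if self.labels.ndim != 2:
            raise ValueError(f"LabelMask expects a 2-D array, got shape {self.labels.shape}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.labels.min() < 0 or self.labels.max() >= self.num_classes:
            raise ValueError(
                f"labels must lie in [0, {self.num_classes}); "
                f"observed [{self.labels.min()}, {self.labels.max()}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic multi-cell field generator.

    3-class mode renders cytoplasm(0) / membrane(1) / nucleus(2); 2-class
    mode renders background(0) / membrane(1).
    """

    num_classes: int = 3
    image_size: tuple[int, int] = (64, 64)
    cell_count_range: tuple[int, int] = (4, 8)
    membrane_thickness: int = 2
    nucleus_radius_fraction: float = 0.4
    texture_noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_classes not in (2, 3):
            raise ValueError("num_classes must be 2 or 3")
        if self.membrane_thickness < 1:
            raise ValueError("membrane_thickness must be >= 1")
        lo, hi = self.cell_count_range
        if lo > hi or lo < 1:
            raise ValueError("cell_count_range must satisfy 1 <= min <= max")
        if not (0.0 < self.nucleus_radius_fraction < 1.0):
            raise ValueError("nucleus_radius_fraction must lie in (0, 1)")
        if self.texture_noise_sd < 0:
            raise ValueError("texture_noise_sd must be >= 0")


@dataclass
class DegradeSpec:
    """One of the three pseudo-degradations, defined on the 8-bit scale.

    kind="noise": additive i.i.d. Gaussian(mu, sigma) samples, clipped.
    kind="contrast": a constant shift of mu everywhere (sigma = 0), clipped.
    kind="blur": convolution with a normalized 2-D Gaussian kernel.
    """

    kind: Literal["noise", "contrast", "blur"]
    mu: float = 0.0
    sigma: float = 0.0
    kernel_size: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("noise", "contrast", "blur"):
            raise ValueError(f"unknown degradation kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.kind == "noise" and self.sigma <= 0:
            raise ValueError("kind='noise' requires sigma > 0")
        if self.kind == "blur":
            if self.kernel_size < 3 or self.kernel_size % 2 == 0:
                raise ValueError("kind='blur' requires an odd kernel_size >= 3")


@dataclass
class FoldSplit:
    """A k-fold partition of sample indices [0, N)."""

    k: int
    assignments: np.ndarray  # sample index -> fold index
    N: int = field(default=0)

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=np.int64)
        if self.N == 0:
            self.N = int(self.assignments.size)
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.assignments.size != self.N:
            raise ValueError("assignments must cover all N samples")
        counts = np.bincount(self.assignments, minlength=self.k)
        if counts.size != self.k or counts.min() == 0:
            raise ValueError("folds must partition [0, N) with no empty fold")
        if counts.max() - counts.min() > 1:
            raise ValueError("fold sizes may differ by at most 1")

    def fold_indices(self, fold: int) -> np.ndarray:
        """Indices of samples held out in `fold`."""
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)

    def content_hash(self) -> str:
        import hashlib

        return hashlib.sha256(self.assignments.tobytes() + bytes([self.k])).hexdigest()[:16]
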