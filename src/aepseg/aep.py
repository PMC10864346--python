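"""Automatic enhancement preprocessing: activations -> translation filters.

The first network's penultimate feature maps (one channel per segmentation
class when the filter multiplier is 1) are passed through ReLU, then sigmoid,
and used as additive filters that translate a low-quality input image into
one enhanced image per filter channel.  ReLU discards negative information
that would erase object shapes; the sigmoid bounds the filter in (0, 1).

Two readings of the translation equation are supported, because the source
formula is ambiguous about where the sigmoid applies:

* ``"printed"`` (default): ``x_hat_c = x + sigmoid(relu(f_c))`` — the filter
  is squashed, then added; each translated pixel lies in [x+0.5, x+1).
* ``"text"``: ``x_hat_c = sigmoid(x + relu(f_c))`` — the sum is squashed, so
  translated images are normalized to (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .networks import softmax

Variant = Literal["printed", "text"]

__all__ = ["FilterStack", "TranslatedSet", "make_filters", "translate", "filters_from_output"]


def _sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t, dtype=np.result_type(t.dtype, np.float32))
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class FilterStack:
    """c translation filters plus the activation chain that produced them."""

    filters: np.ndarray  # (c, H, W)
    activation_record: str = "sigmoid(relu(.))"

    def __post_init__(self) -> None:
        self.filters = np.asarray(self.filters)
        if self.filters.ndim != 3:
            raise ValueError(f"filters must be (c, H, W), got {self.filters.shape}")

    @property
    def num_filters(self) -> int:
        return self.filters.shape[0]


@dataclass
class TranslatedSet:
    """One translated image per filter channel."""

    images: np.ndarray  # (c, H, W)
    variant: Variant = "printed"


def make_filters(preact: np.ndarray) -> FilterStack:
    """sigmoid(relu(.)) over penultimate-feature-map preactivations."""
    preact = np.asarray(preact)
    if not np.isfinite(preact).all():
        raise ValueError("filter preactivations must be finite")
    return FilterStack(_sigmoid(np.maximum(preact, 0.0)))


def translate(
    image: np.ndarray, filters: FilterStack, variant: Variant = "printed"
) -> TranslatedSet:
    """Add each translation filter to the input image (unit range).

    For the "text" variant the filters argument must carry the *pre-sigmoid*
    chain, so the function recovers relu(preact) from sigmoid(relu(preact))
    via the logit; callers in the training pipeline use
    :func:`translate_from_preact` instead, which avoids the round trip.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"image must be 2-D, got {image.shape}")
    if image.min() < -1e-9 or image.max() > 1 + 1e-9:
        raise ValueError("translate expects a unit-range image")
    if filters.filters.shape[1:] != image.shape:
        raise ValueError(
            f"filter spatial size {filters.filters.shape[1:]} does not match "
            f"image {image.shape}"
        )
    if variant == "printed":
        return TranslatedSet(image[None] + filters.filters, "printed")
    if variant == "text":
        # recover relu(preact) = logit(filter), then squash the sum
        f = np.clip(filters.filters, 1e-12, 1 - 1e-12)
        relu_pre = np.log(f / (1 - f))
        return TranslatedSet(_sigmoid(image[None] + np.maximum(relu_pre, 0.0)), "text")
    raise ValueError(f"unknown variant {variant!r}")


def translate_from_preact(
    image: np.ndarray, preact: np.ndarray, variant: Variant = "printed"
) -> TranslatedSet:
    """Translate directly from preactivations (no logit round trip)."""
    if variant == "printed":
        return TranslatedSet(image[None] + make_filters(preact).filters, "printed")
    if variant == "text":
        return TranslatedSet(_sigmoid(image[None] + np.maximum(preact, 0.0)), "text")
    raise ValueError(f"unknown variant {variant!r}")


def filters_from_output(logits: np.ndarray, mode: str) -> FilterStack:
    """Ablation filters built from the first network's C-channel output.

    raw: the output passed through the standard sigmoid(relu(.)) chain;
    softmax: class probabilities used as filters directly;
    argmax: per-pixel one-hot of the winning class (ties -> lowest index).
    """
    logits = np.asarray(logits)
    if not np.isfinite(logits).all():
        raise ValueError("logits must be finite")
    if logits.ndim != 3:
        raise ValueError(f"logits must be (C, H, W), got {logits.shape}")
    if mode == "raw":
        fs = make_filters(logits)
        fs.activation_record = "sigmoid(relu(output))"
        return fs
    if mode == "softmax":
        return FilterStack(softmax(logits, axis=0), "softmax(output)")
    if mode == "argmax":
        winners = np.argmax(logits, axis=0)
        onehot = (winners[None] == np.arange(logits.shape[0])[:, None, None]).astype(logits.dtype)
        return FilterStack(onehot, "argmax(output)")
    raise ValueError(f"unknown filter mode {mode!r}; expected raw|softmax|argmax")
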