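"""Automatic weighted ensemble learning (AWEL).

S = 1 + m*C segmentation logit maps — the first network's output plus one
second-network output per translated image — are stacked along a source axis
and fused by a point-wise 3D convolution: a 1x1x1 kernel, stride 1, padding
0, computing only along the source axis.  That reduces to one trainable
scalar weight per source:

    fused[c, h, w] = sum_i  w_i * stack[i, c, h, w]  (+ optional bias)

Fixing all weights at 1 recovers the plain (unweighted) logit sum, the
fixed-weight ensemble control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnsembleStack",
    "AWELWeights",
    "stack_outputs",
    "awel_aggregate",
    "final_prediction",
    "read_weights",
]


@dataclass
class EnsembleStack:
    stack: np.ndarray  # (S, C, H, W)
    source_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.stack = np.asarray(self.stack)
        if self.stack.ndim != 4:
            raise ValueError(f"stack must be (S, C, H, W), got {self.stack.shape}")
        if not self.source_labels:
            self.source_labels = [f"source{i}" for i in range(self.stack.shape[0])]
        if len(self.source_labels) != self.stack.shape[0]:
            raise ValueError("source_labels must name every source")

    @property
    def S(self) -> int:
        return self.stack.shape[0]


@dataclass
class AWELWeights:
    w: np.ndarray
    bias: float | None = None
    trainable: bool = True

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.w.ndim != 1 or not np.isfinite(self.w).all():
            raise ValueError("weights must be a finite 1-D vector")

    @classmethod
    def initial(cls, S: int, bias: bool = False, trainable: bool = True) -> "AWELWeights":
        # start from an unweighted average so early training is a plain mean
        return cls(np.full(S, 1.0 / S), bias=0.0 if bias else None, trainable=trainable)

    @classmethod
    def fixed_ones(cls, S: int) -> "AWELWeights":
        return cls(np.ones(S), bias=None, trainable=False)


def stack_outputs(first: np.ndarray, translated_logits: list[np.ndarray]) -> EnsembleStack:
    """Order the sources: first network at index 0, then translated outputs."""
    first = np.asarray(first)
    if not translated_logits:
        raise ValueError("AWEL needs at least 2 sources; no translated logits given")
    maps = [first] + [np.asarray(t) for t in translated_logits]
    for i, m in enumerate(maps):
        if m.shape != first.shape:
            name = "first-network" if i == 0 else f"translated{i - 1}"
            raise ValueError(f"source {name} has shape {m.shape}, expected {first.shape}")
    labels = ["first-network"] + [f"translated{i}" for i in range(len(translated_logits))]
    return EnsembleStack(np.stack(maps, axis=0), labels)


def awel_aggregate(stack: EnsembleStack, weights: AWELWeights) -> np.ndarray:
    """Point-wise 3D convolution along the source axis."""
    if weights.w.size != stack.S:
        raise ValueError(f"{weights.w.size} weights for {stack.S} sources")
    fused = np.tensordot(weights.w, stack.stack, axes=(0, 0))
    if weights.bias is not None:
        fused = fused + weights.bias
    return fused


def final_prediction(fused: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over classes; ties break toward the lowest class id."""
    fused = np.asarray(fused)
    if not np.isfinite(fused).all():
        raise ValueError("fused logits must be finite")
    return np.argmax(fused, axis=0).astype(np.int64)


def read_weights(
    weights: AWELWeights | list[AWELWeights], source_labels: list[str] | None = None
) -> list[tuple[str, float]]:
    """Ordered (source_label, value) report; averages across checkpoints.

    Weights are reported as-is — they may legitimately be negative and must
    not be clamped.
    """
    ws = [weights] if isinstance(weights, AWELWeights) else list(weights)
    if not ws:
        raise ValueError("no weights to report")
    sizes = {w.w.size for w in ws}
    if len(sizes) != 1:
        raise ValueError("all checkpoints must share the same number of sources")
    mean = np.mean([w.w for w in ws], axis=0)
    labels = source_labels or ["first-network"] + [
        f"translated{i}" for i in range(mean.size - 1)
    ]
    if len(labels) != mean.size:
        raise ValueError("label count does not match weight count")
    return list(zip(labels, mean.tolist()))
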