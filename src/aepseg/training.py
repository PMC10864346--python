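"""Joint end-to-end training of both networks and the AWEL fusion weights.

The objective is the sum of softmax cross-entropy terms over every head:
the first network's segmentation output, the AWEL-fused output, and one term
per translated image segmented by the second network,

    Loss = CE_n1 + CE_n2 + sum_c CE_n3c

so gradients from the second network's losses flow back through the
translation filters into the first network's trunk, which is what lets the
filters learn to enhance the input without any high-quality reference image.
Cross-entropy is reduced by the mean over pixels and batch so the default
learning rate is scale-stable across image sizes.

Optimization follows the reference protocol: Adam(lr=1e-3, betas=(0.9,
0.999)), batch size 16, images normalized to [0, 1] with no other
preprocessing, k-fold cross-validation with seeded fold assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .datatypes import FoldSplit, Image2D, LabelMask
from .aep import FilterStack, TranslatedSet, _sigmoid
from .awel import AWELWeights
from .networks import (
    FirstNetwork,
    NetworkConfig,
    SecondNetwork,
    build_first_network,
    build_second_network,
    softmax,
)
from .nn.layers import Module, Parameter
from .nn.optim import Adam

AwelMode = Literal["automated", "fixed", "off"]

__all__ = [
    "LossBreakdown",
    "TrainConfig",
    "TrainedBundle",
    "PredictionResult",
    "ce_loss",
    "total_loss",
    "train",
    "train_single_network",
    "predict",
    "predict_single",
]


@dataclass
class LossBreakdown:
    ce_n1: float
    ce_n2: float
    ce_n3: list[float]
    total: float = 0.0

    def __post_init__(self) -> None:
        expected = self.ce_n1 + self.ce_n2 + float(sum(self.ce_n3))
        if self.total == 0.0:
            self.total = expected
        elif abs(self.total - expected) > 1e-6 * max(1.0, abs(expected)):
            raise ValueError("total must equal ce_n1 + ce_n2 + sum(ce_n3)")


@dataclass
class TrainConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    batch_size: int = 16
    learning_rate: float = 1e-3
    adam_betas: tuple[float, float] = (0.9, 0.999)
    epochs: int = 300
    seed: int = 0
    variant: Literal["printed", "text"] = "printed"
    awel_mode: AwelMode = "automated"
    awel_bias: bool = False
    filter_source: Literal["penultimate", "raw", "softmax", "argmax"] = "penultimate"

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.awel_mode not in ("automated", "fixed", "off"):
            raise ValueError(f"unknown awel_mode {self.awel_mode!r}")
        if self.variant not in ("printed", "text"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.filter_source not in ("penultimate", "raw", "softmax", "argmax"):
            raise ValueError(f"unknown filter_source {self.filter_source!r}")

    @property
    def num_translated(self) -> int:
        """Translated images per input: m*C from penultimate maps, C from
        output-based ablation filters."""
        if self.filter_source == "penultimate":
            return self.network.filter_channels
        return self.network.num_classes


@dataclass
class TrainedBundle:
    first: FirstNetwork
    second: SecondNetwork
    awel: "AwelConv"
    config: TrainConfig
    fold: int = 0

    def __post_init__(self) -> None:
        if self.first.cfg.num_classes != self.second.cfg.num_classes:
            raise ValueError("first/second network class counts disagree")
        if self.first.cfg.filter_multiplier != self.second.cfg.filter_multiplier:
            raise ValueError("first/second network filter multipliers disagree")

    def awel_weights(self) -> AWELWeights:
        return AWELWeights(
            self.awel.w.data.astype(np.float64).copy(),
            bias=float(self.awel.bias.data[0]) if self.awel.bias is not None else None,
            trainable=self.config.awel_mode == "automated",
        )


class AwelConv(Module):
    """Trainable point-wise 3D convolution over the source axis."""

    def __init__(self, S: int, mode: AwelMode, bias: bool = False, dtype=np.float32):
        self.S, self.mode = S, mode
        if mode == "fixed":
            init = np.ones(S, dtype=dtype)
        else:
            init = np.full(S, 1.0 / S, dtype=dtype)
        self.w = Parameter(init)
        self.bias = Parameter(np.zeros(1, dtype=dtype)) if bias else None
        self._stack: np.ndarray | None = None

    def parameters(self):
        if self.mode != "automated":
            return iter(())
        return super().parameters()

    def forward(self, stack: np.ndarray, training: bool) -> np.ndarray:
        self._stack = stack if training else None
        fused = np.einsum("s,bschw->bchw", self.w.data, stack)
        if self.bias is not None:
            fused = fused + self.bias.data[0]
        return fused

    def backward(self, gout: np.ndarray) -> np.ndarray:
        stack = self._stack
        if self.mode == "automated":
            self.w.grad += np.einsum("bchw,bschw->s", gout, stack)
            if self.bias is not None:
                self.bias.grad += gout.sum()
        gstack = self.w.data[None, :, None, None, None] * gout[:, None]
        self._stack = None
        return gstack


def _ce_with_grad(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient wrt logits.

    logits: (B, C, H, W); target: (B, H, W) integer class ids.
    """
    b, c, h, w = logits.shape
    if target.shape != (b, h, w):
        raise ValueError(f"target shape {target.shape} does not match logits {logits.shape}")
    if target.min() < 0 or target.max() >= c:
        raise ValueError(f"target labels must lie in [0, {c})")
    p = softmax(logits.astype(np.float64), axis=1)
    bi = np.arange(b)[:, None, None]
    hi = np.arange(h)[None, :, None]
    wi = np.arange(w)[None, None, :]
    true_p = p[bi, target, hi, wi]
    n = b * h * w
    loss = float(-np.log(np.clip(true_p, 1e-300, None)).sum() / n)
    onehot = np.zeros_like(p)
    onehot[bi, target, hi, wi] = 1.0
    grad = ((p - onehot) / n).astype(logits.dtype)
    return loss, grad


def ce_loss(logits: np.ndarray, target: np.ndarray) -> float:
    """Mean softmax cross-entropy; accepts (C,H,W)/(H,W) or batched arrays."""
    logits = np.asarray(logits, dtype=np.float64)
    target = np.asarray(target)
    if logits.ndim == 3:
        logits = logits[None]
        target = target[None]
    loss, _ = _ce_with_grad(logits, target)
    return loss


def total_loss(
    first_logits: np.ndarray,
    fused_logits: np.ndarray | None,
    translated_logits: list[np.ndarray],
    target: np.ndarray,
    awel_mode: AwelMode = "automated",
) -> LossBreakdown:
    """Summed objective: one CE term per head (2 + m*C terms when AWEL is on)."""
    if fused_logits is None and awel_mode != "off":
        raise ValueError("fused logits are required unless awel_mode='off'")
    ce1 = ce_loss(first_logits, target)
    ce2 = 0.0 if awel_mode == "off" else ce_loss(fused_logits, target)
    ce3 = [ce_loss(t, target) for t in translated_logits]
    return LossBreakdown(ce_n1=ce1, ce_n2=ce2, ce_n3=ce3)


class JointModel:
    """Forward/backward orchestration of first network -> filters ->
    translated images -> second network -> AWEL fusion."""

    def __init__(self, cfg: TrainConfig, init_seed_first: int, init_seed_second: int):
        net_cfg = cfg.network
        self.cfg = cfg
        self.first = build_first_network(replace(net_cfg, init_seed=init_seed_first))
        self.second = build_second_network(replace(net_cfg, init_seed=init_seed_second))
        self.S = 1 + cfg.num_translated
        self.awel = AwelConv(
            self.S, cfg.awel_mode, bias=cfg.awel_bias, dtype=net_cfg.np_dtype
        )

    def parameters(self) -> list[Parameter]:
        return (
            list(self.first.parameters())
            + list(self.second.parameters())
            + list(self.awel.parameters())
        )

    def _translate_forward(
        self, x: np.ndarray, pre: np.ndarray, logits1: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, dict]:
        """Build filters and translated images; cache what backward needs.

        The "text" reading of the translation (squash the sum) applies to the
        sources that use the sigmoid(relu(.)) chain — penultimate maps and
        raw outputs; softmax/argmax filters are probabilities already and are
        always added directly.
        """
        cfg = self.cfg
        src = cfg.filter_source
        if src in ("penultimate", "raw"):
            t = pre if src == "penultimate" else logits1
            if cfg.variant == "printed":
                fil = _sigmoid(np.maximum(t, 0.0))
                xhat = x + fil  # broadcast single input channel over filters
            else:
                fil = _sigmoid(np.maximum(t, 0.0))
                xhat = _sigmoid(x + np.maximum(t, 0.0))
            return xhat, fil, {"t": t, "fil": fil, "xhat": xhat}
        if src == "softmax":
            fil = softmax(logits1, axis=1)
            return x + fil, fil, {"fil": fil}
        # argmax: one-hot winners, treated as constants (non-differentiable)
        winners = np.argmax(logits1, axis=1)
        c = logits1.shape[1]
        fil = (winners[:, None] == np.arange(c)[None, :, None, None]).astype(x.dtype)
        return x + fil, fil, {}

    def _translate_backward(
        self, g_xhat: np.ndarray, cache: dict
    ) -> tuple[np.ndarray | None, np.ndarray | None]:
        """Gradients wrt (preact, logits1) from the translated-image gradient."""
        cfg = self.cfg
        src = cfg.filter_source
        if src in ("penultimate", "raw"):
            t, fil, xhat = cache["t"], cache["fil"], cache["xhat"]
            if cfg.variant == "printed":
                g_t = g_xhat * (fil * (1.0 - fil)) * (t > 0)
            else:
                g_t = g_xhat * (xhat * (1.0 - xhat)) * (t > 0)
            g_t = g_t.astype(t.dtype)
            return (g_t, None) if src == "penultimate" else (None, g_t)
        if src == "softmax":
            fil = cache["fil"]
            g_logits = fil * (g_xhat - (g_xhat * fil).sum(axis=1, keepdims=True))
            return None, g_logits.astype(fil.dtype)
        return None, None  # argmax: constant filters

    def forward_backward(self, x: np.ndarray, y: np.ndarray) -> LossBreakdown:
        """One training step's forward pass, loss, and full backward pass."""
        cfg = self.cfg
        b, _, h, w = x.shape
        nt = cfg.num_translated
        c = cfg.network.num_classes

        pre, logits1 = self.first.forward(x, training=True)
        xhat, _fil, cache = self._translate_forward(x, pre, logits1)
        logits2f = self.second.forward(xhat.reshape(b * nt, 1, h, w), training=True)
        logits2 = logits2f.reshape(b, nt, c, h, w)

        ce1, g1 = _ce_with_grad(logits1, y)
        ce3, g3 = [], np.empty_like(logits2)
        for i in range(nt):
            li, gi = _ce_with_grad(logits2[:, i], y)
            ce3.append(li)
            g3[:, i] = gi

        if cfg.awel_mode != "off":
            stack = np.concatenate([logits1[:, None], logits2], axis=1)
            fused = self.awel.forward(stack, training=True)
            ce2, gf = _ce_with_grad(fused, y)
            gstack = self.awel.backward(gf)
            g1 = g1 + gstack[:, 0]
            g3 = g3 + gstack[:, 1:]
        else:
            ce2 = 0.0

        g_xhat = self.second.backward(g3.reshape(b * nt, c, h, w)).reshape(b, nt, h, w)
        g_pre, g_logits1_extra = self._translate_backward(g_xhat, cache)
        if g_logits1_extra is not None:
            g1 = g1 + g_logits1_extra
        if g_pre is None:
            g_pre = np.zeros_like(pre)
        self.first.backward(g_pre, g1.astype(logits1.dtype))
        return LossBreakdown(ce_n1=ce1, ce_n2=ce2, ce_n3=ce3)

    def infer(self, x: np.ndarray) -> dict:
        """Evaluation-mode forward pass returning all intermediate artifacts."""
        cfg = self.cfg
        b, _, h, w = x.shape
        nt = cfg.num_translated
        c = cfg.network.num_classes
        pre, logits1 = self.first.forward(x, training=False)
        xhat, fil, _cache = self._translate_forward(x, pre, logits1)
        logits2 = self.second.forward(xhat.reshape(b * nt, 1, h, w), training=False)
        logits2 = logits2.reshape(b, nt, c, h, w)
        if cfg.awel_mode != "off":
            stack = np.concatenate([logits1[:, None], logits2], axis=1)
            fused = self.awel.forward(stack, training=False)
        else:
            stack = np.concatenate([logits1[:, None], logits2], axis=1)
            fused = logits2.mean(axis=1)
        return {
            "preact": pre,
            "filters": fil,
            "translated": xhat,
            "logits_first": logits1,
            "logits_translated": logits2,
            "stack": stack,
            "fused": fused,
            "mask": np.argmax(fused, axis=1).astype(np.int64),
        }


def _dataset_arrays(
    dataset: list[tuple[Image2D, LabelMask]], dtype
) -> tuple[np.ndarray, np.ndarray, int]:
    xs, ys = [], []
    num_classes = dataset[0][1].num_classes
    for img, mask in dataset:
        if img.shape != mask.shape:
            raise ValueError("image/mask shape mismatch in dataset")
        if mask.num_classes != num_classes:
            raise ValueError("inconsistent num_classes across dataset")
        xs.append(img.to_unit().pixels.astype(dtype))
        ys.append(mask.labels)
    return np.stack(xs)[:, None], np.stack(ys), num_classes


def _mean_iou(pred: np.ndarray, truth: np.ndarray, c: int) -> float:
    # lightweight mIoU for the per-epoch history (full metrics live in
    # aepseg.evaluation); classes absent from both masks are skipped
    ious = []
    for cls in range(c):
        p, t = pred == cls, truth == cls
        union = (p | t).sum()
        if union:
            ious.append((p & t).sum() / union)
    return float(np.mean(ious)) if ious else float("nan")


def train(
    dataset: list[tuple[Image2D, LabelMask]],
    folds: FoldSplit,
    cfg: TrainConfig,
    folds_to_run: list[int] | None = None,
    log=None,
) -> tuple[list[TrainedBundle], list[list[dict]]]:
    """Train one joint model per fold; returns bundles and per-epoch history."""
    x_all, y_all, num_classes = _dataset_arrays(dataset, cfg.network.np_dtype)
    if num_classes != cfg.network.num_classes:
        raise ValueError(
            f"dataset has {num_classes} classes but config expects "
            f"{cfg.network.num_classes}"
        )
    bundles, histories = [], []
    for fold in folds_to_run if folds_to_run is not None else range(folds.k):
        ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(fold,))
        seeds = ss.generate_state(3) % (2**31)
        model = JointModel(cfg, int(seeds[0]), int(seeds[1]))
        shuffle_rng = np.random.default_rng(int(seeds[2]))
        opt = Adam(model.parameters(), lr=cfg.learning_rate, betas=cfg.adam_betas)
        tr_idx = folds.train_indices(fold)
        va_idx = folds.fold_indices(fold)
        history: list[dict] = []
        for epoch in range(1, cfg.epochs + 1):
            perm = shuffle_rng.permutation(tr_idx)
            sums = np.zeros(3)
            nb = 0
            ce3_sum = 0.0
            for start in range(0, perm.size, cfg.batch_size):
                idx = perm[start : start + cfg.batch_size]
                opt.zero_grad()
                bd = model.forward_backward(x_all[idx], y_all[idx])
                opt.step()
                sums += (bd.ce_n1, bd.ce_n2, bd.total)
                ce3_sum += float(np.mean(bd.ce_n3))
                nb += 1
            preds = _predict_masks(model, x_all[va_idx])
            row = {
                "epoch": epoch,
                "ce_n1": sums[0] / nb,
                "ce_n2": sums[1] / nb,
                "ce_n3_mean": ce3_sum / nb,
                "total": sums[2] / nb,
                "val_miou": _mean_iou(preds, y_all[va_idx], num_classes),
            }
            history.append(row)
            if log is not None:
                log(fold, row)
        bundles.append(
            TrainedBundle(model.first, model.second, model.awel, cfg, fold=fold)
        )
        histories.append(history)
    return bundles, histories


def _predict_masks(model: JointModel, x: np.ndarray, chunk: int = 8) -> np.ndarray:
    out = []
    for start in range(0, x.shape[0], chunk):
        out.append(model.infer(x[start : start + chunk])["mask"])
    return np.concatenate(out, axis=0)


@dataclass
class PredictionResult:
    mask: LabelMask
    filters: FilterStack
    translated: TranslatedSet
    logits_first: np.ndarray
    logits_translated: np.ndarray  # (m*C, C, H, W)
    stack: np.ndarray  # (S, C, H, W)
    fused: np.ndarray  # (C, H, W)


def predict(bundle: TrainedBundle, image: Image2D) -> PredictionResult:
    """Full pipeline on one image: filters, translations, fusion, mask."""
    cfg = bundle.config
    x = image.to_unit().pixels.astype(cfg.network.np_dtype)[None, None]
    model = JointModel.__new__(JointModel)
    model.cfg = cfg
    model.first, model.second, model.awel = bundle.first, bundle.second, bundle.awel
    out = model.infer(x)
    return PredictionResult(
        mask=LabelMask(out["mask"][0], cfg.network.num_classes),
        filters=FilterStack(np.asarray(out["filters"][0], dtype=np.float64)),
        translated=TranslatedSet(
            np.asarray(out["translated"][0], dtype=np.float64), cfg.variant
        ),
        logits_first=out["logits_first"][0],
        logits_translated=out["logits_translated"][0],
        stack=out["stack"][0],
        fused=out["fused"][0],
    )


# ---------------------------------------------------------------------------
# plain single-network trainer: the "without preprocessing" control, also
# reused for classical-filter baselines (the filter is applied to the data
# beforehand, training is otherwise identical)
# ---------------------------------------------------------------------------


def train_single_network(
    dataset: list[tuple[Image2D, LabelMask]],
    folds: FoldSplit,
    cfg: TrainConfig,
    folds_to_run: list[int] | None = None,
) -> tuple[list[SecondNetwork], list[list[dict]]]:
    x_all, y_all, num_classes = _dataset_arrays(dataset, cfg.network.np_dtype)
    if num_classes != cfg.network.num_classes:
        raise ValueError("dataset/config class mismatch")
    nets, histories = [], []
    for fold in folds_to_run if folds_to_run is not None else range(folds.k):
        ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(fold,))
        seeds = ss.generate_state(3) % (2**31)
        net = build_second_network(replace(cfg.network, init_seed=int(seeds[0])))
        shuffle_rng = np.random.default_rng(int(seeds[2]))
        opt = Adam(list(net.parameters()), lr=cfg.learning_rate, betas=cfg.adam_betas)
        tr_idx = folds.train_indices(fold)
        va_idx = folds.fold_indices(fold)
        history = []
        for epoch in range(1, cfg.epochs + 1):
            perm = shuffle_rng.permutation(tr_idx)
            tot, nb = 0.0, 0
            for start in range(0, perm.size, cfg.batch_size):
                idx = perm[start : start + cfg.batch_size]
                opt.zero_grad()
                logits = net.forward(x_all[idx], training=True)
                loss, g = _ce_with_grad(logits, y_all[idx])
                net.backward(g)
                opt.step()
                tot += loss
                nb += 1
            preds = []
            for start in range(0, va_idx.size, 8):
                sl = va_idx[start : start + 8]
                preds.append(
                    np.argmax(net.forward(x_all[sl], training=False), axis=1)
                )
            preds = np.concatenate(preds, axis=0)
            history.append(
                {
                    "epoch": epoch,
                    "total": tot / nb,
                    "val_miou": _mean_iou(preds, y_all[va_idx], num_classes),
                }
            )
        nets.append(net)
        histories.append(history)
    return nets, histories


def predict_single(net: SecondNetwork, image: Image2D) -> LabelMask:
    x = image.to_unit().pixels.astype(net.cfg.np_dtype)[None, None]
    logits = net.forward(x, training=False)
    return LabelMask(np.argmax(logits, axis=1)[0].astype(np.int64), net.cfg.num_classes)
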