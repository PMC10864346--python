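"""Segmentation metrics, classical preprocessing baselines, ablations.

Metrics are per-class intersection-over-union and Dice, computed from exact
integer confusion counts.  A class absent from both prediction and ground
truth (0/0) is excluded from that image's average rather than scored 0 or 1,
so images lacking a class do not inflate or deflate scores.  Metrics are
computed per image and then averaged over the evaluation set by default
(pooled-pixel aggregation is available via ``pooled=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .datatypes import FoldSplit, Image2D, LabelMask
from .training import TrainConfig, TrainedBundle, predict, train

__all__ = [
    "MetricsReport",
    "BaselineFilterSpec",
    "confusion_counts",
    "iou_dsc",
    "evaluate_masks",
    "aggregate_reports",
    "baseline_filter",
    "evaluate_bundle",
    "run_ablation",
]


@dataclass
class MetricsReport:
    per_class_iou: np.ndarray  # nan where the class is absent from both masks
    per_class_dsc: np.ndarray
    average_iou: float
    average_dsc: float
    fold_mean: dict[str, float] | None = None
    fold_sd: dict[str, float] | None = None


@dataclass
class BaselineFilterSpec:
    kind: str  # median | gaussian | bilateral | sobel | frangi
    kernel_size: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("median", "gaussian", "bilateral", "sobel", "frangi"):
            raise ValueError(f"unknown baseline filter {self.kind!r}")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and positive")


def confusion_counts(
    pred: LabelMask | np.ndarray, truth: LabelMask | np.ndarray, num_classes: int
) -> dict[str, np.ndarray]:
    """Exact per-class pixel counts: intersection, union, pred and truth sizes."""
    p = pred.labels if isinstance(pred, LabelMask) else np.asarray(pred)
    t = truth.labels if isinstance(truth, LabelMask) else np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if p.max() >= num_classes or t.max() >= num_classes or p.min() < 0 or t.min() < 0:
        raise ValueError(f"labels must lie in [0, {num_classes})")
    inter = np.bincount(p[p == t].ravel(), minlength=num_classes)
    pred_size = np.bincount(p.ravel(), minlength=num_classes)
    truth_size = np.bincount(t.ravel(), minlength=num_classes)
    union = pred_size + truth_size - inter
    return {
        "intersection": inter,
        "union": union,
        "pred_size": pred_size,
        "truth_size": truth_size,
    }


def iou_dsc(counts: dict[str, np.ndarray]) -> MetricsReport:
    """Per-class IoU/DSC from confusion counts, 0/0 classes excluded."""
    inter = counts["intersection"].astype(np.float64)
    union = counts["union"].astype(np.float64)
    denom = (counts["pred_size"] + counts["truth_size"]).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, np.nan)
        dsc = np.where(denom > 0, 2 * inter / denom, np.nan)
    return MetricsReport(
        per_class_iou=iou,
        per_class_dsc=dsc,
        average_iou=float(np.nanmean(iou)) if np.isfinite(iou).any() else float("nan"),
        average_dsc=float(np.nanmean(dsc)) if np.isfinite(dsc).any() else float("nan"),
    )


def evaluate_masks(
    preds: list[LabelMask], truths: list[LabelMask], pooled: bool = False
) -> MetricsReport:
    """Score a prediction set; per-image averaging by default."""
    if len(preds) != len(truths) or not preds:
        raise ValueError("need equal, nonzero numbers of predictions and truths")
    c = truths[0].num_classes
    if pooled:
        total = None
        for p, t in zip(preds, truths):
            cc = confusion_counts(p, t, c)
            total = cc if total is None else {k: total[k] + cc[k] for k in cc}
        return iou_dsc(total)
    reports = [iou_dsc(confusion_counts(p, t, c)) for p, t in zip(preds, truths)]
    iou = np.nanmean([r.per_class_iou for r in reports], axis=0)
    dsc = np.nanmean([r.per_class_dsc for r in reports], axis=0)
    return MetricsReport(
        per_class_iou=iou,
        per_class_dsc=dsc,
        average_iou=float(np.nanmean(iou)),
        average_dsc=float(np.nanmean(dsc)),
    )


def aggregate_reports(reports: list[MetricsReport]) -> MetricsReport:
    """Fold aggregation: mean +/- sd of the average metrics across folds."""
    if not reports:
        raise ValueError("no reports to aggregate")
    ious = np.array([r.average_iou for r in reports])
    dscs = np.array([r.average_dsc for r in reports])
    return MetricsReport(
        per_class_iou=np.nanmean([r.per_class_iou for r in reports], axis=0),
        per_class_dsc=np.nanmean([r.per_class_dsc for r in reports], axis=0),
        average_iou=float(ious.mean()),
        average_dsc=float(dscs.mean()),
        fold_mean={"iou": float(ious.mean()), "dsc": float(dscs.mean())},
        fold_sd={"iou": float(ious.std(ddof=0)), "dsc": float(dscs.std(ddof=0))},
    )


def baseline_filter(image: Image2D, spec: BaselineFilterSpec) -> Image2D:
    """Classical preprocessing filter, output rescaled to the unit range."""
    x = image.to_unit().pixels
    k = spec.kernel_size
    if spec.kind == "median":
        out = ndimage.median_filter(x, size=k, mode="mirror")
    elif spec.kind == "gaussian":
        from .synthetic import gaussian_kernel_sigma

        out = ndimage.gaussian_filter(
            x, sigma=gaussian_kernel_sigma(k), mode="mirror", truncate=(k - 1) / 2.0
        )
    elif spec.kind == "bilateral":
        from skimage.restoration import denoise_bilateral

        out = denoise_bilateral(x, win_size=k)
    elif spec.kind == "sobel":
        gx = ndimage.sobel(x, axis=1, mode="mirror")
        gy = ndimage.sobel(x, axis=0, mode="mirror")
        out = np.hypot(gx, gy)
        m = out.max()
        if m > 0:
            out = out / m
    else:  # frangi, library defaults
        from skimage.filters import frangi

        out = frangi(x)
        m = out.max()
        if m > 0:
            out = out / m
    return Image2D(np.clip(out, 0.0, 1.0), "unit")


def evaluate_bundle(
    bundle: TrainedBundle, dataset: list[tuple[Image2D, LabelMask]], indices: np.ndarray
) -> MetricsReport:
    preds = [predict(bundle, dataset[i][0]).mask for i in indices]
    truths = [dataset[i][1] for i in indices]
    return evaluate_masks(preds, truths)


_ABLATION_AXES = {
    "awel_mode": ["off", "fixed", "automated"],
    "filter_source": ["penultimate", "raw", "softmax", "argmax"],
    "filter_multiplier": [1, 2, 3, 4, 5],
}


def run_ablation(
    dataset: list[tuple[Image2D, LabelMask]],
    folds: FoldSplit,
    base_cfg: TrainConfig,
    axis: str,
    folds_to_run: list[int] | None = None,
) -> list[dict]:
    """One trained-and-evaluated row per axis value, same folds and seeds.

    Returns rows of {axis, value, report, fold_hash}; every row shares the
    fold assignment hash so the protocol (one variable at a time) is
    auditable.
    """
    if axis not in _ABLATION_AXES:
        raise ValueError(f"unknown ablation axis {axis!r}; one of {sorted(_ABLATION_AXES)}")
    rows = []
    run_folds = folds_to_run if folds_to_run is not None else list(range(folds.k))
    for value in _ABLATION_AXES[axis]:
        if axis == "awel_mode":
            cfg = replace(base_cfg, awel_mode=value)
        elif axis == "filter_source":
            cfg = replace(base_cfg, filter_source=value)
        else:
            cfg = replace(
                base_cfg, network=replace(base_cfg.network, filter_multiplier=value)
            )
        bundles, _hist = train(dataset, folds, cfg, folds_to_run=run_folds)
        reports = [
            evaluate_bundle(b, dataset, folds.fold_indices(b.fold)) for b in bundles
        ]
        rows.append(
            {
                "axis": axis,
                "value": value,
                "report": aggregate_reports(reports),
                "fold_hash": folds.content_hash(),
            }
        )
    return rows
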