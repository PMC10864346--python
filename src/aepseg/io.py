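"""Dataset manifests, image/mask files, checkpoints, run configuration.

Images are 8-bit grayscale PNG (or TIFF); masks are single-channel indexed
PNG whose pixel value is the class id.  A dataset manifest is a JSON file
listing image/mask path pairs, the class count, the declared value range and
optional fold assignments plus provenance notes (the synthetic or
degradation spec that produced the data).  Images are normalized to [0, 1]
on load; masks are validated against the declared class count.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image as PILImage

from .datatypes import FoldSplit, Image2D, LabelMask
from .networks import NetworkConfig
from .training import TrainConfig, TrainedBundle
from .training import AwelConv

__all__ = [
    "DatasetManifest",
    "RunConfig",
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "save_dataset",
    "load_dataset",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class DatasetManifest:
    entries: list[tuple[str, str]]  # (image_path, mask_path), manifest-relative
    num_classes: int
    value_range: str = "raw8"
    folds: list[int] | None = None
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "entries": [list(e) for e in self.entries],
                "num_classes": self.num_classes,
                "value_range": self.value_range,
                "folds": self.folds,
                "provenance": self.provenance,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        d = json.loads(text)
        return cls(
            entries=[tuple(e) for e in d["entries"]],
            num_classes=d["num_classes"],
            value_range=d.get("value_range", "raw8"),
            folds=d.get("folds"),
            provenance=d.get("provenance", {}),
        )


def write_image(path: Path, image: Image2D) -> None:
    arr = image.pixels if image.value_range == "raw8" else image.pixels * 255.0
    PILImage.fromarray(np.clip(np.round(arr), 0, 255).astype(np.uint8), mode="L").save(path)


def read_image(path: Path, value_range: str = "raw8") -> Image2D:
    arr = np.asarray(PILImage.open(path).convert("L"), dtype=np.float64)
    img = Image2D(arr, "raw8")
    return img.to_unit() if value_range == "unit" else img


def write_mask(path: Path, mask: LabelMask) -> None:
    if mask.labels.max() > 255:
        raise ValueError("indexed PNG masks support at most 256 classes")
    PILImage.fromarray(mask.labels.astype(np.uint8), mode="L").save(path)


def read_mask(path: Path, num_classes: int) -> LabelMask:
    arr = np.asarray(PILImage.open(path), dtype=np.int64)
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be single-channel indexed PNG")
    if arr.max() >= num_classes:
        raise ValueError(
            f"{path}: mask contains class id {arr.max()} but num_classes={num_classes}"
        )
    return LabelMask(arr, num_classes)


def save_dataset(
    out_dir: Path,
    dataset: list[tuple[Image2D, LabelMask]],
    folds: FoldSplit | None = None,
    provenance: dict | None = None,
) -> Path:
    """Write images/masks plus a manifest.json; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (img, mask) in enumerate(dataset):
        ip, mp = f"image_{i:04d}.png", f"mask_{i:04d}.png"
        write_image(out_dir / ip, img)
        write_mask(out_dir / mp, mask)
        entries.append((ip, mp))
    manifest = DatasetManifest(
        entries=entries,
        num_classes=dataset[0][1].num_classes,
        value_range=dataset[0][0].value_range,
        folds=folds.assignments.tolist() if folds is not None else None,
        provenance=provenance or {},
    )
    path = out_dir / "manifest.json"
    path.write_text(manifest.to_json())
    return path


def load_dataset(
    manifest_path: Path, normalize: bool = True
) -> tuple[list[tuple[Image2D, LabelMask]], DatasetManifest]:
    """Load a manifest-described dataset; images normalized to unit range."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = DatasetManifest.from_json(manifest_path.read_text())
    root = manifest_path.parent
    dataset = []
    for ip, mp in manifest.entries:
        img_path, mask_path = root / ip, root / mp
        for p in (img_path, mask_path):
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
        img = read_image(img_path, "unit" if normalize else manifest.value_range)
        mask = read_mask(mask_path, manifest.num_classes)
        if img.shape != mask.shape:
            raise ValueError(f"{ip}/{mp}: image {img.shape} vs mask {mask.shape}")
        dataset.append((img, mask))
    return dataset, manifest


@dataclass
class RunConfig:
    """Serializable top-level run settings (training + network + paths)."""

    train: TrainConfig = field(default_factory=TrainConfig)
    data_dir: str = ""
    out_dir: str = "runs/run0"
    folds: int = 5
    log_level: str = "INFO"
    deterministic: bool = True

    def to_yaml(self) -> str:
        d = asdict(self.train)
        d["adam_betas"] = list(self.train.adam_betas)
        d["network"] = self.train.network.to_dict()
        return yaml.safe_dump(
            {
                "train": d,
                "data_dir": self.data_dir,
                "out_dir": self.out_dir,
                "folds": self.folds,
                "log_level": self.log_level,
                "deterministic": self.deterministic,
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        t = dict(d["train"])
        t["network"] = NetworkConfig.from_dict(t["network"])
        t["adam_betas"] = tuple(t["adam_betas"])
        return cls(
            train=TrainConfig(**t),
            data_dir=d.get("data_dir", ""),
            out_dir=d.get("out_dir", "runs/run0"),
            folds=d.get("folds", 5),
            log_level=d.get("log_level", "INFO"),
            deterministic=d.get("deterministic", True),
        )

    def fingerprint(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def save_checkpoint(path: Path, bundle: TrainedBundle) -> None:
    """Single-file checkpoint: npz arrays + embedded JSON config metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for prefix, mod in (("first.", bundle.first), ("second.", bundle.second)):
        for k, v in mod.state_arrays().items():
            arrays[prefix + k] = v
    arrays["awel.w"] = bundle.awel.w.data
    if bundle.awel.bias is not None:
        arrays["awel.bias"] = bundle.awel.bias.data
    meta = {
        "network": bundle.config.network.to_dict(),
        "train": {
            "batch_size": bundle.config.batch_size,
            "learning_rate": bundle.config.learning_rate,
            "adam_betas": list(bundle.config.adam_betas),
            "epochs": bundle.config.epochs,
            "seed": bundle.config.seed,
            "variant": bundle.config.variant,
            "awel_mode": bundle.config.awel_mode,
            "awel_bias": bundle.config.awel_bias,
            "filter_source": bundle.config.filter_source,
        },
        "fold": bundle.fold,
    }
    with open(path, "wb") as f:  # keep the exact filename (savez appends .npz)
        np.savez(f, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: Path) -> TrainedBundle:
    from .networks import build_first_network, build_second_network

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    net_cfg = NetworkConfig.from_dict(meta["network"])
    t = dict(meta["train"])
    t["adam_betas"] = tuple(t["adam_betas"])
    cfg = TrainConfig(network=net_cfg, **t)
    first = build_first_network(net_cfg)
    second = build_second_network(net_cfg)
    first.load_state_arrays(
        {k[len("first."):]: v for k, v in arrays.items() if k.startswith("first.")}
    )
    second.load_state_arrays(
        {k[len("second."):]: v for k, v in arrays.items() if k.startswith("second.")}
    )
    awel = AwelConv(1 + cfg.num_translated, cfg.awel_mode, bias=cfg.awel_bias,
                    dtype=net_cfg.np_dtype)
    awel.w.data[...] = arrays["awel.w"]
    if awel.bias is not None:
        awel.bias.data[...] = arrays["awel.bias"]
    return TrainedBundle(first, second, awel, cfg, fold=meta["fold"])
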