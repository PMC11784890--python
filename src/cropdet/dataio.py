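"""Annotation formats, preprocessing and run configuration.

COCO JSON is the canonical on-disk dialect (xywh, 0-based pixel
coordinates); YOLO text files (one per image, normalized ``class cx cy w
h`` lines) are supported for interop.  In memory everything is corner
format.  Letterboxing resizes with preserved aspect ratio and pads
symmetrically with 114-gray to the square network input, and the recorded
transform is invertible on box coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .boxes import xywh_to_xyxy, xyxy_to_xywh
from .losses import LossParams
from .metrics import DetectionRecord, GroundTruth

PAD_VALUE = 114


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# COCO JSON
# ---------------------------------------------------------------------------

def read_coco(path: str | Path) -> dict:
    """Load a COCO detection file, validating the keys we rely on."""
    with open(path) as f:
        data = json.load(f)
    for key in ("images", "annotations", "categories"):
        if key not in data:
            raise SchemaError(f"COCO file missing key: {key!r}")
    for ann in data["annotations"]:
        for key in ("image_id", "category_id", "bbox"):
            if key not in ann:
                raise SchemaError(f"annotation missing key: {key!r}")
        if len(ann["bbox"]) != 4:
            raise SchemaError("bbox must have 4 entries")
    return data


def write_coco(path: str | Path, data: dict):
    for key in ("images", "annotations", "categories"):
        if key not in data:
            raise SchemaError(f"COCO payload missing key: {key!r}")
    with open(path, "w") as f:
        json.dump(data, f)


def coco_to_records(data: dict) -> dict[int, GroundTruth]:
    """Group a COCO dict into per-image ground truth (boxes xyxy)."""
    by_img: dict[int, list] = {img["id"]: [] for img in data["images"]}
    for ann in data["annotations"]:
        by_img.setdefault(ann["image_id"], []).append(ann)
    out = {}
    for img_id, anns in by_img.items():
        if anns:
            boxes = xywh_to_xyxy(np.array([a["bbox"] for a in anns], dtype=float))
            labels = np.array([a["category_id"] for a in anns], dtype=int)
        else:
            boxes = np.zeros((0, 4))
            labels = np.zeros(0, dtype=int)
        out[img_id] = GroundTruth(boxes, labels)
    return out


def detections_to_coco(dets: dict[int, DetectionRecord], categories) -> dict:
    out = {"images": [{"id": int(i)} for i in dets],
           "annotations": [], "categories": list(categories)}
    ann_id = 1
    for img_id, rec in dets.items():
        for box, label, score in zip(rec.boxes, rec.labels, rec.scores):
            xywh = xyxy_to_xywh(box)
            out["annotations"].append({
                "id": ann_id, "image_id": int(img_id),
                "category_id": int(label),
                "bbox": [float(v) for v in xywh], "score": float(score),
                "area": float(xywh[2] * xywh[3]), "iscrowd": 0,
            })
            ann_id += 1
    return out


# ---------------------------------------------------------------------------
# YOLO txt
# ---------------------------------------------------------------------------

def read_yolo_txt(path: str | Path, num_classes: int | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """One file, lines ``class cx cy w h`` normalized.  Returns
    (boxes_normalized_xyxy, labels)."""
    boxes, labels = [], []
    text = Path(path).read_text().strip()
    if text:
        for line in text.splitlines():
            parts = line.split()
            if len(parts) != 5:
                raise SchemaError(f"malformed YOLO line: {line!r}")
            c = int(parts[0])
            if c < 0 or (num_classes is not None and c >= num_classes):
                raise SchemaError(f"class id {c} out of range")
            cx, cy, w, h = map(float, parts[1:])
            boxes.append([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2])
            labels.append(c)
    boxes = np.clip(np.array(boxes, dtype=float).reshape(-1, 4), 0.0, 1.0)
    return boxes, np.array(labels, dtype=int)


def write_yolo_txt(path: str | Path, boxes_xyxy_norm: np.ndarray,
                   labels: np.ndarray):
    lines = []
    for (x1, y1, x2, y2), c in zip(np.asarray(boxes_xyxy_norm).reshape(-1, 4),
                                   labels):
        cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
        lines.append(f"{int(c)} {cx:.6f} {cy:.6f} {x2 - x1:.6f} {y2 - y1:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# letterboxing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LetterboxTransform:
    """Affine map from original to network coordinates: scale then pad."""

    scale: float
    pad_x: float
    pad_y: float
    target: int
    src_w: int
    src_h: int

    def apply_boxes(self, boxes_xyxy: np.ndarray) -> np.ndarray:
        b = np.asarray(boxes_xyxy, dtype=float).copy().reshape(-1, 4)
        b *= self.scale
        b[:, [0, 2]] += self.pad_x
        b[:, [1, 3]] += self.pad_y
        return b

    def invert_boxes(self, boxes_xyxy: np.ndarray) -> np.ndarray:
        b = np.asarray(boxes_xyxy, dtype=float).copy().reshape(-1, 4)
        b[:, [0, 2]] -= self.pad_x
        b[:, [1, 3]] -= self.pad_y
        b /= self.scale
        b[:, [0, 2]] = np.clip(b[:, [0, 2]], 0, self.src_w)
        b[:, [1, 3]] = np.clip(b[:, [1, 3]], 0, self.src_h)
        return b


def letterbox(image: np.ndarray, boxes_xyxy: np.ndarray | None = None,
              target: int = 640) -> tuple[np.ndarray, np.ndarray, LetterboxTransform]:
    """Aspect-preserving resize + symmetric 114-gray pad to target x target."""
    h, w = image.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("empty image")
    scale = min(target / w, target / h)
    new_w, new_h = round(w * scale), round(h * scale)
    resized = _resize_bilinear(image, new_h, new_w)
    out = np.full((target, target, image.shape[2] if image.ndim == 3 else 1),
                  PAD_VALUE, dtype=image.dtype)
    pad_x = (target - new_w) // 2
    pad_y = (target - new_h) // 2
    out[pad_y:pad_y + new_h, pad_x:pad_x + new_w] = (
        resized if image.ndim == 3 else resized[..., None])
    tf = LetterboxTransform(scale, float(pad_x), float(pad_y), target, w, h)
    mapped = tf.apply_boxes(boxes_xyxy) if boxes_xyxy is not None else np.zeros((0, 4))
    return (out if image.ndim == 3 else out[..., 0]), mapped, tf


def _resize_bilinear(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear image resize (align_corners=False convention)."""
    h, w = img.shape[:2]
    if (out_h, out_w) == (h, w):
        return img.copy()
    sy = (np.arange(out_h) + 0.5) * h / out_h - 0.5
    sx = (np.arange(out_w) + 0.5) * w / out_w - 0.5
    y0 = np.clip(np.floor(sy).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(sx).astype(int), 0, w - 1)
    y1 = np.clip(y0 + 1, 0, h - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    ty = np.clip(sy - y0, 0, 1)[:, None]
    tx = np.clip(sx - x0, 0, 1)[None, :]
    im = img.astype(float)
    if img.ndim == 3:
        ty = ty[..., None]
        tx = tx[..., None]
    top = im[y0][:, x0] * (1 - ty) * (1 - tx) + im[y0][:, x1] * (1 - ty) * tx
    bot = im[y1][:, x0] * ty * (1 - tx) + im[y1][:, x1] * ty * tx
    out = top + bot
    return out.astype(img.dtype) if np.issubdtype(img.dtype, np.integer) else out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a training or evaluation run depends on."""

    model_size: str = "tiny"            # "tiny" | "s" | "l"
    num_classes: int = 5
    loss_name: str = "simiou"
    loss_params: LossParams = field(default_factory=LossParams)
    lr: float = 1e-4
    weight_decay: float = 1e-4
    warmup_steps: int = 2000
    epochs: int = 300
    batch_size: int = 4
    input_size: int = 640
    seed: int = 0
    use_cfb: bool = True
    use_lfpn: bool = True

    def __post_init__(self):
        from .losses import LOSS_NAMES
        if self.loss_name not in LOSS_NAMES:
            raise ValueError(f"loss must be one of {LOSS_NAMES}")

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        lp = raw.pop("loss_params", None)
        cfg = RunConfig(**raw)
        if lp:
            cfg.loss_params = LossParams(**lp)
        return cfg

    def to_yaml(self, path: str | Path):
        d = asdict(self)
        with open(path, "w") as f:
            yaml.safe_dump(d, f, sort_keys=False)
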