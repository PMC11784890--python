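"""Synthetic overhead plantation scenes with COCO annotations.

The generator emulates the structure of UAV orchard surveys of oil palm:
a jittered planting grid of canopy blobs in five growth-status classes —
healthy, dead, grass (mismanaged), yellow and small — with the extreme
class imbalance of real surveys (healthy dominates, dead is rarest), a
large fraction of sub-32x32-px targets, a scene-wide illumination gradient
and sensor noise.  Rendering is fully procedural (no external assets) and
a pure function of (spec, seed): identical inputs give byte-identical
images and annotations.

Default class probabilities follow the training-split instance shares of a
262,811-instance oil-palm survey: healthy 0.766, small 0.216, yellow
0.0118, grass 0.0036, dead 0.0023.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

CLASS_NAMES = ("healthy", "dead", "grass", "yellow", "small")

# training-split instance counts of the reference survey
_TRAIN_COUNTS = {"healthy": 201303, "dead": 599, "grass": 953,
                 "yellow": 3103, "small": 56893}
_VAL_COUNTS = {"healthy": 24884, "dead": 61, "grass": 95,
               "yellow": 411, "small": 7395}

# canopy appearance: base RGB hue per class
_CLASS_COLOR = {
    "healthy": (45, 110, 40),
    "dead": (105, 82, 58),
    "grass": (95, 125, 50),
    "yellow": (165, 150, 45),
    "small": (60, 120, 55),
}
_SOIL_COLOR = np.array([120.0, 100.0, 75.0])


@dataclass(frozen=True)
class SceneSpec:
    """Generative parameters of one synthetic plantation image."""

    image_size: tuple[int, int] = (640, 640)        # (H, W)
    grid_spacing: int = 64                          # planting grid pitch, px
    jitter: float = 8.0                             # centre jitter sd, px
    n_plants_range: tuple[int, int] = (40, 80)      # occupied cells per scene
    class_probs: tuple[float, ...] = ()             # over CLASS_NAMES
    radius_mean: float = 13.0                       # canopy radius, px
    radius_sd: float = 3.0
    small_radius_mean: float = 7.0                  # the "small" class mode
    small_radius_sd: float = 1.5
    illumination: float = 0.25                      # gradient amplitude
    occlusion_prob: float = 0.1                     # chance of extra jitter
    noise_sd: float = 4.0                           # sensor noise, 8-bit units
    seed: int = 0

    def __post_init__(self):
        if not self.class_probs:
            object.__setattr__(self, "class_probs", default_class_probs("train"))
        p = np.asarray(self.class_probs, dtype=float)
        if len(p) != len(CLASS_NAMES):
            raise ValueError("need one probability per class")
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValueError("class probabilities must be a distribution")
        h, w = self.image_size
        if self.grid_spacing < 12 or self.grid_spacing > min(h, w):
            raise ValueError("grid too dense or too coarse for the image")

    def spec_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_class_probs(split: str = "train") -> tuple[float, ...]:
    """Class probabilities proportional to the reference survey's per-split
    instance counts."""
    counts = _TRAIN_COUNTS if split == "train" else _VAL_COUNTS
    total = sum(counts.values())
    return tuple(counts[c] / total for c in CLASS_NAMES)


def default_spec(split: str = "train", **overrides) -> SceneSpec:
    """The study-condition scene specification."""
    return SceneSpec(class_probs=default_class_probs(split), **overrides)


def _render_plant(img: np.ndarray, mask: np.ndarray, cx: float, cy: float,
                  radius: float, cls: str, rng: np.random.Generator):
    """Draw one canopy blob and record its pixel mask."""
    h, w = img.shape[:2]
    r_int = int(np.ceil(radius)) + 2
    x0, x1 = int(cx) - r_int, int(cx) + r_int + 1
    y0, y1 = int(cy) - r_int, int(cy) + r_int + 1
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - cx, ys - cy
    rr = np.sqrt(dx * dx + dy * dy)
    if cls == "grass":
        # irregular tuft: radius modulated around the rim
        ang = np.arctan2(dy, dx)
        k = rng.integers(3, 6)
        phase = rng.uniform(0, 2 * np.pi)
        local_r = radius * (1.0 + 0.35 * np.sin(k * ang + phase))
    else:
        local_r = radius
    inside = rr <= local_r
    if not inside.any():
        return None
    color = np.array(_CLASS_COLOR[cls], dtype=float)
    color = color * rng.uniform(0.85, 1.15)
    falloff = np.clip(1.0 - 0.5 * (rr / np.maximum(local_r, 1e-6)) ** 2, 0.0, 1.0)
    speckle = rng.normal(0.0, 12.0, size=rr.shape)
    patch = color[None, None, :] * falloff[..., None] + speckle[..., None]
    region = img[y0:y1, x0:x1]
    region[inside] = 0.35 * region[inside] + 0.65 * patch[inside]
    mask[y0:y1, x0:x1] |= inside
    ys_in, xs_in = np.nonzero(inside)
    # tight box from the rendered extent (renderer emits the annotation)
    return (x0 + xs_in.min(), y0 + ys_in.min(),
            x0 + xs_in.max() + 1, y0 + ys_in.max() + 1)


def generate_scene(spec: SceneSpec, seed: int | None = None
                   ) -> tuple[np.ndarray, list[dict]]:
    """Render one scene.

    Returns an (H, W, 3) uint8 image and a list of annotations
    ``{"bbox": [x, y, w, h], "category_id": int}`` in COCO pixel xywh.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5CE7E]))
    h, w = spec.image_size
    # soil / undergrowth background with low-frequency mottling
    base = np.tile(_SOIL_COLOR, (h, w, 1))
    coarse = rng.normal(0, 1, size=(h // 16 + 1, w // 16 + 1))
    mottle = np.kron(coarse, np.ones((16, 16)))[:h, :w]
    img = base + 18.0 * mottle[..., None] + rng.normal(0, 6.0, size=(h, w, 3))

    # occupied planting-grid cells
    s = spec.grid_spacing
    margin = s // 2
    cols = np.arange(margin, w - margin + 1, s)
    rows = np.arange(margin, h - margin + 1, s)
    cells = [(x, y) for y in rows for x in cols]
    if not cells:
        raise ValueError("grid too dense for image")
    lo, hi = spec.n_plants_range
    hi = min(hi, len(cells))
    lo = min(lo, hi)
    n = int(rng.integers(lo, hi + 1))
    chosen = rng.choice(len(cells), size=n, replace=False)

    mask = np.zeros((h, w), dtype=bool)
    annotations: list[dict] = []
    probs = np.asarray(spec.class_probs)
    for ci in sorted(chosen):
        gx, gy = cells[ci]
        jit = spec.jitter * (2.0 if rng.random() < spec.occlusion_prob else 1.0)
        cx = gx + rng.normal(0, jit)
        cy = gy + rng.normal(0, jit)
        cls = CLASS_NAMES[rng.choice(len(CLASS_NAMES), p=probs)]
        if cls == "small":
            radius = rng.normal(spec.small_radius_mean, spec.small_radius_sd)
            radius = float(np.clip(radius, 3.0, 12.0))
        else:
            radius = rng.normal(spec.radius_mean, spec.radius_sd)
            radius = float(np.clip(radius, 5.0, 26.0))
        cx = float(np.clip(cx, radius + 2, w - radius - 3))
        cy = float(np.clip(cy, radius + 2, h - radius - 3))
        box = _render_plant(img, mask, cx, cy, radius, cls, rng)
        if box is None:
            continue
        x1, y1, x2, y2 = box
        annotations.append({
            "bbox": [float(x1), float(y1), float(x2 - x1), float(y2 - y1)],
            "category_id": CLASS_NAMES.index(cls),
        })

    # scene-wide illumination gradient at a random orientation
    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = (np.cos(theta) * xx / max(w - 1, 1) + np.sin(theta) * yy / max(h - 1, 1))
    img = img * (1.0 + spec.illumination * (ramp[..., None] - 0.5))
    img = img + rng.normal(0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), annotations


def coco_skeleton() -> dict:
    return {
        "images": [],
        "annotations": [],
        "categories": [{"id": i, "name": n} for i, n in enumerate(CLASS_NAMES)],
    }


def generate_dataset(spec: SceneSpec, n_images: int, out_dir: str | Path,
                     split: str = "train", seed: int | None = None) -> dict:
    """Write `n_images` PNG scenes plus one COCO JSON for the split.

    Returns the manifest (also written to ``manifest_<split>.json``), which
    records the seed and a hash of the spec for provenance.
    """
    from PIL import Image

    out = Path(out_dir)
    img_dir = out / split
    img_dir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = spec.seed
    coco = coco_skeleton()
    ann_id = 1
    total = 0
    for i in range(n_images):
        img, anns = generate_scene(spec, seed=seed * 1_000_003 % (2 ** 31) + i)
        name = f"{split}_{i:05d}.png"
        Image.fromarray(img).save(img_dir / name)
        h, w = img.shape[:2]
        coco["images"].append({"id": i, "file_name": f"{split}/{name}",
                               "width": w, "height": h})
        for a in anns:
            coco["annotations"].append({
                "id": ann_id, "image_id": i, "category_id": a["category_id"],
                "bbox": a["bbox"], "area": a["bbox"][2] * a["bbox"][3],
                "iscrowd": 0,
            })
            ann_id += 1
        total += len(anns)
    ann_path = out / f"annotations_{split}.json"
    with open(ann_path, "w") as f:
        json.dump(coco, f)
    manifest = {
        "split": split, "n_images": n_images, "n_annotations": total,
        "seed": seed, "spec_hash": spec.spec_hash(),
        "annotations": str(ann_path.name),
    }
    with open(out / f"manifest_{split}.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest
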