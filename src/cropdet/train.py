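"""Training harness: seeded data order, AdamW with linear warm-up, and the
small-scale overfit recipe used to validate trainability on CPU.

All randomness (parameter initialization, batch order) flows from a single
integer seed.  Training runs in float32; fusion and all exactness-sensitive
math stay float64.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .boxes import xywh_to_xyxy, xyxy_to_cxcywh
from .dataio import RunConfig, letterbox
from .losses import LossParams
from .metrics import DetectionRecord, GroundTruth, evaluate
from .model import Detector, build_detector, predict, training_step
from .nn import Tensor
from .nn.optim import AdamW


@dataclass
class TrainSample:
    """One preprocessed image with normalized cxcywh targets."""

    image: np.ndarray          # (3, H, W) float in [0, 1]
    boxes: np.ndarray          # (m, 4) cxcywh normalized to the input size
    labels: np.ndarray         # (m,)


@dataclass
class TrainLog:
    steps: list[int] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)
    components: list[dict] = field(default_factory=list)
    wall_time: float = 0.0

    def final_loss(self) -> float:
        return self.losses[-1] if self.losses else float("nan")


def prepare_sample(image: np.ndarray, boxes_xyxy: np.ndarray,
                   labels: np.ndarray, input_size: int) -> TrainSample:
    """Letterbox one uint8 image and map its boxes to normalized cxcywh."""
    boxed, mapped, _ = letterbox(image, boxes_xyxy, input_size)
    chw = boxed.astype(np.float64).transpose(2, 0, 1) / 255.0
    cxcywh = xyxy_to_cxcywh(mapped) / input_size if len(mapped) else np.zeros((0, 4))
    return TrainSample(chw, cxcywh, np.asarray(labels, dtype=int))


def fit(model: Detector, samples: list[TrainSample], steps: int,
        batch_size: int = 4, lr: float = 1e-4, weight_decay: float = 1e-4,
        warmup_steps: int = 0, seed: int = 0, loss_name: str = "simiou",
        params: LossParams | None = None, log_every: int = 25,
        dtype=np.float32) -> TrainLog:
    """Gradient-train a detector on an in-memory sample list.

    Batches are drawn as seeded random permutations; the loop aborts with a
    diagnostic if the loss goes non-finite.
    """
    params = params or LossParams()
    rng = np.random.default_rng(seed)
    model.astype(dtype)
    model.train()
    prev_default = nn.tensor._DEFAULT_DTYPE
    nn.set_default_dtype(np.float32 if dtype == np.float32 else np.float64)
    opt = AdamW(model.parameters(), lr=lr, weight_decay=weight_decay,
                warmup_steps=warmup_steps)
    images = np.stack([s.image for s in samples]).astype(dtype)
    targets = [{"boxes": s.boxes, "labels": s.labels} for s in samples]
    log = TrainLog()
    t0 = time.time()
    try:
        for step in range(steps):
            idx = rng.permutation(len(samples))[:batch_size]
            loss, comps = training_step(model, Tensor(images[idx]),
                                        [targets[i] for i in idx],
                                        loss_name, params)
            opt.zero_grad()
            loss.backward()
            opt.step()
            if step % log_every == 0 or step == steps - 1:
                log.steps.append(step)
                log.losses.append(loss.item())
                log.components.append(dict(comps))
    finally:
        nn.set_default_dtype(prev_default)
    log.wall_time = time.time() - t0
    return log


def evaluate_on_samples(model: Detector, samples: list[TrainSample],
                        num_classes: int, top_k: int = 20):
    """Run NMS-free prediction on the (letterboxed) training images and
    score against their own annotations."""
    input_size = model.cfg.input_size
    dets, gts = [], []
    for s in samples:
        img = (s.image.transpose(1, 2, 0) * 255).astype(np.uint8)
        dets.append(predict(model, img, top_k=top_k))
        from .boxes import cxcywh_to_xyxy
        gts.append(GroundTruth(cxcywh_to_xyxy(s.boxes) * input_size, s.labels))
    return evaluate(dets, gts, num_classes)


def overfit_smoke(seed: int = 0, steps: int = 300, n_images: int = 8,
                  image_size: int = 160, verbose: bool = False):
    """The CPU trainability check: a tiny-width detector memorizes a handful
    of two-class synthetic scenes.

    Returns (train-set EvalResult, TrainLog).  The recipe — 8 images of
    160x160 with at most 5 objects from 2 classes, 300 steps of AdamW at
    lr 1e-3 with 50 warm-up steps, batch 4 — is fixed; only the seed varies.
    """
    from .scenes import SceneSpec, generate_scene

    spec = SceneSpec(image_size=(image_size, image_size), grid_spacing=48,
                     jitter=6.0, n_plants_range=(3, 5),
                     class_probs=(0.6, 0.0, 0.0, 0.0, 0.4), seed=seed)
    samples = []
    for i in range(n_images):
        img, anns = generate_scene(spec, 100 + seed * 1000 + i)
        boxes = xywh_to_xyxy(np.array([a["bbox"] for a in anns], dtype=float))
        labels = np.array([0 if a["category_id"] == 0 else 1 for a in anns])
        samples.append(prepare_sample(img, boxes, labels, image_size))
    model = build_detector("tiny", num_classes=2, seed=seed,
                           input_size=image_size)
    log = fit(model, samples, steps=steps, batch_size=4, lr=1e-3,
              weight_decay=1e-4, warmup_steps=50, seed=seed,
              log_every=25 if not verbose else 10)
    result = evaluate_on_samples(model, samples, num_classes=2)
    return result, log, model
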