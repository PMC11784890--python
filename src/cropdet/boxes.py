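"""Axis-aligned bounding boxes and coordinate conventions.

In-memory convention is corner format ``(x1, y1, x2, y2)`` with ``x2 >= x1``
and ``y2 >= y1``; COCO files use ``(x, y, w, h)`` and YOLO text files use
normalized ``(cx, cy, w, h)``.  Conversion helpers here are the single place
those dialects meet.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class Frame(Enum):
    ABSOLUTE = "absolute"
    NORMALIZED = "normalized"


@dataclass(frozen=True)
class Box:
    """One rectangle, optionally carrying a class label and a score."""

    x1: float
    y1: float
    x2: float
    y2: float
    frame: Frame = Frame.ABSOLUTE
    label: int | None = None
    score: float | None = None

    def __post_init__(self):
        if not all(np.isfinite([self.x1, self.y1, self.x2, self.y2])):
            raise ValueError("box coordinates must be finite")
        if self.x2 < self.x1 or self.y2 < self.y1:
            raise ValueError(f"degenerate corner order: {self}")
        if self.frame is Frame.NORMALIZED:
            lo = min(self.x1, self.y1)
            hi = max(self.x2, self.y2)
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError("normalized box outside [0, 1]")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    def as_xyxy(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=float)

    def as_xywh(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.width, self.height], dtype=float)

    def as_cxcywh(self) -> np.ndarray:
        cx, cy = self.center
        return np.array([cx, cy, self.width, self.height], dtype=float)

    def scaled_about_center(self, ratio: float) -> "Box":
        if ratio <= 0:
            raise ValueError("ratio must be positive")
        cx, cy = self.center
        hw, hh = 0.5 * ratio * self.width, 0.5 * ratio * self.height
        return Box(cx - hw, cy - hh, cx + hw, cy + hh, frame=self.frame,
                   label=self.label, score=self.score)


def boxes_to_array(boxes) -> np.ndarray:
    """Coerce Box / sequence-of-4 / array input to a float array (..., 4)."""
    if isinstance(boxes, Box):
        return boxes.as_xyxy()
    if isinstance(boxes, (list, tuple)) and boxes and isinstance(boxes[0], Box):
        return np.stack([b.as_xyxy() for b in boxes])
    arr = np.asarray(boxes, dtype=float)
    if arr.shape[-1] != 4:
        raise ValueError("expected trailing dimension of 4")
    return arr


def xyxy_to_cxcywh(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    cx = 0.5 * (a[..., 0] + a[..., 2])
    cy = 0.5 * (a[..., 1] + a[..., 3])
    return np.stack([cx, cy, a[..., 2] - a[..., 0], a[..., 3] - a[..., 1]], axis=-1)


def cxcywh_to_xyxy(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    hw, hh = 0.5 * a[..., 2], 0.5 * a[..., 3]
    return np.stack([a[..., 0] - hw, a[..., 1] - hh,
                     a[..., 0] + hw, a[..., 1] + hh], axis=-1)


def xywh_to_xyxy(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return np.stack([a[..., 0], a[..., 1],
                     a[..., 0] + a[..., 2], a[..., 1] + a[..., 3]], axis=-1)


def xyxy_to_xywh(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return np.stack([a[..., 0], a[..., 1],
                     a[..., 2] - a[..., 0], a[..., 3] - a[..., 1]], axis=-1)
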