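"""Detector assembly: hybrid CNN backbone + transformer encoder/decoder.

The architecture follows the RTYO recipe: a YOLOv8-style backbone (conv
stem, alternating strided convs and split-bottleneck C2f stages, SPPF
pooling on top) feeding strides 8/16/32 into a hybrid encoder — a single
transformer encoder layer (AIFI) on the deepest map with 2-D sine/cosine
positional coding, then a top-down + bottom-up fusion neck — and a query
decoder head with six layers that refines a fixed set of reference boxes
and emits classification logits.  Detections are the top-scoring queries;
there is no non-maximum suppression.

Variants:
* CFB: the stage-2 and stage-6 C2f blocks use diverse-branch bottleneck
  convolutions (multi-branch in training, fused to plain 3x3 at deploy).
* LFPN: the neck's interpolation upsamplers become CARAFE operators and
  each lateral branch is enhanced by an FEM/FSM gate before fusion.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import nn
from .boxes import cxcywh_to_xyxy
from .dataio import LetterboxTransform, letterbox
from .features import FEM, Carafe, sincos_pos_embed_2d
from .losses import LossParams, box_loss
from .metrics import DetectionRecord, GroundTruth
from .nn import Tensor
from .reparam import C2f, CFB, ConvBN, DBBConv, fuse_modules


@dataclass
class FeaturePyramid:
    """Multi-scale feature maps at strides 8, 16, 32."""

    p3: Tensor
    p4: Tensor
    p5: Tensor

    def as_list(self):
        return [self.p3, self.p4, self.p5]


@dataclass
class QuerySet:
    """Decoder state: content vectors plus normalized cxcywh references."""

    content: Tensor      # (B, nq, dim)
    reference: Tensor    # (B, nq, 4) in [0, 1]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The "l" preset reconstructs the full-scale hybrid (YOLOv8-L backbone
    widths/depths with an RT-DETR-L-style head); "tiny" is a fast CPU
    configuration for tests and demos.
    """

    channels: tuple[int, ...] = (64, 128, 256, 512, 512)
    depths: tuple[int, ...] = (3, 6, 6, 3)
    hidden_dim: int = 256
    num_heads: int = 8
    enc_ffn_dim: int = 1024
    dec_ffn_dim: int = 1024
    dec_layers: int = 6
    neck_depth: int = 3
    num_queries: int = 300
    num_classes: int = 5
    use_cfb: bool = True
    use_lfpn: bool = True
    cfb_both_convs: bool = True     # diverse-branch on both bottleneck convs
    input_size: int = 640

    @staticmethod
    def preset(size: str, **overrides) -> "ModelConfig":
        presets = {
            "l": dict(),
            "s": dict(channels=(32, 64, 128, 256, 256), depths=(1, 2, 2, 1),
                      hidden_dim=128, num_heads=8, enc_ffn_dim=512,
                      dec_ffn_dim=512, neck_depth=1, num_queries=100),
            "tiny": dict(channels=(8, 16, 32, 48, 48), depths=(1, 1, 1, 1),
                         hidden_dim=32, num_heads=4, enc_ffn_dim=64,
                         dec_ffn_dim=64, neck_depth=1, num_queries=30,
                         input_size=160),
        }
        if size not in presets:
            raise ValueError(f"unknown preset {size!r}")
        kw = presets[size]
        kw.update(overrides)
        return ModelConfig(**kw)


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max pools."""

    def __init__(self, ch: int):
        super().__init__()
        half = ch // 2
        self.cv1 = ConvBN(ch, half, 1)
        self.cv2 = ConvBN(half * 4, ch, 1)

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(nn.max_pool2d(y[-1], 5, 1, 2))
        return self.cv2(nn.concatenate(y, axis=1))


class Backbone(nn.Module):
    """Conv stem + four C2f stages; CFB replaces the stage-2 and stage-6
    blocks (layer indices of the ten-layer backbone) when enabled."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        c0, c1, c2, c3, c4 = cfg.channels
        d = cfg.depths
        diverse = ("both" if cfg.cfb_both_convs else "first") if cfg.use_cfb else False
        self.stem = ConvBN(3, c0, 3, 2)
        self.down1 = ConvBN(c0, c1, 3, 2)
        self.stage1 = C2f(c1, c1, d[0], shortcut=True, diverse=diverse)   # layer 2
        self.down2 = ConvBN(c1, c2, 3, 2)
        self.stage2 = C2f(c2, c2, d[1], shortcut=True)
        self.down3 = ConvBN(c2, c3, 3, 2)
        self.stage3 = C2f(c3, c3, d[2], shortcut=True, diverse=diverse)   # layer 6
        self.down4 = ConvBN(c3, c4, 3, 2)
        self.stage4 = C2f(c4, c4, d[3], shortcut=True)
        self.sppf = SPPF(c4)

    def forward(self, x) -> FeaturePyramid:
        h, w = x.shape[-2], x.shape[-1]
        if h % 32 or w % 32:
            raise ValueError("input spatial size must be divisible by 32")
        x = self.stage1(self.down1(self.stem(x)))
        p3 = self.stage2(self.down2(x))
        p4 = self.stage3(self.down3(p3))
        p5 = self.sppf(self.stage4(self.down4(p4)))
        return FeaturePyramid(p3, p4, p5)


def build_backbone(cfg: ModelConfig) -> Backbone:
    return Backbone(cfg)


# ---------------------------------------------------------------------------
# encoder (AIFI) and necks
# ---------------------------------------------------------------------------

class AIFI(nn.Module):
    """Single transformer encoder layer on the flattened deepest map with
    fixed 2-D sine/cosine position coding."""

    def __init__(self, dim: int, heads: int, ffn_dim: int):
        super().__init__()
        self.dim = dim
        self.layer = nn.TransformerEncoderLayer(dim, heads, ffn_dim)

    def forward(self, p5: Tensor) -> Tensor:
        b, c, h, w = p5.shape
        if c != self.dim:
            raise ValueError(f"channel dim {c} != model dim {self.dim}")
        tokens = p5.reshape(b, c, h * w).transpose(0, 2, 1)
        pos = Tensor(sincos_pos_embed_2d(h, w, c).reshape(1, h * w, c).astype(p5.dtype))
        out = self.layer(tokens, pos=pos)
        return out.transpose(0, 2, 1).reshape(b, c, h, w)


def aifi_encode(p5: Tensor, aifi: AIFI) -> Tensor:
    return aifi(p5)


class FusionBlock(nn.Module):
    """Two-path fusion after concatenation: 1x1 projections on both paths,
    a stack of 3x3 convs on the main path, summed (RepC3-style)."""

    def __init__(self, in_ch: int, out_ch: int, n: int):
        super().__init__()
        self.cv1 = ConvBN(in_ch, out_ch, 1)
        self.cv2 = ConvBN(in_ch, out_ch, 1)
        self.body = nn.Sequential(*[ConvBN(out_ch, out_ch, 3) for _ in range(n)])

    def forward(self, x):
        return self.body(self.cv1(x)) + self.cv2(x)


class Neck(nn.Module):
    """Top-down + bottom-up cross-scale fusion on projected hidden maps.

    Baseline: bilinear upsampling, plain lateral projections.  LFPN:
    CARAFE upsampling and FEM-enhanced lateral branches.
    """

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        h = cfg.hidden_dim
        n = cfg.neck_depth
        self.use_lfpn = cfg.use_lfpn
        self.lat5 = ConvBN(h, h, 1)
        self.lat4 = ConvBN(h, h, 1)
        self.fuse_td4 = FusionBlock(2 * h, h, n)
        self.fuse_td3 = FusionBlock(2 * h, h, n)
        self.down3 = ConvBN(h, h, 3, 2)
        self.fuse_bu4 = FusionBlock(2 * h, h, n)
        self.down4 = ConvBN(h, h, 3, 2)
        self.fuse_bu5 = FusionBlock(2 * h, h, n)
        if cfg.use_lfpn:
            self.up5 = Carafe(h)
            self.up4 = Carafe(h)
            self.fem3 = FEM(h)
            self.fem4 = FEM(h)
            self.fem5 = FEM(h)

    def _up(self, x, which: str):
        if self.use_lfpn:
            return (self.up5 if which == "5" else self.up4)(x)
        return nn.upsample2x(x, "bilinear")

    def forward(self, pyr: FeaturePyramid) -> FeaturePyramid:
        p3, p4, p5 = pyr.p3, pyr.p4, pyr.p5
        if self.use_lfpn:
            p3, p4, p5 = self.fem3(p3), self.fem4(p4), self.fem5(p5)
        t5 = self.lat5(p5)
        td4 = self.fuse_td4(nn.concatenate([self._up(t5, "5"), p4], axis=1))
        t4 = self.lat4(td4)
        td3 = self.fuse_td3(nn.concatenate([self._up(t4, "4"), p3], axis=1))
        bu4 = self.fuse_bu4(nn.concatenate([self.down3(td3), t4], axis=1))
        bu5 = self.fuse_bu5(nn.concatenate([self.down4(bu4), t5], axis=1))
        return FeaturePyramid(td3, bu4, bu5)


def lfpn_fuse(pyr: FeaturePyramid, neck: Neck) -> FeaturePyramid:
    return neck(pyr)


# ---------------------------------------------------------------------------
# decoder
# ---------------------------------------------------------------------------

def _inverse_sigmoid(x, eps: float = 1e-6):
    x = nn.clip(x, eps, 1.0 - eps)
    return nn.log(x / (1.0 - x))


class DecoderLayer(nn.Module):
    def __init__(self, dim: int, heads: int, ffn_dim: int):
        super().__init__()
        self.self_attn = nn.MultiheadAttention(dim, heads)
        self.norm1 = nn.LayerNorm(dim)
        self.cross_attn = nn.MultiheadAttention(dim, heads)
        self.norm2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, ffn_dim)
        self.fc2 = nn.Linear(ffn_dim, dim)
        self.norm3 = nn.LayerNorm(dim)

    def forward(self, tgt, memory, pos):
        q = tgt + pos
        tgt = self.norm1(tgt + self.self_attn(q, q, tgt))
        tgt = self.norm2(tgt + self.cross_attn(tgt + pos, memory, memory))
        tgt = self.norm3(tgt + self.fc2(nn.relu(self.fc1(tgt))))
        return tgt


class Decoder(nn.Module):
    """Six-layer query decoder with iterative sigmoid-space box refinement
    and per-layer (deep supervision) heads.  No NMS anywhere."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        d, nq = cfg.hidden_dim, cfg.num_queries
        self.cfg = cfg
        self.query_embed = nn.Parameter(
            np.random.default_rng(12345).normal(0, 0.02, size=(nq, d)))
        # reference boxes start on a regular grid with 10% width/height
        side = int(math.ceil(math.sqrt(nq)))
        gx, gy = np.meshgrid(np.linspace(0.1, 0.9, side), np.linspace(0.1, 0.9, side))
        pts = np.stack([gx.ravel(), gy.ravel()], axis=1)[:nq]
        ref = np.concatenate([pts, np.full((nq, 2), 0.1)], axis=1)
        self.ref_logit = nn.Parameter(np.log(ref / (1 - ref)))
        self.pos_head = nn.MLP(4, 2 * d, d, layers=2)
        self.layers = nn.ModuleList(
            [DecoderLayer(d, cfg.num_heads, cfg.dec_ffn_dim)
             for _ in range(cfg.dec_layers)])
        self.class_heads = nn.ModuleList(
            [nn.Linear(d, cfg.num_classes) for _ in range(cfg.dec_layers)])
        self.box_heads = nn.ModuleList(
            [nn.MLP(d, d, 4, layers=3) for _ in range(cfg.dec_layers)])
        for head in self.class_heads:
            # focal-friendly prior: rare positives at initialization
            head.bias.data[:] = -math.log((1 - 0.01) / 0.01)
        for head in self.box_heads:
            head.layers[-1].weight.data[:] = 0.0
            head.layers[-1].bias.data[:] = 0.0

    def forward(self, memory: Tensor) -> list[tuple[Tensor, Tensor]]:
        b = memory.shape[0]
        nq, d = self.query_embed.shape
        tile = Tensor(np.zeros((b, 1, 1), dtype=memory.dtype))
        tgt = self.query_embed.reshape(1, nq, d) + tile
        ref = nn.sigmoid(self.ref_logit).reshape(1, nq, 4) + tile
        outputs = []
        for layer, cls_head, box_head in zip(self.layers, self.class_heads,
                                             self.box_heads):
            pos = self.pos_head(ref.detach())
            tgt = layer(tgt, memory, pos)
            delta = box_head(tgt)
            # references are detached between layers (refined once per layer)
            # but the initial anchors stay trainable through layer 1
            new_ref = nn.sigmoid(_inverse_sigmoid(ref) + delta)
            outputs.append((cls_head(tgt), new_ref))
            ref = new_ref.detach()
        return outputs


def decode(queries: QuerySet, memory: Tensor, decoder: Decoder):
    return decoder(memory)


# ---------------------------------------------------------------------------
# full detector
# ---------------------------------------------------------------------------

class Detector(nn.Module):
    """RTYO-family detector.  ``use_cfb`` / ``use_lfpn`` select the plain
    baseline or the enhanced variants."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        h = cfg.hidden_dim
        self.backbone = Backbone(cfg)
        c2, c3, c4 = cfg.channels[2], cfg.channels[3], cfg.channels[4]
        self.proj3 = ConvBN(c2, h, 1, act=False)
        self.proj4 = ConvBN(c3, h, 1, act=False)
        self.proj5 = ConvBN(c4, h, 1, act=False)
        self.aifi = AIFI(h, cfg.num_heads, cfg.enc_ffn_dim)
        self.neck = Neck(cfg)
        self.decoder = Decoder(cfg)

    def forward(self, images: Tensor) -> list[tuple[Tensor, Tensor]]:
        pyr = self.backbone(images)
        proj = FeaturePyramid(self.proj3(pyr.p3), self.proj4(pyr.p4),
                              self.proj5(pyr.p5))
        proj.p5 = self.aifi(proj.p5)
        fused = self.neck(proj)
        toks = []
        for fm in fused.as_list():
            b, c, hh, ww = fm.shape
            toks.append(fm.reshape(b, c, hh * ww).transpose(0, 2, 1))
        memory = nn.concatenate(toks, axis=1)
        return self.decoder(memory)

    def fuse(self) -> "Detector":
        """In-place deploy fusion of every re-parameterizable block."""
        fuse_modules(self)
        return self


def build_detector(size: str = "l", num_classes: int = 5, use_cfb: bool = True,
                   use_lfpn: bool = True, seed: int = 0, **overrides) -> Detector:
    """Construct a detector with seeded initialization."""
    nn.seed_all(seed)
    cfg = ModelConfig.preset(size, num_classes=num_classes, use_cfb=use_cfb,
                             use_lfpn=use_lfpn, **overrides)
    return Detector(cfg)


def count_parameters(model: Detector, mode: str = "train") -> int:
    """Exact trainable-parameter count; mode="deploy" counts the fused
    single-branch form (the inference network)."""
    if mode == "train":
        return model.num_parameters()
    if mode != "deploy":
        raise ValueError("mode must be 'train' or 'deploy'")
    clone = copy.deepcopy(model)
    fuse_modules(clone)
    return clone.num_parameters()


def params_in_millions(count: int) -> float:
    return round(count / 1e6, 2)


# ---------------------------------------------------------------------------
# matching and training
# ---------------------------------------------------------------------------

def hungarian_match(logits: np.ndarray, boxes_cxcywh: np.ndarray,
                    gt_boxes_cxcywh: np.ndarray, gt_labels: np.ndarray,
                    w_cls: float = 2.0, w_l1: float = 5.0, w_iou: float = 2.0,
                    focal_alpha: float = 0.25, focal_gamma: float = 2.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """One-to-one assignment of queries to ground-truth objects.

    Cost = w_cls * focal-style class cost + w_l1 * L1(box) +
    w_iou * (1 - GIoU); solved exactly with the Hungarian algorithm.
    Returns (query_indices, gt_indices); empty when there is no gt.
    """
    n_gt = len(gt_labels)
    if n_gt == 0:
        return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
    nq = logits.shape[0]
    if n_gt > nq:
        raise ValueError("more ground-truth objects than queries")
    p = 1.0 / (1.0 + np.exp(-logits))                       # (nq, nc)
    pg = p[:, gt_labels]                                    # (nq, ngt)
    pos = focal_alpha * (1 - pg) ** focal_gamma * (-np.log(np.clip(pg, 1e-8, 1)))
    neg = (1 - focal_alpha) * pg ** focal_gamma * (-np.log(np.clip(1 - pg, 1e-8, 1)))
    cost_cls = pos - neg
    cost_l1 = np.abs(boxes_cxcywh[:, None, :] - gt_boxes_cxcywh[None, :, :]).sum(-1)
    a = cxcywh_to_xyxy(boxes_cxcywh)
    b = cxcywh_to_xyxy(gt_boxes_cxcywh)
    from .losses import giou as giou_fn
    cost_iou = np.zeros((nq, n_gt))
    for j in range(n_gt):
        cost_iou[:, j] = 1.0 - giou_fn(a, np.broadcast_to(b[j], a.shape))
    cost = w_cls * cost_cls + w_l1 * cost_l1 + w_iou * cost_iou
    qi, gi = linear_sum_assignment(cost)
    return qi, gi


def training_step(model: Detector, images: Tensor, targets: list[dict],
                  loss_name: str = "simiou",
                  params: LossParams | None = None) -> tuple[Tensor, dict]:
    """One supervised step: forward, per-layer Hungarian matching, focal
    classification on all queries plus (box loss + L1) on matched pairs,
    summed over decoder layers.  Returns (total loss tensor, components).

    `targets` per image: {"boxes": (m, 4) normalized cxcywh, "labels": (m,)}.
    """
    params = params or LossParams()
    outputs = model(images)
    bsz = images.shape[0]
    total = None
    comps = {"cls": 0.0, "box": 0.0, "l1": 0.0}
    for logits, boxes in outputs:
        layer_loss = None
        for i in range(bsz):
            gt = targets[i]
            gtb, gtl = np.asarray(gt["boxes"], float).reshape(-1, 4), np.asarray(gt["labels"], int)
            qi, gi = hungarian_match(logits.data[i], boxes.data[i], gtb, gtl,
                                     focal_alpha=params.focal_alpha,
                                     focal_gamma=params.focal_gamma)
            nq, nc = logits.shape[1], logits.shape[2]
            tgt_cls = np.zeros((nq, nc))
            if len(qi):
                tgt_cls[qi, gtl[gi]] = 1.0
            # sigmoid focal classification on every query/class
            lg = logits[i]
            pr = nn.sigmoid(lg)
            tc = Tensor(tgt_cls)
            pt = pr * tc + (1.0 - pr) * (1.0 - tc)
            alpha_t = params.focal_alpha * tc + (1 - params.focal_alpha) * (1.0 - tc)
            ce = -nn.log(nn.clip(pt, 1e-8, 1.0))
            focal = alpha_t * (1.0 - pt) ** params.focal_gamma * ce
            denom = max(len(qi), 1)
            cls_loss = focal.sum() * (1.0 / denom)
            comps["cls"] += cls_loss.item()
            img_loss = cls_loss
            if len(qi):
                pred = boxes[i][qi]
                gt_t = Tensor(gtb[gi])
                l1 = nn.absolute(pred - gt_t).sum() * (1.0 / denom)
                pred_xyxy = _cxcywh_to_xyxy_t(pred)
                gt_xyxy = Tensor(cxcywh_to_xyxy(gtb[gi]))
                bl = box_loss(loss_name, pred_xyxy, gt_xyxy, params)
                bl = bl.sum() * (1.0 / denom) if isinstance(bl, Tensor) else bl
                comps["l1"] += l1.item()
                comps["box"] += bl.item()
                img_loss = img_loss + 5.0 * l1 + 2.0 * bl
            layer_loss = img_loss if layer_loss is None else layer_loss + img_loss
        layer_loss = layer_loss * (1.0 / bsz)
        total = layer_loss if total is None else total + layer_loss
    if not np.isfinite(total.data):
        raise FloatingPointError(f"non-finite training loss: {total.data}")
    return total, comps


def _cxcywh_to_xyxy_t(b: Tensor) -> Tensor:
    cx, cy, w, h = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return nn.stack([cx - w * 0.5, cy - h * 0.5, cx + w * 0.5, cy + h * 0.5],
                    axis=-1)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict(model: Detector, image: np.ndarray, top_k: int = 100,
            score_threshold: float = 0.0) -> DetectionRecord:
    """Detect objects in one uint8 RGB image.  Letterboxes to the model's
    input size, runs the NMS-free forward pass and maps the top-k scoring
    query boxes back to original pixel coordinates."""
    cfg = model.cfg
    if top_k > cfg.num_queries * cfg.num_classes:
        raise ValueError("top_k exceeds number of query-class pairs")
    boxed, _, tf = letterbox(image, None, cfg.input_size)
    x = Tensor(boxed.astype(np.float64).transpose(2, 0, 1)[None] / 255.0)
    was_training = model.training
    model.eval()
    logits, boxes = model(x)[-1]
    if was_training:
        model.train()
    scores = 1.0 / (1.0 + np.exp(-logits.data[0]))          # (nq, nc)
    flat = scores.ravel()
    k = min(top_k, flat.size)
    idx = np.argpartition(-flat, k - 1)[:k]
    idx = idx[np.argsort(-flat[idx], kind="stable")]
    qi, ci = np.unravel_index(idx, scores.shape)
    keep = flat[idx] >= score_threshold
    qi, ci, sc = qi[keep], ci[keep], flat[idx][keep]
    xyxy = cxcywh_to_xyxy(boxes.data[0][qi]) * cfg.input_size
    orig = tf.invert_boxes(xyxy)
    return DetectionRecord(orig, ci, sc)
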