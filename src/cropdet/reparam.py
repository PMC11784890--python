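"""Structural re-parameterization: diverse-branch convolutions and the CFB
block.

During training a :class:`DBBConv` runs four parallel branches — a 3x3
convolution, a 1x1 convolution, a 1x1->3x3 sequence, and a 3x3 average
pool — each followed by its own batch normalization, and sums them.  At
deployment the branches collapse algebraically into one plain 3x3
convolution with bias, so the extra capacity costs nothing at inference.
The :class:`CFB` block is the split-bottleneck-concat (C2f) topology with
its bottleneck convolutions replaced by diverse-branch convolutions.

All fusion arithmetic is done in float64 on raw weight arrays; the branch
sum equals the fused convolution exactly in real arithmetic (batch norm in
eval mode), and to ~1e-6 relative in floating point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


@dataclass(frozen=True)
class ConvSpec:
    """Shape contract of a shape-preserving convolution."""

    in_ch: int
    out_ch: int
    kernel: int = 3
    stride: int = 1
    groups: int = 1
    has_norm: bool = True

    def __post_init__(self):
        if self.kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        if self.in_ch % self.groups or self.out_ch % self.groups:
            raise ValueError("groups must divide channel counts")

    @property
    def padding(self) -> int:
        return self.kernel // 2


@dataclass
class FusedConv:
    """A plain 3x3 convolution with bias — the deploy-time form."""

    weight: np.ndarray  # (out, in, 3, 3)
    bias: np.ndarray    # (out,)

    @property
    def param_count(self) -> int:
        return int(self.weight.size + self.bias.size)


# ---------------------------------------------------------------------------
# fusion arithmetic (pure numpy, float64)
# ---------------------------------------------------------------------------

def fuse_conv_bn(weight: np.ndarray, bias: np.ndarray | None,
                 mean: np.ndarray, var: np.ndarray,
                 scale: np.ndarray, shift: np.ndarray,
                 eps: float = 1e-5) -> tuple[np.ndarray, np.ndarray]:
    """Fold a per-channel affine normalization into the preceding conv.

    Returns (weight', bias') with conv(x; W', b') == BN(conv(x; W, b)).
    """
    weight = np.asarray(weight, dtype=np.float64)
    out_ch = weight.shape[0]
    for arr, name in ((mean, "mean"), (var, "var"), (scale, "scale"), (shift, "shift")):
        if np.asarray(arr).reshape(-1).shape[0] != out_ch:
            raise ValueError(f"norm stat {name} does not match {out_ch} channels")
    if np.any(np.asarray(var) + eps <= 0):
        raise ValueError("variance + eps must be positive")
    bias = np.zeros(out_ch) if bias is None else np.asarray(bias, dtype=np.float64)
    std = np.sqrt(np.asarray(var, dtype=np.float64) + eps)
    factor = np.asarray(scale, dtype=np.float64) / std
    w = weight * factor[:, None, None, None]
    b = np.asarray(shift, dtype=np.float64) + (bias - np.asarray(mean, dtype=np.float64)) * factor
    return w, b


def avgpool_to_conv(k: int, channels: int) -> np.ndarray:
    """Dense conv kernel equivalent to a stride-1 k x k average pool:
    channel-diagonal with every spatial entry 1/k^2."""
    if k % 2 == 0:
        raise ValueError("pooling window must be odd")
    w = np.zeros((channels, channels, k, k), dtype=np.float64)
    idx = np.arange(channels)
    w[idx, idx] = 1.0 / (k * k)
    return w


def merge_1x1_then_3x3(w1x1: np.ndarray, b1: np.ndarray | None,
                       w3x3: np.ndarray, b3: np.ndarray | None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Collapse conv1x1 (C->D) followed by conv3x3 (D->O) into one 3x3 conv.

    Valid under the convention that the intermediate map is padded with the
    1x1 branch's own bias value (see :class:`PadWithBias`), which is what
    makes the composition exact at borders.
    """
    w1 = np.asarray(w1x1, dtype=np.float64)
    w3 = np.asarray(w3x3, dtype=np.float64)
    if w1.shape[2:] != (1, 1):
        raise ValueError("first kernel must be 1x1")
    if w3.shape[1] != w1.shape[0]:
        raise ValueError(f"channel chain mismatch: {w3.shape[1]} vs {w1.shape[0]}")
    w = np.einsum("odhw,dc->ochw", w3, w1[:, :, 0, 0])
    b1 = np.zeros(w1.shape[0]) if b1 is None else np.asarray(b1, dtype=np.float64)
    b3 = np.zeros(w3.shape[0]) if b3 is None else np.asarray(b3, dtype=np.float64)
    b = b3 + np.einsum("odhw,d->o", w3, b1)
    return w, b


def embed_1x1_in_3x3(w1x1: np.ndarray) -> np.ndarray:
    """Place a 1x1 kernel at the centre of a zero 3x3 kernel."""
    o, c = w1x1.shape[0], w1x1.shape[1]
    w = np.zeros((o, c, 3, 3), dtype=np.float64)
    w[:, :, 1, 1] = np.asarray(w1x1, dtype=np.float64)[:, :, 0, 0]
    return w


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class ConvBN(nn.Module):
    """Convolution + batch norm (+ optional SiLU): the backbone workhorse."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 act: bool = True, padding: int | None = None):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, kernel, stride, padding, bias=False)
        self.bn = nn.BatchNorm2d(out_ch)
        self.act = act
        self.deployed = False

    def forward(self, x):
        if self.deployed:
            y = self.conv(x)
        else:
            y = self.bn(self.conv(x))
        return nn.silu(y) if self.act else y

    def deploy(self):
        """Fold the batch norm into the conv (weight + bias), in place."""
        if self.deployed:
            return self
        w, b = fuse_conv_bn(self.conv.weight.data, None, self.bn.running_mean,
                            self.bn.running_var, self.bn.weight.data,
                            self.bn.bias.data, self.bn.eps)
        conv = self.conv
        conv.weight = nn.Parameter(w)
        conv.bias = nn.Parameter(b)
        self._modules.pop("bn", None)
        del self.__dict__["bn"]
        self.deployed = True
        return self

    def fused(self) -> FusedConv:
        w, b = fuse_conv_bn(self.conv.weight.data, None, self.bn.running_mean,
                            self.bn.running_var, self.bn.weight.data,
                            self.bn.bias.data, self.bn.eps)
        if self.conv.kernel == 1:
            w = embed_1x1_in_3x3(w)
        return FusedConv(w, b)


class PadWithBias(nn.Module):
    """Pad spatially by 1, filling borders with a per-channel constant.

    Used between the 1x1 and 3x3 convs of the sequential branch so that the
    branch equals its fused single conv exactly, including at borders.
    """

    def __init__(self, channels: int):
        super().__init__()
        self.channels = channels

    def forward(self, x, bias_vec: Tensor):
        padded = nn.pad2d(x, 1)
        n, c, h, w = padded.shape
        mask = np.ones((1, 1, h, w), dtype=padded.dtype)
        mask[:, :, 1:-1, 1:-1] = 0.0
        return padded + Tensor(mask) * bias_vec.reshape(1, -1, 1, 1)


class DBBConv(nn.Module):
    """Diverse-branch 3x3 convolution: four branches in training, one fused
    conv at deployment.

    Branches (each ending in its own BatchNorm, summed before activation):
      * main 3x3 conv
      * 1x1 conv (embedded at the kernel centre when fused)
      * 1x1 -> 3x3 sequence (intermediate width = in channels)
      * 3x3 stride-1 average pool (omitted when stride > 1)
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1):
        super().__init__()
        self.in_ch, self.out_ch, self.stride = in_ch, out_ch, stride
        self.main = ConvBN(in_ch, out_ch, 3, stride, act=False)
        self.one = ConvBN(in_ch, out_ch, 1, stride, act=False)
        self.seq_1x1 = nn.Conv2d(in_ch, in_ch, 1, 1, bias=False)
        self.seq_bn1 = nn.BatchNorm2d(in_ch)
        self.seq_pad = PadWithBias(in_ch)
        self.seq_3x3 = nn.Conv2d(in_ch, out_ch, 3, stride, padding=0, bias=False)
        self.seq_bn2 = nn.BatchNorm2d(out_ch)
        self.has_pool = stride == 1
        if self.has_pool:
            self.pool_bn = nn.BatchNorm2d(in_ch)
            if in_ch != out_ch:
                raise ValueError("avg-pool branch requires in_ch == out_ch")
        self._fused: FusedConv | None = None
        self.deployed = False

    def forward(self, x):
        if self.deployed:
            f = self._fused
            return nn.conv2d(x, Tensor(f.weight), Tensor(f.bias), self.stride, 1)
        y = self.main(x) + self.one(x)
        # sequential branch with bias-value padding for exact fusability
        mid = self.seq_bn1(self.seq_1x1(x))
        mid_bias = self.seq_bn_bias()
        mid = self.seq_pad(mid, mid_bias)
        y = y + self.seq_bn2(self.seq_3x3(mid))
        if self.has_pool:
            y = y + self.pool_bn(nn.avg_pool2d(x, 3, self.stride, 1))
        return y

    def seq_bn_bias(self) -> Tensor:
        """Padding value of the sequential branch: the BN output at zero
        input in eval mode (= shift - scale * mean / std)."""
        std = np.sqrt(self.seq_bn1.running_var + self.seq_bn1.eps)
        val = self.seq_bn1.bias.data - self.seq_bn1.weight.data * self.seq_bn1.running_mean / std
        return Tensor(val)

    def fuse(self) -> FusedConv:
        """Collapse all branches into one 3x3 kernel + bias (eval-mode BN)."""
        if self.deployed:
            return self._fused
        w, b = self.main.fused().weight, self.main.fused().bias
        f1 = self.one.fused()
        w, b = w + f1.weight, b + f1.bias
        # sequential: fold BN1 into the 1x1 first, then merge with (3x3+BN2)
        w1, b1 = fuse_conv_bn(self.seq_1x1.weight.data, None,
                              self.seq_bn1.running_mean, self.seq_bn1.running_var,
                              self.seq_bn1.weight.data, self.seq_bn1.bias.data,
                              self.seq_bn1.eps)
        w3, b3 = fuse_conv_bn(self.seq_3x3.weight.data, None,
                              self.seq_bn2.running_mean, self.seq_bn2.running_var,
                              self.seq_bn2.weight.data, self.seq_bn2.bias.data,
                              self.seq_bn2.eps)
        ws, bs = merge_1x1_then_3x3(w1, b1, w3, b3)
        w, b = w + ws, b + bs
        if self.has_pool:
            wp, bp = fuse_conv_bn(avgpool_to_conv(3, self.in_ch), None,
                                  self.pool_bn.running_mean, self.pool_bn.running_var,
                                  self.pool_bn.weight.data, self.pool_bn.bias.data,
                                  self.pool_bn.eps)
            w, b = w + wp, b + bp
        self._fused = FusedConv(w, b)
        return self._fused

    def deploy(self):
        """Switch to single-branch inference.  The training branches are
        dropped so the parameter count equals a plain 3x3 conv with bias."""
        fused = self.fuse()
        self.deployed = True
        self._params.clear()
        self._modules.clear()
        self.weight = nn.Parameter(fused.weight)
        self.bias = nn.Parameter(fused.bias)
        self._fused = FusedConv(self.weight.data, self.bias.data)
        return self


def dbb_fuse(block: DBBConv) -> FusedConv:
    """Functional alias: fused kernel/bias of a diverse-branch conv."""
    return block.fuse()


class Bottleneck(nn.Module):
    """Two 3x3 convs with a residual add (the C2f inner unit)."""

    def __init__(self, ch: int, shortcut: bool = True, diverse: bool | str = False):
        super().__init__()
        # diverse: False = plain, True/"both" = both convs, "first" = first only
        first = diverse in (True, "both", "first")
        second = diverse in (True, "both")
        self.cv1 = DBBConv(ch, ch) if first else ConvBN(ch, ch, 3, act=False)
        self.cv2 = DBBConv(ch, ch) if second else ConvBN(ch, ch, 3, act=False)
        self.shortcut = shortcut

    def forward(self, x):
        y = nn.silu(self.cv2(nn.silu(self.cv1(x))))
        return x + y if self.shortcut else y


class C2f(nn.Module):
    """YOLOv8's split-bottleneck-concat block.

    cv1 projects to 2c, the tensor is split in half, n bottlenecks chain on
    the second half with every intermediate kept, and cv2 projects the
    (2 + n) c concatenation back to the output width.  With ``diverse`` set
    the bottleneck convolutions become diverse-branch convs, which is the
    CFB configuration.
    """

    def __init__(self, in_ch: int, out_ch: int, n: int = 1, shortcut: bool = True,
                 diverse: bool | str = False, e: float = 0.5):
        super().__init__()
        self.c = int(out_ch * e)
        self.cv1 = ConvBN(in_ch, 2 * self.c, 1)
        self.cv2 = ConvBN((2 + n) * self.c, out_ch, 1)
        self.blocks = nn.ModuleList(
            [Bottleneck(self.c, shortcut, diverse) for _ in range(n)])
        self.diverse = diverse

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.c]
        b = y[:, self.c:]
        outs = [a, b]
        for blk in self.blocks:
            outs.append(blk(outs[-1]))
        return self.cv2(nn.concatenate(outs, axis=1))

    def fuse(self):
        for blk in self.blocks:
            for cv in (blk.cv1, blk.cv2):
                if isinstance(cv, DBBConv):
                    cv.deploy()
        return self


def CFB(in_ch: int, out_ch: int, n: int = 1, shortcut: bool = True,
        diverse: bool | str = "both") -> C2f:
    """The C2f block with diverse-branch bottleneck convs (multi-branch in
    training, plain convs after ``.fuse()``)."""
    return C2f(in_ch, out_ch, n, shortcut, diverse=diverse)


def fuse_modules(root: nn.Module) -> nn.Module:
    """Deploy-fuse a whole module tree in place: every diverse-branch conv
    collapses to a single 3x3 conv, then every remaining conv+BN pair folds
    into a conv with bias.  Idempotent."""
    for m in list(root.modules()):
        if isinstance(m, DBBConv) and not m.deployed:
            m.deploy()
    for m in list(root.modules()):
        if isinstance(m, ConvBN) and not m.deployed:
            m.deploy()
    return root


def cfb_block(x, block: C2f, mode: str = "train"):
    """Run a CFB block in the requested mode.

    mode="deploy" requires ``block.fuse()`` to have been called first; this
    guards against silently evaluating un-fused branches.
    """
    if mode not in ("train", "deploy"):
        raise ValueError("mode must be 'train' or 'deploy'")
    if mode == "deploy":
        for m in block.modules():
            if isinstance(m, DBBConv) and not m.deployed:
                raise RuntimeError("deploy mode requested before fuse() was called")
    return block(x)
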