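"""Feature-map operators of the LFPN neck and the AIFI encoder.

* :class:`Carafe` — content-aware reassembly upsampling: a lightweight
  predictor derives a softmax-normalized ``k_up x k_up`` kernel for every
  output location and the output is the corresponding convex combination of
  the source neighborhood, so upsampling follows the content instead of a
  fixed interpolation stencil.
* :class:`FEM` — channel enhancement for lateral branches: average-pool the
  map along height and along width, squeeze the two directional descriptors
  through a shared bottleneck into a per-channel sigmoid gate, add the gated
  values back residually, then screen channels with a 1x1 projection.
* :func:`sincos_pos_embed_2d` — the fixed 2-D sine/cosine positional code
  added before the transformer encoder layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .reparam import ConvBN


@dataclass(frozen=True)
class CarafeConfig:
    compressed_ch: int = 64
    k_encoder: int = 3
    k_up: int = 5
    scale: int = 2

    def __post_init__(self):
        if self.scale < 2:
            raise ValueError("scale must be >= 2")
        if self.k_encoder % 2 == 0 or self.k_up % 2 == 0:
            raise ValueError("kernel sizes must be odd")


class Carafe(nn.Module):
    """CARAFE upsampler: predict per-location reassembly kernels, normalize
    them with a softmax, and reassemble the source neighborhood."""

    def __init__(self, channels: int, cfg: CarafeConfig | None = None):
        super().__init__()
        self.cfg = cfg or CarafeConfig()
        c = self.cfg
        self.channels = channels
        self.compressor = nn.Conv2d(channels, c.compressed_ch, 1, bias=True)
        self.encoder = nn.Conv2d(c.compressed_ch, c.scale ** 2 * c.k_up ** 2,
                                 c.k_encoder, bias=True)

    def predict_kernels(self, x) -> Tensor:
        """Softmax-normalized kernels, shape (N, k_up^2, s*H, s*W)."""
        c = self.cfg
        raw = self.encoder(self.compressor(x))
        n, _, h, w = raw.shape
        s, k2 = c.scale, c.k_up ** 2
        # pixel-shuffle the s^2 sub-position groups up to full resolution
        shuffled = raw.reshape(n, k2, s, s, h, w).transpose(0, 1, 4, 2, 5, 3)
        shuffled = shuffled.reshape(n, k2, h * s, w * s)
        return nn.softmax(shuffled, axis=1)

    def forward(self, x, kernels: Tensor | None = None):
        x = nn.as_tensor(x)
        c = self.cfg
        if c.scale != 2:
            raise ValueError("only scale-2 reassembly is wired up")
        if kernels is None:
            kernels = self.predict_kernels(x)
        n, ch, h, w = x.shape
        k, r = c.k_up, c.k_up // 2
        padded = nn.pad2d_replicate(x, r)
        out = None
        idx = 0
        for u in range(k):
            for v in range(k):
                shifted = padded[:, :, u:u + h, v:v + w]
                up = nn.upsample2x(shifted, "nearest")
                term = up * kernels[:, idx:idx + 1]
                out = term if out is None else out + term
                idx += 1
        return out


class FEM(nn.Module):
    """Feature enhancement for a lateral branch (the FSM of the neck)."""

    def __init__(self, channels: int, reduction: int = 4):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = nn.Conv2d(2 * channels, hidden, 1, bias=True)
        self.fc2 = nn.Conv2d(hidden, channels, 1, bias=True)
        self.proj = ConvBN(channels, channels, 1, act=False)
        self.channels = channels

    def channel_descriptor(self, x) -> Tensor:
        """Concatenated height-pooled and width-pooled channel summaries,
        shape (N, 2C, 1, 1)."""
        x = nn.as_tensor(x)
        n, ch, h, w = x.shape
        if h == 0 or w == 0:
            raise ValueError("empty feature map")
        along_w = x.mean(axis=3, keepdims=True)          # (N, C, H, 1)
        along_h = x.mean(axis=2, keepdims=True)          # (N, C, 1, W)
        d1 = along_w.mean(axis=2, keepdims=True)
        d2 = along_h.mean(axis=3, keepdims=True)
        return nn.concatenate([d1, d2], axis=1)

    def gate(self, x) -> Tensor:
        """Per-channel weight map fm in (0, 1)."""
        d = self.channel_descriptor(x)
        return nn.sigmoid(self.fc2(nn.relu(self.fc1(d))))

    def forward(self, x):
        x = nn.as_tensor(x)
        g = self.gate(x)
        enhanced = x + g * x
        return self.proj(enhanced)


def fem_enhance(x, fem: FEM):
    """Functional alias for :meth:`FEM.forward`."""
    return fem(x)


def sincos_pos_embed_2d(h: int, w: int, dim: int,
                        temperature: float = 10000.0) -> np.ndarray:
    """Fixed 2-D sine/cosine positional grid of shape (h, w, dim).

    The channel axis splits into four quarters: sin/cos of the x coordinate
    and sin/cos of the y coordinate, each over a geometric frequency ladder.
    Deterministic, bounded by [-1, 1].
    """
    if dim % 4 != 0:
        raise ValueError("embedding dim must be divisible by 4")
    quarter = dim // 4
    omega = 1.0 / temperature ** (np.arange(quarter) / quarter)
    ys, xs = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    argx = xs[..., None] * omega
    argy = ys[..., None] * omega
    return np.concatenate(
        [np.sin(argx), np.cos(argx), np.sin(argy), np.cos(argy)], axis=-1)
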