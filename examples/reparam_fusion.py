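"""Collapse a diverse-branch convolution into a single 3x3 conv.

Shows that the four-branch training block and its fused deploy form give
identical outputs, and that the fused parameter count equals a plain conv.
"""

import numpy as np

from cropdet import nn
from cropdet.nn import Tensor
from cropdet.reparam import DBBConv, dbb_fuse

nn.seed_all(0)
block = DBBConv(16, 16).eval()
x = np.random.default_rng(1).normal(size=(1, 16, 32, 32))

y_branches = block(Tensor(x)).data
fused = dbb_fuse(block)
y_fused = nn.conv2d(Tensor(x), Tensor(fused.weight), Tensor(fused.bias), 1, 1).data

print(f"training branches:  {block.num_parameters():,} parameters")
print(f"fused single conv:  {fused.param_count:,} parameters "
      f"(= 16*16*9 + 16 = {16 * 16 * 9 + 16:,})")
print(f"max |multi-branch - fused| output difference: "
      f"{np.abs(y_branches - y_fused).max():.2e}")
print("The extra branches exist only during training; at deployment the "
      "block is algebraically a plain 3x3 convolution, so the capacity is "
      "free at inference time.")
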