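"""Multi-scale dual-domain feature fusion layer (MS-DFFM).

Channel attention (squeeze-and-excitation with a hard-sigmoid gate)
followed by multi-scale spatial attention, joined to the input by a
residual connection:

    s   = SE(x)                     # per-channel gates in [0, 1]
    p   = GELU(Conv1x1(s))          # pointwise feature transform
    a   = Conv1x1(5×5(s) + Σ strip_pairs(s))   # multi-scale attention map
    y   = x + a ⊙ p                 # (or x + a + p in "add" mode)

The strip pairs are 1×3/3×1, 1×7/7×1, 1×11/11×1 and 1×21/21×1,
depthwise, with "same" zero padding; their sum with the 5×5 base is
fused by the exit 1×1 convolution before combining.  Whether the
attention map multiplies or adds to the pointwise path is exposed as
``combine`` because both wirings are defensible readings of this
layer family's design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import Conv2d, GELU, HardSigmoid, Module, ReLU, global_avg_pool

__all__ = ["AttentionConfig", "SEGate", "MSDFFM", "se_gate", "ms_dffm_forward"]


@dataclass
class AttentionConfig:
    """Shape of the dual-domain attention layer."""

    channels: int
    se_reduction: int = 16
    se_min_width: int = 8
    base_kernel: int = 5
    strip_kernels: tuple[int, ...] = (3, 7, 11, 21)
    combine: str = "multiply"           # "multiply" | "add"

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("need at least one channel")
        if len(self.strip_kernels) != 4:
            raise ValueError("the spatial branch uses exactly four strip pairs")
        if self.combine not in ("multiply", "add"):
            raise ValueError("combine must be 'multiply' or 'add'")

    @property
    def se_width(self) -> int:
        return max(min(self.se_min_width, self.channels),
                   self.channels // self.se_reduction, 1)


class SEGate(Module):
    """Squeeze-and-excitation channel gate with a hard-sigmoid output.

    Global average pooling → 1×1 bottleneck (ReLU) → 1×1 expansion →
    hard-sigmoid; the input is scaled per channel by the resulting
    gate in [0, 1], so the stage can never amplify a channel.
    """

    def __init__(self, channels: int, reduction: int = 16, min_width: int = 8,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        mid = max(min(min_width, channels), channels // reduction, 1)
        self.squeeze = Conv2d(channels, mid, 1, rng=rng)
        self.act = ReLU()
        self.excite = Conv2d(mid, channels, 1, rng=rng)
        self.gate = HardSigmoid()

    def gates(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        pooled = global_avg_pool(x).reshape(b, c, 1, 1)
        return self.gate(self.excite(self.act(self.squeeze(pooled))))

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gates(x)


class MSDFFM(Module):
    def __init__(self, config: AttentionConfig | int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if isinstance(config, int):
            config = AttentionConfig(config)
        rng = rng or np.random.default_rng()
        c = config.channels
        self.config = config
        self.se = SEGate(c, config.se_reduction, config.se_min_width, rng=rng)
        self.entry = Conv2d(c, c, 1, rng=rng)
        self.gelu = GELU()
        self.base = Conv2d(c, c, config.base_kernel, groups=c, rng=rng)
        for i, sk in enumerate(config.strip_kernels):
            setattr(self, f"strip{i}_h", Conv2d(c, c, (1, sk), groups=c, rng=rng))
            setattr(self, f"strip{i}_v", Conv2d(c, c, (sk, 1), groups=c, rng=rng))
        self.exit = Conv2d(c, c, 1, rng=rng)

    def attention_path(self, x: Tensor) -> Tensor:
        """Everything between the input and the residual addition."""
        if x.shape[1] != self.config.channels:
            raise ValueError(
                f"channel mismatch: layer built for {self.config.channels} "
                f"channels, input has {x.shape[1]}")
        s = self.se(x)
        p = self.gelu(self.entry(s))
        base = self.base(s)
        agg = base
        for i in range(len(self.config.strip_kernels)):
            h = getattr(self, f"strip{i}_h")(base)
            agg = agg + getattr(self, f"strip{i}_v")(h)
        att = self.exit(agg)
        return att * p if self.config.combine == "multiply" else att + p

    def forward(self, x: Tensor) -> Tensor:
        return x + self.attention_path(x)

    def zero_attention(self) -> "MSDFFM":
        """Zero every weight on the attention path; the layer becomes x → x."""
        for p in self.parameters():
            p.data = np.zeros_like(p.data)
        return self


def se_gate(x: Tensor | np.ndarray, gate: SEGate) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(x)
    return gate(t)


def ms_dffm_forward(x: Tensor | np.ndarray, layer: MSDFFM) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(x)
    return layer(t)
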