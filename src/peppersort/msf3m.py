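"""Multi-scale frequency-domain feature fusion layer (MSF3M).

The layer lifts a feature map into the frequency domain, splits the
spectrum into magnitude and phase, runs each through an independent
multi-scale convolution branch, reconstructs a complex spectrum from
the attended pair, inverts the transform, and multiplies the result
elementwise with the original input:

    OUTPUT = IFFT( Mag_attn·cos(Pha_att) + j·Mag_attn·sin(Pha_att) ) ⊙ INPUT

Each branch is a 5×5 depthwise convolution, three parallel strip
pairs (1×7/7×1, 1×11/11×1, 1×21/21×1, depthwise), summed together
with the 5×5 output, then fused by a pointwise 1×1 convolution.  All
convolutions use "same" zero padding so shapes are preserved.  The
magnitude and phase branches share structure but not parameters.

Phase-branch outputs are deliberately *not* re-wrapped into (−π, π]:
the reconstruction consumes them only through cos/sin, which are
2π-periodic, so wrapping would be a no-op numerically and would break
differentiability at the wrap points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Conv2d, Module

__all__ = ["BranchSpec", "MultiScaleFreqBranch", "MSF3M",
           "multiscale_freq_branch", "msf3m_forward"]


@dataclass
class BranchSpec:
    """Kernel layout of one magnitude/phase branch."""

    channels: int
    base_kernel: int = 5
    strip_kernels: tuple[int, ...] = (7, 11, 21)
    fusion_kernel: int = 1

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("branch needs at least one channel")
        if len(self.strip_kernels) != 3:
            raise ValueError("the multi-scale branch uses exactly three strip pairs")


class MultiScaleFreqBranch(Module):
    """5×5 base → three strip pairs → sum → 1×1 fusion (per spectrum component)."""

    def __init__(self, spec: BranchSpec, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        c, k = spec.channels, spec.base_kernel
        self.spec = spec
        self.base = Conv2d(c, c, k, groups=c, rng=rng)
        for i, sk in enumerate(spec.strip_kernels):
            setattr(self, f"strip{i}_h", Conv2d(c, c, (1, sk), groups=c, rng=rng))
            setattr(self, f"strip{i}_v", Conv2d(c, c, (sk, 1), groups=c, rng=rng))
        self.fuse = Conv2d(c, c, spec.fusion_kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.spec.channels:
            raise ValueError(
                f"channel mismatch: branch built for {self.spec.channels} "
                f"channels, input has {x.shape[1]}")
        base = self.base(x)
        agg = base
        for i in range(len(self.spec.strip_kernels)):
            h = getattr(self, f"strip{i}_h")(base)
            agg = agg + getattr(self, f"strip{i}_v")(h)
        return self.fuse(agg)

    def configure_identity(self) -> "MultiScaleFreqBranch":
        """Set every kernel to an impulse so the branch is the identity map.

        The 5×5 base and each strip convolution become delta kernels;
        the aggregation then sums 1 + len(strips) identical copies of
        the input, and the 1×1 fusion divides by that count.
        """
        c = self.spec.channels
        for name, conv in [("base", self.base)] + [
                (f"strip{i}_{d}", getattr(self, f"strip{i}_{d}"))
                for i in range(len(self.spec.strip_kernels)) for d in "hv"]:
            w = np.zeros_like(conv.weight.data)
            kh, kw = w.shape[2], w.shape[3]
            w[:, 0, kh // 2, kw // 2] = 1.0
            conv.weight.data = w
            conv.bias.data = np.zeros_like(conv.bias.data)
        n_terms = 1 + len(self.spec.strip_kernels)
        wf = np.zeros_like(self.fuse.weight.data)
        wf[np.arange(c), np.arange(c), 0, 0] = 1.0 / n_terms
        self.fuse.weight.data = wf
        self.fuse.bias.data = np.zeros_like(self.fuse.bias.data)
        return self


def _stage_check(t: Tensor, stage: str) -> Tensor:
    if not np.all(np.isfinite(t.data)):
        raise FloatingPointError(f"non-finite activations at MSF3M stage '{stage}'")
    return t


class MSF3M(Module):
    """The full frequency-domain fusion layer (forward, differentiable)."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        spec = BranchSpec(channels)
        self.magnitude_branch = MultiScaleFreqBranch(spec, rng=rng)
        self.phase_branch = MultiScaleFreqBranch(spec, rng=rng)

    def configure_identity(self) -> "MSF3M":
        """Make both branches exact identities (the layer becomes x ⊙ x)."""
        self.magnitude_branch.configure_identity()
        self.phase_branch.configure_identity()
        return self

    def forward(self, x: Tensor) -> Tensor:
        _stage_check(x, "input")
        re = ad.fft2_re(x)
        im = ad.fft2_im(x)
        _stage_check(re, "fft")
        mag = ad.hypot(re, im)
        pha = ad.atan2(im, re)
        mag_att = _stage_check(self.magnitude_branch(mag), "branch")
        pha_att = _stage_check(self.phase_branch(pha), "branch")
        re2 = mag_att * pha_att.cos()
        im2 = mag_att * pha_att.sin()
        _stage_check(re2, "reconstruction")
        y = _stage_check(ad.ifft2_real(re2, im2), "ifft")
        return y * x


def multiscale_freq_branch(component: Tensor | np.ndarray,
                           branch: MultiScaleFreqBranch) -> Tensor:
    """Apply one magnitude/phase branch to a spectrum component."""
    t = component if isinstance(component, Tensor) else Tensor(component)
    return branch(t)


def msf3m_forward(x: Tensor | np.ndarray, layer: MSF3M) -> Tensor:
    """Run the full MSF3M layer on a (B, C, H, W) feature map."""
    t = x if isinstance(x, Tensor) else Tensor(x)
    return layer(t)
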