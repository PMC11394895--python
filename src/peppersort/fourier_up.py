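"""Deep Fourier up-sampling: resolution doubling with global support.

The input is transformed to the frequency domain, its magnitude and
phase are periodically tiled 2×2 along H and W, an optional depthwise
convolution pair processes the padded components, and the inverse
transform is taken at the doubled size.  Because the inverse carries
the 1/(NM) factor at the *new* size (1/(4·H·W)), tiling without the
convolution is exactly zero-interleaving:

    y[2i, 2j] = x[i, j],     y = 0 at every odd coordinate,

which is the algebraic signature of a periodically replicated
spectrum.  Unlike bilinear or nearest-neighbour operators, every
output pixel depends on every input pixel once the convolution is on.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat
from .nn import Conv2d, Module
from .spectral import PolarSpectrum

__all__ = ["cyclic_pad_spectrum", "FourierUpsample", "fourier_upsample_forward"]


def cyclic_pad_spectrum(polar: PolarSpectrum) -> PolarSpectrum:
    """2×2 periodic tiling of magnitude and phase along the last two axes."""
    reps = (1,) * (polar.magnitude.ndim - 2) + (2, 2)
    return PolarSpectrum(np.tile(polar.magnitude, reps),
                         np.tile(polar.phase, reps),
                         attended=polar.attended)


def _tile2x2(t: Tensor) -> Tensor:
    return concat([concat([t, t], axis=-2)] * 2, axis=-1)


class FourierUpsample(Module):
    """(B, C, H, W) → (B, C, 2H, 2W) through the padded spectrum.

    ``bypass_conv=True`` skips the post-padding convolutions, leaving
    the pure spectral replication (used as an analytic reference and
    for the zero-interleaving identity).
    """

    def __init__(self, channels: int, kernel: int = 3, bypass_conv: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.bypass_conv = bypass_conv
        self.mag_conv = Conv2d(channels, channels, kernel, groups=channels, rng=rng)
        self.pha_conv = Conv2d(channels, channels, kernel, groups=channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if not np.all(np.isfinite(x.data)):
            raise FloatingPointError("non-finite input to Fourier up-sampling")
        re = ad.fft2_re(x)
        im = ad.fft2_im(x)
        mag = _tile2x2(ad.hypot(re, im))
        pha = _tile2x2(ad.atan2(im, re))
        if not self.bypass_conv:
            mag = self.mag_conv(mag)
            pha = self.pha_conv(pha)
        re2 = mag * pha.cos()
        im2 = mag * pha.sin()
        if not np.all(np.isfinite(re2.data)):
            raise FloatingPointError(
                "non-finite spectrum after Fourier up-sampling convolution")
        return ad.ifft2_real(re2, im2)


def fourier_upsample_forward(x: Tensor | np.ndarray, layer: FourierUpsample) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(x)
    return layer(t)
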