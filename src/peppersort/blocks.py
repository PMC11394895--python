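"""Supporting network blocks: GELAN-family and C2f-style components.

These follow their cited reference designs: ``RepNCSPELAN4`` and
``ADown`` from the GELAN generation of YOLO backbones, ``SPPELAN`` as
the ELAN-aggregated spatial pyramid pooling, and ``C2fSE`` as the
standard C2f split-bottleneck block with a squeeze-and-excitation
gate appended to each bottleneck output.  Re-parameterized (RepConv)
bottlenecks are built directly in their deploy-time single-conv form.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat
from .msdffm import SEGate
from .nn import BatchNorm2d, Conv2d, Module, SiLU

__all__ = ["ConvBNAct", "Bottleneck", "C2f", "C2fSE", "SPPELAN", "ADown",
           "RepNCSP", "RepNCSPELAN4"]


class ConvBNAct(Module):
    """Conv → BatchNorm → SiLU, the standard YOLO conv unit."""

    def __init__(self, cin, cout, kernel=3, stride=1, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, stride=stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = SiLU()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class Bottleneck(Module):
    def __init__(self, cin, cout, shortcut=True, se=False, rng=None):
        super().__init__()
        self.cv1 = ConvBNAct(cin, cout, 3, rng=rng)
        self.cv2 = ConvBNAct(cout, cout, 3, rng=rng)
        self.se = SEGate(cout, rng=rng) if se else None
        self.add = shortcut and cin == cout

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        if self.se is not None:
            y = self.se(y)
        return x + y if self.add else y


class C2f(Module):
    """Split → n bottlenecks with dense concatenation → 1×1 fuse."""

    def __init__(self, cin, cout, n=1, shortcut=True, se=False, rng=None):
        super().__init__()
        self.h = cout // 2
        self.cv1 = ConvBNAct(cin, 2 * self.h, 1, rng=rng)
        self.bottlenecks = [Bottleneck(self.h, self.h, shortcut, se, rng=rng)
                            for _ in range(n)]
        for i, b in enumerate(self.bottlenecks):
            setattr(self, f"b{i}", b)
        self.cv2 = ConvBNAct((2 + n) * self.h, cout, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        parts = [y[:, :self.h], y[:, self.h:]]
        for b in self.bottlenecks:
            parts.append(b(parts[-1]))
        return self.cv2(concat(parts, axis=1))


class C2fSE(C2f):
    """C2f with an SE gate on every bottleneck output."""

    def __init__(self, cin, cout, n=1, shortcut=True, rng=None):
        super().__init__(cin, cout, n=n, shortcut=shortcut, se=True, rng=rng)


class SPPELAN(Module):
    """Spatial pyramid pooling with ELAN-style aggregation."""

    def __init__(self, cin, cout, cmid=None, rng=None):
        super().__init__()
        cmid = cmid or max(cout // 2, 1)
        self.cv1 = ConvBNAct(cin, cmid, 1, rng=rng)
        self.cv2 = ConvBNAct(4 * cmid, cout, 1, rng=rng)
        self.pool_kernel = 5

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(ad.maxpool2d(y[-1], self.pool_kernel, stride=1, padding=2))
        return self.cv2(concat(y, axis=1))


class ADown(Module):
    """Hybrid average/max-pool downsampling (stride 2) on split channels."""

    def __init__(self, cin, cout, rng=None):
        super().__init__()
        half_in, half_out = cin // 2, cout // 2
        self.cv1 = ConvBNAct(half_in, half_out, 3, stride=2, rng=rng)
        self.cv2 = ConvBNAct(cin - half_in, cout - half_out, 1, rng=rng)

    def forward(self, x):
        x = ad.avgpool2d(x, 2, stride=1, padding=0)
        half = x.shape[1] // 2
        x1 = self.cv1(x[:, :half])
        x2 = self.cv2(ad.maxpool2d(x[:, half:], 3, stride=2, padding=1))
        return concat([x1, x2], axis=1)


class RepNCSP(Module):
    """CSP block with deploy-form re-parameterized bottlenecks."""

    def __init__(self, cin, cout, n=1, rng=None):
        super().__init__()
        h = max(cout // 2, 1)
        self.cv1 = ConvBNAct(cin, h, 1, rng=rng)
        self.cv2 = ConvBNAct(cin, h, 1, rng=rng)
        self.bottlenecks = [Bottleneck(h, h, shortcut=True, rng=rng)
                            for _ in range(n)]
        for i, b in enumerate(self.bottlenecks):
            setattr(self, f"b{i}", b)
        self.cv3 = ConvBNAct(2 * h, cout, 1, rng=rng)

    def forward(self, x):
        a = self.cv1(x)
        for b in self.bottlenecks:
            a = b(a)
        return self.cv3(concat([a, self.cv2(x)], axis=1))


class RepNCSPELAN4(Module):
    """GELAN aggregation: split, two chained RepNCSP+conv stages, concat."""

    def __init__(self, cin, cout, cmid=None, cinner=None, n=1, rng=None):
        super().__init__()
        cmid = cmid or max(cout // 2, 2)
        cinner = cinner or max(cmid // 2, 1)
        self.half = cmid // 2
        self.cv1 = ConvBNAct(cin, cmid, 1, rng=rng)
        self.stage1 = _CSPStage(cmid - self.half, cinner, n, rng=rng)
        self.stage2 = _CSPStage(cinner, cinner, n, rng=rng)
        self.cv4 = ConvBNAct(cmid + 2 * cinner, cout, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        parts = [y[:, :self.half], y[:, self.half:]]
        parts.append(self.stage1(parts[-1]))
        parts.append(self.stage2(parts[-1]))
        return self.cv4(concat(parts, axis=1))


class _CSPStage(Module):
    def __init__(self, cin, cout, n=1, rng=None):
        super().__init__()
        self.csp = RepNCSP(cin, cout, n, rng=rng)
        self.conv = ConvBNAct(cout, cout, 3, rng=rng)

    def forward(self, x):
        return self.conv(self.csp(x))
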