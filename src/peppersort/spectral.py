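"""Exact 2-D Fourier transforms and Cartesian/polar spectrum conversion.

Conventions
-----------
The forward transform is the unnormalized 2-D DFT

    X^(k, l) = sum_x sum_y X(x, y) · exp(-j·2π·(kx/N + ly/M)),

and the inverse carries the full 1/(NM) factor ("backward"
normalization).  Transforms act on the last two axes, so arrays with
leading batch/channel axes are handled per channel.  Phase is the
quadrant-aware two-argument angle in (−π, π]; the one-argument
arctangent of im/re would fold quadrants II/III onto IV/I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RealGrid", "ComplexSpectrum", "PolarSpectrum",
           "fft2d", "ifft2d", "to_polar", "from_polar"]

#: relative imaginary residue above which ifft2d warns of upstream corruption
IMAG_RESIDUE_TOL = 1e-4


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(np.atleast_1d(arr)))[0]
        raise ValueError(f"{name} contains non-finite values "
                         f"(first at index {tuple(int(i) for i in bad)})")


@dataclass
class RealGrid:
    """A real-valued spatial-domain array; last two axes are (height N, width M)."""

    values: np.ndarray
    #: magnitude of the imaginary residue discarded by the inverse transform
    imag_residue: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim < 2 or min(self.values.shape[-2:]) < 1:
            raise ValueError("RealGrid needs at least a 1x1 spatial extent")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class ComplexSpectrum:
    """Frequency-domain array split into real and imaginary parts."""

    re: np.ndarray
    im: np.ndarray

    def __post_init__(self):
        self.re = np.asarray(self.re, dtype=np.float64)
        self.im = np.asarray(self.im, dtype=np.float64)
        if self.re.shape != self.im.shape:
            raise ValueError("real and imaginary parts must share a shape")
        if self.re.ndim < 2 or min(self.re.shape[-2:]) < 1:
            raise ValueError("spectrum must have a nonzero spatial extent")

    @property
    def shape(self):
        return self.re.shape

    def as_complex(self) -> np.ndarray:
        return self.re + 1j * self.im


@dataclass
class PolarSpectrum:
    """Magnitude/phase representation of a spectrum.

    ``attended`` distinguishes a raw polar split from one whose
    magnitude and phase have passed through attention convolutions (in
    which case the phase is no longer wrapped to (−π, π] — it is only
    ever consumed through cos/sin, which are 2π-periodic).
    """

    magnitude: np.ndarray
    phase: np.ndarray
    attended: bool = field(default=False)

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=np.float64)
        self.phase = np.asarray(self.phase, dtype=np.float64)
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase must share a shape")

    @property
    def shape(self):
        return self.magnitude.shape


def fft2d(grid: RealGrid | np.ndarray) -> ComplexSpectrum:
    """Unnormalized forward 2-D DFT over the last two axes."""
    values = grid.values if isinstance(grid, RealGrid) else np.asarray(grid, float)
    _check_finite(values, "fft2d input")
    spec = np.fft.fft2(values)
    return ComplexSpectrum(spec.real, spec.imag)


def ifft2d(spec: ComplexSpectrum) -> RealGrid:
    """1/(NM)-normalized inverse 2-D DFT; keeps the real component.

    The discarded imaginary residue is recorded on the returned grid;
    a residue above ``IMAG_RESIDUE_TOL`` times the output scale raises
    a warning, since a spectrum of a real signal should invert to a
    (numerically) real signal.
    """
    _check_finite(spec.re, "ifft2d input (real part)")
    _check_finite(spec.im, "ifft2d input (imaginary part)")
    out = np.fft.ifft2(spec.as_complex())
    residue = float(np.max(np.abs(out.imag))) if out.size else 0.0
    scale = float(np.max(np.abs(out.real))) if out.size else 0.0
    if scale > 0 and residue > IMAG_RESIDUE_TOL * scale:
        warnings.warn(
            f"ifft2d imaginary residue {residue:.3e} exceeds "
            f"{IMAG_RESIDUE_TOL:g} of the output scale; the spectrum is "
            "not conjugate-symmetric", RuntimeWarning, stacklevel=2)
    return RealGrid(out.real, imag_residue=residue)


def to_polar(spec: ComplexSpectrum) -> PolarSpectrum:
    """Magnitude sqrt(re²+im²) and quadrant-aware phase atan2(im, re)."""
    _check_finite(spec.re, "to_polar input (real part)")
    _check_finite(spec.im, "to_polar input (imaginary part)")
    mag = np.hypot(spec.re, spec.im)
    pha = np.arctan2(spec.im, spec.re)
    return PolarSpectrum(mag, pha, attended=False)


def from_polar(polar: PolarSpectrum) -> ComplexSpectrum:
    """re = magnitude·cos(phase), im = magnitude·sin(phase)."""
    _check_finite(polar.magnitude, "from_polar magnitude")
    _check_finite(polar.phase, "from_polar phase")
    if np.any(polar.magnitude < 0):
        raise ValueError("magnitude must be nonnegative everywhere")
    return ComplexSpectrum(polar.magnitude * np.cos(polar.phase),
                           polar.magnitude * np.sin(polar.phase))
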