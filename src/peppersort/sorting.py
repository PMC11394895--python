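"""High-quality granule sorting by average local pixel value difference.

A granule crop is graded on *color uniformity*: convert to grayscale,
compute for every pixel the absolute difference between it and the
mean of its 3×3 neighborhood (the vALD map), compare against 10% of
the image's global average absolute deviation (GAD), and mark pixels
under the threshold white ("flat").  The resulting binary mask is
then assessed: a granule is accepted as high quality only if its
non-flat (black) pixels are both globally rare and not scattered
across many sliding windows.

Conventions adopted where the written procedure is ambiguous: the
3×3 neighborhood mean includes the center pixel (uniform 1/9 kernel;
an 8-neighbor variant is available), borders use replicate padding,
ties compare with ≤ so a perfectly uniform image is entirely flat,
and GAD is the mean absolute deviation from the global mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import uniform_filter

__all__ = ["FlatStats", "FlatMask", "SortingConfig", "SortingVerdict",
           "to_gray", "compute_vald", "mark_flat_regions",
           "assess_flat_mask", "select_high_quality", "sort_granule",
           "classify_maturity_color", "fuse_views"]

_LUMA = np.array([0.299, 0.587, 0.114])

WHITE, BLACK = 255, 0


@dataclass
class FlatStats:
    """Per-pixel local difference map and the global deviation scalar."""

    vald: np.ndarray    # |pixel − 3×3 neighborhood mean|, ≥ 0
    gad: float          # mean |pixel − global mean|, intensity units


@dataclass
class FlatMask:
    """Binary map: white (255) = flat/uniform, black (0) = non-flat."""

    mask: np.ndarray

    def __post_init__(self):
        values = np.unique(self.mask)
        if not np.all(np.isin(values, (BLACK, WHITE))):
            raise ValueError("flat mask may contain only 0 and 255")

    @property
    def black_fraction(self) -> float:
        return float((self.mask == BLACK).mean())


@dataclass
class SortingConfig:
    flat_fraction: float = 0.10          # threshold = this × GAD
    window: int = 16
    stride: int = 16
    window_black_threshold: float = 0.5  # a window this black is "non-flat"
    scatter_threshold: float = 0.25      # max tolerated fraction of such windows
    global_black_threshold: float = 0.25
    include_center: bool = True          # 3×3 mean includes the pixel itself
    require_both_views: bool = True

    def __post_init__(self):
        for name in ("flat_fraction", "window_black_threshold",
                     "scatter_threshold", "global_black_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.window < 1 or self.stride < 1:
            raise ValueError("window and stride must be ≥ 1")


@dataclass
class SortingVerdict:
    maturity: str                        # "mature" | "semi_mature" | "unknown"
    global_black: float
    max_window_black: float
    scattered_fraction: float
    accepted: bool
    reason: str                          # "ok" | "global_black" | "scattered"


def to_gray(image: np.ndarray) -> np.ndarray:
    """RGB (H, W, 3) in [0, 255] or [0, 1] → float grayscale in [0, 255]."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        if img.max() <= 1.0:
            img = img * 255.0
        img = img[..., :3] @ _LUMA
    return np.clip(img, 0, 255)


def compute_vald(img: np.ndarray) -> FlatStats:
    """vALD map and global average deviation of a grayscale image."""
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    local_mean = uniform_filter(img, size=3, mode="nearest")
    vald = np.abs(img - local_mean)
    gad = float(np.abs(img - img.mean()).mean())
    return FlatStats(vald=vald, gad=gad)


def _vald_excluding_center(img: np.ndarray) -> np.ndarray:
    # 8-neighbor mean: (9·inclusive_mean − center)/8
    local = uniform_filter(img, size=3, mode="nearest")
    return np.abs(img - (9.0 * local - img) / 8.0)


def mark_flat_regions(img: np.ndarray, flat_fraction: float = 0.10,
                      include_center: bool = True) -> FlatMask:
    """White where vALD ≤ flat_fraction·GAD, black elsewhere."""
    if not 0.0 <= flat_fraction <= 1.0:
        raise ValueError("flat_fraction must be in [0, 1]")
    img = np.asarray(img, dtype=np.float64)
    stats = compute_vald(img)
    vald = stats.vald if include_center else _vald_excluding_center(img)
    flat = vald <= flat_fraction * stats.gad
    return FlatMask(np.where(flat, WHITE, BLACK).astype(np.uint8))


def assess_flat_mask(mask: FlatMask, config: SortingConfig) -> dict:
    """Global and sliding-window black-pixel statistics of a flat mask."""
    m = mask.mask
    h, w = m.shape
    if config.window > h or config.window > w:
        raise ValueError(
            f"window {config.window} exceeds mask size {h}x{w}")
    black = (m == BLACK).astype(np.float64)
    views = sliding_window_view(black, (config.window, config.window))
    views = views[::config.stride, ::config.stride]
    win = views.mean(axis=(-2, -1)).ravel()
    scattered = float((win > config.window_black_threshold).mean())
    return {
        "global_black": float(black.mean()),
        "window_black": win,
        "max_window_black": float(win.max()),
        "scattered_fraction": scattered,
    }


def select_high_quality(mask: FlatMask, config: SortingConfig | None = None,
                        maturity: str = "unknown") -> SortingVerdict:
    """Accept iff black pixels are globally rare and not scattered.

    Both comparisons use ≤, so a mask sitting exactly on a threshold
    is still accepted; the decision is monotone in every black-pixel
    statistic.
    """
    config = config or SortingConfig()
    stats = assess_flat_mask(mask, config)
    if stats["global_black"] > config.global_black_threshold:
        accepted, reason = False, "global_black"
    elif stats["scattered_fraction"] > config.scatter_threshold:
        accepted, reason = False, "scattered"
    else:
        accepted, reason = True, "ok"
    return SortingVerdict(
        maturity=maturity,
        global_black=stats["global_black"],
        max_window_black=stats["max_window_black"],
        scattered_fraction=stats["scattered_fraction"],
        accepted=accepted,
        reason=reason,
    )


def classify_maturity_color(image: np.ndarray) -> str:
    """Color-heuristic maturity call: mature granules are uniformly red.

    Compares mean red vs. green over bright pixels; a trained
    classifier can replace this in the full pipeline.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3:
        return "unknown"
    if img.max() <= 1.0:
        img = img * 255.0
    lum = img[..., :3].mean(axis=-1)
    fg = lum > max(10.0, 0.2 * lum.max())
    if not fg.any():
        return "unknown"
    r, g = img[..., 0][fg].mean(), img[..., 1][fg].mean()
    return "mature" if g < 0.6 * r else "semi_mature"


def sort_granule(image: np.ndarray, config: SortingConfig | None = None) -> SortingVerdict:
    """Full per-granule pipeline: gray → vALD → flat mask → verdict."""
    config = config or SortingConfig()
    gray = to_gray(image)
    mask = mark_flat_regions(gray, config.flat_fraction, config.include_center)
    return select_high_quality(mask, config,
                               maturity=classify_maturity_color(image))


def fuse_views(front: SortingVerdict, back: SortingVerdict,
               require_both: bool = True) -> bool:
    """Combine front/back verdicts; conservatively both must accept."""
    if require_both:
        return front.accepted and back.accepted
    return front.accepted or back.accepted
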