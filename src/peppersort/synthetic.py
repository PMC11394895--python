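"""Deterministic synthetic imagery emulating peppercorn cluster photos.

Real data for this problem is desk-unfriendly (private photographs of
harvested pepper clusters), so every stage of the pipeline is
exercised on generated scenes instead: round granules with a
class-dependent surface model on a dark textured background, with
per-granule polygon labels.

Two maturity classes are modelled:

* ``mature`` — a single uniform red hue with a gentle sinusoidal
  surface modulation and small Gaussian jitter, so granule crops are
  *flat* in the local-pixel-difference sense;
* ``semi_mature`` — red–green mottling from thresholded low-frequency
  noise, producing dense patch boundaries that the flat-region sorter
  must reject.

The generators are not photorealistic; they are built so that (a) the
two classes are separable by color statistics with a wide margin and
(b) the flat/mottled split exercises the vALD sorter in both
directions.  All outputs are byte-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .labels import PolygonLabel

__all__ = ["SceneSpec", "CLASS_NAMES", "generate_cluster_scene",
           "generate_granule_crop", "generate_cls_arrays",
           "generate_cls_dataset"]

CLASS_NAMES = ("mature", "semi_mature")

# surface color models (RGB, 0-255)
_MATURE_HUE = np.array([200.0, 40.0, 35.0])
_SEMI_HUE_RED = np.array([190.0, 60.0, 40.0])
_SEMI_HUE_GREEN = np.array([110.0, 165.0, 55.0])


@dataclass
class SceneSpec:
    """Parameters of one rendered cluster scene."""

    image_size: int = 256
    granule_count: int = 6
    mature_fraction: float = 1.0
    radius_range: tuple[float, float] = (0.07, 0.11)   # fraction of image size
    texture_amp: float = 3.0          # sinusoidal surface modulation (intensity)
    color_jitter: float = 1.5         # per-pixel Gaussian noise std (intensity)
    mottle_sigma: float = 1.0         # patch scale of semi-mature mottling (px)
    background_level: float = 12.0
    noise_level: float = 1.0          # additive scene noise std
    polygon_vertices: int = 16
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.mature_fraction <= 1.0:
            raise ValueError("mature_fraction must be in [0, 1]")
        if self.radius_range[0] <= 0:
            raise ValueError("radii must be positive")
        if self.polygon_vertices < 8:
            raise ValueError("polygons need at least 8 vertices")


def _granule_surface(rng: np.random.Generator, size: tuple[int, int],
                     maturity: str, spec_amp: float, jitter: float,
                     mottle_sigma: float) -> np.ndarray:
    """(h, w, 3) surface color field for one granule's bounding patch."""
    h, w = size
    yy, xx = np.mgrid[0:h, 0:w]
    if maturity == "mature":
        base = np.broadcast_to(_MATURE_HUE, (h, w, 3)).copy()
    else:
        noise = rng.standard_normal((h, w))
        patches = gaussian_filter(noise, sigma=mottle_sigma) > 0
        base = np.where(patches[..., None], _SEMI_HUE_RED, _SEMI_HUE_GREEN)
    phase = rng.uniform(0, 2 * np.pi, size=2)
    wavelength = max(h, w) / rng.uniform(1.5, 2.5)
    texture = spec_amp * np.sin(2 * np.pi * xx / wavelength + phase[0]) \
        * np.sin(2 * np.pi * yy / wavelength + phase[1])
    out = base + texture[..., None]
    out += rng.normal(0.0, jitter, size=out.shape)
    return out


def _disk_polygon(cx: float, cy: float, r: float, size: int,
                  vertices: int, rng: np.random.Generator) -> np.ndarray:
    angles = np.linspace(0, 2 * np.pi, vertices, endpoint=False)
    radii = r * (1.0 + rng.uniform(-0.03, 0.03, size=vertices))
    xs = np.clip((cx + radii * np.cos(angles)) / size, 0.0, 1.0)
    ys = np.clip((cy + radii * np.sin(angles)) / size, 0.0, 1.0)
    return np.stack([xs, ys], axis=1)


def generate_cluster_scene(spec: SceneSpec):
    """Render one cluster scene.

    Returns ``(image, labels, classes)``: a uint8 (H, W, 3) image, a
    list of :class:`PolygonLabel` with normalized coordinates, and
    the per-granule class-name list.  Identical specs (including the
    seed) produce identical bytes.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    img = np.empty((size, size, 3))
    img[:] = spec.background_level
    img += gaussian_filter(rng.normal(0, 6.0, (size, size)), 4.0)[..., None]

    n_mature = int(round(spec.granule_count * spec.mature_fraction))
    classes = ["mature"] * n_mature + \
        ["semi_mature"] * (spec.granule_count - n_mature)
    rng.shuffle(classes)

    yy, xx = np.mgrid[0:size, 0:size]
    placed: list[tuple[float, float, float]] = []
    labels: list[PolygonLabel] = []
    for maturity in classes:
        r = rng.uniform(*spec.radius_range) * size
        if r + 2 >= size / 2:
            raise ValueError("granule radius does not fit the canvas")
        for attempt in range(200):
            cx = rng.uniform(r + 1, size - r - 1)
            cy = rng.uniform(r + 1, size - r - 1)
            if all(np.hypot(cx - px, cy - py) >= 0.6 * (r + pr)
                   for px, py, pr in placed):
                break
        else:
            raise RuntimeError(
                f"could not place {spec.granule_count} granules after bounded "
                "retries; reduce the count or radii")
        placed.append((cx, cy, r))

        x0, x1 = int(cx - r) - 1, int(cx + r) + 2
        y0, y1 = int(cy - r) - 1, int(cy + r) + 2
        surface = _granule_surface(rng, (y1 - y0, x1 - x0), maturity,
                                   spec.texture_amp, spec.color_jitter,
                                   spec.mottle_sigma)
        dist = np.hypot(xx[y0:y1, x0:x1] - cx, yy[y0:y1, x0:x1] - cy)
        inside = dist <= r
        shading = 1.0 - 0.18 * (dist / r) ** 2
        patch = img[y0:y1, x0:x1]
        patch[inside] = (surface * shading[..., None])[inside]

        poly = _disk_polygon(cx, cy, r, size, spec.polygon_vertices, rng)
        labels.append(PolygonLabel(class_id=CLASS_NAMES.index(maturity),
                                   vertices=poly))

    img += rng.normal(0.0, spec.noise_level, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), labels, classes


def generate_granule_crop(maturity: str, size: int = 64,
                          rng: np.random.Generator | None = None,
                          texture_amp: float = 3.0, color_jitter: float = 1.5,
                          mottle_sigma: float = 1.0) -> np.ndarray:
    """One centred granule crop on a black background, uint8 (size, size, 3).

    Emulates the segment-then-crop output that the classifier and the
    quality sorter consume.
    """
    if maturity not in CLASS_NAMES:
        raise ValueError(f"unknown maturity {maturity!r}")
    rng = rng or np.random.default_rng()
    img = np.zeros((size, size, 3))
    r = rng.uniform(0.38, 0.44) * size
    cx = cy = size / 2 + rng.uniform(-1, 1, size=2)
    yy, xx = np.mgrid[0:size, 0:size]
    dist = np.hypot(xx - cx[0], yy - cy[1])
    inside = dist <= r
    surface = _granule_surface(rng, (size, size), maturity,
                               texture_amp, color_jitter, mottle_sigma)
    shading = 1.0 - 0.18 * (dist / r) ** 2
    img[inside] = (surface * shading[..., None])[inside]
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_cls_arrays(per_class: int = 200, size: int = 64,
                        split: float = 0.8, seed: int = 0):
    """In-memory two-class granule dataset ready for training.

    Returns a :class:`peppersort.model.ClsDataset` with float images
    in [0, 1], channel-first, split per class at ``split``.
    """
    from .model import ClsDataset

    rng = np.random.default_rng(seed)
    images, labels = [], []
    for class_id, name in enumerate(CLASS_NAMES):
        for _ in range(per_class):
            crop = generate_granule_crop(name, size=size, rng=rng)
            images.append(crop.transpose(2, 0, 1) / 255.0)
            labels.append(class_id)
    images = np.asarray(images)
    labels = np.asarray(labels)
    n_train = int(round(per_class * split))
    train_idx, val_idx = [], []
    for class_id in range(len(CLASS_NAMES)):
        idx = np.where(labels == class_id)[0]
        idx = rng.permutation(idx)
        train_idx.extend(idx[:n_train])
        val_idx.extend(idx[n_train:])
    train_idx = rng.permutation(np.array(train_idx))
    val_idx = np.array(val_idx)
    return ClsDataset(train_images=images[train_idx],
                      train_labels=labels[train_idx],
                      val_images=images[val_idx],
                      val_labels=labels[val_idx],
                      class_names=CLASS_NAMES)


def generate_cls_dataset(out_dir: str | Path, per_class: int = 200,
                         size: int = 64, split: float = 0.8,
                         seed: int = 0) -> dict:
    """Write a ``train/<class>/``, ``val/<class>/`` image-folder dataset."""
    from PIL import Image

    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    counts = {"train": 0, "val": 0}
    n_train = int(round(per_class * split))
    for name in CLASS_NAMES:
        for i in range(per_class):
            crop = generate_granule_crop(name, size=size, rng=rng)
            part = "train" if i < n_train else "val"
            dest = out_dir / part / name
            dest.mkdir(parents=True, exist_ok=True)
            Image.fromarray(crop).save(dest / f"{name}_{i:04d}.png")
            counts[part] += 1
    return counts
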