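"""YOLO-style polygon segmentation labels and polygon cropping.

One text file per image; each line is a class index followed by an
even number of coordinates normalized to [0, 1]:

    <class> x1 y1 x2 y2 ... xn yn

The writer emits 6-decimal fixed point, so a read/write round trip is
lossless to 1e-6.  Pixel coordinates are 0-based and half-open:
denormalization multiplies by width/height and floors for box edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["PolygonLabel", "LabelParseError", "read_yolo_seg_labels",
           "write_yolo_seg_labels", "crop_by_polygon", "load_image",
           "save_image"]


class LabelParseError(ValueError):
    pass


@dataclass
class PolygonLabel:
    class_id: int
    vertices: np.ndarray          # (V, 2) normalized (x, y)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.class_id < 0:
            raise ValueError("class index must be nonnegative")
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 \
                or len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 (x, y) vertices")
        if self.vertices.min() < 0.0 or self.vertices.max() > 1.0:
            raise ValueError("coordinates must be normalized to [0, 1]")


def read_yolo_seg_labels(path: str | Path) -> list[PolygonLabel]:
    labels = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        tokens = line.split()
        try:
            class_id = int(tokens[0])
            coords = [float(t) for t in tokens[1:]]
        except ValueError as exc:
            raise LabelParseError(
                f"{path}:{lineno}: non-numeric token ({exc})") from None
        if len(coords) % 2 != 0:
            raise LabelParseError(
                f"{path}:{lineno}: odd coordinate count {len(coords)}")
        if len(coords) < 6:
            raise LabelParseError(
                f"{path}:{lineno}: polygon needs ≥ 3 vertices, "
                f"got {len(coords) // 2}")
        verts = np.array(coords).reshape(-1, 2)
        if verts.min() < 0.0 or verts.max() > 1.0:
            raise LabelParseError(
                f"{path}:{lineno}: coordinates outside [0, 1]")
        labels.append(PolygonLabel(class_id, verts))
    return labels


def write_yolo_seg_labels(labels: list[PolygonLabel], path: str | Path) -> None:
    lines = []
    for lab in labels:
        coords = " ".join(f"{v:.6f}" for v in lab.vertices.ravel())
        lines.append(f"{lab.class_id} {coords}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def crop_by_polygon(image: np.ndarray, label: PolygonLabel,
                    mask_background: bool = False) -> np.ndarray:
    """Axis-aligned bounding-box crop of a polygon (optionally masked).

    With ``mask_background=True`` pixels outside the polygon are set
    to 0 — the form the quality sorter expects, since its flat-region
    statistics should describe the granule, not the scene behind it.
    """
    h, w = image.shape[:2]
    px = label.vertices[:, 0] * w
    py = label.vertices[:, 1] * h
    x0, x1 = int(np.floor(px.min())), int(np.floor(px.max()))
    y0, y1 = int(np.floor(py.min())), int(np.floor(py.max()))
    x1, y1 = min(x1, w), min(y1, h)
    if x1 <= x0 or y1 <= y0:
        raise ValueError("polygon has zero area after denormalization")
    crop = image[y0:y1, x0:x1].copy()
    if mask_background:
        from skimage.draw import polygon as draw_polygon
        mask = np.zeros(crop.shape[:2], dtype=bool)
        rr, cc = draw_polygon(py - y0, px - x0, shape=mask.shape)
        mask[rr, cc] = True
        crop[~mask] = 0
    return crop


def load_image(path: str | Path) -> np.ndarray:
    from PIL import Image
    return np.asarray(Image.open(path).convert("RGB"))


def save_image(image: np.ndarray, path: str | Path) -> None:
    from PIL import Image
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)
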