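"""Contour geometry and image-feature extraction for microdissected shapes.

A "shape" is one laser-microdissected hepatocyte cross-section, exported
as a closed contour polygon in pixel coordinates.  From each shape and
its 4-channel image patch (phalloidin 425, WGA 488, E-cadherin 568,
Glul 647) a 17-dimensional feature vector is computed: the mean, median,
minimum and maximum intensity per channel over the shape's bounding box,
plus the polygon area in um2.  Distances from the shape centroid to the
nearest portal-vein and central-vein landmark give the spatial position
used by the zonation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Contour",
    "CHANNELS",
    "FEATURE_NAMES",
    "bounding_box",
    "offset_box",
    "shape_area",
    "polygon_centroid",
    "extract_features",
    "simplify_contour",
    "landmark_distances",
]

#: Stain channels in canonical order (ascending wavelength, nm).
CHANNELS = (425, 488, 568, 647)

#: Canonical feature order: per channel the four box statistics, area last.
FEATURE_NAMES = tuple(
    f"ch{ch}_{stat}" for ch in CHANNELS for stat in ("mean", "median", "min", "max")
) + ("area_um2",)


@dataclass(frozen=True)
class Contour:
    """Closed polygon in pixel coordinates with a um/px calibration."""

    vertices: np.ndarray  # (n, 2) float array of (x, y)
    pixel_size_um: float = 1.0

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 1:
            raise ValueError("contour needs an (n, 2) vertex array with n >= 1")
        object.__setattr__(self, "vertices", v)


def bounding_box(contour: Contour | np.ndarray) -> tuple[int, int, int, int]:
    """Integer bounding box (x0, y0, x1, y1): floor of minima, ceil of maxima.

    A degenerate axis is widened to one pixel so the box always has area.
    """
    v = contour.vertices if isinstance(contour, Contour) else np.asarray(contour, dtype=float)
    if v.size == 0:
        raise ValueError("empty contour has no bounding box")
    x0 = int(np.floor(v[:, 0].min()))
    x1 = int(np.ceil(v[:, 0].max()))
    y0 = int(np.floor(v[:, 1].min()))
    y1 = int(np.ceil(v[:, 1].max()))
    if x1 <= x0:
        x1 = x0 + 1
    if y1 <= y0:
        y1 = y0 + 1
    return (x0, y0, x1, y1)


def offset_box(
    box: tuple[int, int, int, int],
    offset_px: int = 1000,
    image_bounds: tuple[int, int] | None = None,
) -> tuple[int, int, int, int]:
    """Expand a box by ``offset_px`` on every side, clamped to the image.

    ``image_bounds`` is (width, height); ``None`` clamps at 0 only.
    """
    x0, y0, x1, y1 = box
    x0, y0 = max(0, x0 - offset_px), max(0, y0 - offset_px)
    x1, y1 = x1 + offset_px, y1 + offset_px
    if image_bounds is not None:
        w, h = image_bounds
        x1, y1 = min(x1, w), min(y1, h)
    return (x0, y0, x1, y1)


def shape_area(contour: Contour) -> float:
    """Polygon area in um2 by the absolute shoelace formula."""
    v = contour.vertices
    if v.shape[0] < 3:
        raise ValueError("polygon area needs at least 3 vertices")
    x, y = v[:, 0], v[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(abs(signed)) * contour.pixel_size_um**2


def polygon_centroid(contour: Contour) -> tuple[float, float]:
    """Area-weighted polygon centroid, in the contour's pixel coordinates."""
    v = contour.vertices
    if v.shape[0] < 3:
        raise ValueError("polygon centroid needs at least 3 vertices")
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-12:  # degenerate: fall back to vertex mean
        return (float(x.mean()), float(y.mean()))
    cx = float(((x + xn) * cross).sum() / (6.0 * a))
    cy = float(((y + yn) * cross).sum() / (6.0 * a))
    return (cx, cy)


def extract_features(patches: np.ndarray, contour: Contour) -> dict[str, float]:
    """17 image features for one shape.

    ``patches`` holds the four stain channels cropped to the shape's
    bounding box, shape (4, H, W).  Statistics are taken over *all*
    pixels of the bounding box (not masked to the polygon), plus the
    polygon area, yielding the canonical 17-vector in ``FEATURE_NAMES``
    order.
    """
    patches = np.asarray(patches, dtype=float)
    if patches.ndim != 3 or patches.shape[0] != len(CHANNELS):
        raise ValueError(f"expected {len(CHANNELS)} channel patches of identical shape, got {patches.shape}")
    features: dict[str, float] = {}
    for ch, patch in zip(CHANNELS, patches):
        flat = patch.ravel()
        features[f"ch{ch}_mean"] = float(flat.mean())
        features[f"ch{ch}_median"] = float(np.median(flat))
        features[f"ch{ch}_min"] = float(flat.min())
        features[f"ch{ch}_max"] = float(flat.max())
    features["area_um2"] = shape_area(contour)
    return features


def simplify_contour(contour: Contour, remove_fraction: float = 0.99) -> Contour:
    """Uniformly decimate a contour, removing ~``remove_fraction`` of vertices.

    Keeps every ceil(1/(1-remove_fraction))-th vertex starting from the
    first.  If decimation would leave fewer than 3 vertices, 3 evenly
    spaced vertices are kept instead (with a warning).  Retained vertices
    are always a subsequence of the input.
    """
    if not 0.0 <= remove_fraction < 1.0:
        raise ValueError("remove_fraction must be in [0, 1)")
    v = contour.vertices
    n = v.shape[0]
    step = int(np.ceil(1.0 / (1.0 - remove_fraction)))
    idx = np.arange(0, n, step)
    if idx.size < 3:
        warnings.warn("decimation would leave fewer than 3 vertices; keeping 3 evenly spaced")
        idx = np.unique(np.linspace(0, n - 1, 3).round().astype(int))
    return Contour(v[idx], contour.pixel_size_um)


def landmark_distances(
    centroid_um: tuple[float, float],
    pv_landmarks: np.ndarray,
    cv_landmarks: np.ndarray,
) -> tuple[float, float]:
    """Euclidean distance (um) to the nearest PV and nearest CV landmark."""
    c = np.asarray(centroid_um, dtype=float)
    pv = np.atleast_2d(np.asarray(pv_landmarks, dtype=float))
    cv = np.atleast_2d(np.asarray(cv_landmarks, dtype=float))
    if pv.size == 0 or cv.size == 0:
        raise ValueError("need at least one PV and one CV landmark")
    d_pv = float(np.min(np.hypot(*(pv - c).T)))
    d_cv = float(np.min(np.hypot(*(cv - c).T)))
    return (d_pv, d_cv)
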