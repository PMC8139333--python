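"""Univariate shape descriptors and CIELAB color statistics of fruit tiles.

Linear descriptors: area, perimeter, circularity (4*pi*A / convex-hull
perimeter squared), solidity (A / hull area), aspect (height / max width),
moment-ellipse axis ratio, widths at 25/50/75% of height, total height and
maximum width.  Color statistics are CIELAB means and ranges over fruit
pixels in the 8-bit offset encoding (L * 255/100, a + 128, b + 128) so that
values are commensurate with 8-bit channel conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from skimage.color import rgb2lab
from skimage.measure import find_contours, label as cc_label, regionprops

from .segmentation import FruitTile

__all__ = ["LinearDescriptorRecord", "LabStats", "descriptors", "lab_stats", "trace_contour"]


@dataclass
class LinearDescriptorRecord:
    area: float
    perimeter: float
    circularity: float
    solidity: float
    aspect: float
    ellipse_ratio: float
    width_25: float
    width_50: float
    width_75: float
    height: float
    max_width: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


@dataclass
class LabStats:
    L_mean: float
    a_mean: float
    b_mean: float
    L_range: tuple[float, float]
    a_range: tuple[float, float]
    b_range: tuple[float, float]

    def as_dict(self) -> dict[str, float]:
        return {
            "L_mean": self.L_mean,
            "a_mean": self.a_mean,
            "b_mean": self.b_mean,
            "L_min": self.L_range[0],
            "L_max": self.L_range[1],
            "a_min": self.a_range[0],
            "a_max": self.a_range[1],
            "b_min": self.b_range[0],
            "b_max": self.b_range[1],
        }


def trace_contour(mask: np.ndarray) -> np.ndarray:
    """Trace the object boundary as a closed (row, col) polygon.

    Uses marching squares at level 0.5 on the zero-padded mask, so the
    polygon passes midway between foreground and background pixel centers
    (a solid h x w rectangle of pixels traces to an exactly h x w polygon).
    """
    padded = np.pad(np.asarray(mask, dtype=float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        raise ValueError("empty mask")
    longest = max(contours, key=len)
    return longest[:-1] - 1.0  # drop duplicated endpoint, undo padding


def _polyline_length(poly: np.ndarray) -> float:
    closed = np.vstack([poly, poly[:1]])
    return float(np.hypot(*np.diff(closed, axis=0).T).sum())


def descriptors(mask: np.ndarray) -> LinearDescriptorRecord:
    """Linear shape descriptors of a single-component binary mask.

    Widths are measured per pixel row from the top of the bounding box
    (fruits are oriented calyx-up by convention); ``width_q`` is the
    horizontal extent of the foreground in the row at q * height.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    if cc_label(m, connectivity=2).max() != 1:
        raise ValueError("mask must contain exactly one connected component")
    area = float(m.sum())
    contour = trace_contour(m)
    perimeter = _polyline_length(contour)
    hull = ConvexHull(contour)
    hull_perimeter = float(hull.area)  # in 2-D, .area is the hull boundary length
    hull_area = float(hull.volume)
    circularity = 4.0 * np.pi * area / hull_perimeter**2
    # marching squares cuts convex corners by half a pixel, which can push
    # the ratio a hair above 1 for convex shapes; clip to the definition
    solidity = min(1.0, area / hull_area)

    rows = np.nonzero(m.any(axis=1))[0]
    r0, r1 = rows[0], rows[-1] + 1
    height = float(r1 - r0)
    col_idx = np.arange(m.shape[1])
    widths = np.array(
        [col_idx[m[r]].max() - col_idx[m[r]].min() + 1 if m[r].any() else 0 for r in range(r0, r1)],
        dtype=float,
    )
    max_width = float(widths.max())

    def width_at(q: float) -> float:
        r = min(int(q * height), int(height) - 1)
        return float(widths[r])

    props = regionprops(m.astype(np.uint8))[0]
    minor = props.axis_minor_length
    ellipse_ratio = props.axis_major_length / minor if minor > 0 else np.inf
    return LinearDescriptorRecord(
        area=area,
        perimeter=perimeter,
        circularity=circularity,
        solidity=solidity,
        aspect=height / max_width,
        ellipse_ratio=float(ellipse_ratio),
        width_25=width_at(0.25),
        width_50=width_at(0.50),
        width_75=width_at(0.75),
        height=height,
        max_width=max_width,
    )


def lab_stats(tile: FruitTile | np.ndarray, mask: np.ndarray | None = None) -> LabStats:
    """CIELAB statistics over fruit pixels, 8-bit offset encoding.

    L is rescaled by 255/100 and the chromatic axes are offset by +128, so
    an achromatic pixel has a = b = 128 and all values live on a 0-255-like
    scale.
    """
    if isinstance(tile, FruitTile):
        pixels, mask = tile.pixels, tile.fruit_mask
    else:
        pixels = np.asarray(tile)
        if mask is None:
            mask = pixels.any(axis=2)
    if not mask.any():
        raise ValueError("no fruit pixels")
    lab = rgb2lab(pixels / 255.0)
    L = lab[..., 0][mask] * 255.0 / 100.0
    a = lab[..., 1][mask] + 128.0
    b = lab[..., 2][mask] + 128.0
    return LabStats(
        L_mean=float(L.mean()),
        a_mean=float(a.mean()),
        b_mean=float(b.mean()),
        L_range=(float(L.min()), float(L.max())),
        a_range=(float(a.min()), float(a.max())),
        b_range=(float(b.min()), float(b.max())),
    )
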