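"""Shared fixtures: rendered boards, analytic contours, matched tiles."""

from __future__ import annotations

import numpy as np
import pytest

from fruitmorph import fixtures, segmentation


def ray_polygon(radius_fn, n: int = 200) -> np.ndarray:
    """Polygon whose vertices lie exactly on the landmarking ray directions."""
    t = np.arange(n) * 2 * np.pi / n
    u = np.column_stack([-np.cos(t), np.sin(t)])
    return radius_fn(t)[:, None] * u


def ellipse_radius(a: float, b: float):
    """Polar radius of an axis-aligned ellipse (column semi-axis a, row b)."""

    def r(theta):
        return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)

    return r


@pytest.fixture(scope="session")
def board_and_truth():
    spec = fixtures.BoardSpec(seed=3)
    return fixtures.render_board(spec)


@pytest.fixture(scope="session")
def matched_tiles():
    """Tiles from three boards with ground-truth side labels, centroid-matched."""
    tiles, truth = [], []
    for s in range(3):
        img, gt = fixtures.render_board(fixtures.BoardSpec(seed=s))
        mask = segmentation.morph_clean(segmentation.binarize(img, "mean"))
        rois = [r for r in segmentation.extract_rois(mask, img) if r.object_class == "fruit"]
        for r in rois:
            d = [np.hypot(r.centroid[0] - c[0], r.centroid[1] - c[1]) for c in gt.centroids]
            j = int(np.argmin(d))
            truth.append("external" if gt.color_labels[j] == 0 else "internal")
            tiles.append(segmentation.make_tile(r, img, size=360))
    return tiles, truth
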