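"""Board-image segmentation: from raw photograph to curated fruit tiles.

The stages mirror the acquisition protocol of fruits laid on a near-black
surface: Gaussian blur + global threshold (mean of the blurred grayscale, or
Otsu), binary opening, connected-component ROI extraction with a rule that
separates fruits from the printed label card, square fruit-centered tiles
with an exactly black background, and a batch-relative k-means split of
tiles into internal (cut face) and external sides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2hsv, rgb2lab
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.transform import rescale
from sklearn.cluster import KMeans

__all__ = [
    "SegmentedObject",
    "FruitTile",
    "SideFeatures",
    "binarize",
    "morph_clean",
    "extract_rois",
    "make_tile",
    "side_features",
    "classify_side",
    "segment_board",
    "LabelReader",
    "filename_label_reader",
]

_LUMA = np.array([0.2125, 0.7154, 0.0721])  # Rec. 709, as used by rgb2gray


@dataclass
class SegmentedObject:
    """One connected region of the board foreground."""

    mask: np.ndarray  # H x W bool
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    centroid: tuple[float, float]
    area_px: int
    object_class: str  # fruit | label | distractor


@dataclass
class FruitTile:
    """A square, background-black, fruit-centered RGB crop."""

    pixels: np.ndarray  # S x S x 3 uint8
    genotype: str = ""
    side: str = ""  # internal | external (set by classify_side)
    fruit_index: int = 0
    downscaled_by: float = 1.0

    @property
    def fruit_mask(self) -> np.ndarray:
        return self.pixels.any(axis=2)


@dataclass
class SideFeatures:
    """Per-tile grayscale statistics used for the internal/external split."""

    color_mean: float
    color_sd: float
    mean_sd_ratio: float


def binarize(image: np.ndarray, method: str = "mean", blur_size: int = 5) -> np.ndarray:
    """Foreground mask from the blurred grayscale image.

    The RGB image is converted to grayscale by the standard luminance
    weighting, blurred with a Gaussian of the given (odd) window size, and
    thresholded at either the mean pixel value or the Otsu threshold.
    Comparison is strict: ties go to background.
    """
    if blur_size < 1 or blur_size % 2 == 0:
        raise ValueError("blur_size must be odd and >= 1")
    img = np.asarray(image)
    gray = img @ _LUMA if img.ndim == 3 else img.astype(float)
    if blur_size == 1:
        blurred = gray
    else:
        # sigma chosen so the Gaussian's effective support matches the window
        sigma = 0.3 * ((blur_size - 1) * 0.5 - 1) + 0.8
        blurred = gaussian(gray, sigma=sigma, preserve_range=True)
    if method == "mean":
        thr = blurred.mean()
    elif method == "otsu":
        if blurred.max() == blurred.min():
            warnings.warn("constant image: Otsu threshold undefined, returning all-background")
            return np.zeros(blurred.shape, dtype=bool)
        thr = threshold_otsu(blurred.astype(np.uint8) if img.dtype == np.uint8 else blurred)
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return blurred > thr


def morph_clean(
    mask: np.ndarray, erode_iter: int = 1, dilate_iter: int = 1, kernel_size: int = 3
) -> np.ndarray:
    """Binary erosion then dilation with a square structuring element."""
    if erode_iter < 0 or dilate_iter < 0:
        raise ValueError("iteration counts must be >= 0")
    selem = np.ones((kernel_size, kernel_size), dtype=bool)
    out = np.asarray(mask, dtype=bool)
    if erode_iter:
        out = ndi.binary_erosion(out, structure=selem, iterations=erode_iter)
    if dilate_iter:
        out = ndi.binary_dilation(out, structure=selem, iterations=dilate_iter)
    return out


def extract_rois(
    mask: np.ndarray,
    image: np.ndarray,
    min_area_frac: float = 0.0005,
    max_area_frac: float = 0.25,
    label_extent: float = 0.85,
    label_saturation: float = 0.15,
) -> list[SegmentedObject]:
    """Connected components of the foreground, classified fruit/label/distractor.

    An ROI is the label card iff its extent (area / bbox area) is at least
    ``label_extent`` and its mean HSV saturation is at most
    ``label_saturation`` — a bright, low-saturation rectangle.  ROIs outside
    the [min, max] area bounds are distractors; everything else is a fruit.
    """
    lab = cc_label(np.asarray(mask, dtype=bool), connectivity=2)
    img = np.asarray(image)
    total = mask.size
    objs: list[SegmentedObject] = []
    props = regionprops(lab)
    if not props:
        warnings.warn("no foreground components found")
        return objs
    sat = rgb2hsv(img)[..., 1] if img.ndim == 3 else np.zeros(mask.shape)
    for p in props:
        if p.area < min_area_frac * total:
            continue
        region_mask = lab == p.label
        extent = p.area / ((p.bbox[2] - p.bbox[0]) * (p.bbox[3] - p.bbox[1]))
        mean_sat = float(sat[region_mask].mean())
        if extent >= label_extent and mean_sat <= label_saturation:
            cls = "label"
        elif p.area > max_area_frac * total:
            cls = "distractor"
        else:
            cls = "fruit"
        objs.append(
            SegmentedObject(
                mask=region_mask,
                bbox=tuple(p.bbox),
                centroid=tuple(p.centroid),
                area_px=int(p.area),
                object_class=cls,
            )
        )
    return objs


def make_tile(
    obj: SegmentedObject,
    image: np.ndarray,
    size: int = 1000,
    genotype: str = "",
    fruit_index: int = 0,
    allow_downscale: bool = True,
) -> FruitTile:
    """Center the fruit in a size x size tile with an exactly black background."""
    if obj.object_class != "fruit":
        raise ValueError(f"make_tile expects a fruit ROI, got {obj.object_class!r}")
    if obj.area_px == 0:
        raise ValueError("empty object")
    img = np.asarray(image)
    r0, c0, r1, c1 = obj.bbox
    crop = np.where(obj.mask[r0:r1, c0:c1, None], img[r0:r1, c0:c1], 0).astype(np.uint8)
    cmask = obj.mask[r0:r1, c0:c1]
    factor = 1.0

    def needed_span(mask2d):
        # span required to place the mask with its centroid on the tile center
        rr, cc = np.nonzero(mask2d)
        h2, w2 = mask2d.shape
        return 2 * max(
            rr.mean(), h2 - rr.mean(), cc.mean(), w2 - cc.mean()
        )

    if needed_span(cmask) > size:
        if not allow_downscale:
            raise ValueError(
                f"fruit of extent {crop.shape[:2]} cannot be centered in a {size}px tile"
            )
        factor = size / needed_span(cmask) * 0.995
        crop = (rescale(crop, factor, channel_axis=2, preserve_range=True)).astype(np.uint8)
        cmask = rescale(cmask.astype(float), factor, preserve_range=True) > 0.5
        crop[~cmask] = 0
    h, w = crop.shape[:2]
    rr, cc = np.nonzero(cmask)
    cen = rr.mean(), cc.mean()
    tile = np.zeros((size, size, 3), dtype=np.uint8)
    off_r = min(max(int(round(size / 2 - cen[0])), 0), size - h)
    off_c = min(max(int(round(size / 2 - cen[1])), 0), size - w)
    tile[off_r : off_r + h, off_c : off_c + w] = crop
    return FruitTile(tile, genotype=genotype, fruit_index=fruit_index, downscaled_by=factor)


def side_features(tile: FruitTile) -> SideFeatures:
    """Grayscale mean, SD and their ratio over fruit pixels only."""
    gray = tile.pixels @ _LUMA
    vals = gray[tile.fruit_mask]
    if vals.size == 0:
        raise ValueError("tile has no fruit pixels")
    m, s = float(vals.mean()), float(vals.std())
    return SideFeatures(m, s, m / s if s > 0 else np.inf)


def classify_side(tiles: Sequence[FruitTile], seed: int = 0) -> list[str]:
    """Batch-relative internal/external split by k-means (k=2) on SideFeatures.

    Features are standardized before clustering; the cluster with the higher
    mean CIELAB L over fruit pixels is labeled ``internal`` (cut surfaces
    expose pale flesh).  The method is batch-relative: both sides should be
    present.
    """
    if len(tiles) < 2:
        raise ValueError("need at least two tiles for a batch-relative split")
    feats = np.array(
        [[f.color_mean, f.color_sd, f.mean_sd_ratio] for f in map(side_features, tiles)]
    )
    for col in range(feats.shape[1]):
        finite = np.isfinite(feats[:, col])
        cap = feats[finite, col].max() if finite.any() else 0.0
        feats[~finite, col] = cap
    sd = feats.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("all tiles identical: cannot split into sides")
    z = (feats - feats.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(z)
    L_by_cluster = np.zeros(2)
    for c in (0, 1):
        Ls = [
            rgb2lab(t.pixels / 255.0)[..., 0][t.fruit_mask].mean()
            for t, lab in zip(tiles, km.labels_)
            if lab == c
        ]
        L_by_cluster[c] = np.mean(Ls) if Ls else -np.inf
    internal = int(np.argmax(L_by_cluster))
    sides = ["internal" if lab == internal else "external" for lab in km.labels_]
    for t, s in zip(tiles, sides):
        t.side = s
    return sides


LabelReader = Callable[[np.ndarray], str]


def filename_label_reader(source: str) -> LabelReader:
    """Default OCR stub: ignore the card image, return the file stem."""

    def read(_card: np.ndarray) -> str:
        from pathlib import Path

        return Path(source).stem

    return read


def segment_board(
    image: np.ndarray,
    tile_size: int = 1000,
    method: str = "mean",
    blur_size: int = 5,
    erode_iter: int = 1,
    dilate_iter: int = 1,
    kernel_size: int = 3,
    label_reader: LabelReader | None = None,
    source: str = "board",
) -> list[FruitTile]:
    """Full single-board pipeline: binarize, clean, extract, tile.

    Side classification is batch-relative and therefore left to the caller
    (apply :func:`classify_side` over all tiles of a genotype).
    """
    mask = binarize(image, method=method, blur_size=blur_size)
    mask = morph_clean(mask, erode_iter, dilate_iter, kernel_size)
    rois = extract_rois(mask, image)
    genotype = source
    labels = [o for o in rois if o.object_class == "label"]
    if labels:
        card = labels[0]
        r0, c0, r1, c1 = card.bbox
        reader = label_reader or filename_label_reader(source)
        genotype = reader(np.asarray(image)[r0:r1, c0:c1])
    tiles = [
        make_tile(o, image, size=tile_size, genotype=genotype, fruit_index=i)
        for i, o in enumerate(o for o in rois if o.object_class == "fruit")
    ]
    return tiles
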