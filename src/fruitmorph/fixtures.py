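"""Seeded synthetic data: board images, fruit contours and pedigree phenotypes.

Real sliced-fruit photographs are not distributable with the package, so
every downstream stage is exercised against generators that emulate the
study conditions: boards of convex-ish fruit silhouettes drawn from two
shape families ("globose", aspect ~ 1, vs "elongated", aspect ~ 2) on a
near-black background with a bright label card, and phenotypes simulated
under the additive + dominance pedigree model y = mu + a + d + eps.

All generators are bit-reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.draw import polygon as draw_polygon

from .genetics import Pedigree, build_A, build_D

__all__ = [
    "ShapeFamilyParams",
    "BoardSpec",
    "GroundTruth",
    "SimulatedPhenotypes",
    "generate_contour",
    "render_board",
    "save_ground_truth",
    "load_ground_truth",
    "generate_silhouettes",
    "render_disc_with_wedge",
    "cross_pedigree",
    "simulate_phenotypes",
    "GLOBOSE",
    "ELONGATED",
]


@dataclass(frozen=True)
class ShapeFamilyParams:
    """Parameters of one fruit shape family.

    ``aspect_mean`` is the height/width ratio (~1 for globose fruits, >1 for
    elongated ones); ``boundary_noise`` is the relative amplitude of the
    low-order radial perturbation applied to the base ellipse.
    """

    family: str = "globose"
    aspect_mean: float = 1.0
    aspect_sd: float = 0.05
    boundary_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.boundary_noise <= 0.2:
            raise ValueError("boundary_noise must lie in [0, 0.2]")
        if self.family not in ("globose", "elongated"):
            raise ValueError("family must be 'globose' or 'elongated'")


GLOBOSE = ShapeFamilyParams("globose", aspect_mean=1.0)
ELONGATED = ShapeFamilyParams("elongated", aspect_mean=2.0)


def generate_contour(
    params: ShapeFamilyParams,
    n_points: int = 120,
    radius: float = 60.0,
    center: tuple[float, float] = (0.0, 0.0),
    rng: np.random.Generator | None = None,
    max_retries: int = 20,
) -> np.ndarray:
    """A closed fruit outline as an (n_points, 2) array of (row, col) vertices.

    The outline is a radius-modulated ellipse: the polar radius of an ellipse
    with column semi-axis ``radius`` and row semi-axis ``radius*aspect`` is
    multiplied by ``1 + sum_m c_m cos(m theta + phi_m)`` over harmonics
    m = 2..5 with total amplitude ``boundary_noise``.  Because the radius
    function stays positive the polygon is star-shaped about its center and
    simple by construction.  Vertices are ordered counter-clockwise
    (positive shoelace area in (col, row) axes).
    """
    if n_points < 30:
        raise ValueError("n_points must be >= 30")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    for _ in range(max_retries):
        aspect = max(0.3, rng.normal(params.aspect_mean, params.aspect_sd))
        a = radius  # column semi-axis
        b = radius * aspect  # row semi-axis
        r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        if params.boundary_noise > 0:
            amps = rng.uniform(0.3, 1.0, 4)
            amps *= params.boundary_noise / amps.sum()
            phases = rng.uniform(0.0, 2.0 * np.pi, 4)
            mod = np.ones_like(theta)
            for m, (c, ph) in enumerate(zip(amps, phases), start=2):
                mod += c * np.cos(m * theta + ph)
            r = r * mod
        if r.min() > 0.1 * radius:
            row = center[0] + r * np.sin(theta)
            col = center[1] + r * np.cos(theta)
            return np.column_stack([row, col])
    raise RuntimeError("could not generate a valid contour within the retry cap")


@dataclass
class BoardSpec:
    """Layout of one synthetic board image."""

    n_fruits: int = 4
    families: tuple[ShapeFamilyParams, ...] = (GLOBOSE, ELONGATED)
    fruit_colors: tuple[tuple[int, int, int], ...] = ((150, 30, 30), (235, 200, 180))
    label_text: str = "GENO-001"
    board_size: tuple[int, int] = (768, 1024)
    background_level: int = 15
    fruit_radius: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_level >= 40:
            raise ValueError("background must be near-black (level < 40)")


@dataclass
class GroundTruth:
    """Pixel-exact per-fruit truth emitted alongside every rendered board."""

    masks: list[np.ndarray]
    centroids: list[tuple[float, float]]
    family_labels: list[str]
    color_labels: list[int]
    contours: list[np.ndarray]
    label_box: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open

    @property
    def foreground(self) -> np.ndarray:
        out = np.zeros_like(self.masks[0]) if self.masks else None
        for m in self.masks:
            out |= m
        return out


def _draw_label_card(img: np.ndarray, rng: np.random.Generator) -> tuple[int, int, int, int]:
    h, w = img.shape[:2]
    ch, cw = h // 8, w // 4
    r0, c0 = h // 40, w // 40
    img[r0 : r0 + ch, c0 : c0 + cw] = 235
    # dark glyph-like strokes (not meaningful text; OCR is a pluggable hook)
    n_strokes = 6
    for i in range(n_strokes):
        sc = c0 + int((i + 0.5) * cw / n_strokes)
        top = r0 + ch // 4 + int(rng.integers(0, ch // 6))
        bot = r0 + 3 * ch // 4
        img[top:bot, sc : sc + 2] = 20
        if rng.random() < 0.5:
            img[top : top + 2, sc - cw // (3 * n_strokes) : sc + 2] = 20
    return (r0, c0, r0 + ch, c0 + cw)


def render_board(spec: BoardSpec, max_retries: int = 200) -> tuple[np.ndarray, GroundTruth]:
    """Render a board image and its pixel-exact ground truth.

    Fruits alternate through ``spec.families`` (and the matching entry of
    ``spec.fruit_colors``), are placed without overlap below the label card,
    and are filled with their base color plus a mild radial shading and
    pixel-level texture so color statistics are non-degenerate.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.board_size
    img = np.full((H, W, 3), spec.background_level, dtype=np.uint8)
    label_box = _draw_label_card(img, rng)

    R = spec.fruit_radius
    max_r = R * 2.4 * 1.25  # elongated semi-axis + noise headroom
    placed: list[tuple[float, float, float]] = []
    masks, centroids, fams, colors_used, contours = [], [], [], [], []
    for i in range(spec.n_fruits):
        fam = spec.families[i % len(spec.families)]
        color = np.array(spec.fruit_colors[i % len(spec.fruit_colors)], dtype=float)
        reff = R * max(1.0, fam.aspect_mean) * (1 + fam.boundary_noise)
        for attempt in range(max_retries):
            cr = rng.uniform(label_box[2] + reff + 5, H - reff - 5)
            cc = rng.uniform(reff + 5, W - reff - 5)
            if all(np.hypot(cr - pr, cc - pc) > reff + pr_r + 8 for pr, pc, pr_r in placed):
                break
        else:
            raise RuntimeError(f"could not place fruit {i} without overlap")
        placed.append((cr, cc, reff))
        contour = generate_contour(fam, n_points=160, radius=R, center=(cr, cc), rng=rng)
        rr, cc_px = draw_polygon(contour[:, 0], contour[:, 1], shape=(H, W))
        mask = np.zeros((H, W), dtype=bool)
        mask[rr, cc_px] = True
        # radial shading + texture inside the fruit
        dr = rr - cr
        dc = cc_px - cc
        shade = 1.0 - 0.25 * np.clip(np.hypot(dr, dc) / reff, 0, 1) ** 2
        noise = rng.normal(0.0, 4.0, size=(rr.size, 3))
        vals = np.clip(color[None, :] * shade[:, None] + noise, 0, 255)
        img[rr, cc_px] = vals.astype(np.uint8)
        masks.append(mask)
        centroids.append((float(rr.mean()), float(cc_px.mean())))
        fams.append(fam.family)
        colors_used.append(i % len(spec.fruit_colors))
        contours.append(contour)
    gt = GroundTruth(masks, centroids, fams, colors_used, contours, label_box)
    return img, gt


def _rle_encode(mask: np.ndarray) -> str:
    flat = mask.ravel(order="C").astype(np.int8)
    edges = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], edges, [flat.size]])
    runs = np.diff(bounds)
    start = int(flat[0])
    return f"{start}:" + ",".join(map(str, runs.tolist()))


def _rle_decode(s: str, shape: tuple[int, int]) -> np.ndarray:
    start, runs_s = s.split(":")
    runs = np.array([int(r) for r in runs_s.split(",")])
    vals = (np.arange(runs.size) + int(start)) % 2
    return np.repeat(vals.astype(bool), runs).reshape(shape)


def save_ground_truth(gt: GroundTruth, path) -> None:
    """Write ground truth as a JSON sidecar with run-length-encoded masks."""
    shape = gt.masks[0].shape if gt.masks else (0, 0)
    payload = {
        "shape": list(shape),
        "masks": [_rle_encode(m) for m in gt.masks],
        "centroids": gt.centroids,
        "family_labels": gt.family_labels,
        "color_labels": gt.color_labels,
        "contours": [c.tolist() for c in gt.contours],
        "label_box": list(gt.label_box),
    }
    Path(path).write_text(json.dumps(payload))


def load_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    shape = tuple(payload["shape"])
    return GroundTruth(
        masks=[_rle_decode(s, shape) for s in payload["masks"]],
        centroids=[tuple(c) for c in payload["centroids"]],
        family_labels=payload["family_labels"],
        color_labels=payload["color_labels"],
        contours=[np.array(c) for c in payload["contours"]],
        label_box=tuple(payload["label_box"]),
    )


def generate_silhouettes(
    n_per_family: int,
    families: tuple[ShapeFamilyParams, ...] = (GLOBOSE, ELONGATED),
    size: int = 64,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary silhouette images for the shape-clustering stage.

    Returns ``(images, labels)`` with images of shape (n, size, size) in
    {0, 1} (float) and integer family labels.  Each silhouette is a contour
    from its family rasterized centered, scaled to fit the frame.
    """
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for fi, fam in enumerate(families):
        for _ in range(n_per_family):
            contour = generate_contour(fam, n_points=100, radius=1.0, rng=rng)
            span = max(
                contour[:, 0].max() - contour[:, 0].min(),
                contour[:, 1].max() - contour[:, 1].min(),
            )
            scale = 0.85 * size / span
            c = contour * scale
            c[:, 0] += size / 2 - c[:, 0].mean()
            c[:, 1] += size / 2 - c[:, 1].mean()
            rr, cc = draw_polygon(c[:, 0], c[:, 1], shape=(size, size))
            im = np.zeros((size, size), dtype=float)
            im[rr, cc] = 1.0
            images.append(im)
            labels.append(fi)
    return np.stack(images), np.array(labels)


def render_disc_with_wedge(
    size: int = 200,
    disc_color: tuple[int, int, int] = (184, 46, 8),
    wedge_color: tuple[int, int, int] = (76, 75, 20),
    wedge_half_angle_deg: float = 25.0,
    wedge_depth: float = 0.45,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A centered red disc with a green wedge at the top (mock calyx).

    Returns ``(tile, disc_mask, wedge_mask)`` where the wedge mask marks the
    sepal-colored sector and the disc mask the remaining fruit pixels.
    """
    rng = np.random.default_rng(seed)
    tile = np.zeros((size, size, 3), dtype=np.uint8)
    c = (size - 1) / 2.0
    rad = 0.42 * size
    rows, cols = np.mgrid[0:size, 0:size]
    dist = np.hypot(rows - c, cols - c)
    inside = dist <= rad
    # angle from "up" direction
    ang = np.degrees(np.arctan2(cols - c, -(rows - c)))
    wedge = inside & (np.abs(ang) <= wedge_half_angle_deg) & (dist >= (1 - wedge_depth) * rad)
    disc = inside & ~wedge
    for mask, color in ((disc, disc_color), (wedge, wedge_color)):
        vals = np.clip(
            np.array(color, float)[None, :] + rng.normal(0, 3.0, (int(mask.sum()), 3)), 0, 255
        )
        tile[mask] = vals.astype(np.uint8)
    return tile, disc, wedge


def cross_pedigree(
    n_parents: int = 30, n_crosses: int = 24, offspring_per_cross: int = 20, seed: int = 0
) -> Pedigree:
    """A breeding-design pedigree: unrelated parents, full-sib families.

    Mirrors a program of ``n_crosses`` distinct parent pairs with
    ``offspring_per_cross`` full sibs each.
    """
    rng = np.random.default_rng(seed)
    pairs: set[tuple[int, int]] = set()
    while len(pairs) < n_crosses:
        i, j = sorted(rng.choice(n_parents, size=2, replace=False).tolist())
        pairs.add((i, j))
    records = [(f"P{i:03d}", None, None) for i in range(n_parents)]
    for k, (i, j) in enumerate(sorted(pairs)):
        for o in range(offspring_per_cross):
            records.append((f"C{k:02d}O{o:02d}", f"P{i:03d}", f"P{j:03d}"))
    return Pedigree.from_records(records)


@dataclass
class SimulatedPhenotypes:
    """Phenotypes drawn under y = mu + a + d + eps with pedigree covariances."""

    pedigree: Pedigree
    sigma2_a: float
    sigma2_d: float
    sigma2_e: float
    y: np.ndarray
    a_true: np.ndarray
    d_true: np.ndarray
    seed: int
    A: np.ndarray = field(repr=False, default=None)
    D: np.ndarray = field(repr=False, default=None)


def _sym_sqrt(K: np.ndarray) -> np.ndarray:
    w, U = np.linalg.eigh(0.5 * (K + K.T))
    if w.min() < -1e-6:
        raise ValueError("kinship matrix is not positive semidefinite")
    return U @ (np.sqrt(np.clip(w, 0.0, None))[:, None] * U.T)


def simulate_phenotypes(
    pedigree: Pedigree,
    sigma2_a: float,
    sigma2_d: float,
    sigma2_e: float,
    seed: int = 0,
    mu: float = 0.0,
) -> SimulatedPhenotypes:
    """Draw one phenotype vector with Cov(y) = A*s2a + D*s2d + I*s2e.

    Genetic values are realized through the symmetric square roots of A and D.
    """
    if min(sigma2_a, sigma2_d, sigma2_e) < 0:
        raise ValueError("variances must be non-negative")
    rng = np.random.default_rng(seed)
    A = build_A(pedigree)
    D = build_D(pedigree)
    n = len(pedigree)
    a = _sym_sqrt(A) @ rng.standard_normal(n) * np.sqrt(sigma2_a)
    d = _sym_sqrt(D) @ rng.standard_normal(n) * np.sqrt(sigma2_d)
    eps = rng.standard_normal(n) * np.sqrt(sigma2_e)
    y = mu + a + d + eps
    return SimulatedPhenotypes(pedigree, sigma2_a, sigma2_d, sigma2_e, y, a, d, seed, A, D)
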