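"""Pseudolandmarks and Generalized Procrustes Analysis of fruit outlines.

Fifty (by default) pseudolandmarks are placed where equally spaced rays
from the outline's area centroid intersect the contour.  Configurations are
then superimposed by GPA (translation, scale and rotation removed; no
reflection), per-landmark variability is summarized, aligned coordinates
feed a PCA, and group effects on shape are tested by a permutation
Procrustes ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "LandmarkConfiguration",
    "GPAResult",
    "ProcrustesAnovaResult",
    "polygon_centroid",
    "orient_contour",
    "radial_landmarks",
    "gpa_align",
    "variable_regions",
    "procrustes_anova",
    "shape_pca",
]


@dataclass
class LandmarkConfiguration:
    points: np.ndarray  # k x 2 (row, col), ordered by ray angle
    source_id: str = ""


@dataclass
class GPAResult:
    aligned: np.ndarray  # n x k x 2
    mean_shape: np.ndarray  # k x 2, centered, unit centroid size
    centroid_sizes: np.ndarray  # n
    per_landmark_sd: np.ndarray  # k
    iterations_used: int
    objective_history: list[float] = None  # sum of squared distances to the mean, per iteration


@dataclass
class ProcrustesAnovaResult:
    observed_stat: float
    p_value: float
    n_perm: int


def polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    """Area centroid of a closed polygon (shoelace), robust to uneven spacing."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 1], v[:, 0]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area6 = 3.0 * cross.sum()
    if area6 == 0:
        raise ValueError("degenerate polygon")
    cx = ((x + xn) * cross).sum() / area6
    cy = ((y + yn) * cross).sum() / area6
    return np.array([cy, cx])


def orient_contour(contour: np.ndarray) -> np.ndarray:
    """Rotate a contour so its major principal axis is vertical, flat end up.

    Landmark correspondence across fruits needs a common orientation: the
    major axis of the vertex scatter is rotated onto the row axis, then the
    contour is flipped (180 degrees) if the end with the lower local radial
    variance — the flatter, calyx end — is not at the top (smaller row).
    """
    v = np.asarray(contour, dtype=float)
    c = polygon_centroid(v)
    centered = v - c
    cov = np.cov(centered.T)
    w, U = np.linalg.eigh(cov)
    major = U[:, np.argmax(w)]  # (row, col) direction
    # rotation sending the major axis onto (1, 0) i.e. the row axis
    ang = np.arctan2(major[1], major[0])
    R = np.array([[np.cos(ang), np.sin(ang)], [-np.sin(ang), np.cos(ang)]])
    rot = centered @ R.T
    r = np.hypot(rot[:, 0], rot[:, 1])
    top = rot[:, 0] < 0
    if top.sum() >= 3 and (~top).sum() >= 3 and r[top].var() > r[~top].var():
        rot = -rot
    return rot + c


def radial_landmarks(
    contour: np.ndarray | LandmarkConfiguration,
    k: int = 50,
    theta0: float | None = None,
    source_id: str = "",
) -> LandmarkConfiguration:
    """Intersections of k equally spaced centroid rays with the contour.

    Rays start at the polygon's area centroid; the default start angle
    points "up" (decreasing row).  Intersections use exact ray/segment
    algebra; where a ray crosses the outline more than once the farthest
    point is kept (protrusions preserved).
    """
    v = np.asarray(contour if not isinstance(contour, LandmarkConfiguration) else contour.points)
    c = polygon_centroid(v)
    p = v - c
    q = np.roll(p, -1, axis=0) - p  # segment direction vectors
    if theta0 is None:
        theta0 = 0.0
    points = np.empty((k, 2))
    multi = 0
    for i in range(k):
        ang = theta0 + 2.0 * np.pi * i / k
        u = np.array([-np.cos(ang), np.sin(ang)])  # up at theta0=0, CCW in (row,col)
        # solve p_j + s * q_j = t * u  for each segment j
        det = q[:, 0] * u[1] - q[:, 1] * u[0]
        ok = np.abs(det) > 1e-12
        s = np.where(ok, (p[:, 1] * u[0] - p[:, 0] * u[1]) / np.where(ok, det, 1.0), -1.0)
        t = np.where(
            np.abs(u[0]) > np.abs(u[1]),
            (p[:, 0] + s * q[:, 0]) / u[0],
            (p[:, 1] + s * q[:, 1]) / np.where(u[1] == 0, 1.0, u[1]),
        )
        # tolerance so a ray through a vertex (s ~ 0 on one segment, ~1 on
        # the previous) is counted exactly once
        hits = ok & (s >= -1e-9) & (s < 1.0 - 1e-9) & (t > 0.0)
        if not hits.any():
            raise ValueError("a ray has no intersection: centroid outside the contour?")
        if hits.sum() > 1:
            multi += 1
        tbest = t[hits].max()
        points[i] = c + tbest * u
    if multi >= 0.1 * k:
        warnings.warn(f"contour not star-shaped: {multi}/{k} rays hit the outline multiple times")
    return LandmarkConfiguration(points=points, source_id=source_id)


def _center_and_scale(pts: np.ndarray) -> tuple[np.ndarray, float]:
    c = pts.mean(axis=0)
    centered = pts - c
    size = np.sqrt((centered**2).sum())
    if size == 0:
        raise ValueError("degenerate configuration: all points coincident")
    return centered / size, size


def _optimal_rotation(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Orthogonal rotation (det +1, no reflection) minimizing |src R - dst|."""
    U, _, Vt = np.linalg.svd(src.T @ dst)
    d = np.sign(np.linalg.det(U @ Vt))
    S = np.diag([1.0, d])
    return U @ S @ Vt


def gpa_align(
    configs: list[LandmarkConfiguration] | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GPAResult:
    """Generalized Procrustes superimposition of n landmark configurations."""
    if isinstance(configs, np.ndarray):
        arrays = [configs[i] for i in range(configs.shape[0])]
    else:
        arrays = [c.points for c in configs]
    if len(arrays) < 2:
        raise ValueError("need at least two configurations")
    k = arrays[0].shape[0]
    if any(a.shape != (k, 2) for a in arrays):
        raise ValueError("all configurations must share the same landmark count")
    normed, sizes = zip(*(_center_and_scale(a.astype(float)) for a in arrays))
    X = np.stack(normed)
    mean = X[0].copy()
    mean /= np.sqrt((mean**2).sum())
    it = 0
    history: list[float] = []
    for it in range(1, max_iter + 1):
        for i in range(X.shape[0]):
            X[i] = X[i] @ _optimal_rotation(X[i], mean)
        history.append(float(((X - X.mean(axis=0)) ** 2).sum()))
        new_mean = X.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= np.sqrt((new_mean**2).sum())
        if np.abs(new_mean - mean).max() < tol:
            mean = new_mean
            break
        mean = new_mean
    sd = np.sqrt(X.var(axis=0).sum(axis=1))
    return GPAResult(
        aligned=X,
        mean_shape=mean,
        centroid_sizes=np.array(sizes),
        per_landmark_sd=sd,
        iterations_used=it,
        objective_history=history,
    )


def variable_regions(gpa: GPAResult) -> np.ndarray:
    """Boolean flags marking landmarks whose SD exceeds the mean SD (strict).

    Aligned configurations have unit centroid size, so SDs below 1e-9 are
    numerical noise and never flagged.
    """
    sd = gpa.per_landmark_sd
    return (sd > sd.mean()) & (sd > 1e-9)


def procrustes_anova(
    gpa: GPAResult,
    groups,
    n_perm: int = 100,
    seed: int | None = None,
) -> ProcrustesAnovaResult:
    """Permutation test of a group effect on aligned shape coordinates.

    The statistic is the classical F ratio (between-group SS / df_b) /
    (within SS / df_w) on the flattened aligned coordinates; the p-value
    uses the add-one rule and so lies on the grid {1,...,n_perm+1}/(n_perm+1).
    """
    groups = np.asarray(groups)
    Y = gpa.aligned.reshape(gpa.aligned.shape[0], -1)
    labels, inv = np.unique(groups, return_inverse=True)
    g = labels.size
    n = Y.shape[0]
    if g < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(inv)
    if counts.min() < 2:
        raise ValueError("each group needs at least two members")

    def fstat(inv_labels: np.ndarray) -> float:
        grand = Y.mean(axis=0)
        ssb = 0.0
        for gi in range(g):
            sel = Y[inv_labels == gi]
            diff = sel.mean(axis=0) - grand
            ssb += sel.shape[0] * (diff @ diff)
        sst = ((Y - grand) ** 2).sum()
        ssw = sst - ssb
        return (ssb / (g - 1)) / (ssw / (n - g))

    observed = fstat(inv)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if fstat(rng.permutation(inv)) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return ProcrustesAnovaResult(observed_stat=float(observed), p_value=float(p), n_perm=n_perm)


def shape_pca(gpa: GPAResult) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the flattened aligned coordinates.

    Returns (scores, loadings, explained-variance fractions); fractions sum
    to 1 over all retained components.
    """
    n = gpa.aligned.shape[0]
    if n <= 2:
        raise ValueError("need more than two configurations for a shape PCA")
    Y = gpa.aligned.reshape(n, -1)
    pca = PCA()
    scores = pca.fit_transform(Y)
    return scores, pca.components_, pca.explained_variance_ratio_
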