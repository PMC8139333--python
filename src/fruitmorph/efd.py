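"""Elliptical Fourier descriptors (EFD) of closed fruit outlines.

A closed contour is expanded as a truncated Fourier series whose harmonics
are rotating ellipses (Kuhl–Giardina formulation, arc-length
parameterization of the polygonal outline).  Four harmonics — 16
coefficients — suffice for fruit-like shapes.  The set supports the
conventional first-ellipse normalization (size, rotation and starting-point
invariance), reconstruction at arbitrary resolution, and a PCA across
specimens with a k-means helper on the leading scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = ["EFDSet", "efd_decompose", "efd_normalize", "efd_reconstruct", "efd_pca"]


@dataclass
class EFDSet:
    """Coefficients of one outline: per harmonic (a_n, b_n, c_n, d_n).

    ``coeffs`` has shape (n_harmonics, 4); x(t) uses (a, b), y(t) uses
    (c, d), with x = column and y = row of the image plane.  ``dc`` is the
    (A0, C0) centroid term.
    """

    coeffs: np.ndarray
    dc: tuple[float, float]
    normalized: bool = False

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_coefficients(self) -> int:
        return int(self.coeffs.size)

    def flat(self) -> np.ndarray:
        return self.coeffs.ravel()


def efd_decompose(contour: np.ndarray, n_harmonics: int = 4) -> EFDSet:
    """Elliptical Fourier coefficients of a closed (row, col) polygon.

    Coefficients are the exact piecewise-linear arc-length integrals

        a_n = T/(2 n^2 pi^2) sum_i (dx_i/dt_i) (cos phi_i - cos phi_{i-1}),

    with phi_i = 2 pi n t_i / T, and analogously b (sine terms) and c, d for
    the y coordinate.  The dc term is the exact trapezoid average of the
    coordinates over arc length.
    """
    v = np.asarray(contour, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError("contour must be an (N, 2) array")
    if v.shape[0] < 2 * n_harmonics + 1:
        raise ValueError("contour has too few vertices for the requested order")
    x = v[:, 1]
    y = v[:, 0]
    dx = np.diff(np.append(x, x[0]))
    dy = np.diff(np.append(y, y[0]))
    dt = np.hypot(dx, dy)
    keep = dt > 0
    if not keep.any():
        raise ValueError("degenerate contour of zero length")
    dx, dy, dt = dx[keep], dy[keep], dt[keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T
    n = np.arange(1, n_harmonics + 1)[:, None]
    dcos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    dsin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    const = T / (2.0 * np.pi**2 * n.ravel() ** 2)
    a = const * (dx / dt * dcos).sum(axis=1)
    b = const * (dx / dt * dsin).sum(axis=1)
    c = const * (dy / dt * dcos).sum(axis=1)
    d = const * (dy / dt * dsin).sum(axis=1)
    # trapezoid average over arc length (exact for piecewise-linear outline)
    x0, y0 = x[keep], y[keep]
    x1 = x0 + dx
    y1 = y0 + dy
    A0 = float((dt * (x0 + x1) / 2.0).sum() / T)
    C0 = float((dt * (y0 + y1) / 2.0).sum() / T)
    return EFDSet(np.column_stack([a, b, c, d]), dc=(A0, C0), normalized=False)


def _rotate_start(coeffs: np.ndarray, theta: float) -> np.ndarray:
    out = np.empty_like(coeffs)
    for i, (a, b, c, d) in enumerate(coeffs):
        nt = (i + 1) * theta
        ct, st = np.cos(nt), np.sin(nt)
        out[i, 0] = a * ct + b * st
        out[i, 1] = -a * st + b * ct
        out[i, 2] = c * ct + d * st
        out[i, 3] = -c * st + d * ct
    return out


def _rotate_space(coeffs: np.ndarray, psi: float) -> np.ndarray:
    cp, sp = np.cos(psi), np.sin(psi)
    out = np.empty_like(coeffs)
    out[:, 0] = cp * coeffs[:, 0] + sp * coeffs[:, 2]
    out[:, 1] = cp * coeffs[:, 1] + sp * coeffs[:, 3]
    out[:, 2] = -sp * coeffs[:, 0] + cp * coeffs[:, 2]
    out[:, 3] = -sp * coeffs[:, 1] + cp * coeffs[:, 3]
    return out


def _normalize_candidate(coeffs: np.ndarray, theta: float) -> np.ndarray:
    c = _rotate_start(coeffs, theta)
    a1, b1, c1, d1 = c[0]
    psi = np.arctan2(c1, a1)
    c = _rotate_space(c, psi)
    E = c[0, 0]
    return c / E


def efd_normalize(efd: EFDSet) -> EFDSet:
    """First-ellipse normalization: size, rotation, starting-point invariant.

    The parameter origin is shifted onto the first harmonic's semi-major
    axis, the outline is rotated so that axis lies along x, and all
    coefficients are scaled by the semi-major length (a1 becomes 1, b1 and
    c1 become 0).  The residual half-turn ambiguity of the major axis is
    broken deterministically by choosing the candidate whose rounded
    coefficient vector is lexicographically larger.  The dc term is kept
    unchanged (it carries location, which normalization disregards).
    """
    if efd.normalized:
        return efd
    a1, b1, c1, d1 = efd.coeffs[0]
    denom = a1**2 + c1**2 - b1**2 - d1**2
    num = 2.0 * (a1 * b1 + c1 * d1)
    if abs(num) < 1e-12 and abs(denom) < 1e-12:
        warnings.warn("circular first harmonic: rotation undefined, using identity")
        theta = 0.0
    else:
        theta = 0.5 * np.arctan2(num, denom)
    # pick the semi-major (not minor) axis
    cand = _rotate_start(efd.coeffs, theta)
    if np.hypot(cand[0, 0], cand[0, 2]) < np.hypot(cand[0, 1], cand[0, 3]):
        theta += 0.5 * np.pi
    c_a = _normalize_candidate(efd.coeffs, theta)
    c_b = _normalize_candidate(efd.coeffs, theta + np.pi)
    chosen = max(c_a, c_b, key=lambda c: tuple(np.round(c.ravel(), 8)))
    return EFDSet(chosen, dc=efd.dc, normalized=True)


def efd_reconstruct(efd: EFDSet, n_points: int = 200) -> np.ndarray:
    """Evaluate the truncated series at equally spaced parameter values.

    Returns an (n_points, 2) closed (row, col) polygon (last point omitted).
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    n = np.arange(1, efd.n_harmonics + 1)[:, None]
    cosnt = np.cos(n * t)
    sinnt = np.sin(n * t)
    a, b, c, d = efd.coeffs.T
    x = efd.dc[0] + a @ cosnt + b @ sinnt
    y = efd.dc[1] + c @ cosnt + d @ sinnt
    return np.column_stack([y, x])


def efd_pca(
    sets: list[EFDSet], n_clusters: int | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None]:
    """PCA across specimens of normalized coefficient vectors.

    The first-harmonic size coefficient a1 (identically 1 after
    normalization) is excluded from the matrix.  If ``n_clusters`` is given,
    k-means on the first two scores is run and its labels returned as the
    fourth element (else None).
    """
    if len(sets) < 3:
        raise ValueError("need at least three coefficient sets")
    if not all(s.normalized for s in sets):
        raise ValueError("all sets must be normalized first")
    orders = {s.n_harmonics for s in sets}
    if len(orders) != 1:
        raise ValueError("all sets must share the harmonic order")
    M = np.stack([s.flat()[1:] for s in sets])  # drop a1
    pca = PCA()
    scores = pca.fit_transform(M)
    labels = None
    if n_clusters is not None:
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        labels = km.fit_predict(scores[:, :2])
    return scores, pca.components_, pca.explained_variance_ratio_, labels
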