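"""Independent oracles used by the tests.

Each oracle recomputes a quantity by brute force, enumeration, closed form
or Monte-Carlo simulation, independent of the implementation it checks.
"""

from __future__ import annotations

import numpy as np

LUMA = np.array([0.2125, 0.7154, 0.0721])


def brute_force_otsu(gray: np.ndarray) -> int:
    """Exhaustive search over all 256 thresholds minimizing within-class variance."""
    g = gray.ravel()
    best_v, best_t = np.inf, 0
    for t in range(256):
        lo, hi = g[g <= t], g[g > t]
        if lo.size == 0 or hi.size == 0:
            continue
        v = lo.size * lo.var() + hi.size * hi.var()
        if v < best_v:
            best_v, best_t = v, t
    return best_t


def efd_quadrature(contour: np.ndarray, n_harmonics: int, refine: int = 10) -> np.ndarray:
    """Trapezoid evaluation of the defining Fourier integrals at refined resolution.

    The polygon is resampled with ``refine`` points per edge and the
    integrals (2/T) * int f(t) cos/sin(2 pi n t / T) dt are computed
    numerically over arc length.
    """
    v = np.asarray(contour, dtype=float)
    closed = np.vstack([v, v[:1]])
    fine = []
    for p, q in zip(closed[:-1], closed[1:]):
        for s in np.linspace(0.0, 1.0, refine, endpoint=False):
            fine.append(p + s * (q - p))
    fine = np.array(fine)
    closed = np.vstack([fine, fine[:1]])
    d = np.diff(closed, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    x = closed[:, 1]
    y = closed[:, 0]
    from scipy.integrate import simpson

    out = np.empty((n_harmonics, 4))
    for n in range(1, n_harmonics + 1):
        cn = np.cos(2 * np.pi * n * t / T)
        sn = np.sin(2 * np.pi * n * t / T)
        out[n - 1] = [
            2 / T * simpson(x * cn, x=t),
            2 / T * simpson(x * sn, x=t),
            2 / T * simpson(y * cn, x=t),
            2 / T * simpson(y * sn, x=t),
        ]
    return out


def gene_dropping(pedigree, n_rep: int = 1_000_000, seed: int = 0):
    """Monte-Carlo IBD estimates of the A and D matrices by allele dropping.

    Each founder gets two unique alleles; offspring inherit one random
    allele from each parent.  a_ij is estimated as twice the probability
    that random alleles of i and j are identical by descent; d_ij as the
    probability that i and j share both (unordered) alleles by descent.
    """
    rng = np.random.default_rng(seed)
    s, d = pedigree.parent_indices()
    n = len(pedigree)
    al1 = np.empty((n, n_rep), dtype=np.int32)
    al2 = np.empty((n, n_rep), dtype=np.int32)
    next_allele = 0
    for i in range(n):
        if s[i] < 0 and d[i] < 0:
            al1[i] = 2 * i
            al2[i] = 2 * i + 1
        else:
            pick_s = rng.integers(0, 2, n_rep, dtype=np.int8)
            pick_d = rng.integers(0, 2, n_rep, dtype=np.int8)
            al1[i] = np.where(pick_s == 0, al1[s[i]], al2[s[i]])
            al2[i] = np.where(pick_d == 0, al1[d[i]], al2[d[i]])
    A = np.empty((n, n))
    D = np.empty((n, n))
    for i in range(n):
        for j in range(i + 1):
            share = (
                (al1[i] == al1[j]).mean()
                + (al1[i] == al2[j]).mean()
                + (al2[i] == al1[j]).mean()
                + (al2[i] == al2[j]).mean()
            )
            A[i, j] = A[j, i] = share / 2.0
            both = ((al1[i] == al1[j]) & (al2[i] == al2[j])) | (
                (al1[i] == al2[j]) & (al2[i] == al1[j])
            )
            D[i, j] = D[j, i] = both.mean()
    return A, D


def pairwise_procrustes(x: np.ndarray, y: np.ndarray):
    """Closed-form superimposition of two configurations (no reflection).

    Both are centered and scaled to unit centroid size; y is rotated onto x
    by the SVD solution.  Returns (x_aligned, y_aligned, squared distance).
    """

    def norm(p):
        q = p - p.mean(axis=0)
        return q / np.sqrt((q**2).sum())

    xn, yn = norm(x), norm(y)
    U, _, Vt = np.linalg.svd(yn.T @ xn)
    S = np.diag([1.0, np.sign(np.linalg.det(U @ Vt))])
    R = U @ S @ Vt
    ya = yn @ R
    return xn, ya, float(((xn - ya) ** 2).sum())


def kl_quadrature(mu: float, sigma: float) -> float:
    """Numerical KL( N(mu, sigma^2) || N(0,1) ) by dense trapezoid integration."""
    z = np.linspace(mu - 10 * sigma, mu + 10 * sigma, 400_001)
    log_p = -0.5 * ((z - mu) / sigma) ** 2 - np.log(sigma * np.sqrt(2 * np.pi))
    log_q = -0.5 * z**2 - 0.5 * np.log(2 * np.pi)
    integrand = np.exp(log_p) * (log_p - log_q)
    return float(np.trapezoid(integrand, z))


def exhaustive_color_assignment(cluster_means: np.ndarray, palette: np.ndarray) -> np.ndarray:
    """Nearest reference per cluster via the full distance table."""
    table = np.array(
        [[np.sqrt(((cm - ref) ** 2).sum()) for ref in palette] for cm in cluster_means]
    )
    return table.argmin(axis=1)
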