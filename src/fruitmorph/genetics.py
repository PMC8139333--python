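"""Pedigree-based genetic analysis of fruit phenotypes.

Implements the quantitative-genetics layer of the pipeline: the additive (A)
and dominance (D) relationship matrices computed recursively from a pedigree,
and a Bayesian variance-component model

    y = mu + a + d + eps,
    a ~ N(0, A * sigma2_a),  d ~ N(0, D * sigma2_d),  eps ~ N(0, I * sigma2_e),

fitted by Gibbs sampling in the eigenbasis of each kernel (the RKHS form).
The additive and dominance variance fractions are

    h2_a = s2_a / (s2_a + s2_d + s2_e),   h2_d = s2_d / (s2_a + s2_d + s2_e),

where s2 are posterior means.

The model is exposed statsmodels-style: build a
:class:`VarianceComponentsModel` from data, call :meth:`fit`, inspect the
returned :class:`VarianceComponentsResults` (posterior summaries,
``summary()`` table).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pedigree",
    "build_A",
    "build_D",
    "VarianceComponentsModel",
    "VarianceComponentsResults",
]


UNKNOWN = {None, "", "0", 0}


@dataclass
class Pedigree:
    """A pedigree as parallel id/sire/dam lists, topologically ordered.

    Founders have both parents unknown (coded ``0``, empty string or None in
    the input).  Construction sorts records so that parents always precede
    offspring and rejects cyclic pedigrees.
    """

    ids: list[str]
    sires: list[str | None]
    dams: list[str | None]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [str(i) for i in self.ids]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in pedigree")
        norm = lambda p: None if p in UNKNOWN or (isinstance(p, float) and np.isnan(p)) else str(p)
        sires = [norm(s) for s in self.sires]
        dams = [norm(d) for d in self.dams]
        known = set(ids)
        for p in sires + dams:
            if p is not None and p not in known:
                raise ValueError(f"parent {p!r} has no pedigree record")
        order = self._toposort(ids, sires, dams)
        self.ids = [ids[i] for i in order]
        self.sires = [sires[i] for i in order]
        self.dams = [dams[i] for i in order]
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    @staticmethod
    def _toposort(ids: list[str], sires: list[str | None], dams: list[str | None]) -> list[int]:
        idx = {iid: k for k, iid in enumerate(ids)}
        n = len(ids)
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = [0] * n
        for k in range(n):
            for p in (sires[k], dams[k]):
                if p is not None:
                    children[idx[p]].append(k)
                    indeg[k] += 1
        queue = [k for k in range(n) if indeg[k] == 0]
        out: list[int] = []
        while queue:
            k = queue.pop()
            out.append(k)
            for c in children[k]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(out) != n:
            raise ValueError("cyclic pedigree: an individual is its own ancestor")
        return out

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "Pedigree":
        ids, sires, dams = zip(*records) if records else ((), (), ())
        return cls(list(ids), list(sires), list(dams))

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        """Read a 3-column (id, sire, dam) CSV; 0/empty marks unknown parents."""
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        cols = list(df.columns[:3])
        return cls(df[cols[0]].tolist(), df[cols[1]].tolist(), df[cols[2]].tolist())

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, iid: str) -> int:
        return self._index[str(iid)]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire/dam row indices into the sorted pedigree; -1 for unknown."""
        s = np.array([-1 if p is None else self._index[p] for p in self.sires])
        d = np.array([-1 if p is None else self._index[p] for p in self.dams])
        return s, d


def build_A(pedigree: Pedigree) -> np.ndarray:
    """Additive (numerator) relationship matrix by the tabular method.

    a_ii = 1 + 0.5 * a(sire, dam); a_ij = 0.5 * (a(j, sire_i) + a(j, dam_i))
    for j preceding i.  Founders are non-inbred and mutually unrelated.
    """
    n = len(pedigree)
    s, d = pedigree.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        for j in range(i):
            aij = 0.0
            if si >= 0:
                aij += 0.5 * A[j, si]
            if di >= 0:
                aij += 0.5 * A[j, di]
            A[i, j] = A[j, i] = aij
        A[i, i] = 1.0 + (0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0)
    return A


def build_D(pedigree: Pedigree) -> np.ndarray:
    """Dominance relationship matrix (classical non-inbred approximation).

    d_ij = 0.25 * (a(s_i,s_j) a(d_i,d_j) + a(s_i,d_j) a(d_i,s_j)) for i != j
    when both individuals have both parents recorded, else 0; d_ii = 1.
    """
    A = build_A(pedigree)
    n = len(pedigree)
    s, d = pedigree.parent_indices()
    D = np.eye(n)
    both = (s >= 0) & (d >= 0)
    for i in range(n):
        if not both[i]:
            continue
        for j in range(i):
            if not both[j]:
                continue
            D[i, j] = D[j, i] = 0.25 * (
                A[s[i], s[j]] * A[d[i], d[j]] + A[s[i], d[j]] * A[d[i], s[j]]
            )
    return D


@dataclass
class _EigenKernel:
    """Eigendecomposition of a PSD kernel, small eigenvalues truncated."""

    vectors: np.ndarray  # n x m
    values: np.ndarray  # m

    @classmethod
    def from_kernel(cls, K: np.ndarray, jitter: float = 1e-8) -> "_EigenKernel":
        Ks = 0.5 * (K + K.T)
        w, U = np.linalg.eigh(Ks)
        if w.min() < -1e-6 * max(1.0, w.max()):
            raise ValueError("kernel is not positive semidefinite")
        keep = w > max(jitter, 1e-10 * w.max())
        return cls(np.ascontiguousarray(U[:, keep]), w[keep])


class VarianceComponentsModel:
    """Bayesian additive + dominance variance-component model.

    Parameters
    ----------
    y : array-like, shape (n,)
        Phenotypes, one value per pedigree individual (averaged per genotype).
    A, D : ndarray, shape (n, n)
        Additive and dominance relationship matrices, rows ordered as ``y``.

    Variance priors are scaled-inverse-chi-squared.  By default df = 5 for
    every component and the prior scales allocate half of var(y) to genetics
    (split equally between a and d) and half to the residual.
    """

    def __init__(self, y, A: np.ndarray, D: np.ndarray | None = None):
        self.y = np.asarray(y, dtype=float).ravel()
        n = self.y.size
        if A.shape != (n, n):
            raise ValueError("A must be n x n with n = len(y)")
        if D is not None and D.shape != (n, n):
            raise ValueError("D must be n x n with n = len(y)")
        self.A = A
        self.D = D
        self._ka = _EigenKernel.from_kernel(A)
        self._kd = _EigenKernel.from_kernel(D) if D is not None else None

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, trait: str, pedigree: Pedigree, id_col: str = "genotype"
    ) -> "VarianceComponentsModel":
        """Build the model from a per-genotype phenotype table.

        Rows are averaged per genotype, matched to the pedigree order; kernel
        rows are subset to genotypes present in the table.
        """
        means = data.groupby(data[id_col].astype(str))[trait].mean()
        idx = [pedigree.index_of(g) for g in means.index]
        order = np.argsort(idx)
        rows = np.asarray(idx)[order]
        y = means.to_numpy()[order]
        A = build_A(pedigree)[np.ix_(rows, rows)]
        D = build_D(pedigree)[np.ix_(rows, rows)]
        return cls(y, A, D)

    def fit(
        self,
        iterations: int = 20_000,
        burn_in: int = 5_000,
        thin: int = 10,
        seed: int | None = None,
        prior_df: float = 5.0,
        prior_scales: Mapping[str, float] | None = None,
    ) -> "VarianceComponentsResults":
        """Run the Gibbs sampler and return posterior summaries.

        Random effects are sampled in the eigenbasis of their kernel, where
        the full conditional precision is diagonal, so each sweep costs a few
        matrix-vector products.
        """
        if burn_in >= iterations:
            raise ValueError("burn_in must be smaller than iterations")
        rng = np.random.default_rng(seed)
        y = self.y
        n = y.size
        vy = float(np.var(y)) or 1.0
        df = float(prior_df)
        if prior_scales is None:
            # mode of scaled-inv-chi2(df, S) is S*df/(df+2); target half of
            # var(y) for genetics split over a and d, half for the residual
            Sa = Sd = 0.25 * vy * (df + 2.0) / df
            Se = 0.5 * vy * (df + 2.0) / df
        else:
            Sa, Sd, Se = (prior_scales[k] for k in ("a", "d", "e"))

        ka, kd = self._ka, self._kd
        Ua, wa = ka.vectors, ka.values
        ma = wa.size
        if kd is not None:
            Ud, wd = kd.vectors, kd.values
            md = wd.size
        else:
            Ud = wd = None
            md = 0

        mu = float(y.mean())
        a = np.zeros(n)
        dvec = np.zeros(n)
        s2a = s2d = 0.5 * vy / 2.0
        s2e = 0.5 * vy

        kept = []
        for it in range(iterations):
            # intercept
            resid = y - a - dvec
            mu = rng.normal(resid.mean(), np.sqrt(s2e / n))
            # additive effects in eigenbasis of A
            r = y - mu - dvec
            ra = Ua.T @ r
            prec = 1.0 / s2e + 1.0 / (wa * s2a)
            mean = ra / (s2e * prec)
            gam_a = mean + rng.standard_normal(ma) / np.sqrt(prec)
            a = Ua @ gam_a
            s2a = (gam_a * gam_a / wa).sum() + df * Sa
            s2a /= rng.chisquare(df + ma)
            # dominance effects in eigenbasis of D
            if Ud is not None:
                r = y - mu - a
                rd = Ud.T @ r
                prec = 1.0 / s2e + 1.0 / (wd * s2d)
                mean = rd / (s2e * prec)
                gam_d = mean + rng.standard_normal(md) / np.sqrt(prec)
                dvec = Ud @ gam_d
                s2d = (gam_d * gam_d / wd).sum() + df * Sd
                s2d /= rng.chisquare(df + md)
            # residual variance
            e = y - mu - a - dvec
            s2e = (e @ e + df * Se) / rng.chisquare(df + n)
            if it >= burn_in and (it - burn_in) % thin == 0:
                kept.append((mu, s2a, s2d if Ud is not None else 0.0, s2e))

        samples = pd.DataFrame(kept, columns=["mu", "sigma2_a", "sigma2_d", "sigma2_e"])
        return VarianceComponentsResults(
            model=self,
            samples=samples,
            settings={
                "iterations": iterations,
                "burn_in": burn_in,
                "thin": thin,
                "seed": seed,
                "prior_df": df,
                "prior_scales": {"a": Sa, "d": Sd, "e": Se},
            },
        )


@dataclass
class VarianceComponentsResults:
    """Posterior summaries of the additive + dominance model."""

    model: VarianceComponentsModel
    samples: pd.DataFrame
    settings: dict

    @property
    def posterior_means(self) -> pd.Series:
        return self.samples.mean()

    @property
    def h2_samples(self) -> pd.DataFrame:
        tot = self.samples[["sigma2_a", "sigma2_d", "sigma2_e"]].sum(axis=1)
        return pd.DataFrame(
            {"h2_a": self.samples["sigma2_a"] / tot, "h2_d": self.samples["sigma2_d"] / tot}
        )

    @property
    def h2_a(self) -> float:
        """Additive fraction from posterior-mean variances."""
        m = self.posterior_means
        return float(m["sigma2_a"] / (m["sigma2_a"] + m["sigma2_d"] + m["sigma2_e"]))

    @property
    def h2_d(self) -> float:
        """Dominance fraction from posterior-mean variances."""
        m = self.posterior_means
        return float(m["sigma2_d"] / (m["sigma2_a"] + m["sigma2_d"] + m["sigma2_e"]))

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        src = self.h2_samples if name.startswith("h2") else self.samples
        lo, hi = np.quantile(src[name], [(1 - level) / 2, 1 - (1 - level) / 2])
        return float(lo), float(hi)

    def split_chain_rhat(self, name: str = "sigma2_a") -> float:
        """Split-chain potential-scale-reduction diagnostic on one parameter."""
        x = self.samples[name].to_numpy()
        half = x.size // 2
        chains = np.stack([x[:half], x[half : 2 * half]])
        within = chains.var(axis=1, ddof=1).mean()
        between = half * chains.mean(axis=1).var(ddof=1)
        var_hat = (half - 1) / half * within + between / half
        return float(np.sqrt(var_hat / within)) if within > 0 else np.inf

    def summary(self) -> str:
        m = self.posterior_means
        sd = self.samples.std()
        h2 = self.h2_samples
        lines = [
            "Variance components (Gibbs posterior)",
            "=" * 46,
            f"{'parameter':<12}{'mean':>10}{'sd':>10}{'2.5%':>10}{'97.5%':>10}",
            "-" * 46 + "----",
        ]
        for name in ["mu", "sigma2_a", "sigma2_d", "sigma2_e"]:
            lo, hi = self.credible_interval(name)
            lines.append(f"{name:<12}{m[name]:>10.4f}{sd[name]:>10.4f}{lo:>10.4f}{hi:>10.4f}")
        for name in ["h2_a", "h2_d"]:
            lo, hi = self.credible_interval(name)
            point = self.h2_a if name == "h2_a" else self.h2_d
            lines.append(f"{name:<12}{point:>10.4f}{h2[name].std():>10.4f}{lo:>10.4f}{hi:>10.4f}")
        lines.append("-" * 50)
        s = self.settings
        lines.append(
            f"iterations={s['iterations']} burn_in={s['burn_in']} thin={s['thin']} "
            f"seed={s['seed']} kept={len(self.samples)}"
        )
        rhat = self.split_chain_rhat()
        lines.append(f"split-chain Rhat(sigma2_a)={rhat:.3f}")
        if rhat > 1.1:
            lines.append("warning: split-chain Rhat > 1.1, chain may not have mixed")
        return "\n".join(lines)
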