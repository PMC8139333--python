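"""Variational autoencoder on fruit silhouettes and latent shape clustering.

Binarized, calyx-free external silhouettes resized to 64x64 are encoded by a
4-stage stride-2 convolutional encoder (kernel 3, ReLU) into a latent
Gaussian N(mu_x, sigma_x); the decoder mirrors it with transposed
convolutions and a final sigmoid.  The loss is pixelwise binary
cross-entropy plus the KL divergence to N(0, I), with per-dimension closed
form 0.5 * (mu^2 + sigma^2 - ln sigma^2 - 1).

The number of distinct fruit shapes is discovered by k-means on the latent
means for k in a grid (2..9 by default), scored by the mean silhouette
index; decoding a cluster centroid generates the typical shape of that
cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from . import nn

__all__ = [
    "VAESpec",
    "ConvVAE",
    "LatentEmbedding",
    "ShapeClustering",
    "vae_loss",
    "train_vae",
    "select_k",
    "generate_cluster_shape",
]


@dataclass
class VAESpec:
    """Architecture hyperparameters of the silhouette VAE."""

    input_size: int = 64
    channels: tuple[int, ...] = (8, 16, 32, 32)  # 4 conv stages, stride 2 each
    kernel: int = 3
    latent_dim: int = 8
    beta: float = 1.0
    learning_rate: float = 1e-3
    batch_size: int = 32


@dataclass
class LatentEmbedding:
    mu: np.ndarray  # n x latent_dim
    sigma: np.ndarray  # n x latent_dim, > 0


@dataclass
class ShapeClustering:
    k_grid: list[int]
    silhouette_by_k: dict[int, float]
    best_k: int
    labels: np.ndarray
    centroids: np.ndarray  # best_k x latent_dim


def vae_loss(
    batch: np.ndarray, logits: np.ndarray, mu: np.ndarray, sigma: np.ndarray, beta: float = 1.0
) -> tuple[float, float, float]:
    """Total, reconstruction and KL parts of the VAE objective.

    Reconstruction is pixelwise binary cross-entropy of the sigmoid of
    ``logits`` against the batch, summed over pixels; KL is
    0.5 * (mu^2 + sigma^2 - ln sigma^2 - 1) summed over latent dimensions.
    Both are averaged over the batch.
    """
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    n = batch.shape[0]
    # numerically stable BCE-with-logits
    bce = np.maximum(logits, 0) - logits * batch + np.log1p(np.exp(-np.abs(logits)))
    recon = float(bce.sum() / n)
    s2 = sigma**2
    kl = float((0.5 * (mu**2 + s2 - np.log(s2) - 1.0)).sum() / n)
    return recon + beta * kl, recon, kl


class ConvVAE:
    """Convolutional VAE with hand-derived backprop (see :mod:`fruitmorph.nn`)."""

    def __init__(self, spec: VAESpec | None = None, seed: int = 0):
        self.spec = spec or VAESpec()
        s = self.spec
        rng = np.random.default_rng(seed)
        chans = (1,) + s.channels
        enc_layers: list[nn.Layer] = []
        for cin, cout in zip(chans[:-1], chans[1:]):
            enc_layers += [nn.Conv2d(cin, cout, k=s.kernel, stride=2, pad=1, rng=rng), nn.ReLU()]
        enc_layers.append(nn.Flatten())
        self.encoder = nn.Sequential(*enc_layers)
        self._feat_hw = s.input_size // 2 ** len(s.channels)
        feat = s.channels[-1] * self._feat_hw**2
        self.fc_mu = nn.Dense(feat, s.latent_dim, rng=rng)
        self.fc_logvar = nn.Dense(feat, s.latent_dim, rng=rng)
        dec_layers: list[nn.Layer] = [
            nn.Dense(s.latent_dim, feat, rng=rng),
            nn.ReLU(),
            nn.Reshape((s.channels[-1], self._feat_hw, self._feat_hw)),
        ]
        rev = s.channels[::-1] + (1,)
        for i, (cin, cout) in enumerate(zip(rev[:-1], rev[1:])):
            dec_layers.append(
                nn.ConvTranspose2d(cin, cout, k=s.kernel, stride=2, pad=1, output_padding=1, rng=rng)
            )
            if i < len(rev) - 2:
                dec_layers.append(nn.ReLU())
        self.decoder = nn.Sequential(*dec_layers)  # outputs logits; sigmoid in loss/decode

    def params(self):
        return (
            self.encoder.params()
            + self.fc_mu.params()
            + self.fc_logvar.params()
            + self.decoder.params()
        )

    def encode(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Latent mean and log-variance for (n, 64, 64) silhouettes."""
        h = self.encoder.forward(x[:, None, :, :])
        return self.fc_mu.forward(h), self.fc_logvar.forward(h)

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Decoded silhouettes in [0, 1], shape (n, 64, 64)."""
        logits = self.decoder.forward(z)
        return nn.sigmoid(logits[:, 0])

    def _step(self, x: np.ndarray, rng: np.random.Generator) -> tuple[float, float, float]:
        s = self.spec
        n = x.shape[0]
        h = self.encoder.forward(x[:, None, :, :])
        mu = self.fc_mu.forward(h)
        logvar = np.clip(self.fc_logvar.forward(h), -15.0, 15.0)
        std = np.exp(0.5 * logvar)
        eps = rng.standard_normal(mu.shape)
        z = mu + eps * std
        logits = self.decoder.forward(z)[:, 0]
        total, recon, kl = vae_loss(x, logits, mu, std, beta=s.beta)
        if not np.isfinite(total):
            raise FloatingPointError("non-finite VAE loss")
        dlogits = (nn.sigmoid(logits) - x) / n
        dz = self.decoder.backward(dlogits[:, None, :, :])
        dmu = dz + s.beta * mu / n
        dlogvar = dz * eps * 0.5 * std + s.beta * 0.5 * (np.exp(logvar) - 1.0) / n
        dh = self.fc_mu.backward(dmu) + self.fc_logvar.backward(dlogvar)
        self.encoder.backward(dh)
        return total, recon, kl


def train_vae(
    tiles: np.ndarray,
    spec: VAESpec | None = None,
    epochs: int = 30,
    seed: int = 0,
) -> tuple[ConvVAE, LatentEmbedding, list[float]]:
    """Train the silhouette VAE and embed every input.

    ``tiles`` is (n, 64, 64) with values in [0, 1].  Returns the model, the
    latent embedding (posterior means and sigmas, computed without
    sampling) and the per-epoch mean training loss.
    """
    x = np.asarray(tiles, dtype=float)
    if x.ndim != 3 or x.shape[0] < 50:
        raise ValueError("need at least 50 silhouettes of shape (n, S, S)")
    spec = spec or VAESpec()
    if x.shape[1] != spec.input_size or x.shape[2] != spec.input_size:
        raise ValueError(f"silhouettes must be {spec.input_size}x{spec.input_size}")
    model = ConvVAE(spec, seed=seed)
    opt = nn.Adam(model.params(), lr=spec.learning_rate)
    rng = np.random.default_rng(seed + 1)
    n = x.shape[0]
    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            batch = x[order[start : start + spec.batch_size]]
            total, _, _ = model._step(batch, rng)
            opt.step()
            losses.append(total)
        history.append(float(np.mean(losses)))
    mu, logvar = model.encode(x)
    emb = LatentEmbedding(mu=mu, sigma=np.exp(0.5 * np.clip(logvar, -15, 15)))
    return model, emb, history


def select_k(
    embedding: LatentEmbedding | np.ndarray,
    k_min: int = 2,
    k_max: int = 9,
    seed: int = 0,
    n_init: int = 10,
) -> ShapeClustering:
    """Silhouette-scored k-means over the latent means for k in [k_min, k_max].

    ``best_k`` maximizes the mean silhouette index; ties break toward the
    smaller k.  Values of k with more clusters than points are skipped.
    """
    mu = embedding.mu if isinstance(embedding, LatentEmbedding) else np.asarray(embedding)
    n = mu.shape[0]
    results: dict[int, tuple[float, np.ndarray, np.ndarray]] = {}
    for k in range(k_min, k_max + 1):
        if k >= n:
            warnings.warn(f"skipping k={k}: only {n} points")
            continue
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(mu)
        labels = km.labels_
        if np.unique(labels).size < 2:
            score = 0.0
        else:
            score = float(silhouette_score(mu, labels))
        results[k] = (score, labels, km.cluster_centers_)
    if not results:
        raise ValueError("no feasible k in the grid")
    best_k = max(results, key=lambda k: (results[k][0], -k))
    score, labels, centroids = results[best_k]
    return ShapeClustering(
        k_grid=sorted(results),
        silhouette_by_k={k: results[k][0] for k in sorted(results)},
        best_k=best_k,
        labels=labels,
        centroids=centroids,
    )


def generate_cluster_shape(
    model: ConvVAE, clustering: ShapeClustering, cluster_id: int
) -> np.ndarray:
    """Decode the centroid of one latent cluster: the cluster-typical shape."""
    if not 0 <= cluster_id < clustering.best_k:
        raise ValueError(f"invalid cluster id {cluster_id}")
    z = clustering.centroids[cluster_id][None, :]
    return model.decode(z)[0]
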