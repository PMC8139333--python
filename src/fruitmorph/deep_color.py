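"""Internal-color phenotyping: denoising autoencoder + reference-palette k-means.

Internal (cut-face) fruit tiles are smoothed with a convolutional
autoencoder (ReLU + max-pooling encoder, transposed-convolution decoder,
mean-squared-error loss) so that repeatable color patterns dominate pixel
noise.  Fruit pixels are then clustered with k-means (k = 4), each cluster
is assigned to the nearest reference color in RGB, and the profile reports
the fruit-surface percentage of each reference class.

Reference palette (RGB): orange-like (198, 99, 35), quasired (184, 46, 8),
pale (194, 144, 78) and green (76, 75, 20) for sepals; black is background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2lab
from sklearn.cluster import KMeans

from . import nn
from .segmentation import FruitTile

__all__ = ["ReferencePalette", "ColorProfile", "ColorAE", "train_denoiser", "denoise", "color_profile"]


@dataclass(frozen=True)
class ReferencePalette:
    orange_like: tuple[int, int, int] = (198, 99, 35)
    quasired: tuple[int, int, int] = (184, 46, 8)
    pale: tuple[int, int, int] = (194, 144, 78)
    green: tuple[int, int, int] = (76, 75, 20)

    def names(self) -> list[str]:
        return ["orange_like", "quasired", "pale", "green"]

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.names()], dtype=float)


@dataclass
class ColorProfile:
    """Surface percentages per reference color over fruit pixels."""

    percent: dict[str, float]  # sums to 100 over the four classes
    percent_flesh: dict[str, float]  # green excluded, renormalized
    cluster_means: np.ndarray  # up to k RGB triples
    n_fruit_px: int


class ColorAE:
    """Small convolutional denoising autoencoder (MSE loss)."""

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder = nn.Sequential(
            nn.Conv2d(3, 8, k=3, stride=1, pad=1, rng=rng),
            nn.ReLU(),
            nn.MaxPool2d(),
            nn.Conv2d(8, 16, k=3, stride=1, pad=1, rng=rng),
            nn.ReLU(),
            nn.MaxPool2d(),
        )
        self.decoder = nn.Sequential(
            nn.ConvTranspose2d(16, 8, k=3, stride=2, pad=1, output_padding=1, rng=rng),
            nn.ReLU(),
            nn.ConvTranspose2d(8, 3, k=3, stride=2, pad=1, output_padding=1, rng=rng),
        )

    def params(self):
        return self.encoder.params() + self.decoder.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.decoder.forward(self.encoder.forward(x)))

    def train_step(self, noisy: np.ndarray, clean: np.ndarray) -> float:
        logits = self.decoder.forward(self.encoder.forward(noisy))
        out = nn.sigmoid(logits)
        n = noisy.shape[0]
        diff = out - clean
        loss = float((diff**2).sum() / n)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite autoencoder loss")
        dlogits = 2.0 * diff * out * (1.0 - out) / n
        self.encoder.backward(self.decoder.backward(dlogits))
        return loss


def _to_batch(tiles) -> np.ndarray:
    arr = np.stack([t.pixels if isinstance(t, FruitTile) else np.asarray(t) for t in tiles])
    return arr.transpose(0, 3, 1, 2).astype(float) / 255.0


def train_denoiser(
    tiles,
    epochs: int = 40,
    noise_sigma: float = 15.0,
    seed: int = 0,
    batch_size: int = 8,
    lr: float = 1e-2,
) -> tuple[ColorAE, list[float]]:
    """Train the denoiser on clean tiles corrupted with additive Gaussian noise.

    ``tiles`` are uint8 RGB arrays (or FruitTiles) whose sides are a
    multiple of 4 (two pooling stages); ``noise_sigma`` is on the 0-255
    scale.  Returns the model and the per-epoch loss history.
    """
    x = _to_batch(tiles)
    if x.shape[0] < 20:
        raise ValueError("need at least 20 tiles")
    if x.shape[2] % 4 or x.shape[3] % 4:
        raise ValueError("tile side must be a multiple of 4")
    model = ColorAE(seed=seed)
    opt = nn.Adam(model.params(), lr=lr)
    rng = np.random.default_rng(seed + 1)
    n = x.shape[0]
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            clean = x[order[start : start + batch_size]]
            noisy = np.clip(clean + rng.normal(0, noise_sigma / 255.0, clean.shape), 0, 1)
            losses.append(model.train_step(noisy, clean))
            opt.step()
        history.append(float(np.mean(losses)))
    return model, history


def denoise(model: ColorAE, tile: FruitTile | np.ndarray) -> np.ndarray:
    """Denoised uint8 RGB image; background is forced back to exact black."""
    pixels = tile.pixels if isinstance(tile, FruitTile) else np.asarray(tile)
    h, w = pixels.shape[:2]
    ph, pw = (-h) % 4, (-w) % 4
    x = pixels.astype(float) / 255.0
    x = np.pad(x, ((0, ph), (0, pw), (0, 0)), mode="edge")
    out = model.forward(x.transpose(2, 0, 1)[None])[0].transpose(1, 2, 0)[:h, :w]
    out8 = np.clip(out * 255.0, 0, 255).astype(np.uint8)
    out8[~pixels.any(axis=2)] = 0
    return out8


def color_profile(
    tile: FruitTile | np.ndarray,
    palette: ReferencePalette | None = None,
    k: int = 4,
    seed: int = 0,
    use_cielab: bool = False,
) -> ColorProfile:
    """k-means color quantization of fruit pixels mapped to the palette.

    Each cluster is assigned to the reference color nearest to the cluster's
    mean (Euclidean distance in raw RGB by default; CIELAB optional);
    clusters mapping to the same reference pool their pixel shares, and
    references with no cluster report 0.
    """
    palette = palette or ReferencePalette()
    pixels = tile.pixels if isinstance(tile, FruitTile) else np.asarray(tile)
    fg = pixels.any(axis=2)
    vals = pixels[fg].astype(float)
    if vals.shape[0] < 100:
        raise ValueError("need at least 100 fruit pixels")
    n_distinct = np.unique(vals, axis=0).shape[0]
    k_eff = min(k, n_distinct)
    if k_eff < k:
        warnings.warn(f"only {n_distinct} distinct colors: clustering with k={k_eff}")
    km = KMeans(n_clusters=k_eff, n_init=10, random_state=seed).fit(vals)
    means = km.cluster_centers_
    counts = np.bincount(km.labels_, minlength=k_eff).astype(float)
    ref = palette.as_array()
    if use_cielab:
        to_lab = lambda a: rgb2lab(a[None] / 255.0)[0]
        dists = np.linalg.norm(to_lab(means)[:, None, :] - to_lab(ref)[None, :, :], axis=2)
    else:
        dists = np.linalg.norm(means[:, None, :] - ref[None, :, :], axis=2)
    assign = dists.argmin(axis=1)
    names = palette.names()
    percent = {nm: 0.0 for nm in names}
    for ci, ref_i in enumerate(assign):
        percent[names[ref_i]] += 100.0 * counts[ci] / counts.sum()
    flesh_total = sum(v for nm, v in percent.items() if nm != "green")
    percent_flesh = {
        nm: (100.0 * v / flesh_total if flesh_total > 0 else 0.0)
        for nm, v in percent.items()
        if nm != "green"
    }
    return ColorProfile(
        percent=percent,
        percent_flesh=percent_flesh,
        cluster_means=means,
        n_fruit_px=int(counts.sum()),
    )
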