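"""Image curation and augmentation utilities.

*Perceptual hashing* (pHash): an image is reduced to 32x32 grayscale, an
orthonormal 2-D type-II DCT ``F = A f A^T`` is taken, and the top-left 8x8
low-frequency block is thresholded at its mean (DC term excluded) to give a
64-bit signature.  Signatures are compared by Hamming distance; visually
similar images land within a few bits of each other, which drives both
near-duplicate removal and the spatial-constraint check when compositing
foregrounds onto candidate backgrounds.

*Elastic distortion*: a per-pixel random displacement field in [-1, 1] is
Gaussian-smoothed (smoothness delta, a fraction of the short image side by
default), scaled by the strength alpha (pixels), and applied by bilinear
resampling.  It perturbs an animal's pose without destroying the image,
enriching the pose diversity of small training sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter, map_coordinates

__all__ = [
    "HashSignature",
    "dct_matrix",
    "phash",
    "hamming",
    "filter_similar",
    "compose",
    "elastic_distortion",
    "DEFAULT_DELTA",
    "DEFAULT_ALPHA",
]

# elastic-distortion defaults: smoothness (fraction of min(W, H)) / strength (px)
DEFAULT_DELTA = 0.07
DEFAULT_ALPHA = 5.0

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class HashSignature:
    """64-bit perceptual hash, stored as a length-64 uint8 0/1 vector."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bits) != 64 or any(b not in (0, 1) for b in self.bits):
            raise ValueError("a hash signature is exactly 64 binary bits")

    def __int__(self) -> int:
        return int("".join(map(str, self.bits)), 2)


@lru_cache(maxsize=8)
def dct_matrix(n: int) -> np.ndarray:
    """Orthonormal type-II DCT basis ``A(i, j) = c(i) cos[(j + 0.5) pi i / N]``
    with ``c(0) = sqrt(1/N)`` and ``c(i>0) = sqrt(2/N)``, so that A A^T = I."""
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    a = np.cos((j + 0.5) * math.pi * i / n)
    a[0] *= math.sqrt(1.0 / n)
    a[1:] *= math.sqrt(2.0 / n)
    return a


def _to_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        return image[..., :3] @ _LUMA
    if image.ndim == 2:
        return image
    raise ValueError(f"expected a 2-D or 3-D raster, got shape {image.shape}")


def phash(image: np.ndarray) -> HashSignature:
    """Perceptual hash of a raster (grayscale 2-D or RGB 3-D array).

    Pipeline: 32x32 bilinear reduction, grayscale, 2-D DCT, top-left 8x8
    block, bit = 1 iff the coefficient strictly exceeds the block mean
    computed without the DC term.  Deterministic; a constant image hashes
    to all zeros.
    """
    if np.asarray(image).size == 0:
        raise ValueError("cannot hash an empty image")
    gray = _to_gray(image)
    small = np.asarray(
        Image.fromarray(gray.astype(np.float32), mode="F").resize((32, 32), Image.BILINEAR)
    ).astype(float)
    a = dct_matrix(32)
    coeffs = (a @ small @ a.T)[:8, :8]
    mean = (coeffs.sum() - coeffs[0, 0]) / 63.0
    # scale-relative epsilon so float residue in a degenerate (e.g. constant)
    # image never flips a bit that is exactly "equal to the mean"
    tol = 1e-8 * (np.abs(coeffs).max() + 1.0)
    bits = (coeffs > mean + tol).astype(int)
    bits[0, 0] = 0  # the DC term carries only overall brightness
    return HashSignature(tuple(int(b) for b in bits.ravel()))


def hamming(a: HashSignature, b: HashSignature) -> int:
    """Number of differing bits between two signatures (0..64)."""
    if len(a.bits) != len(b.bits):
        raise ValueError("signature length mismatch")
    return int(sum(x ^ y for x, y in zip(a.bits, b.bits)))


def filter_similar(
    images: list[np.ndarray],
    keep_fraction: float = 0.6,
    dup_threshold: int = 5,
) -> list[int]:
    """Curate an image pool by perceptual-hash similarity.

    1. hash every image and take all-pairs Hamming distances;
    2. drop near-duplicates: for any pair at distance <= ``dup_threshold``,
       the later image is removed;
    3. rank the survivors by their nearest-neighbor distance (most dissimilar
       first) and keep the top ``ceil(keep_fraction * n_survivors)``.

    Returns kept indices into the original list, ascending.  Deterministic;
    ties rank by original index.
    """
    if not images:
        raise ValueError("cannot filter an empty image list")
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must lie in (0, 1]")
    hashes = [phash(img) for img in images]
    n = len(images)
    dist = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = hamming(hashes[i], hashes[j])

    dropped = set()
    for i in range(n):
        if i in dropped:
            continue
        for j in range(i + 1, n):
            if j not in dropped and dist[i, j] <= dup_threshold:
                dropped.add(j)
    survivors = [i for i in range(n) if i not in dropped]

    if len(survivors) == 1:
        return survivors
    # nearest-neighbor distance among survivors; larger = more dissimilar
    nn = {
        i: min(dist[i, j] for j in survivors if j != i)
        for i in survivors
    }
    ranked = sorted(survivors, key=lambda i: (-nn[i], i))
    n_keep = math.ceil(keep_fraction * len(survivors))
    return sorted(ranked[:n_keep])


def compose(foreground: np.ndarray, mask: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Blend a foreground onto a background through a binary mask:
    ``mask * foreground + (1 - mask) * background``."""
    foreground = np.asarray(foreground, dtype=float)
    background = np.asarray(background, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if foreground.shape != background.shape:
        raise ValueError(
            f"foreground/background shape mismatch: {foreground.shape} vs {background.shape}"
        )
    if mask.shape != foreground.shape[: mask.ndim]:
        raise ValueError(f"mask shape {mask.shape} does not match images {foreground.shape}")
    if foreground.ndim == 3 and mask.ndim == 2:
        mask = mask[..., None]
    return mask * foreground + (1.0 - mask) * background


def plausible_composites(
    foregrounds: list[np.ndarray],
    backgrounds: list[np.ndarray],
    dup_threshold: int = 5,
) -> list[tuple[int, int]]:
    """Spatial-constraint pairing for compositing: each foreground may use a
    background at most once up to perceptual-hash near-duplication, so no
    foreground is pasted repeatedly onto what is effectively one scene.

    Returns accepted (foreground_index, background_index) pairs.
    """
    bg_hashes = [phash(bg) for bg in backgrounds]
    pairs: list[tuple[int, int]] = []
    for fi in range(len(foregrounds)):
        used: list[HashSignature] = []
        for bi, bh in enumerate(bg_hashes):
            if any(hamming(bh, u) <= dup_threshold for u in used):
                continue
            used.append(bh)
            pairs.append((fi, bi))
    return pairs


def elastic_distortion(
    image: np.ndarray,
    delta: float = DEFAULT_DELTA,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    delta_in_pixels: bool = False,
) -> np.ndarray:
    """Warp an image by a smoothed random displacement field.

    ``delta`` sets the Gaussian smoothing scale — by default a fraction of
    min(W, H); pass ``delta_in_pixels=True`` to give it in raw pixels.
    ``alpha`` (pixels) scales the field, bounding the displacement magnitude:
    the raw field is uniform in [-1, 1] and Gaussian smoothing is a convex
    average, so |dx|, |dy| <= alpha everywhere.  ``alpha = 0`` is exactly the
    identity.  Deterministic given the seed.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    image = np.asarray(image, dtype=float)
    h, w = image.shape[:2]
    sigma = delta if delta_in_pixels else delta * min(w, h)
    rng = np.random.default_rng(seed)
    dx = gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma, mode="reflect") * alpha
    dy = gaussian_filter(rng.uniform(-1, 1, (h, w)), sigma, mode="reflect") * alpha

    ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = [ys + dy, xs + dx]
    if image.ndim == 2:
        return map_coordinates(image, coords, order=1, mode="nearest")
    out = np.empty_like(image)
    for c in range(image.shape[2]):
        out[..., c] = map_coordinates(image[..., c], coords, order=1, mode="nearest")
    return out
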