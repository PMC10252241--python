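"""Fixed-size patch extraction and linear + positional embedding.

An optional, off-by-default preprocessing representation: images are tiled
row-major into non-overlapping P x P patches (N = W*H / P**2 of them), which
can then be mapped through a shared seeded linear projection plus a
per-position additive vector.  The default classification pipeline feeds
images directly to the convolutional plan; this module provides the
auxiliary sequence representation only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PatchSet", "patch_count", "extract_patches", "reconstruct", "embed_patches"]

DEFAULT_PATCH_SIZE = 16


@dataclass(frozen=True)
class PatchSet:
    patches: np.ndarray  # (N, P*P*C) row-major patch vectors
    positions: np.ndarray  # (N,) ints 0..N-1
    patch_size: int
    source_shape: tuple[int, int, int]  # (H, W, C)


def patch_count(height: int, width: int, patch: int) -> int:
    """Number of non-overlapping patches, ``W*H / P**2``; exact tiling only."""
    if patch < 1:
        raise ValueError("patch size must be >= 1")
    if height % patch or width % patch:
        raise ValueError(
            f"image {height}x{width} is not divisible by patch size {patch}"
        )
    return (width * height) // (patch * patch)


def extract_patches(image: np.ndarray, patch: int = DEFAULT_PATCH_SIZE) -> PatchSet:
    """Tile the image row-major into flattened P x P x C patch vectors."""
    image = np.asarray(image)
    if image.ndim == 2:
        image = image[:, :, None]
    if image.ndim != 3:
        raise ValueError("image must be HxW or HxWxC")
    h, w, c = image.shape
    n = patch_count(h, w, patch)
    tiles = image.reshape(h // patch, patch, w // patch, patch, c)
    tiles = tiles.transpose(0, 2, 1, 3, 4).reshape(n, patch * patch * c)
    return PatchSet(
        patches=tiles,
        positions=np.arange(n),
        patch_size=patch,
        source_shape=(h, w, c),
    )


def reconstruct(patchset: PatchSet) -> np.ndarray:
    """Invert :func:`extract_patches`; exact round-trip."""
    h, w, c = patchset.source_shape
    p = patchset.patch_size
    order = np.argsort(patchset.positions)
    tiles = patchset.patches[order].reshape(h // p, w // p, p, p, c)
    return tiles.transpose(0, 2, 1, 3, 4).reshape(h, w, c)


def embed_patches(patchset: PatchSet, dim: int, seed: int) -> np.ndarray:
    """Shared linear map + per-position additive embedding; (N, dim) output."""
    if dim < 1:
        raise ValueError("embedding dim must be >= 1")
    rng = np.random.default_rng(seed)
    d_in = patchset.patches.shape[1]
    weight = rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_in, dim))
    positional = rng.normal(0.0, 0.02, size=(len(patchset.positions), dim))
    return patchset.patches.astype(np.float64) @ weight + positional[patchset.positions]
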