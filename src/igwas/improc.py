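"""Image preprocessing shared by the quality scorer and the phenotyper."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["to_float", "downsample", "prep_batch", "random_rotate"]


def to_float(pixels: np.ndarray) -> np.ndarray:
    """uint8 RGB -> float in [0, 1]."""
    return np.asarray(pixels, dtype=float) / 255.0


def downsample(img: np.ndarray, hw: int) -> np.ndarray:
    """Reduce an (H, W, 3) float image to (hw, hw, 3) by block averaging.

    Falls back to bilinear zoom when H or W is not a multiple of hw.
    """
    h, w, _ = img.shape
    if h % hw == 0 and w % hw == 0:
        bh, bw = h // hw, w // hw
        return img.reshape(hw, bh, hw, bw, 3).mean(axis=(1, 3))
    return ndimage.zoom(img, (hw / h, hw / w, 1.0), order=1)


def prep_batch(images, hw: int, flip_right: bool = False) -> np.ndarray:
    """Stack FundusImages into an (N, hw, hw, 3) float batch, centered at 0.

    With ``flip_right``, right-eye images are horizontally mirrored first
    so that both eyes present the same orientation to the encoder.
    """
    out = np.empty((len(images), hw, hw, 3))
    for i, img in enumerate(images):
        px = to_float(img.pixels)
        if flip_right and getattr(img, "eye", None) == "right":
            px = px[:, ::-1, :]
        out[i] = downsample(px, hw)
    return out - 0.5


def random_rotate(batch: np.ndarray, max_deg: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-image random rotation in +/-max_deg (train-time augmentation)."""
    if max_deg <= 0:
        return batch
    out = np.empty_like(batch)
    angles = rng.uniform(-max_deg, max_deg, size=batch.shape[0])
    for i in range(batch.shape[0]):
        out[i] = ndimage.rotate(batch[i], angles[i], axes=(0, 1),
                                reshape=False, order=1, mode="constant",
                                cval=-0.5)
    return out
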