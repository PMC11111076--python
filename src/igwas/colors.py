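"""Retina-color phenotypes.

Three quantitative traits per image: the mean red, green and blue
intensity of the central (foveal) patch. On the full-scale 1536x2048
fundus grid the patch is the half-open, 0-based pixel window
rows [600:1000), cols [800:1200) — 400x400 pixels, slightly off the
geometric center; at other resolutions the same fractional window
(floor-rounded) is used, preserving the offset. Right-eye images are
horizontally mirrored before cropping so both eyes sample the same
anatomical region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ColorTriplet", "extract_retina_color", "REFERENCE_SHAPE",
           "REFERENCE_WINDOW", "color_table"]

REFERENCE_SHAPE = (1536, 2048)
REFERENCE_WINDOW = ((600, 1000), (800, 1200))   # (row0,row1), (col0,col1)


@dataclass
class ColorTriplet:
    mean_red: float
    mean_green: float
    mean_blue: float
    subject_id: str = ""
    eye: str = "left"

    def as_array(self) -> np.ndarray:
        return np.array([self.mean_red, self.mean_green, self.mean_blue])


def _window(shape: tuple[int, int]) -> tuple[slice, slice]:
    rows, cols = shape
    (r0, r1), (c0, c1) = REFERENCE_WINDOW
    if (rows, cols) == REFERENCE_SHAPE:
        return slice(r0, r1), slice(c0, c1)
    rr0 = int(np.floor(r0 / REFERENCE_SHAPE[0] * rows))
    rr1 = int(np.floor(r1 / REFERENCE_SHAPE[0] * rows))
    cc0 = int(np.floor(c0 / REFERENCE_SHAPE[1] * cols))
    cc1 = int(np.floor(c1 / REFERENCE_SHAPE[1] * cols))
    if rr1 <= rr0 or cc1 <= cc0:
        raise ValueError(f"color window empty for image shape {shape}")
    return slice(rr0, rr1), slice(cc0, cc1)


def extract_retina_color(image) -> ColorTriplet:
    """Per-channel arithmetic means of the central foveal patch."""
    px = np.asarray(image.pixels, dtype=float)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected RGB image, got shape {px.shape}")
    eye = getattr(image, "eye", "left")
    if eye == "right":
        px = px[:, ::-1, :]
    rs, cs = _window(px.shape[:2])
    patch = px[rs, cs, :]
    means = patch.mean(axis=(0, 1))
    return ColorTriplet(
        mean_red=float(means[0]), mean_green=float(means[1]),
        mean_blue=float(means[2]),
        subject_id=getattr(image, "subject_id", ""), eye=eye,
    )


def color_table(images):
    """DataFrame of color triplets, one row per image."""
    import pandas as pd

    rows = []
    for img in images:
        t = extract_retina_color(img)
        rows.append((t.subject_id, t.eye, t.mean_red, t.mean_green, t.mean_blue))
    return pd.DataFrame(
        rows, columns=["subject_id", "eye", "mean_red", "mean_green", "mean_blue"]
    )
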