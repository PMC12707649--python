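"""Small shared raster utilities."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad


def resize_bilinear(image, out_h: int, out_w: int):
    """Bilinear resize; accepts plain arrays or autodiff tensors."""
    return ad.bilinear_resize(image, out_h, out_w)


def to_grey01(image: np.ndarray) -> np.ndarray:
    """Coerce a raster to single-channel float in [0, 1].

    Accepts uint8 (0..255) or float inputs; a trailing colour axis is
    averaged away.
    """
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    arr = arr.astype(float)
    if arr.size and arr.max() > 1.0:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)
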