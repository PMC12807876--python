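"""Small morphology helpers shared across modules."""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

__all__ = ["remove_small", "fill_holes_3d"]


def remove_small(mask: np.ndarray, min_size: int, connectivity_full: bool = True) -> np.ndarray:
    """Drop connected components with fewer than ``min_size`` pixels/voxels."""
    structure = np.ones((3,) * mask.ndim, int) if connectivity_full else None
    labels, n = ndi.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    counts = np.bincount(labels.ravel())
    keep = counts >= min_size
    keep[0] = False
    return keep[labels]


def fill_holes_3d(mask: np.ndarray) -> np.ndarray:
    """Fill holes volumetrically and then per z slice.

    A pure 3-D fill leaks when a cap slice of a closed shell has even a
    small gap (the interior then connects to the open planes beyond), so
    each slice is filled in 2-D afterwards.
    """
    out = ndi.binary_fill_holes(mask)
    for z in range(out.shape[0]):
        out[z] = ndi.binary_fill_holes(out[z])
    return out
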