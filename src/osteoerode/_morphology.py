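"""Exact Euclidean-ball binary morphology shared by the phantom generator and metrics.

A voxel belongs to a ball of radius ``r`` iff its center lies *strictly*
within Euclidean distance ``r`` of the ball center. The strict inequality
matters for integer radii: with ``<=`` the ball would carry degenerate
single-voxel tips at exactly distance ``r`` along the axes, and a closing
could then never refill any surface-layer voxel (a ball touching the voxel
only at its tip always escapes the object). The strict ball has a flat
bottom disk instead and behaves like the rolling-ball intuition.

Dilation and erosion are evaluated through exact distance transforms
(squared distances between integer voxel centers are integers, so the
comparisons are exact after rounding); closing pads the grid first, giving
unbounded-domain semantics: extensive and independent of where the object
sits in the array.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def dist_sq(mask: np.ndarray) -> np.ndarray:
    """Squared Euclidean distance from each voxel to the nearest True voxel."""
    if not mask.any():
        return np.full(mask.shape, np.inf)
    d = ndimage.distance_transform_edt(~mask)
    return np.rint(d * d)


def ball_dilate(mask: np.ndarray, radius: float) -> np.ndarray:
    """Dilation by the discrete ball (array-bounded; pad first for unbounded semantics)."""
    return dist_sq(mask) < radius * radius - 1e-7


def ball_erode(mask: np.ndarray, radius: float) -> np.ndarray:
    """Erosion by the discrete ball: keep voxels with no background strictly within ``radius``."""
    return dist_sq(~mask) >= radius * radius - 1e-7


def ball_close(mask: np.ndarray, radius: float) -> np.ndarray:
    """Unbounded-domain morphological closing by the discrete ball."""
    pad = int(np.ceil(radius)) + 1
    padded = np.pad(mask, pad, mode="constant", constant_values=False)
    closed = ball_erode(ball_dilate(padded, radius), radius)
    return closed[pad:-pad, pad:-pad, pad:-pad] | mask


def background_structure(foreground_connectivity: int) -> np.ndarray:
    """Dual background connectivity structure (foreground 26 <-> background 6)."""
    if foreground_connectivity not in (6, 26):
        raise ValueError(f"connectivity must be 6 or 26, got {foreground_connectivity}")
    return ndimage.generate_binary_structure(3, 1 if foreground_connectivity == 26 else 3)


def fill_enclosed_background(mask: np.ndarray, foreground_connectivity: int = 26) -> np.ndarray:
    """Topological hole filling: add background components not reaching the volume border."""
    return ndimage.binary_fill_holes(mask, structure=background_structure(foreground_connectivity))
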