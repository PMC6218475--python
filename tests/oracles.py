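"""Brute-force reference implementations used to validate the package.

Everything here is written directly from definitions (explicit offset
enumeration, frontier flood fill, BFS component labeling, pairwise
distances) and deliberately avoids the code paths under test
(`osteoerode._morphology`, `scipy.ndimage` morphology).
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# discrete ball morphology by direct definition
# ---------------------------------------------------------------------------

def ball_offsets(radius: float) -> list[tuple[int, int, int]]:
    """Integer offsets strictly within Euclidean `radius` of the origin."""
    n = int(np.ceil(radius))
    offs = []
    for dz in range(-n, n + 1):
        for dy in range(-n, n + 1):
            for dx in range(-n, n + 1):
                if dz * dz + dy * dy + dx * dx < radius * radius - 1e-7:
                    offs.append((dz, dy, dx))
    return offs


def _shift(mask: np.ndarray, dz: int, dy: int, dx: int) -> np.ndarray:
    """Translate a boolean grid, zero-filling; out-of-array is background."""
    out = np.zeros_like(mask)
    z0, z1 = max(dz, 0), mask.shape[0] + min(dz, 0)
    y0, y1 = max(dy, 0), mask.shape[1] + min(dy, 0)
    x0, x1 = max(dx, 0), mask.shape[2] + min(dx, 0)
    if z0 < z1 and y0 < y1 and x0 < x1:
        out[z0:z1, y0:y1, x0:x1] = mask[z0 - dz:z1 - dz, y0 - dy:y1 - dy, x0 - dx:x1 - dx]
    return out


def brute_dilate(mask: np.ndarray, radius: float) -> np.ndarray:
    out = np.zeros_like(mask)
    for dz, dy, dx in ball_offsets(radius):
        out |= _shift(mask, dz, dy, dx)
    return out


def brute_erode(mask: np.ndarray, radius: float) -> np.ndarray:
    return ~brute_dilate(~mask, radius)


def brute_close(mask: np.ndarray, radius: float) -> np.ndarray:
    """Unbounded-domain closing: pad so the array boundary cannot interfere."""
    pad = int(np.ceil(radius)) + 1
    padded = np.pad(mask, pad)
    closed = brute_erode(brute_dilate(padded, radius), radius)
    return closed[pad:-pad, pad:-pad, pad:-pad]


# ---------------------------------------------------------------------------
# flood fill and connected components by frontier expansion / BFS
# ---------------------------------------------------------------------------

_OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
_OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def brute_border_flood(background: np.ndarray, connectivity: int = 6) -> np.ndarray:
    """Background voxels reachable from the volume border (frontier expansion)."""
    offs = _OFFSETS_6 if connectivity == 6 else _OFFSETS_26
    reached = np.zeros_like(background)
    border = np.zeros_like(background)
    border[0], border[-1] = True, True
    border[:, 0], border[:, -1] = True, True
    border[:, :, 0], border[:, :, -1] = True, True
    frontier = background & border
    while frontier.any():
        reached |= frontier
        grown = np.zeros_like(background)
        for dz, dy, dx in offs:
            grown |= _shift(frontier, dz, dy, dx)
        frontier = grown & background & ~reached
    return reached


def brute_fill_holes(mask: np.ndarray, connectivity: int = 6) -> np.ndarray:
    """Fill background components not connected to the volume border."""
    return mask | (~mask & ~brute_border_flood(~mask, connectivity))


def brute_fill_pores(mask: np.ndarray, radius: float, background_connectivity: int = 6) -> np.ndarray:
    """Reference for fill_pores: ball closing then border-flood hole filling."""
    return brute_fill_holes(brute_close(mask, radius), background_connectivity)


def brute_label_components(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    """BFS connected-component labeling (returns labels and component count)."""
    offs = _OFFSETS_6 if connectivity == 6 else _OFFSETS_26
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for seed in zip(*np.nonzero(mask)):
        if labels[seed]:
            continue
        current += 1
        stack = [seed]
        labels[seed] = current
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offs:
                nz, ny, nx = z + dz, y + dy, x + dx
                if 0 <= nz < mask.shape[0] and 0 <= ny < mask.shape[1] and 0 <= nx < mask.shape[2]:
                    if mask[nz, ny, nx] and not labels[nz, ny, nx]:
                        labels[nz, ny, nx] = current
                        stack.append((nz, ny, nx))
    return labels, current


# ---------------------------------------------------------------------------
# distances by direct pairwise computation (small volumes only)
# ---------------------------------------------------------------------------

def brute_min_distances(query: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Euclidean distance from each True voxel of `query` to the nearest True voxel of `targets`."""
    q = np.argwhere(query).astype(float)
    t = np.argwhere(targets).astype(float)
    if t.size == 0:
        return np.full(len(q), np.inf)
    d2 = ((q[:, None, :] - t[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(d2.min(axis=1))


def brute_surface_shell(mask: np.ndarray, distance: float) -> np.ndarray:
    """Voxels within `distance` of the opposite phase, by pairwise distances."""
    out = np.zeros_like(mask)
    inside = np.argwhere(mask)
    outside = np.argwhere(~mask)
    if inside.size and outside.size:
        din = brute_min_distances(mask, ~mask)
        out[tuple(inside.T)] = din <= distance + 1e-9
        dout = brute_min_distances(~mask, mask)
        out[tuple(outside.T)] |= dout <= distance + 1e-9
    return out
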