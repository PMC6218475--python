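"""Bone mask extraction and per-bone label restriction.

Thresholding is deliberately simple — Otsu or a fixed value, both logged —
because the scientifically sensitive choices live downstream in the erosion
metrics. Per-bone delineation is taken as user input (a painted or
registered label volume); no automatic bone-instance separation is
attempted.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from osteoerode.volume_io import BoneMask, LabeledBones, VoxelVolume

logger = logging.getLogger(__name__)

#: Name used for mask voxels not covered by any input label.
UNASSIGNED_NAME = "unassigned"


def threshold_bone(
    volume: VoxelVolume, method: str = "otsu", fixed_value: float | None = None
) -> BoneMask:
    """Binarize a grayscale volume into a bone mask.

    The mask contains every voxel with intensity >= the threshold. With
    ``method='otsu'`` the threshold is computed from the intensity
    histogram; a constant volume is rejected with advice to use a fixed
    threshold instead. The applied threshold is logged in either case.
    """
    data = volume.data
    if method == "otsu":
        if np.all(data == data.flat[0]):
            raise ValueError(
                "volume has a single intensity value; Otsu is undefined — use method='fixed' "
                "with an explicit fixed_value"
            )
        otsu = float(threshold_otsu(data))
        # skimage's convention is foreground strictly above the Otsu value;
        # shift to the smallest intensity above it so mask = data >= threshold.
        above = data[data > otsu]
        threshold = float(above.min()) if above.size else np.inf
    elif method == "fixed":
        if fixed_value is None:
            raise ValueError("method='fixed' requires fixed_value")
        threshold = float(fixed_value)
    else:
        raise ValueError(f"unknown thresholding method {method!r} (use 'otsu' or 'fixed')")
    logger.info("threshold_bone: method=%s threshold=%g", method, threshold)
    return BoneMask(data=data >= threshold, voxel_size_um=volume.voxel_size_um)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")


def keep_components(mask: BoneMask, min_voxels: int, connectivity: int = 26) -> BoneMask:
    """Drop connected components smaller than ``min_voxels`` (despeckling).

    Never adds voxels and is idempotent at fixed parameters. An empty
    result is permitted but logged as a warning.
    """
    if min_voxels < 1:
        raise ValueError(f"min_voxels must be >= 1, got {min_voxels}")
    labeled, n = ndimage.label(mask.data, structure=_structure(connectivity))
    if n == 0:
        logger.warning("keep_components: input mask is empty")
        return BoneMask(data=mask.data.copy(), voxel_size_um=mask.voxel_size_um)
    sizes = np.bincount(labeled.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    out = keep[labeled]
    if not out.any():
        logger.warning("keep_components: no component reaches min_voxels=%d; result is empty", min_voxels)
    return BoneMask(data=out, voxel_size_um=mask.voxel_size_um)


def label_bones(mask: BoneMask, labels: LabeledBones) -> LabeledBones:
    """Restrict a per-bone label volume to the bone mask.

    Labels outside the mask are zeroed. Mask voxels carrying label 0 are
    assigned a reserved ``unassigned`` label (one past the largest known
    label) and their count is logged, so no bone voxel silently drops out
    of per-bone accounting.
    """
    if labels.shape != mask.shape:
        raise ValueError(f"labels shape {labels.shape} != mask shape {mask.shape}")
    restricted = np.where(mask.data, labels.data, 0).astype(np.int32)
    names = dict(labels.label_names)
    uncovered = mask.data & (restricted == 0)
    n_unassigned = int(uncovered.sum())
    if n_unassigned:
        reserved = max([*names.keys(), int(restricted.max())], default=0) + 1
        restricted[uncovered] = reserved
        names[reserved] = UNASSIGNED_NAME
        logger.info("label_bones: %d mask voxels not covered by labels -> label %d (%s)",
                    n_unassigned, reserved, UNASSIGNED_NAME)
    return LabeledBones(data=restricted, label_names=names, voxel_size_um=mask.voxel_size_um)
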