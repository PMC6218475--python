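"""Synthetic cortical-shell phantoms with exactly known defect ground truth.

A phantom is a hollow ellipsoidal shell of "bone" intensity over background,
optionally carved with hemispherical surface pits (open defects) and fully
enclosed intracortical cavities (full pores). Every carve is tallied voxel by
voxel, so the generator returns exact ground-truth counts alongside the noisy
rendering and the true binary mask.

Discrete ball convention: a voxel belongs to a ball of radius ``r`` iff its
center lies strictly within Euclidean distance ``r`` of the ball center —
the same convention as the morphology in :mod:`osteoerode._morphology`, so
carved defects and structuring elements agree voxel for voxel.

If the ellipsoid's z extent exceeds the volume, the shell is cut open at the
z faces and the medullary lumen stays connected to the border — use this to
build tube-like phantoms whose inner space is not treated as an enclosed
pore by topological hole filling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from osteoerode._morphology import ball_close, fill_enclosed_background
from osteoerode.volume_io import DEFAULT_VOXEL_SIZE_UM, BoneMask, VoxelVolume


class GeometryError(ValueError):
    """Raised when a requested pit or cavity cannot be carved consistently."""


@dataclass
class Pit:
    """Hemispherical surface pit: ball centered on the outer shell surface.

    ``center_direction`` is a 3-vector (z, y, x) from the phantom center
    toward the surface point; it is normalized internally.
    """

    center_direction: tuple[float, float, float]
    radius_vox: float

    def __post_init__(self) -> None:
        d = np.asarray(self.center_direction, dtype=float)
        norm = float(np.linalg.norm(d))
        if norm == 0:
            raise GeometryError("pit center_direction must be nonzero")
        self.center_direction = tuple(d / norm)
        if self.radius_vox <= 0:
            raise GeometryError(f"pit radius must be > 0, got {self.radius_vox}")


@dataclass
class Cavity:
    """Enclosed spherical cavity strictly inside the cortical wall."""

    center: tuple[float, float, float]
    radius_vox: float

    def __post_init__(self) -> None:
        if self.radius_vox <= 0:
            raise GeometryError(f"cavity radius must be > 0, got {self.radius_vox}")


@dataclass
class PhantomSpec:
    """Parametric description of a synthetic bone shell.

    Parameters
    ----------
    shape : (int, int, int)
        Volume dimensions (z, y, x).
    outer_radii : (float, float, float)
        Outer ellipsoid semi-axes in voxels (z, y, x), each >= 3.
    cortical_thickness : float
        Wall thickness in voxels, >= 2 and < min(outer_radii).
    pits, cavities : sequences
        Surface pits and enclosed cavities to carve, in order.
    intensities : (bone, background)
        Rendering intensities, bone > background.
    noise_sigma : float
        Std of additive Gaussian intensity noise (0 disables).
    seed : int
        Seed for the noise generator; identical spec + seed is bitwise
        reproducible.
    regularize_radius_vox : float, optional
        When set, the intact shell is closed with a ball of this radius
        (and enclosed background filled) *before* any carving, so the
        intact surface has no discretization crevices at that scale:
        pore filling at the same radius then leaves an uncarved phantom
        exactly unchanged. Ground-truth counts refer to the regularized
        shell.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    outer_radii: tuple[float, float, float] = (40.0, 24.0, 24.0)
    cortical_thickness: float = 8.0
    pits: Sequence[Pit] = field(default_factory=list)
    cavities: Sequence[Cavity] = field(default_factory=list)
    intensities: tuple[float, float] = (1.0, 0.0)
    noise_sigma: float = 0.0
    seed: int = 0
    regularize_radius_vox: float | None = None

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise GeometryError(f"shape must be a positive integer triple, got {self.shape}")
        self.outer_radii = tuple(float(r) for r in self.outer_radii)
        if len(self.outer_radii) != 3 or min(self.outer_radii) < 3:
            raise GeometryError(f"outer_radii must be >= 3 voxels on every axis, got {self.outer_radii}")
        self.cortical_thickness = float(self.cortical_thickness)
        if self.cortical_thickness < 2:
            raise GeometryError(f"cortical_thickness must be >= 2 voxels, got {self.cortical_thickness}")
        if self.cortical_thickness >= min(self.outer_radii):
            raise GeometryError(
                f"cortical_thickness {self.cortical_thickness} must be < min outer radius {min(self.outer_radii)}"
            )
        self.pits = [p if isinstance(p, Pit) else Pit(**p) for p in self.pits]
        self.cavities = [c if isinstance(c, Cavity) else Cavity(**c) for c in self.cavities]
        bone, background = (float(v) for v in self.intensities)
        if bone <= background:
            raise GeometryError(f"bone intensity must exceed background, got {self.intensities}")
        self.intensities = (bone, background)
        if self.noise_sigma < 0:
            raise GeometryError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        self.seed = int(self.seed)
        if self.regularize_radius_vox is not None and self.regularize_radius_vox <= 0:
            raise GeometryError(f"regularize_radius_vox must be > 0, got {self.regularize_radius_vox}")

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "intensities" in d and isinstance(d["intensities"], dict):
            d["intensities"] = (d["intensities"]["bone"], d["intensities"]["background"])
        if "shell" in d:
            shell = d.pop("shell")
            d["outer_radii"] = shell["outer_radii"]
            d["cortical_thickness"] = shell["cortical_thickness"]
        return cls(**d)


@dataclass
class GroundTruth:
    """Exact voxel tallies recorded while carving a phantom."""

    bone_voxels_intact: int
    pit_voxels: list[int]
    cavity_voxels: list[int]

    @property
    def expected_erosion_fraction(self) -> float:
        if self.bone_voxels_intact == 0:
            return 0.0
        return sum(self.pit_voxels) / self.bone_voxels_intact

    @property
    def expected_full_pore_voxels(self) -> int:
        return sum(self.cavity_voxels)

    def to_dict(self) -> dict:
        return {
            "bone_voxels_intact": self.bone_voxels_intact,
            "pit_voxels": list(self.pit_voxels),
            "cavity_voxels": list(self.cavity_voxels),
            "expected_erosion_fraction": self.expected_erosion_fraction,
            "expected_full_pore_voxels": self.expected_full_pore_voxels,
        }


def _ball_region(shape, center, radius):
    """Voxel coordinates of the discrete ball (center-distance < radius), clipped to shape.

    Returns an index tuple usable for fancy indexing plus the boolean ball
    within its bounding box, for neighbor checks.
    """
    center = np.asarray(center, dtype=float)
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return (np.empty(0, int),) * 3
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]), indexing="ij"
    )
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    inside = d2 < radius * radius - 1e-7  # strict ball, same convention as the morphology
    return zz[inside], yy[inside], xx[inside]


_SIX_NEIGHBORS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)], dtype=int
)


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, BoneMask, GroundTruth]:
    """Generate a phantom volume, its true bone mask, and exact ground truth.

    The mask is the noise-free occupancy (intact shell minus pits minus
    cavities); the volume renders it at the spec intensities plus seeded
    Gaussian noise. Pit/cavity counts are the voxels actually removed, in
    carving order, so overlapping defects never double-count.

    Raises
    ------
    GeometryError
        If a pit is at least as large as the cortical wall, or a cavity is
        not fully enclosed by bone (touches the outer surface, the lumen, or
        a previously carved defect).
    """
    shape = spec.shape
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    outer = np.asarray(spec.outer_radii, dtype=float)
    inner = outer - spec.cortical_thickness

    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    rel = [(zz - center[0]), (yy - center[1]), (xx - center[2])]
    outer_field = sum((c / r) ** 2 for c, r in zip(rel, outer))
    inner_field = sum((c / r) ** 2 for c, r in zip(rel, inner))
    mask = (outer_field <= 1.0) & (inner_field > 1.0)
    if not mask.any():
        raise GeometryError("shell does not intersect the volume; enlarge shape or radii")
    if spec.regularize_radius_vox is not None:
        mask = fill_enclosed_background(ball_close(mask, spec.regularize_radius_vox))
    bone_voxels_intact = int(mask.sum())

    pit_counts: list[int] = []
    for i, pit in enumerate(spec.pits):
        if pit.radius_vox >= spec.cortical_thickness:
            raise GeometryError(
                f"pit {i}: radius {pit.radius_vox} >= cortical thickness {spec.cortical_thickness}; "
                "pit would breach the wall"
            )
        d = np.asarray(pit.center_direction, dtype=float)
        t = 1.0 / np.sqrt(np.sum((d / outer) ** 2))
        surface_point = center + t * d
        if np.any(surface_point < -0.5) or np.any(surface_point > np.asarray(shape) - 0.5):
            raise GeometryError(f"pit {i}: surface point {surface_point} lies outside the volume")
        idx = _ball_region(shape, surface_point, pit.radius_vox)
        carve = mask[idx]
        removed = int(carve.sum())
        mask[idx] = False
        pit_counts.append(removed)

    cavity_counts: list[int] = []
    for i, cav in enumerate(spec.cavities):
        idx = _ball_region(shape, cav.center, cav.radius_vox)
        pts = np.stack(idx, axis=1)
        if pts.shape[0] == 0:
            raise GeometryError(f"cavity {i}: ball at {cav.center} contains no voxels inside the volume")
        if not mask[idx].all():
            raise GeometryError(
                f"cavity {i}: ball at {cav.center} r={cav.radius_vox} intersects non-bone voxels "
                "(outer background, lumen, or a previous defect)"
            )
        # full enclosure: every 6-neighbor of every cavity voxel must be bone
        # (checked before carving, so the ball's own voxels still qualify).
        for off in _SIX_NEIGHBORS:
            nb = pts + off
            if np.any((nb < 0) | (nb >= np.asarray(shape))):
                raise GeometryError(f"cavity {i}: touches the volume border")
            nb_idx = (nb[:, 0], nb[:, 1], nb[:, 2])
            if not mask[nb_idx].all():
                raise GeometryError(f"cavity {i}: not fully enclosed by bone (touches a surface)")
        removed = int(mask[idx].sum())
        mask[idx] = False
        cavity_counts.append(removed)

    bone, background = spec.intensities
    volume = np.where(mask, bone, background).astype(np.float64)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        volume = volume + rng.normal(0.0, spec.noise_sigma, size=shape)

    truth = GroundTruth(
        bone_voxels_intact=bone_voxels_intact,
        pit_voxels=pit_counts,
        cavity_voxels=cavity_counts,
    )
    vol = VoxelVolume(data=volume, voxel_size_um=spec.voxel_size_um)
    bmask = BoneMask(data=mask, voxel_size_um=spec.voxel_size_um)
    return vol, bmask, truth
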