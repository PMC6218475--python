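import numpy as np
import pytest

from osteoerode.phantom import Cavity, PhantomSpec, Pit, generate_phantom
from osteoerode.volume_io import BoneMask, LabeledBones

# Open-ended tube phantom: the z semi-axis exceeds the volume, so the shell
# is cut at the z faces and the medullary lumen stays border-connected
# (hole filling must not swallow it).
TUBE = dict(shape=(64, 64, 64), outer_radii=(60.0, 26.0, 26.0), cortical_thickness=9.0)


@pytest.fixture(scope="session")
def intact_tube():
    spec = PhantomSpec(**TUBE, regularize_radius_vox=6.0)
    _, mask, truth = generate_phantom(spec)
    return mask, truth


@pytest.fixture(scope="session")
def pitted_tube():
    spec = PhantomSpec(
        **TUBE,
        regularize_radius_vox=6.0,
        pits=[Pit(center_direction=(0, 0, 1), radius_vox=3.0)],
    )
    _, mask, truth = generate_phantom(spec)
    return mask, truth


@pytest.fixture(scope="session")
def cavity_tube():
    # cavity at mid-wall depth (~4.5 voxels from either surface)
    spec = PhantomSpec(
        **TUBE,
        regularize_radius_vox=6.0,
        cavities=[Cavity(center=(31.5, 31.5 + 21.5, 31.5), radius_vox=1.9)],
    )
    _, mask, truth = generate_phantom(spec)
    return mask, truth


def two_shell_phantom(pit_radius=3.0, closing_radius=6.0):
    """Two disjoint tube shells stacked along y, labeled 1 (pitted) and 2 (intact)."""
    spec_a = PhantomSpec(
        **TUBE,
        regularize_radius_vox=closing_radius,
        pits=[Pit(center_direction=(0, 0, 1), radius_vox=pit_radius)],
    )
    spec_b = PhantomSpec(**TUBE, regularize_radius_vox=closing_radius)
    _, mask_a, truth_a = generate_phantom(spec_a)
    _, mask_b, truth_b = generate_phantom(spec_b)
    nz, ny, nx = mask_a.shape
    gap = 2 * int(np.ceil(closing_radius)) + 4  # closing must not bridge the shells
    data = np.zeros((nz, 2 * ny + gap, nx), dtype=bool)
    labels = np.zeros_like(data, dtype=np.int32)
    data[:, :ny, :] = mask_a.data
    labels[:, :ny, :][mask_a.data] = 1
    data[:, ny + gap:, :] = mask_b.data
    labels[:, ny + gap:, :][mask_b.data] = 2
    mask = BoneMask(data=data)
    labeled = LabeledBones(data=labels, label_names={1: "shell A", 2: "shell B"})
    return mask, labeled, truth_a, truth_b


@pytest.fixture(scope="session")
def two_shells():
    return two_shell_phantom()
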