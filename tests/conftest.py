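import numpy as np
import pytest

from sabrqa.core import Prescription, StructureMask, StructureRole, VoxelGrid


@pytest.fixture
def grid32():
    return VoxelGrid((32, 32, 32), (2.0, 2.0, 2.0))


@pytest.fixture
def grid64():
    return VoxelGrid((64, 64, 64), (2.0, 2.0, 2.0))


def sphere_mask(grid: VoxelGrid, center_mm, radius_mm, label="S",
                role=StructureRole.PTV) -> StructureMask:
    x, y, z = grid.coordinates_mm()
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    c = np.asarray(center_mm, dtype=float)
    vox = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= radius_mm**2
    return StructureMask(grid=grid, voxels=vox, label=label, role=role)


def box_mask(grid: VoxelGrid, lo_idx, hi_idx, label="B",
             role=StructureRole.PTV) -> StructureMask:
    vox = np.zeros(grid.shape, dtype=bool)
    sl = tuple(slice(a, b) for a, b in zip(lo_idx, hi_idx))
    vox[sl] = True
    return StructureMask(grid=grid, voxels=vox, label=label, role=role)


@pytest.fixture
def centered_sphere(grid64):
    center = [grid64.spacing[0] * (grid64.shape[0] - 1) / 2] * 3
    return sphere_mask(grid64, center, 16.0, label="PTV", role=StructureRole.PTV)


@pytest.fixture
def rx40():
    return Prescription("PTV", 40.0, 5)
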