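import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gistmon import ImageGrid, LesionMask, render_lesion

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

SPHERE_VOLUME_R10 = 4.0 / 3.0 * np.pi * 10.0**3  # 4188.79 mm^3


@pytest.fixture
def unit_grid():
    return ImageGrid((32, 32, 32), (1.0, 1.0, 1.0))


@pytest.fixture
def ball_mask_factory():
    """Voxelized ball of a given radius (mm) at a given isotropic spacing."""

    def make(radius_mm: float, spacing_mm: float, margin_vox: int = 3):
        n = int(np.ceil(2 * radius_mm / spacing_mm)) + 2 * margin_vox
        n |= 1  # odd so a voxel centre sits at the sphere centre
        grid = ImageGrid((n, n, n), (spacing_mm,) * 3)
        volume = 4.0 / 3.0 * np.pi * radius_mm**3
        mask, ct = render_lesion(volume, grid, density_hu=55.0)
        return mask, ct

    return make


def random_mask(rng: np.random.Generator, max_side: int = 9) -> LesionMask:
    """A small random binary mask on a random anisotropic grid."""
    shape = tuple(int(s) for s in rng.integers(2, max_side, size=3))
    spacing = tuple(float(s) for s in rng.uniform(0.5, 3.0, size=3))
    axial = int(rng.integers(0, 3))
    values = (rng.random(shape) < rng.uniform(0.05, 0.6)).astype(np.uint8)
    return LesionMask(ImageGrid(shape, spacing, axial), values)
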