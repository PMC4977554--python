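import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from nucmorph.volume import LabelMask, Volume3D


def digital_ball_mask(radius_um: float, voxel_um: float, margin_um: float = 1.0) -> LabelMask:
    """Digitized sphere: voxels whose centers lie within radius_um of center."""
    n = int(np.ceil(2 * (radius_um + margin_um) / voxel_um))
    ax = np.arange(n) * voxel_um
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    c = (n - 1) * voxel_um / 2
    ball = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius_um**2
    return LabelMask(ball.astype(np.uint8), (voxel_um,) * 3)


@pytest.fixture(scope="session")
def sphere_mask_5um() -> LabelMask:
    """Spherical nucleus mask, radius 5 µm at 0.35 µm isotropic voxels."""
    return digital_ball_mask(5.0, 0.35)


@pytest.fixture(scope="session")
def noisy_clump_phantom():
    """One cell phantom with 5 planted clumps and mild noise."""
    from nucmorph.phantoms import CellPhantomSpec, make_cell_phantom

    spec = CellPhantomSpec(n_clumps=5, noise_sd=0.02, seed=1)
    return make_cell_phantom(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def rot90_volume(vol: Volume3D, k: int = 1) -> Volume3D:
    return Volume3D(np.rot90(vol.data, k=k, axes=(1, 2)).copy(), vol.voxel_size,
                    vol.intensity_convention)


def rot90_mask(mask: LabelMask, k: int = 1) -> LabelMask:
    return LabelMask(np.rot90(mask.data, k=k, axes=(1, 2)).copy(), mask.voxel_size, mask.role)
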