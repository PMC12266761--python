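import numpy as np
import pytest

from mitomorph.morph3d import ObjectView


def digitized_sphere_mask(radius: int, pad: int = 3) -> np.ndarray:
    """Binary mask of a sphere of ``radius`` voxels, centered on a voxel."""
    n = 2 * radius + 2 * pad + 1
    c = n // 2
    z, y, x = np.ogrid[:n, :n, :n]
    return (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius**2


def sphere_object(radius: int) -> ObjectView:
    mask = digitized_sphere_mask(radius)
    return ObjectView(label=1, mask=mask, offset=(0, 0, 0), touches_edge=False)


@pytest.fixture(scope="session")
def sphere15():
    return sphere_object(15)


@pytest.fixture(scope="session")
def mixed_phantom():
    """A 40-organelle mixed-family phantom shared across metric tests."""
    from mitomorph.phantoms import PhantomSpec, generate_phantom_volume

    spec = PhantomSpec(count=40, grid_shape=(50, 256, 256), seed=3)
    return generate_phantom_volume(spec)
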