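import numpy as np
import pytest

from dtinet.gradients import default_gradient_table
from dtinet.phantom import BundleSpec, PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def gtab():
    return default_gradient_table()


def straight_bundle_spec(radius_mm: float = 1.1) -> PhantomSpec:
    """One straight tube along x between two box regions, 2 mm voxels."""
    shape = (20, 9, 9)

    def box(x0, x1):
        m = np.zeros(shape, dtype=bool)
        m[x0: x1 + 1, 3:6, 3:6] = True
        return m

    regions = {1: box(1, 3), 2: box(16, 18)}
    bundle = BundleSpec(
        name="rod_left",
        centerline=np.array([[4.0, 8.0, 8.0], [36.0, 8.0, 8.0]]),
        radius_mm=radius_mm,
        endpoint_regions=(1, 2),
        hemisphere="left",
    )
    return PhantomSpec(grid_shape=shape, voxel_size=(2.0, 2.0, 2.0),
                       regions=regions, bundles=(bundle,))


@pytest.fixture(scope="session")
def straight_phantom():
    spec = straight_bundle_spec()
    labels, tensors = build_phantom(spec)
    return spec, labels, tensors
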