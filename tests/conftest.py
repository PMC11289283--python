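import numpy as np
import pytest

from vascage.synthetic import (
    NetworkGenParams,
    generate_vessel_network,
    power_radius_law,
    voxelize_network,
)


@pytest.fixture(scope="session")
def phantom_params():
    """Well-separated phantom parameters used by the round-trip tests."""
    return NetworkGenParams(
        domain_shape_um=(300.0, 300.0, 300.0),
        target_length_density=0.12,
        branch_rate=3.0,
        radius_law=power_radius_law(3.5, 0.9, 0.08),
        seed=1,
        min_separation_um=16.0,
    )


@pytest.fixture(scope="session")
def phantom_network(phantom_params):
    return generate_vessel_network(phantom_params)


@pytest.fixture(scope="session")
def phantom_volume(phantom_network):
    graph, _ = phantom_network
    return voxelize_network(graph, (1.0, 1.0, 1.0), (300, 300, 300))


def straight_cylinder_volume(shape=(40, 40, 60), radius=5.0, axis=2):
    """Solid cylinder along one axis, 1 µm voxels, centered in-plane."""
    vol = np.zeros(shape, dtype=bool)
    axes = [i for i in range(3) if i != axis]
    # center on a voxel center: a perfectly voxel-border-symmetric cylinder
    # has its medial axis between voxels and can thin away entirely
    centers = [shape[a] // 2 + 0.5 for a in axes]
    grids = np.meshgrid(*[np.arange(shape[a]) + 0.5 for a in axes], indexing="ij")
    disk = (grids[0] - centers[0]) ** 2 + (grids[1] - centers[1]) ** 2 <= radius**2
    sl = [slice(None)] * 3
    for k in range(shape[axis]):
        sl[axis] = k
        idx = tuple(sl)
        plane = np.zeros([shape[a] for a in axes], dtype=bool)
        plane[disk] = True
        vol[idx] = plane
    return vol
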