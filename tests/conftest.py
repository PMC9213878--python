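import numpy as np
import pytest

from cmiwarp.core import LandmarkSet, Skeleton, SkeletonNode, SkeletonTree, VoxelScale


def make_skeleton(nodes, edges, radius=None):
    """Build a one-tree skeleton from {id: (x, y, z)} and id-pair edges."""
    node_objs = {
        i: SkeletonNode(i, np.asarray(p, dtype=float), radius) for i, p in nodes.items()
    }
    edge_set = {(min(a, b), max(a, b)) for a, b in edges}
    sk = Skeleton(
        [SkeletonTree(1, "toy", node_objs, edge_set)],
        dataset_name="toy",
        voxel_scale=VoxelScale(1, 1, 1),
    )
    sk.validate()
    return sk


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_landmarks(moving, fixed, moving_name="a", fixed_name="b", active=None):
    moving = np.asarray(moving, dtype=float)
    n = moving.shape[0]
    if active is None:
        active = np.ones(n, dtype=bool)
    return LandmarkSet(
        [f"p{i:03d}" for i in range(n)],
        moving,
        np.asarray(fixed, dtype=float),
        active,
        moving_name=moving_name,
        fixed_name=fixed_name,
    )


@pytest.fixture
def random_box_points(rng):
    """60 random points in a (160 um)^3 box, the scale of a traced volume."""
    return rng.uniform(0.0, 160.0, size=(60, 3))


@pytest.fixture
def affine_map(rng):
    """A well-conditioned non-trivial affine map and its callable."""
    matrix = np.array([[1.05, 0.03, -0.02], [0.01, 0.97, 0.04], [-0.03, 0.02, 1.02]])
    offset = np.array([5.0, -3.0, 8.0])
    return matrix, offset, lambda p: p @ matrix.T + offset
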