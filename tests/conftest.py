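import numpy as np
import pytest

from streetseg import PointCloud, Cluster, SceneSpec, TreeParams, generate_scene


def cluster_from(points, labels=None) -> Cluster:
    """Wrap a raw coordinate array as a single cluster over its own cloud."""
    cloud = PointCloud(np.asarray(points, float), labels=labels)
    return Cluster(cloud, np.arange(len(cloud)))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_scene():
    """Low-density 6-tree scene with both defect types, plus its truth."""
    spec = SceneSpec(
        n_trees=6,
        seed=11,
        defects=frozenset({"glued_pair", "trunk_gap"}),
        crown_density=150.0,
    )
    return generate_scene(spec)


@pytest.fixture(scope="session")
def clean_scene():
    """Low-density 6-tree defect-free scene."""
    spec = SceneSpec(n_trees=6, seed=7, crown_density=150.0)
    return generate_scene(spec)
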