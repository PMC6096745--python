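"""Shared fixtures: one synthetic liver fixture reused across the suite.

The default tree/surface pair is liver-scale (bounding ellipsoid semi-axes
120 x 80 x 60 mm, ~400 centreline points, 31 bifurcations) so radius
schedules in tens of mm are meaningful.  Session scope keeps expensive
artefacts (the uniqueness map) computed once.
"""

import warnings

import numpy as np
import pytest

from lusplan.geometry import RigidTransform
from lusplan.synthetic import TreeGenParams, generate_surface, generate_tree


@pytest.fixture(scope="session")
def tree():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_tree(TreeGenParams(seed=1))


@pytest.fixture(scope="session")
def surface():
    return generate_surface(n_vertices=600, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rigid_transform(rng, max_translation=50.0) -> RigidTransform:
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    t = rng.uniform(-max_translation, max_translation, 3)
    return RigidTransform(rot.as_matrix(), t)
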