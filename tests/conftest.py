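import numpy as np
import pytest

from gaparea3d import (
    articular_annotations,
    make_phantom,
    split_cylinder_spec,
)
from gaparea3d.phantoms import PhantomSpec


@pytest.fixture(scope="session")
def unfractured_cylinder():
    """Whole cylinder (r=25, h=30, 0.5 mm voxels): no fracture, truth 0."""
    spec = PhantomSpec(cuts=(), displacements=((0.0, 0.0, 0.0),))
    volume, labels, meshes, truth = make_phantom(spec)
    return spec, volume, labels, meshes, truth


@pytest.fixture(scope="session")
def split_cylinder_g3_s4():
    """Diametral cut, 3 mm gap + 4 mm step-off: analytic area 50*5 = 250."""
    spec = split_cylinder_spec(3.0, 4.0)
    volume, labels, meshes, truth = make_phantom(spec)
    ann = articular_annotations(spec, meshes)
    return spec, volume, labels, meshes, truth, ann


@pytest.fixture(scope="session")
def split_cylinder_g3_s0():
    """Diametral cut, pure 3 mm gap: analytic area 50*3 = 150."""
    spec = split_cylinder_spec(3.0, 0.0)
    volume, labels, meshes, truth = make_phantom(spec)
    ann = articular_annotations(spec, meshes)
    return spec, volume, labels, meshes, truth, ann


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
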