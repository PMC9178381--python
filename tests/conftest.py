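import numpy as np
import pytest
from hypothesis import settings

from archopose import synthetic

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def blueprint():
    """Default bilateral guineafowl-scale blueprint, zero noise."""
    return synthetic.LimbBlueprint(sides=("right", "left"), seed=11)


@pytest.fixture(scope="session")
def limb(blueprint):
    return synthetic.generate_limb(blueprint)


@pytest.fixture(scope="session")
def noisy_limb():
    """Mesh noise at 0.5% of the shortest segment (pes, 55 mm): 0.275 mm,
    so the noise stays within 0.5% of bone length for every bone."""
    bp = synthetic.LimbBlueprint(sides=("right", "left"), noise_sd=0.275,
                                 seed=11)
    return synthetic.generate_limb(bp)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


def random_rigid_transform(rng):
    from scipy.spatial.transform import Rotation

    from archopose.geometry import RigidTransform
    R = Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()
    t = rng.uniform(-50, 50, 3)
    return RigidTransform(R, t)
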