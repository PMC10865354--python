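import numpy as np
import pytest

from screenopt.dataset import generate_dataset
from screenopt.spheres import Sphere, SphereSet


@pytest.fixture
def small_dataset():
    """10 positives / 200 negatives, 2 planted clusters."""
    return generate_dataset(n_pos=10, ratio=20, n_clusters=2, seed=42)


@pytest.fixture
def sphere_set():
    rng = np.random.default_rng(7)
    spheres = tuple(
        Sphere(index=i + 1, x=float(c[0]), y=float(c[1]), z=float(c[2]), radius=0.7)
        for i, c in enumerate(rng.uniform(-5, 5, size=(10, 3)))
    )
    return SphereSet(spheres=spheres, provenance="fixture")
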