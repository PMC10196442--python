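import numpy as np
import pytest

from spineplane.geometry import Box3D, PlaneTriplet, VertebraAnnotation
from spineplane.phantom import PhantomSpec, generate, sample_spine_geometry


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One rendered 64-voxel phantom with full ground truth."""
    return generate(PhantomSpec(grid_size=64, seed=3))


@pytest.fixture(scope="session")
def spine_geometry():
    """Annotations only (no rendering), native field of view."""
    return sample_spine_geometry(PhantomSpec(seed=11))


def random_triplet(rng) -> PlaneTriplet:
    """Haar-ish random rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    return PlaneTriplet(q)


def random_annotation(rng, frame="world", fov=160.0) -> VertebraAnnotation:
    e = rng.uniform(8, 24)
    c = rng.uniform(0.2 * fov, 0.8 * fov, size=3)
    box = Box3D(c if frame == "world" else c / fov,
                np.full(3, e) if frame == "world" else np.full(3, e / fov),
                frame=frame)
    return VertebraAnnotation(box=box, planes=random_triplet(rng), class_id=int(rng.integers(1, 4)))
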