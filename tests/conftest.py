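import numpy as np
import pytest

from emtdig import (
    DigitizationSession,
    DigitizedPoint,
    fixture_head_truth,
    make_fixture,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def head35():
    return make_fixture("head35")


@pytest.fixture(scope="session")
def phantom5():
    return make_fixture("phantom_5")


def session_from_truth(fixture, offset=None) -> DigitizationSession:
    """Ideal head-frame session equal to the fixture ground truth."""
    truth = fixture_head_truth(fixture)
    off = np.zeros(3) if offset is None else np.asarray(offset, dtype=float)
    pts = tuple(
        DigitizedPoint(p.label, p.kind, truth[p.label] + off, frame="head")
        for p in fixture.points
    )
    return DigitizationSession(pts)


def random_rigid(rng):
    """Random proper rigid transform (uniform rotation, bounded shift)."""
    from scipy.spatial.transform import Rotation

    from emtdig import RigidTransform

    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-50, 50, size=3)
    return RigidTransform(R, t)
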