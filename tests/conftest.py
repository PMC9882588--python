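import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sasbead as sb

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=20,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sphere_cloud() -> sb.PointCloud:
    """Reference uniform sphere, R = 50 Å, N = 5000, fixed seed."""
    spec = sb.ModelSpec(subunits=(sb.Subunit("sphere", (50.0,)),), seed=7)
    return sb.build_model(spec)


@pytest.fixture(scope="session")
def sphere_pd(sphere_cloud) -> sb.PairDistribution:
    return sb.pair_histogram(sphere_cloud)


def make_cloud(positions, weights=None) -> sb.PointCloud:
    """Hand-built cloud for analytic test cases (unit point volume)."""
    positions = np.asarray(positions, dtype=float)
    if weights is None:
        weights = np.ones(len(positions))
    return sb.PointCloud(
        positions=positions,
        weights=np.asarray(weights, dtype=float),
        subunit_index=np.zeros(len(positions), dtype=np.intp),
        point_density=1.0,
        point_volume=1.0,
    )
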