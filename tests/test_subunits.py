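"""Geometry layer: volumes, membership, uniform sampling, model assembly."""

import math

import numpy as np
import pytest

import sasbead as sb
from sasbead.subunits import (
    SUBUNIT_KINDS,
    _bounding_half_extents,
    allocate_points,
    sample_points,
)

# one representative of every kind, with its independently computed volume
KIND_CASES = [
    (sb.Subunit("sphere", (50.0,)), 4 / 3 * math.pi * 50**3),
    (sb.Subunit("ellipsoid_triaxial", (50.0, 50.0, 100.0)), 4 / 3 * math.pi * 50 * 50 * 100),
    (sb.Subunit("cylinder", (50.0, 400.0)), math.pi * 50**2 * 400),
    (sb.Subunit("disc", (50.0, 20.0)), math.pi * 50**2 * 20),
    (sb.Subunit("cube", (10.0,)), 1000.0),
    (sb.Subunit("cuboid", (10.0, 20.0, 30.0)), 6000.0),
    (sb.Subunit("sphere_hollow", (50.0, 40.0)), 4 / 3 * math.pi * (50**3 - 40**3)),
    (sb.Subunit("cube_hollow", (20.0, 10.0)), 20**3 - 10**3),
    (sb.Subunit("ring_cylindrical", (40.0, 20.0, 100.0)), math.pi * (40**2 - 20**2) * 100),
    (sb.Subunit("ring_discoidal", (40.0, 30.0, 10.0)), math.pi * (40**2 - 30**2) * 10),
]


@pytest.mark.parametrize("subunit, expected", KIND_CASES, ids=lambda c: getattr(c, "kind", None))
def test_volume_closed_forms(subunit, expected):
    assert sb.volume(subunit) == pytest.approx(expected, rel=1e-12)


def test_every_kind_has_a_case():
    assert {s.kind for s, _ in KIND_CASES} == set(SUBUNIT_KINDS)


@pytest.mark.parametrize(
    "kind, dims",
    [
        ("sphere_hollow", (50.0, 50.0)),  # inner must be < outer
        ("ring_cylindrical", (20.0, 40.0, 100.0)),
        ("sphere", (0.0,)),
        ("cylinder", (50.0, -1.0)),
        ("cylinder", (50.0,)),  # wrong arity
    ],
)
def test_invalid_dimensions_rejected(kind, dims):
    with pytest.raises(sb.InvalidParameterError):
        sb.Subunit(kind, dims)


def test_unknown_kind_rejected():
    with pytest.raises(sb.UnsupportedSubunitError):
        sb.Subunit("torus", (10.0, 2.0))


@pytest.mark.parametrize(
    "subunit, point, expected",
    [
        (sb.Subunit("sphere", (50.0,)), (0, 0, 49), True),
        (sb.Subunit("sphere", (50.0,)), (0, 0, 51), False),
        (sb.Subunit("sphere", (50.0,)), (0, 0, 50), True),  # boundary is inside
        (sb.Subunit("ring_cylindrical", (40.0, 20.0, 100.0)), (30, 0, 0), True),
        (sb.Subunit("ring_cylindrical", (40.0, 20.0, 100.0)), (10, 0, 0), False),
        (sb.Subunit("ring_cylindrical", (40.0, 20.0, 100.0)), (30, 0, 51), False),
        (sb.Subunit("cube", (10.0,), com=(100, 0, 0)), (104, 4, -4), True),
    ],
)
def test_contains_examples(subunit, point, expected):
    assert sb.contains(subunit, np.array(point, dtype=float)) is expected


@pytest.mark.parametrize("subunit", [s for s, _ in KIND_CASES], ids=lambda s: s.kind)
def test_monte_carlo_volume_oracle(subunit):
    """Hit fraction of uniform box samples reproduces volume/box-volume (5σ)."""
    rng = np.random.default_rng(11)
    half = _bounding_half_extents(subunit)
    n = 100_000
    pts = rng.uniform(-half, half, size=(n, 3)) + np.asarray(subunit.com)
    frac = sb.contains(subunit, pts).mean()
    p = sb.volume(subunit) / float(np.prod(2 * half))
    if p == 1.0:  # cube/cuboid fill their bounding box exactly
        assert frac == 1.0
    else:
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < 5 * sigma


def test_sampling_sphere_moments():
    """Uniform-ball moments: mean at origin, Rg = sqrt(3/5)·R within 1%."""
    rng = np.random.default_rng(5)
    pts = sample_points(sb.Subunit("sphere", (50.0,)), 100_000, rng)
    assert np.linalg.norm(pts.mean(axis=0)) < 1.0
    rg = np.sqrt((np.linalg.norm(pts - pts.mean(axis=0), axis=1) ** 2).mean())
    assert rg == pytest.approx(math.sqrt(3 / 5) * 50, rel=0.01)


def test_sampling_respects_com_and_bounds():
    rng = np.random.default_rng(5)
    pts = sample_points(sb.Subunit("cube", (10.0,), com=(100, 0, 0)), 10_000, rng)
    assert pts[:, 0].min() >= 95 and pts[:, 0].max() <= 105
    assert np.abs(pts[:, 1:]).max() <= 5


def test_sampling_cylinder_z_fraction():
    """Half the volume of a L=400 cylinder lies at |z| < 100."""
    rng = np.random.default_rng(5)
    n = 100_000
    pts = sample_points(sb.Subunit("cylinder", (50.0, 400.0)), n, rng)
    frac = (np.abs(pts[:, 2]) < 100).mean()
    assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / n)


def test_allocation_largest_remainder():
    # volumes 1:2 (second sphere has 2^(1/3) times the radius)
    v1 = sb.volume(sb.Subunit("sphere", (50.0,)))
    v2 = sb.volume(sb.Subunit("sphere", (50.0 * 2 ** (1 / 3),)))
    counts = allocate_points(np.array([v1, v2]), 3000)
    assert counts.sum() == 3000
    assert abs(counts[0] - 1000) <= 1 and abs(counts[1] - 2000) <= 1
    # exact ties broken by order
    assert list(allocate_points(np.array([1.0, 1.0]), 3)) == [2, 1]


def test_build_model_single_sphere_counts_and_weights():
    spec = sb.ModelSpec(subunits=(sb.Subunit("sphere", (50.0,)),), seed=0)
    cloud = sb.build_model(spec)
    assert len(cloud) == 5000
    assert np.all(cloud.weights == cloud.weights[0])
    assert cloud.point_volume == pytest.approx(sb.volume(spec.subunits[0]) / 5000)


def test_build_model_volume_proportional_density():
    """Per-subunit counts track volumes within largest-remainder rounding."""
    spec = sb.ModelSpec(
        subunits=(
            sb.Subunit("sphere", (50.0,), com=(-300, 0, 0)),
            sb.Subunit("sphere", (50.0 * 2 ** (1 / 3),), com=(300, 0, 0)),
        ),
        n_points_total=3000,
        seed=1,
    )
    counts = sb.build_model(spec).counts_per_subunit()
    assert abs(counts[0] - 1000) <= 1 and abs(counts[1] - 2000) <= 1


def test_overlap_exclusion_later_subunit_wins():
    """Shell points are removed from the region of a later-listed core."""
    shell = sb.Subunit("cylinder", (40.0, 400.0), contrast=1.0)
    core = sb.Subunit("cylinder", (20.0, 360.0), contrast=-1.0)
    spec = sb.ModelSpec(subunits=(shell, core), exclude_overlap=True, seed=3)
    cloud = sb.build_model(spec)
    shell_pts = cloud.positions[cloud.subunit_index == 0]
    assert not sb.contains(core, shell_pts).any()
    # the core keeps all its points
    assert cloud.counts_per_subunit()[1] == sb.build_model(
        sb.ModelSpec(subunits=(shell, core), exclude_overlap=False, seed=3)
    ).counts_per_subunit()[1]


def test_overlap_kept_when_not_excluding():
    """Without exclusion both subunits populate the overlap region."""
    shell = sb.Subunit("cylinder", (40.0, 400.0), contrast=1.0)
    core = sb.Subunit("cylinder", (20.0, 360.0), contrast=-1.0)
    spec = sb.ModelSpec(subunits=(shell, core), exclude_overlap=False, seed=3)
    cloud = sb.build_model(spec)
    assert len(cloud) == 5000
    shell_pts = cloud.positions[cloud.subunit_index == 0]
    assert sb.contains(core, shell_pts).any()


def test_build_model_deterministic():
    spec = sb.ModelSpec(
        subunits=(
            sb.Subunit("cylinder", (40.0, 400.0)),
            sb.Subunit("sphere", (30.0,), com=(0, 0, 230)),
        ),
        seed=42,
    )
    a, b = sb.build_model(spec), sb.build_model(spec)
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.weights, b.weights)
    assert np.array_equal(a.subunit_index, b.subunit_index)


def test_model_spec_validation():
    with pytest.raises(sb.InvalidParameterError):
        sb.ModelSpec(subunits=())
    with pytest.raises(sb.InvalidParameterError):
        sb.ModelSpec(subunits=(sb.Subunit("sphere", (50.0,)),), n_points_total=10)
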