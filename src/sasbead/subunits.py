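"""Geometric subunit catalogue and uniform-density point sampling.

A scattering particle is modelled as a collection of geometric subunits
(sphere, cylinder, cube, ...), each carrying an excess scattering length
density (contrast) and a center-of-mass displacement.  The particle is
discretised into N point scatterers ("beads") distributed uniformly over the
combined volume, with the point density constant across subunits, so that a
subunit receives a share of the points proportional to its volume.

All lengths are in Å, volumes in Å³, contrasts in arbitrary relative units
(they may be negative: e.g. a lipid core in water seen by X-rays).

Subunits are axis-aligned; cylinders, discs and rings have their symmetry
axis along z.  The only placement freedom is the center-of-mass shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyModelError, InvalidParameterError, UnsupportedSubunitError

__all__ = [
    "SUBUNIT_KINDS",
    "Subunit",
    "ModelSpec",
    "PointCloud",
    "volume",
    "contains",
    "sample_points",
    "allocate_points",
    "build_model",
]

# kind -> ordered dimension names, as documented to users
SUBUNIT_KINDS: dict[str, tuple[str, ...]] = {
    "sphere": ("R",),
    "ellipsoid_triaxial": ("a", "b", "c"),
    "cylinder": ("R", "L"),
    "disc": ("R", "L"),
    "cube": ("a",),
    "cuboid": ("a", "b", "c"),
    "sphere_hollow": ("R", "r"),
    "cube_hollow": ("a", "b"),
    "ring_cylindrical": ("R", "r", "L"),
    "ring_discoidal": ("R", "r", "L"),
}

# kinds whose second-to-last dims entry is an inner length that must be
# strictly smaller than the outer one
_HOLLOW_KINDS = {"sphere_hollow", "cube_hollow", "ring_cylindrical", "ring_discoidal"}

_MIN_VOLUME = 1e-6  # Å³; degenerate bodies below this are rejected


@dataclass(frozen=True)
class Subunit:
    """One geometric body: kind, dimensions (Å), contrast Δρ, center of mass.

    Parameters
    ----------
    kind:
        One of the keys of :data:`SUBUNIT_KINDS`.
    dims:
        Ordered positive lengths in Å.  Meaning depends on ``kind``:
        radius ``R``; semi-axes ``a, b, c``; radius+length ``R, L``;
        side ``a``; sides ``a, b, c``; outer+inner radius ``R, r``;
        outer radius, inner radius, length ``R, r, L``.
    contrast:
        Excess scattering length density Δρ (relative units, may be negative).
    com:
        Center-of-mass displacement (Å).
    """

    kind: str
    dims: tuple[float, ...]
    contrast: float = 1.0
    com: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in SUBUNIT_KINDS:
            raise UnsupportedSubunitError(
                f"unknown subunit kind {self.kind!r}; "
                f"supported: {', '.join(SUBUNIT_KINDS)}"
            )
        names = SUBUNIT_KINDS[self.kind]
        dims = tuple(float(d) for d in self.dims)
        if len(dims) != len(names):
            raise InvalidParameterError(
                f"{self.kind} takes {len(names)} dims {names}, got {len(dims)}"
            )
        if any(not math.isfinite(d) or d <= 0 for d in dims):
            raise InvalidParameterError(
                f"{self.kind} dims must be strictly positive, got {dims}"
            )
        if self.kind in _HOLLOW_KINDS and not dims[1] < dims[0]:
            raise InvalidParameterError(
                f"{self.kind}: inner dimension must be < outer, got {dims}"
            )
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "com", tuple(float(c) for c in self.com))
        object.__setattr__(self, "contrast", float(self.contrast))
        if len(self.com) != 3:
            raise InvalidParameterError("com must be a 3-vector")
        if volume(self) < _MIN_VOLUME:
            raise InvalidParameterError(
                f"{self.kind} with dims {dims} has volume < {_MIN_VOLUME} Å³"
            )

    @property
    def volume(self) -> float:  # noqa: A003 - mirrors the free function
        return volume(self)


def volume(subunit: Subunit) -> float:
    """Exact analytic volume of the body in Å³ (hollow kinds: outer − inner)."""
    d = subunit.dims
    kind = subunit.kind
    if kind == "sphere":
        return 4.0 / 3.0 * math.pi * d[0] ** 3
    if kind == "ellipsoid_triaxial":
        return 4.0 / 3.0 * math.pi * d[0] * d[1] * d[2]
    if kind in ("cylinder", "disc"):
        return math.pi * d[0] ** 2 * d[1]
    if kind == "cube":
        return d[0] ** 3
    if kind == "cuboid":
        return d[0] * d[1] * d[2]
    if kind == "sphere_hollow":
        return 4.0 / 3.0 * math.pi * (d[0] ** 3 - d[1] ** 3)
    if kind == "cube_hollow":
        return d[0] ** 3 - d[1] ** 3
    if kind in ("ring_cylindrical", "ring_discoidal"):
        return math.pi * (d[0] ** 2 - d[1] ** 2) * d[2]
    raise UnsupportedSubunitError(f"unknown subunit kind {kind!r}")


def _bounding_half_extents(subunit: Subunit) -> np.ndarray:
    """Half-extents of the axis-aligned bounding cuboid, body frame."""
    d = subunit.dims
    kind = subunit.kind
    if kind == "sphere" or kind == "sphere_hollow":
        return np.full(3, d[0])
    if kind == "ellipsoid_triaxial":
        return np.array(d, dtype=float)
    if kind in ("cylinder", "disc"):
        return np.array([d[0], d[0], d[1] / 2.0])
    if kind == "cube" or kind == "cube_hollow":
        return np.full(3, d[0] / 2.0)
    if kind == "cuboid":
        return np.array(d, dtype=float) / 2.0
    if kind in ("ring_cylindrical", "ring_discoidal"):
        return np.array([d[0], d[0], d[2] / 2.0])
    raise UnsupportedSubunitError(f"unknown subunit kind {kind!r}")


def contains(subunit: Subunit, points: np.ndarray) -> np.ndarray:
    """Boolean mask: which ``points`` (world frame, Å) lie inside the body.

    Boundary points count as inside.  Accepts a single 3-vector or an (n, 3)
    array; returns a scalar bool or an (n,) mask accordingly.
    """
    pts = np.asarray(points, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts) - np.asarray(subunit.com)
    d = subunit.dims
    kind = subunit.kind
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    if kind == "sphere":
        inside = x * x + y * y + z * z <= d[0] ** 2
    elif kind == "ellipsoid_triaxial":
        inside = (x / d[0]) ** 2 + (y / d[1]) ** 2 + (z / d[2]) ** 2 <= 1.0
    elif kind in ("cylinder", "disc"):
        inside = (x * x + y * y <= d[0] ** 2) & (np.abs(z) <= d[1] / 2.0)
    elif kind == "cube":
        inside = np.max(np.abs(pts), axis=1) <= d[0] / 2.0
    elif kind == "cuboid":
        half = np.asarray(d) / 2.0
        inside = np.all(np.abs(pts) <= half, axis=1)
    elif kind == "sphere_hollow":
        r2 = x * x + y * y + z * z
        inside = (r2 <= d[0] ** 2) & (r2 >= d[1] ** 2)
    elif kind == "cube_hollow":
        m = np.max(np.abs(pts), axis=1)
        inside = (m <= d[0] / 2.0) & (m >= d[1] / 2.0)
    elif kind in ("ring_cylindrical", "ring_discoidal"):
        rho2 = x * x + y * y
        inside = (
            (rho2 <= d[0] ** 2) & (rho2 >= d[1] ** 2) & (np.abs(z) <= d[2] / 2.0)
        )
    else:
        raise UnsupportedSubunitError(f"unknown subunit kind {kind!r}")
    return bool(inside[0]) if scalar else inside


def sample_points(subunit: Subunit, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` points uniformly inside the body, shifted to its com.

    Rejection sampling from the axis-aligned bounding cuboid: uniform by
    construction and a single code path for every kind.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    half = _bounding_half_extents(subunit)
    box_volume = float(np.prod(2.0 * half))
    efficiency = volume(subunit) / box_volume
    out = np.empty((n, 3))
    got = 0
    # body-frame subunit for the inside test (com applied at the end)
    body = Subunit(subunit.kind, subunit.dims, subunit.contrast, (0.0, 0.0, 0.0))
    while got < n:
        need = n - got
        batch = int(need / max(efficiency, 1e-3) * 1.1) + 16
        cand = rng.uniform(-half, half, size=(batch, 3))
        keep = cand[contains(body, cand)]
        take = min(len(keep), need)
        out[got : got + take] = keep[:take]
        got += take
    return out + np.asarray(subunit.com)


@dataclass(frozen=True)
class ModelSpec:
    """A particle model: ordered subunits plus sampling options.

    ``exclude_overlap`` controls multi-subunit overlap regions: if True
    (default) points of an earlier subunit that fall inside any later subunit
    are deleted, so later subunits "carve" earlier ones; if False all points
    are kept and the effective contrast of an overlap region is the sum of
    the overlapping subunits' contrasts.
    """

    subunits: tuple[Subunit, ...]
    exclude_overlap: bool = True
    n_points_total: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        subs = tuple(self.subunits)
        if len(subs) < 1:
            raise InvalidParameterError("ModelSpec needs at least one subunit")
        if self.n_points_total < 100:
            raise InvalidParameterError("n_points_total must be >= 100")
        object.__setattr__(self, "subunits", subs)

    @property
    def total_volume(self) -> float:
        """Sum of subunit volumes (overlaps counted once per subunit)."""
        return sum(volume(s) for s in self.subunits)


@dataclass(frozen=True)
class PointCloud:
    """Sampled scatterer positions with per-point excess scattering lengths.

    ``weights`` holds Δb_i = Δρ(owning subunit) · V_point, where V_point is
    the effective per-point volume, constant across the whole model (constant
    point density).  ``subunit_index`` records provenance.
    """

    positions: np.ndarray  # (N, 3) Å
    weights: np.ndarray  # (N,) Δb
    subunit_index: np.ndarray  # (N,) int
    point_density: float  # points / Å³
    point_volume: float = field(default=0.0)  # Å³ per point

    def __post_init__(self) -> None:
        pos = np.ascontiguousarray(self.positions, dtype=float)
        w = np.ascontiguousarray(self.weights, dtype=float)
        idx = np.ascontiguousarray(self.subunit_index, dtype=np.intp)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise InvalidParameterError("positions must be (N, 3)")
        if len(w) != len(pos) or len(idx) != len(pos):
            raise InvalidParameterError("weights/subunit_index length mismatch")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "subunit_index", idx)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_points(self) -> int:
        return len(self.positions)

    def counts_per_subunit(self) -> np.ndarray:
        return np.bincount(self.subunit_index)


def allocate_points(volumes: np.ndarray, total: int) -> np.ndarray:
    """Split ``total`` points across subunits ∝ volume (largest remainder).

    Ties in the remainders are broken by subunit order.
    """
    v = np.asarray(volumes, dtype=float)
    quota = total * v / v.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = total - counts.sum()
    # stable sort => earlier subunits win remainder ties
    order = np.argsort(-remainder, kind="stable")
    counts[order[:short]] += 1
    return counts


def build_model(spec: ModelSpec, rng: np.random.Generator | None = None) -> PointCloud:
    """Sample the full multi-subunit model as a constant-density point cloud.

    Points are allocated across subunits proportional to volume, sampled
    uniformly per subunit, then overlap handling is applied (see
    :class:`ModelSpec`).  Deleted points are not replaced, so the density
    stays constant and the total may drop below ``n_points_total``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    vols = np.array([volume(s) for s in spec.subunits])
    counts = allocate_points(vols, spec.n_points_total)
    v_point = vols.sum() / spec.n_points_total
    positions = []
    weights = []
    index = []
    for i, (sub, n_i) in enumerate(zip(spec.subunits, counts)):
        if n_i == 0:
            continue
        pts = sample_points(sub, int(n_i), rng)
        positions.append(pts)
        weights.append(np.full(n_i, sub.contrast * v_point))
        index.append(np.full(n_i, i, dtype=np.intp))
    pos = np.concatenate(positions)
    w = np.concatenate(weights)
    idx = np.concatenate(index)
    if spec.exclude_overlap and len(spec.subunits) > 1:
        keep = np.ones(len(pos), dtype=bool)
        for j, sub_j in enumerate(spec.subunits):
            earlier = idx < j  # later subunits take precedence
            if not earlier.any():
                continue
            sel = np.flatnonzero(earlier & keep)
            if len(sel):
                keep[sel[contains(sub_j, pos[sel])]] = False
        pos, w, idx = pos[keep], w[keep], idx[keep]
    if len(pos) == 0:
        raise EmptyModelError(
            "overlap exclusion removed every point; model is fully engulfed"
        )
    return PointCloud(pos, w, idx, 1.0 / v_point, v_point)
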