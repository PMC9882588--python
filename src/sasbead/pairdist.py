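"""Pair-distance distributions and the histogram-based Debye transform.

The scattering intensity of a dilute solution of identical particles, each
represented by N point scatterers with excess scattering lengths Δb_j, is the
Debye double sum

    I(q) = n · Σ_jk Δb_j Δb_k sin(q r_jk)/(q r_jk).

Binning the pairs by distance reduces this to a single sum over bins,

    I(q) = n · Σ_i p_i sin(q r_i)/(q r_i),   r_i = (i − ½)·dr,

where p_i is the number of pairs in bin i weighted by the product of their
excess scattering lengths.  Self-terms (j = k) are excluded, and the curve is
normalized by the forward scattering so that P(0) = 1 — the number density n
and the per-point effective volumes drop out.

The binned p_i is also the discrete estimate of the pair distance
distribution p(r), the real-space fingerprint of the particle shape, from
which D_max and the radius of gyration

    R_g² = ½ ∫ r² p(r) dr / ∫ p(r) dr

are derived.

Polydispersity (sample heterogeneity) is modelled as a Gaussian distribution
of a global size-scale factor s: all pair distances are scaled by s and each
scaled histogram is weighted by the Gaussian times the squared relative
volume v² = s⁶ (scattering ∝ volume²; exact for spheres).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .errors import (
    GridError,
    InsufficientPointsError,
    InvalidParameterError,
    ZeroForwardScatteringError,
)
from .subunits import PointCloud

__all__ = [
    "PairDistribution",
    "ScatteringCurve",
    "iter_pair_chunks",
    "pair_arrays",
    "max_pair_distance",
    "default_n_bins",
    "pair_histogram",
    "polydisperse_histogram",
    "intensity_from_histogram",
    "debye_intensity",
]

_EDGE_EPS = 1e-9  # widens the last bin so the largest distance falls inside
_CONTRAST_TOL = 1e-10  # |ΣΔb| below this fraction of Σ|Δb| is "contrast matched"


@dataclass(frozen=True)
class PairDistribution:
    """Contrast-weighted pair-distance histogram with derived scalars.

    ``r`` holds bin centers r_i = (i − ½)·dr; ``p`` the weighted pair counts
    (arbitrary units, may be negative for multi-contrast models).  ``dmax``
    is the exact largest pair distance (not a bin edge), ``rg`` the radius of
    gyration from the discrete second moment of the histogram.
    """

    r: np.ndarray
    p: np.ndarray
    dr: float
    dmax: float
    rg: float
    n_bins: int
    total_contrast: float = 0.0  # Σ Δb over the cloud
    abs_contrast: float = 0.0  # Σ |Δb|
    sum_p: float = field(default=0.0)  # Σ p_i (self-terms excluded)

    def export_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(r, p) as written to file: leading (0, 0) row, max |p| = 1."""
        peak = np.max(np.abs(self.p))
        p = self.p / peak if peak > 0 else self.p
        return (
            np.concatenate([[0.0], self.r]),
            np.concatenate([[0.0], p]),
        )


@dataclass(frozen=True)
class ScatteringCurve:
    """q grid with form factor P(q), effective structure factor and total I.

    ``P`` is normalized so P(0) = 1; ``S_eff`` is 1 everywhere when no
    structure factor is applied; ``I`` is the total intensity (P · S_eff,
    with interface roughness folded in if requested).
    """

    q: np.ndarray
    P: np.ndarray
    S_eff: np.ndarray
    I: np.ndarray  # noqa: E741 - field name matches the physics

    @classmethod
    def from_form_factor(cls, q: np.ndarray, P: np.ndarray) -> "ScatteringCurve":
        ones = np.ones_like(P)
        return cls(q=q, P=P, S_eff=ones, I=P.copy())

    def replace(self, **kw) -> "ScatteringCurve":
        return replace(self, **kw)


def iter_pair_chunks(cloud: PointCloud, chunk: int = 1024):
    """Yield (distances, weight products) over all j<k pairs in chunks.

    Streaming keeps peak memory at O(chunk·N) instead of O(N²), so large
    clouds can be histogrammed without materializing all N(N−1)/2 pairs.
    """
    if len(cloud) < 2:
        raise InsufficientPointsError("need at least 2 points for pair distances")
    pos, w = cloud.positions, cloud.weights
    n = len(pos)
    for a in range(0, n, chunk):
        b = min(a + chunk, n)
        blk = pos[a:b]
        if b - a >= 2:
            iu = np.triu_indices(b - a, k=1)
            yield pdist(blk), (w[a:b, None] * w[None, a:b])[iu]
        if b < n:
            yield (
                cdist(blk, pos[b:]).ravel(),
                (w[a:b, None] * w[None, b:]).ravel(),
            )


def pair_arrays(
    cloud: PointCloud, chunk: int = 1024
) -> tuple[np.ndarray, np.ndarray]:
    """All j<k pair distances and weight products Δb_j·Δb_k as flat arrays.

    Materializes N(N−1)/2 entries — convenient for small clouds; large
    clouds should use :func:`iter_pair_chunks`.
    """
    parts = list(iter_pair_chunks(cloud, chunk))
    return (
        np.concatenate([p[0] for p in parts]),
        np.concatenate([p[1] for p in parts]),
    )


def max_pair_distance(cloud: PointCloud, chunk: int = 1024) -> float:
    """Exact largest pair distance D_max (streaming)."""
    return max(float(d.max()) for d, _ in iter_pair_chunks(cloud, chunk))


def default_n_bins(n_points: int) -> int:
    """√(number of pairs), clipped to [50, 1000]."""
    n_pairs = n_points * (n_points - 1) // 2
    return int(min(max(np.ceil(np.sqrt(n_pairs)), 50), 1000))


def _finalize_distribution(
    p: np.ndarray,
    dr: float,
    exact_dmax: float,
    cloud: PointCloud,
) -> PairDistribution:
    n_bins = len(p)
    r = (np.arange(n_bins) + 0.5) * dr
    sum_p = float(p.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rg2 = 0.5 * float((r * r * p).sum()) / sum_p if sum_p != 0 else np.nan
    rg = float(np.sqrt(rg2)) if rg2 >= 0 else float("nan")
    return PairDistribution(
        r=r,
        p=p,
        dr=dr,
        dmax=exact_dmax,
        rg=rg,
        n_bins=n_bins,
        total_contrast=float(cloud.weights.sum()),
        abs_contrast=float(np.abs(cloud.weights).sum()),
        sum_p=sum_p,
    )


def pair_histogram(cloud: PointCloud, n_bins: int | None = None) -> PairDistribution:
    """Bin all j<k pair distances, weighted by Δb_j·Δb_k.

    The bin width is chosen as dr = D_max·(1+ε)/n_bins so the largest
    observed distance falls inside the last bin.  Self-pairs are excluded.
    Two streaming passes over the pairs (max, then accumulate) keep memory
    independent of N².
    """
    if n_bins is None:
        n_bins = default_n_bins(len(cloud))
    if n_bins < 1:
        raise InvalidParameterError("n_bins must be >= 1")
    dmax = max_pair_distance(cloud)
    if dmax <= 0:
        raise InsufficientPointsError("all points coincide; no pair distances")
    dr = dmax * (1.0 + _EDGE_EPS) / n_bins
    edges = np.arange(n_bins + 1) * dr
    p = np.zeros(n_bins)
    for d, w in iter_pair_chunks(cloud):
        p += np.histogram(d, bins=edges, weights=w)[0]
    return _finalize_distribution(p, dr, dmax, cloud)


def polydisperse_histogram(
    cloud: PointCloud,
    sigma_poly: float,
    n_bins: int | None = None,
    n_nodes: int = 15,
) -> PairDistribution:
    """Pair histogram averaged over a Gaussian size-scale distribution.

    The scale s multiplies every pair distance; histograms for the node
    scales s_m (midpoint rule over [1−3σ, 1+3σ]) are accumulated on a common
    grid spanning D_max·(1+3σ) with weights

        w_m = exp(−½ ((s_m − 1)/σ)²) · s_m⁶,

    the s⁶ factor being the squared relative volume v = s³.  R_g and D_max
    are recomputed from the polydisperse histogram.
    """
    if not 0 < sigma_poly < 0.33:
        raise InvalidParameterError(
            "sigma_poly must be in (0, 0.33); use pair_histogram for a "
            "monodisperse sample"
        )
    if n_nodes < 1:
        raise InvalidParameterError("n_nodes must be >= 1")
    if n_bins is None:
        n_bins = default_n_bins(len(cloud))
    dmax_mono = max_pair_distance(cloud)
    grid_dmax = dmax_mono * (1.0 + 3.0 * sigma_poly)
    h = 6.0 * sigma_poly / n_nodes
    s_nodes = 1.0 - 3.0 * sigma_poly + (np.arange(n_nodes) + 0.5) * h
    gauss = np.exp(-0.5 * ((s_nodes - 1.0) / sigma_poly) ** 2) * s_nodes**6
    dr = grid_dmax * (1.0 + _EDGE_EPS) / n_bins
    edges = np.arange(n_bins + 1) * dr
    p = np.zeros(n_bins)
    for d, w in iter_pair_chunks(cloud):
        for s, g in zip(s_nodes, gauss):
            p += g * np.histogram(d * s, bins=edges, weights=w)[0]
    return _finalize_distribution(
        p, dr, dmax_mono * float(s_nodes.max()), cloud
    )


def _check_forward_scattering(total_contrast: float, abs_contrast: float) -> None:
    if abs(total_contrast) <= _CONTRAST_TOL * abs_contrast:
        raise ZeroForwardScatteringError(
            "net excess scattering length Σ Δb ≈ 0 (contrast-matched model); "
            "the normalized form factor P(q) = I(q)/I(0) is undefined"
        )


def intensity_from_histogram(
    pd: PairDistribution, q: np.ndarray
) -> ScatteringCurve:
    """Debye transform of a pair-distance histogram, normalized to P(0)=1.

    P(q) = Σ_i p_i sinc(q r_i) / Σ_i p_i, with sinc(0) = 1.  sin(x)/x is
    evaluated once per (q, bin), never per pair.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise GridError("q grid must be non-negative")
    _check_forward_scattering(pd.total_contrast, pd.abs_contrast)
    if pd.sum_p == 0:
        raise ZeroForwardScatteringError("histogram sums to zero; P(q) undefined")
    # np.sinc(x) = sin(πx)/(πx), with the removable singularity handled
    sinc = np.sinc(q[:, None] * pd.r[None, :] / np.pi)
    P = sinc @ pd.p / pd.sum_p
    return ScatteringCurve.from_form_factor(q, P)


def debye_intensity(cloud: PointCloud, q: np.ndarray) -> ScatteringCurve:
    """Direct Debye double sum over all pairs (no binning), P(0)=1.

    Exact but O(N²) per q point — intended for small clouds and as the
    independent cross-check of the histogram route.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise GridError("q grid must be non-negative")
    d, w = pair_arrays(cloud)
    total = float(cloud.weights.sum())
    _check_forward_scattering(total, float(np.abs(cloud.weights).sum()))
    sum_w = float(w.sum())
    if sum_w == 0:
        raise ZeroForwardScatteringError("pair weights sum to zero")
    P = np.empty_like(q)
    for i, qi in enumerate(q):
        P[i] = float(np.sinc(qi * d / np.pi) @ w) / sum_w
    return ScatteringCurve.from_form_factor(q, P)
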