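"""Simulated experimental noise for calculated scattering curves.

The error model imitates the q-dependent counting statistics of typical
synchrotron SAXS data:

    σ(q) = s · sqrt( (I(q) + c) / (k·q) ),   k = 5·10⁶,  c = 0.05 Å,

where s is a user scale (doubling s doubles σ everywhere).  Simulated
intensities are drawn independently per grid point from
Normal(I(q), σ(q)).  Negative draws are kept — buffer-subtracted SAXS data
legitimately go negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridError, InvalidParameterError
from .pairdist import ScatteringCurve

__all__ = ["NOISE_K", "NOISE_C", "SimulatedData", "error_model", "simulate_data"]

NOISE_K = 5e6  # flux-like constant, chosen to imitate synchrotron SAXS noise
NOISE_C = 0.05  # Å; floor added to I(q) in the error model


@dataclass(frozen=True)
class SimulatedData:
    """Noisy simulated measurement: q, I_sim and the error estimate σ(q)."""

    q: np.ndarray
    i_sim: np.ndarray
    sigma: np.ndarray
    noise_scale: float = 1.0
    seed: int = 0


def error_model(
    q: np.ndarray, I: np.ndarray, noise_scale: float = 1.0
) -> np.ndarray:
    """Standard error σ(q) = s·√((I + 0.05)/(5·10⁶·q)).

    Diverges at q = 0, so the grid must be strictly positive there; drop
    q = 0 before calling (``simulate_data`` does this automatically).
    """
    q = np.asarray(q, dtype=float)
    I = np.asarray(I, dtype=float)
    if noise_scale < 0:
        raise InvalidParameterError("noise_scale must be >= 0")
    if np.any(q <= 0):
        raise GridError("noise grid must be strictly positive (σ diverges at q=0)")
    return noise_scale * np.sqrt((I + NOISE_C) / (NOISE_K * q))


def simulate_data(
    curve: ScatteringCurve,
    noise_scale: float = 1.0,
    seed: int = 0,
) -> SimulatedData:
    """Draw I_sim(q) ~ Normal(I(q), σ(q)) independently per grid point.

    Grid points with q = 0 are dropped (the error model diverges there).
    Reproducible under ``seed``.
    """
    mask = curve.q > 0
    q = curve.q[mask]
    I = curve.I[mask]
    sigma = error_model(q, I, noise_scale)
    rng = np.random.default_rng(seed)
    i_sim = I + sigma * rng.standard_normal(len(q)) if noise_scale > 0 else I.copy()
    return SimulatedData(
        q=q, i_sim=i_sim, sigma=sigma, noise_scale=noise_scale, seed=seed
    )
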