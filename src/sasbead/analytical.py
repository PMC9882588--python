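"""Closed-form form factors and a χ² fitting harness.

These analytic models serve two roles: as independent oracles that the
Monte-Carlo bead simulation must reproduce, and as fit models for simulated
data, closing the loop of a virtual scattering experiment (simulate noisy
data from a bead model, refine the analytic model, recover the input
parameters).

All form factors are orientationally averaged and normalized so P(0) = 1.
Orientational averages use fixed-order Gauss–Legendre quadrature on
cos α ∈ [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import j1

from .errors import FitFailureError, InvalidParameterError, ZeroForwardScatteringError
from .noise import SimulatedData

__all__ = [
    "sphere_ff",
    "cylinder_ff",
    "ellipsoid_rev_ff",
    "core_shell_cylinder_ff",
    "AnalyticModel",
    "FitResult",
    "fit",
]

_DEFAULT_QUAD = 128


def _gauss_legendre_cos(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and weights for ∫₀¹ f(u) du, u = cos α; weights sum to 1."""
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def _sphere_amplitude(x: np.ndarray) -> np.ndarray:
    """Normalized sphere amplitude 3(sin x − x cos x)/x³, A(0) = 1."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-3
    xs = np.where(small, 1.0, x)
    amp = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    series = 1.0 - x * x / 10.0 + x**4 / 280.0
    return np.where(small, series, amp)


def sphere_ff(q: np.ndarray, R: float) -> np.ndarray:
    """Form factor of a homogeneous sphere of radius R (Å), P(0) = 1."""
    if R <= 0:
        raise InvalidParameterError("R must be > 0")
    return _sphere_amplitude(np.asarray(q, dtype=float) * R) ** 2


def _cylinder_amplitude(
    q: np.ndarray, R: float, L: float, u: np.ndarray
) -> np.ndarray:
    """Normalized cylinder amplitude on the (q, cos α) grid; A(0, ·) = 1."""
    q = q[:, None]
    sin_a = np.sqrt(1.0 - u * u)[None, :]
    u = u[None, :]
    xr = q * R * sin_a
    xl = 0.5 * q * L * u
    small = np.abs(xr) < 1e-8
    xr_safe = np.where(small, 1.0, xr)
    radial = np.where(small, 1.0, 2.0 * j1(xr_safe) / xr_safe)
    return radial * np.sinc(xl / np.pi)


def cylinder_ff(
    q: np.ndarray, R: float, L: float, n_quad: int = _DEFAULT_QUAD
) -> np.ndarray:
    """Orientationally averaged form factor of a cylinder (radius R, length L)."""
    if R <= 0 or L <= 0:
        raise InvalidParameterError("R and L must be > 0")
    q = np.asarray(q, dtype=float)
    u, w = _gauss_legendre_cos(n_quad)
    amp = _cylinder_amplitude(q, R, L, u)
    return (amp * amp) @ w


def ellipsoid_rev_ff(
    q: np.ndarray, r_eq: float, r_pol: float, n_quad: int = _DEFAULT_QUAD
) -> np.ndarray:
    """Form factor of an ellipsoid of revolution (semi-axes r_eq, r_eq, r_pol)."""
    if r_eq <= 0 or r_pol <= 0:
        raise InvalidParameterError("semi-axes must be > 0")
    q = np.asarray(q, dtype=float)
    u, w = _gauss_legendre_cos(n_quad)
    r_eff = np.sqrt(r_eq**2 * (1.0 - u**2) + r_pol**2 * u**2)
    amp = _sphere_amplitude(q[:, None] * r_eff[None, :])
    return (amp * amp) @ w


def core_shell_cylinder_ff(
    q: np.ndarray,
    r_core: float,
    l_core: float,
    t_shell: float,
    rho_core: float,
    rho_shell: float,
    n_quad: int = _DEFAULT_QUAD,
) -> np.ndarray:
    """Core–shell cylinder form factor, shell of uniform thickness t_shell.

    The amplitude superposes two coaxial cylinders: the core of radius
    r_core and length l_core at contrast (ρ_core − ρ_shell), plus the outer
    envelope (r_core + t_shell, l_core + 2·t_shell) at ρ_shell, each
    weighted by its volume; P(q) is the orientational average of the squared
    amplitude normalized by the forward amplitude.
    """
    if min(r_core, l_core, t_shell) <= 0:
        raise InvalidParameterError("all lengths must be > 0")
    q = np.asarray(q, dtype=float)
    v_core = np.pi * r_core**2 * l_core
    r_out = r_core + t_shell
    l_out = l_core + 2.0 * t_shell
    v_out = np.pi * r_out**2 * l_out
    a0 = (rho_core - rho_shell) * v_core + rho_shell * v_out
    if abs(a0) <= 1e-12 * (abs(rho_core - rho_shell) * v_core + abs(rho_shell) * v_out):
        raise ZeroForwardScatteringError(
            "net forward amplitude of the core-shell cylinder is zero"
        )
    u, w = _gauss_legendre_cos(n_quad)
    amp = (rho_core - rho_shell) * v_core * _cylinder_amplitude(q, r_core, l_core, u)
    amp = amp + rho_shell * v_out * _cylinder_amplitude(q, r_out, l_out, u)
    return (amp * amp) @ w / a0**2


# ---------------------------------------------------------------------------
# fitting harness

# kind -> (callable(q, **shape_params), ordered shape parameter names)
_MODEL_REGISTRY: dict[str, tuple] = {
    "sphere": (sphere_ff, ("R",)),
    "cylinder": (cylinder_ff, ("R", "L")),
    "ellipsoid_rev": (ellipsoid_rev_ff, ("r_eq", "r_pol")),
    "core_shell_cylinder": (
        core_shell_cylinder_ff,
        ("r_core", "l_core", "t_shell", "rho_core", "rho_shell"),
    ),
}

# parameters allowed to be negative (contrasts); everything else is a length
_UNBOUNDED = {"rho_core", "rho_shell"}


@dataclass(frozen=True)
class AnalyticModel:
    """An analytic form factor with current parameter values and a free mask.

    ``params`` must contain every shape parameter of ``kind`` plus "scale"
    (overall intensity multiplier, since simulated data are normalized to
    I(0) ≈ 1 only up to binning and structure-factor effects).  ``free``
    lists the parameter names refined by :func:`fit`; the rest are fixed.
    """

    kind: str
    params: dict[str, float]
    free: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.kind not in _MODEL_REGISTRY:
            raise InvalidParameterError(
                f"unknown analytic model {self.kind!r}; "
                f"supported: {', '.join(_MODEL_REGISTRY)}"
            )
        _, names = _MODEL_REGISTRY[self.kind]
        required = set(names) | {"scale"}
        missing = required - set(self.params)
        if missing:
            raise InvalidParameterError(f"missing parameters: {sorted(missing)}")
        unknown = set(self.free) - required
        if unknown:
            raise InvalidParameterError(f"unknown free parameters: {sorted(unknown)}")
        object.__setattr__(self, "params", dict(self.params))
        object.__setattr__(self, "free", tuple(self.free))

    def evaluate(self, q: np.ndarray, params: dict[str, float] | None = None):
        """scale · P(q) with the given (or stored) parameter values."""
        p = dict(self.params)
        if params:
            p.update(params)
        func, names = _MODEL_REGISTRY[self.kind]
        return p["scale"] * func(np.asarray(q, dtype=float), *(p[n] for n in names))


@dataclass(frozen=True)
class FitResult:
    """Refined parameters, their standard deviations and reduced χ²."""

    params_hat: dict[str, float]
    params_sd: dict[str, float]
    chi2_red: float
    n_points: int
    n_free: int
    cost: float

    def __str__(self) -> str:
        lines = [f"chi2_red = {self.chi2_red:.4g}  (n={self.n_points}, free={self.n_free})"]
        for name, sd in self.params_sd.items():
            lines.append(f"  {name:>10s} = {self.params_hat[name]:.6g} +/- {sd:.2g}")
        return "\n".join(lines)


def fit(
    data: SimulatedData,
    model: AnalyticModel,
    init: dict[str, float] | None = None,
    n_starts: int = 3,
    jitter: float = 0.05,
) -> FitResult:
    """Weighted least-squares refinement of an analytic model against data.

    Minimizes χ² = Σ ((I_sim − scale·P_model)/σ)² over the model's free
    parameters (bounded trust-region least squares, numerical Jacobian).
    To guard against parameter correlation (e.g. core/shell contrast vs
    scale) the fit is multi-started from ``n_starts`` relatively jittered
    copies of the initial guess and the lowest-χ² solution is kept.
    Standard deviations come from the covariance (JᵀJ)⁻¹·χ²_red at the
    optimum.
    """
    if np.any(data.sigma <= 0):
        raise InvalidParameterError("data.sigma must be strictly positive for fitting")
    if not model.free:
        raise InvalidParameterError("model has no free parameters")
    p0_full = dict(model.params)
    if init:
        p0_full.update(init)
    names = list(model.free)
    x0 = np.array([p0_full[n] for n in names], dtype=float)
    lo = np.array([-np.inf if n in _UNBOUNDED else 1e-6 for n in names])
    hi = np.full(len(names), np.inf)

    def residuals(x: np.ndarray) -> np.ndarray:
        trial = dict(zip(names, x))
        return (data.i_sim - model.evaluate(data.q, trial)) / data.sigma

    rng = np.random.default_rng(1234)  # jitter only; fit itself is deterministic
    best = None
    for start in range(n_starts):
        if start == 0:
            x_start = x0
        else:
            x_start = x0 * (1.0 + jitter * rng.standard_normal(len(x0)))
            x_start = np.clip(x_start, lo, hi)
        try:
            res = least_squares(
                residuals, x_start, bounds=(lo, hi), method="trf", x_scale="jac"
            )
        except Exception:  # singular start; try the next one
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitFailureError("least-squares fit failed to converge from any start")

    n_pts, n_free = len(data.q), len(names)
    dof = max(n_pts - n_free, 1)
    chi2_red = 2.0 * best.cost / dof
    jtj = best.jac.T @ best.jac
    cov = np.linalg.pinv(jtj) * chi2_red
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return FitResult(
        params_hat=dict(zip(names, (float(v) for v in best.x))),
        params_sd=dict(zip(names, (float(v) for v in sd))),
        chi2_red=float(chi2_red),
        n_points=n_pts,
        n_free=n_free,
        cost=float(best.cost),
    )
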