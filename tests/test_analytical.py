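"""Closed-form form factors and the least-squares fitting harness."""

import numpy as np
import pytest

import sasbead as sb
from sasbead.analytical import AnalyticModel, fit
from sasbead.noise import SimulatedData, error_model


def test_sphere_ff_limits_and_first_zero():
    q = np.array([0.0, 1e-5])
    np.testing.assert_allclose(sb.sphere_ff(q, 50.0), 1.0, atol=1e-9)
    # first zero of the amplitude at x = qR ≈ 4.4934 (root of tan x = x)
    q_zero = 4.493409 / 50.0
    assert sb.sphere_ff(np.array([q_zero]), 50.0)[0] < 1e-10


def test_sphere_ff_guinier_regime():
    """P ≈ exp(−q²Rg²/3) with Rg² = (3/5)R² within 1% for qR < 1."""
    R = 50.0
    q = np.linspace(1e-4, 1.0 / R, 30)
    P = sb.sphere_ff(q, R)
    guinier = np.exp(-(q**2) * (3 / 5) * R**2 / 3)
    np.testing.assert_allclose(P, guinier, rtol=0.01)


def test_cylinder_ff_guinier_rg():
    """Low-q slope returns Rg² = R²/2 + L²/12 (R=50, L=400 → 120.76 Å)."""
    R, L = 50.0, 400.0
    rg_true = np.sqrt(R**2 / 2 + L**2 / 12)
    q = np.linspace(1e-4, 0.4 / rg_true, 40)
    P = sb.cylinder_ff(q, R, L)
    slope = np.polyfit(q**2, np.log(P), 1)[0]
    rg_fit = np.sqrt(-3 * slope)
    assert rg_fit == pytest.approx(rg_true, rel=0.01)


def test_cylinder_ff_bounds():
    q = np.linspace(0.0, 0.5, 200)
    P = sb.cylinder_ff(q, 50.0, 400.0)
    assert P[0] == pytest.approx(1.0, abs=1e-12)
    assert np.all((P >= 0) & (P <= 1))


def test_ellipsoid_reduces_to_sphere():
    q = np.linspace(0.0, 0.2, 50)
    np.testing.assert_allclose(
        sb.ellipsoid_rev_ff(q, 50.0, 50.0), sb.sphere_ff(q, 50.0), atol=1e-10
    )


def test_core_shell_homogeneous_limit():
    """Equal contrasts collapse to the bare outer cylinder."""
    q = np.linspace(0.0, 0.3, 80)
    P = sb.core_shell_cylinder_ff(q, 20.0, 360.0, 20.0, 1.0, 1.0)
    np.testing.assert_allclose(P, sb.cylinder_ff(q, 40.0, 400.0), atol=1e-12)


def test_core_shell_vanishing_shell_limit():
    q = np.linspace(0.0, 0.3, 80)
    P = sb.core_shell_cylinder_ff(q, 20.0, 360.0, 1e-5, -1.0, 1.0)
    np.testing.assert_allclose(P, sb.cylinder_ff(q, 20.0, 360.0), rtol=1e-3)


def test_core_shell_zero_forward_amplitude_rejected():
    # choose rho_core so (rho_c - rho_s)·V_core + rho_s·V_out = 0
    v_core = np.pi * 20.0**2 * 360.0
    v_out = np.pi * 40.0**2 * 400.0
    rho_core = 1.0 - v_out / v_core
    with pytest.raises(sb.ZeroForwardScatteringError):
        sb.core_shell_cylinder_ff(
            np.linspace(0, 0.1, 5), 20.0, 360.0, 20.0, rho_core, 1.0
        )


def test_quadrature_order_converged():
    """128-point Gauss–Legendre matches a 1024-point reference to 1e-8."""
    q = np.linspace(0.0, 0.5, 200)
    P128 = sb.core_shell_cylinder_ff(q, 20.0, 360.0, 20.0, -1.0, 1.0, n_quad=128)
    P1024 = sb.core_shell_cylinder_ff(q, 20.0, 360.0, 20.0, -1.0, 1.0, n_quad=1024)
    np.testing.assert_allclose(P128, P1024, atol=1e-8, rtol=1e-8)


def test_all_form_factors_normalized():
    q0 = np.array([0.0])
    assert sb.sphere_ff(q0, 30.0)[0] == pytest.approx(1.0, abs=1e-12)
    assert sb.cylinder_ff(q0, 30.0, 100.0)[0] == pytest.approx(1.0, abs=1e-12)
    assert sb.ellipsoid_rev_ff(q0, 30.0, 60.0)[0] == pytest.approx(1.0, abs=1e-12)
    assert sb.core_shell_cylinder_ff(q0, 20.0, 360.0, 20.0, -1.0, 1.0)[0] == (
        pytest.approx(1.0, abs=1e-12)
    )


@pytest.mark.parametrize(
    "subunit, oracle, rg",
    [
        (sb.Subunit("sphere", (50.0,)), lambda q: sb.sphere_ff(q, 50.0),
         np.sqrt(3 / 5) * 50.0),
        (sb.Subunit("cylinder", (50.0, 400.0)),
         lambda q: sb.cylinder_ff(q, 50.0, 400.0),
         np.sqrt(50.0**2 / 2 + 400.0**2 / 12)),
    ],
    ids=["sphere", "cylinder"],
)
def test_bead_model_matches_oracles_in_guinier_region(subunit, oracle, rg):
    """Typical N=5000 bead P(q) within 0.5% of the closed form for q·Rg ≤ 1.

    The Guinier-region deviation is dominated by the realization's Rg
    fluctuation, so the claim is about the typical (median-over-seeds)
    realization rather than every single one.
    """
    q = np.linspace(1e-3, 1.0 / rg, 40)
    devs = []
    for seed in range(5):
        spec = sb.ModelSpec(subunits=(subunit,), seed=seed)
        P_mc = sb.intensity_from_histogram(
            sb.pair_histogram(sb.build_model(spec)), q
        ).P
        devs.append(np.abs(P_mc / oracle(q) - 1.0).max())
    assert np.median(devs) < 0.005


# ---------------------------------------------------------------------------
# fitting


def test_fit_self_consistency_noise_free():
    """Noise-free data generated by the model, init at truth → exact recovery."""
    q = np.linspace(0.005, 0.3, 150)
    truth = {"scale": 1.3, "R": 48.0}
    model = AnalyticModel("sphere", params=truth, free=("scale", "R"))
    data = SimulatedData(q=q, i_sim=model.evaluate(q), sigma=np.full(len(q), 1e-3))
    res = fit(data, model, n_starts=1)
    assert res.params_hat["R"] == pytest.approx(48.0, abs=1e-5)
    assert res.params_hat["scale"] == pytest.approx(1.3, abs=1e-5)
    assert res.chi2_red < 1e-12


def test_fit_recovers_sphere_radius_from_noisy_data():
    """Simulated sphere data (R = 50 Å, s = 1) → R̂ = 50 within 3 SD."""
    q = np.linspace(0.001, 0.3, 300)
    P = sb.sphere_ff(q, 50.0)
    curve = sb.ScatteringCurve.from_form_factor(q, P)
    data = sb.simulate_data(curve, noise_scale=1.0, seed=21)
    model = AnalyticModel(
        "sphere", params={"scale": 1.0, "R": 45.0}, free=("scale", "R")
    )
    res = fit(data, model)
    assert abs(res.params_hat["R"] - 50.0) < 3 * max(res.params_sd["R"], 1e-3)
    assert res.chi2_red == pytest.approx(1.0, abs=0.3)


def test_fit_requires_free_parameters_and_positive_sigma():
    q = np.linspace(0.01, 0.3, 50)
    model = AnalyticModel("sphere", params={"scale": 1.0, "R": 50.0}, free=())
    data = SimulatedData(q=q, i_sim=sb.sphere_ff(q, 50.0), sigma=np.ones(50))
    with pytest.raises(sb.InvalidParameterError):
        fit(data, model)
    bad = SimulatedData(q=q, i_sim=data.i_sim, sigma=np.zeros(50))
    with pytest.raises(sb.InvalidParameterError):
        fit(bad, AnalyticModel("sphere", params={"scale": 1.0, "R": 50.0}, free=("R",)))


def test_model_validation():
    with pytest.raises(sb.InvalidParameterError):
        AnalyticModel("pyramid", params={"scale": 1.0}, free=())
    with pytest.raises(sb.InvalidParameterError):
        AnalyticModel("sphere", params={"scale": 1.0}, free=())  # missing R
    with pytest.raises(sb.InvalidParameterError):
        AnalyticModel("sphere", params={"scale": 1.0, "R": 1.0}, free=("L",))


def test_fit_reads_simulated_data_file(tmp_path):
    """The fit consumes the 3-column .dat emitted by the noise module."""
    from sasbead.io import read_simulated_data, write_simulated_data

    q = np.linspace(0.001, 0.3, 200)
    curve = sb.ScatteringCurve.from_form_factor(q, sb.sphere_ff(q, 50.0))
    data = sb.simulate_data(curve, seed=2)
    path = tmp_path / "sphere.dat"
    write_simulated_data(path, data)
    back = read_simulated_data(path)
    model = AnalyticModel(
        "sphere", params={"scale": 1.0, "R": 40.0}, free=("scale", "R")
    )
    res = fit(back, model)
    assert res.params_hat["R"] == pytest.approx(50.0, abs=0.5)
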