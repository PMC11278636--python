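"""Discrete Fourier transform and GSER inversion routes."""

import numpy as np
import pytest
from scipy.integrate import quad

import halorheo as h
from halorheo.gser_inversion import (
    DiscreteFTSpec,
    analytic_trapped_npaf,
    analytic_trapped_npaf_transform,
    default_omega_grid,
    ft_piecewise_linear,
    supported_band,
    trapped_modulus_forms,
)

BEAD = h.ProbeParticle(radius_a=1e-6, temperature_T=298.0)


class TestPiecewiseLinearFT:
    def test_ramp_is_exact_for_any_sampling(self):
        """i w transform of y = t equals 1/(i w) to machine precision."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            t = np.sort(rng.uniform(0.01, 20.0, size=rng.integers(5, 40)))
            omega = np.geomspace(0.05, 50.0, 30)
            spec = DiscreteFTSpec(omega=omega, value_at_zero=0.0,
                                  terminal_gradient=1.0)
            ft = ft_piecewise_linear(t, t, spec)
            np.testing.assert_allclose(1j * omega * ft.values,
                                       1.0 / (1j * omega), rtol=1e-12)

    def test_exponential_within_half_percent(self):
        tc = 0.7
        t = np.linspace(0.0, 25 * tc, 4001)
        omega = np.geomspace(0.1 / tc, 10.0 / tc, 25)
        spec = DiscreteFTSpec(omega=omega, terminal_gradient=0.0)
        ft = ft_piecewise_linear(t, np.exp(-t / tc), spec)
        exact = tc / (1 + 1j * omega * tc)
        assert np.max(np.abs(ft.values - exact) / np.abs(exact)) < 5e-3

    def test_smooth_function_matches_quadrature_oracle(self):
        """Arbitrary smooth decaying data agree with adaptive quadrature."""
        f = lambda t: np.exp(-t / 2.0) * (1.0 + 0.3 * np.cos(t))
        t = np.linspace(0.0, 40.0, 8001)
        omega = np.array([0.3, 1.0, 3.0])
        spec = DiscreteFTSpec(omega=omega, terminal_gradient=0.0)
        ft = ft_piecewise_linear(t, f(t), spec)
        for w, val in zip(omega, ft.values):
            re, _ = quad(lambda s: f(s) * np.cos(w * s), 0, 40, limit=800)
            im, _ = quad(lambda s: -f(s) * np.sin(w * s), 0, 40, limit=800)
            oracle = re + 1j * im
            assert abs(val - oracle) / abs(oracle) < 1e-4

    def test_out_of_band_frequencies_flagged_not_dropped(self):
        t = np.linspace(0.0, 10.0, 101)
        omega = np.array([1e-3, 1.0, 1e4])
        spec = DiscreteFTSpec(omega=omega, terminal_gradient=0.0)
        ft = ft_piecewise_linear(t, np.exp(-t), spec)
        lo, hi = supported_band(t)
        np.testing.assert_array_equal(ft.reliable,
                                      (omega >= lo) & (omega <= hi))
        assert np.all(np.isfinite(ft.values))

    def test_initial_extension_step_function(self):
        """Zero below t0 = 1 with a jump onto constant data transforms to the
        closed-form shifted step, exp(-i w)/(i w)."""
        t = np.linspace(1.0, 6.0, 11)
        y = np.ones_like(t)
        omega = np.geomspace(0.1, 5.0, 12)
        spec = DiscreteFTSpec(omega=omega, value_at_zero=0.0,
                              initial_gradient=0.0, terminal_gradient=0.0)
        ft = ft_piecewise_linear(t, y, spec)
        np.testing.assert_allclose(
            ft.values, np.exp(-1j * omega) / (1j * omega), rtol=1e-12)

    def test_default_initial_extension_is_linear_from_origin(self):
        """With no stated initial gradient the sub-t0 extension is the chord
        from (0, value_at_zero): exact for a pure ramp sampled from t0 > 0."""
        t = np.linspace(0.5, 8.0, 16)
        omega = np.geomspace(0.2, 4.0, 9)
        spec = DiscreteFTSpec(omega=omega, value_at_zero=0.0,
                              terminal_gradient=1.0)
        ft = ft_piecewise_linear(t, t, spec)
        np.testing.assert_allclose(1j * omega * ft.values,
                                   1.0 / (1j * omega), rtol=1e-12)

    def test_invalid_inputs(self):
        omega = np.array([1.0])
        with pytest.raises(ValueError):
            ft_piecewise_linear(np.array([1.0, 0.5]), np.array([0.0, 1.0]),
                                DiscreteFTSpec(omega=omega))
        with pytest.raises(ValueError):
            DiscreteFTSpec(omega=np.array([-1.0]))


class TestComplianceAndFreeGSER:
    def test_compliance_proportionality(self):
        msd = np.array([0.0, 1e-14, 2e-14])
        J = h.compliance_from_msd(msd, BEAD, dim=1)
        assert J[0] == 0.0
        hot = h.ProbeParticle(radius_a=1e-6, temperature_T=2 * 298.0)
        np.testing.assert_allclose(h.compliance_from_msd(msd, hot, dim=1),
                                   J / 2.0)

    def test_newtonian_self_consistency_machine_precision(self):
        """Exact 1D diffusive MSD inverts to G' = 0, G'' = w eta — this pins
        the one-dimensional GSER prefactor."""
        eta = 1e-3
        D = BEAD.kBT / (6 * np.pi * BEAD.radius_a * eta)
        t = np.linspace(0.0, 10.0, 201)
        msd = 2 * D * t
        omega = np.geomspace(1.0, 100.0, 21)
        curve = h.gser_free(t, msd, omega=omega, particle=BEAD, dim=1,
                            terminal_gradient=2 * D)
        np.testing.assert_allclose(curve.g_double_prime, omega * eta,
                                   rtol=1e-12)
        np.testing.assert_allclose(curve.g_prime, 0.0,
                                   atol=1e-12 * curve.g_double_prime.max())

    def test_route_equivalence_with_compliance(self):
        """G* from the MSD equals 1/(i w J_hat) on the identical transform."""
        rng = np.random.default_rng(1)
        t = np.linspace(0.0, 5.0, 101)
        msd = np.cumsum(np.abs(rng.standard_normal(101))) * 1e-15
        msd[0] = 0.0
        omega = np.geomspace(2.0, 50.0, 11)
        term = float(np.polyfit(t[-20:], msd[-20:], 1)[0])
        curve = h.gser_free(t, msd, omega=omega, particle=BEAD, dim=1,
                            terminal_gradient=term)
        J = h.compliance_from_msd(msd, BEAD, dim=1)
        spec = DiscreteFTSpec(omega=omega, value_at_zero=0.0,
                              terminal_gradient=term * J[1] / msd[1])
        Jhat = ft_piecewise_linear(t, J, spec).values
        np.testing.assert_allclose(curve.gstar, 1.0 / (1j * omega * Jhat),
                                   rtol=1e-12)


class TestTrappedGSER:
    def test_three_forms_agree_to_machine_precision(self):
        rng = np.random.default_rng(2)
        omega = np.geomspace(0.1, 10, 40)
        A_hat = rng.standard_normal(40) * 0.3 + 1j * rng.standard_normal(40)
        f1, f2, f3 = trapped_modulus_forms(A_hat, omega)
        np.testing.assert_allclose(f1, f2, rtol=1e-12)
        np.testing.assert_allclose(f2, f3, rtol=1e-12)

    def test_exact_ou_transform_gives_newtonian_modulus(self):
        """A_hat = (z0/k)/(1 + i w z0/k) substituted into the trapped relation
        returns exactly G* = i w eta."""
        eta, kappa = 1e-3, 1e-6
        zeta0 = 6 * np.pi * BEAD.radius_a * eta
        tc = zeta0 / kappa
        omega = np.geomspace(0.1 / tc, 10 / tc, 25)
        A_hat = tc / (1 + 1j * omega * tc)
        _, f2, _ = trapped_modulus_forms(A_hat, omega)
        gstar = kappa / (6 * np.pi * BEAD.radius_a) * f2
        np.testing.assert_allclose(gstar, 1j * omega * eta, rtol=1e-12)

    def test_sampled_ou_npaf_recovers_viscosity(self):
        eta, kappa = 1e-3, 1e-6
        zeta0 = 6 * np.pi * BEAD.radius_a * eta
        tc = zeta0 / kappa
        t = np.linspace(0, 25 * tc, 3001)
        omega = np.geomspace(0.2 / tc, 5 / tc, 15)
        curve = h.gser_trapped(t, np.exp(-t / tc), kappa, omega=omega,
                               particle=BEAD)
        np.testing.assert_allclose(curve.g_double_prime, omega * eta,
                                   rtol=2e-2)
        assert np.all(np.abs(curve.g_prime) < 0.05 * omega * eta)

    def test_nmsd_input_equivalent_to_npaf(self):
        tc = 1.0
        t = np.linspace(0, 20, 2001)
        omega = np.geomspace(0.5, 5, 9)
        a = h.gser_trapped(t, np.exp(-t / tc), 1e-6, omega=omega,
                           particle=BEAD, input_kind="npaf")
        b = h.gser_trapped(t, 1 - np.exp(-t / tc), 1e-6, omega=omega,
                           particle=BEAD, input_kind="nmsd")
        np.testing.assert_allclose(a.gstar, b.gstar, rtol=1e-10)


class TestJeffreysIdentity:
    fluid = h.JeffreysFluid(eta1=1e-3, eta2=9e-3, G=0.05)
    kappa = 1e-6

    def test_lhs_equals_model_modulus(self):
        """The viscosity-form left side is the model's G* at every frequency."""
        omega = np.geomspace(1e-2, 1e4, 50)
        lhs_gp = (omega**2 * self.fluid.tau2 * self.fluid.eta2
                  / (1 + (omega * self.fluid.tau2) ** 2))
        lhs_gpp = omega * (self.fluid.eta1 + self.fluid.eta2
                           / (1 + (omega * self.fluid.tau2) ** 2))
        curve = h.complex_modulus_jeffreys(self.fluid, omega)
        np.testing.assert_allclose(curve.g_prime, lhs_gp, rtol=1e-13)
        np.testing.assert_allclose(curve.g_double_prime, lhs_gpp, rtol=1e-13)

    def test_terminal_limit(self):
        omega = np.array([1e-6 / self.fluid.tau2])
        curve = h.complex_modulus_jeffreys(self.fluid, omega)
        eta0 = curve.gstar[0] / (1j * omega[0])
        assert abs(eta0) == pytest.approx(self.fluid.eta0, rel=1e-6)

    def test_analytic_npaf_closes_the_identity(self):
        """A_hat from the embedding's eigenmodes satisfies the trapped-probe
        identity to 1e-6 across the grid — simulator drift matrix and
        inversion algebra agree."""
        omega = np.geomspace(1e0, 1e5, 60)
        resid = h.jeffreys_gser_identity(self.fluid, BEAD, self.kappa, omega)
        assert np.max(resid) < 1e-6

    def test_analytic_npaf_normalisation_and_transform(self):
        tau = np.linspace(0.0, 60.0, 60001)
        A = analytic_trapped_npaf(self.fluid, BEAD, self.kappa, tau)
        assert A[0] == pytest.approx(1.0, rel=1e-10)
        assert np.all(np.abs(A) <= 1.0 + 1e-10)
        # the mode-sum transform agrees with the numerically transformed
        # time-domain autocorrelation
        omega = np.array([1e1, 1e2, 1e3])
        spec = DiscreteFTSpec(omega=omega, terminal_gradient=0.0)
        ft = ft_piecewise_linear(tau, A, spec)
        A_hat = analytic_trapped_npaf_transform(self.fluid, BEAD, self.kappa,
                                                omega)
        np.testing.assert_allclose(ft.values, A_hat, rtol=1e-3)

    def test_newtonian_fluid_identity(self):
        fluid = h.JeffreysFluid.newtonian(1e-3)
        omega = np.geomspace(1e1, 1e4, 30)
        resid = h.jeffreys_gser_identity(fluid, BEAD, self.kappa, omega)
        assert np.max(resid) < 1e-10


class TestJeffreysFit:
    def test_exact_curve_recovered(self):
        fluid = h.JeffreysFluid(eta1=1e-3, eta2=1e-2, G=0.03)
        omega = np.geomspace(0.1 / fluid.tau2, 10 / fluid.tau2, 40)
        curve = h.complex_modulus_jeffreys(fluid, omega)
        G_fit, tau_fit = h.fit_jeffreys_modulus(curve, fluid.eta1)
        assert G_fit == pytest.approx(fluid.G, rel=1e-6)
        assert tau_fit == pytest.approx(fluid.tau2, rel=1e-6)

    def test_band_and_grid_helpers(self):
        t = np.linspace(0.0, 10.0, 101)
        lo, hi = supported_band(t)
        assert lo == pytest.approx(2 * np.pi / 10.0)
        assert hi == pytest.approx(np.pi / 0.1)
        grid = default_omega_grid(t)
        assert grid[0] >= lo * 0.999 and grid[-1] <= hi * 1.001


class TestTransformProperties:
    """Property-based checks of the discrete transform."""

    from hypothesis import given, settings, strategies as st

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_ramp_exact_on_random_grids(self, grid_seed):
        """Linearity in time is transformed exactly whatever the sampling."""
        rng = np.random.default_rng(grid_seed)
        t = np.sort(rng.uniform(0.01, 15.0, size=int(rng.integers(4, 30))))
        slope = float(rng.uniform(0.1, 5.0))
        omega = np.geomspace(0.1, 20.0, 9)
        spec = DiscreteFTSpec(omega=omega, value_at_zero=0.0,
                              terminal_gradient=slope)
        ft = ft_piecewise_linear(t, slope * t, spec)
        np.testing.assert_allclose(1j * omega * ft.values,
                                   slope / (1j * omega), rtol=1e-10)

    @given(st.floats(min_value=1e-4, max_value=1e2),
           st.floats(min_value=1e-4, max_value=1e2),
           st.floats(min_value=1e-4, max_value=1e2))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_trapped_forms_always_agree(self, re, im, w):
        """The three trapped-probe expressions are one identity (away from
        the i w A_hat = 1 pole, where all forms are flagged trap-dominated
        and cancellation makes any of them meaningless)."""
        from hypothesis import assume

        A_hat = np.array([re - 1j * im])
        omega = np.array([w])
        iwA = 1j * omega * A_hat
        assume(abs(1.0 - iwA[0]) > 1e-3 * max(1.0, abs(iwA[0])))
        f1, f2, f3 = trapped_modulus_forms(A_hat, omega)
        np.testing.assert_allclose(f1, f2, rtol=1e-8)
        np.testing.assert_allclose(f2, f3, rtol=1e-8)
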