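"""Cylindrical decomposition and correlation estimators."""

import numpy as np
import pytest

import halorheo as h
from halorheo.halo_simulator import TrajectoryEnsemble
from halorheo.trajectory_stats import (
    CorrelationSet,
    _collapse_metric,
    annulus_area_ratio,
    make_lag_grid,
)


def make_traj(positions, dt=0.1, R_hat=10.0):
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 2:
        positions = positions[None]
    times = np.arange(positions.shape[1]) * dt
    return TrajectoryEnsemble(times=times, positions=positions,
                              params={"R_hat": R_hat, "model": "synthetic"})


class TestCylindricalDecompose:
    def test_static_point(self):
        p = np.tile([3.0, 4.0, 1.0], (20, 1))
        comp = h.cylindrical_decompose(make_traj(p), R_hat=5.0)
        assert np.ptp(comp.s) == 0.0
        np.testing.assert_allclose(comp.r, 5.0)

    def test_full_loop_arc_length(self):
        theta = np.linspace(0, 2 * np.pi, 400)
        R = 12.0
        p = np.column_stack([R * np.cos(theta), R * np.sin(theta),
                             np.zeros_like(theta)])
        comp = h.cylindrical_decompose(make_traj(p, R_hat=R))
        assert comp.s[0, -1] - comp.s[0, 0] == pytest.approx(2 * np.pi * R)

    def test_branch_cut_continuity(self):
        """Crossing the +-pi cut must not jump the arc length by ~2 pi R."""
        theta = np.linspace(np.pi - 0.3, np.pi + 0.3, 50)
        R = 8.0
        p = np.column_stack([R * np.cos(theta), R * np.sin(theta),
                             np.zeros_like(theta)])
        comp = h.cylindrical_decompose(make_traj(p, R_hat=R))
        steps = np.abs(np.diff(comp.s[0]))
        assert steps.max() < 0.2 * R

    def test_reconstruction_is_exact(self):
        rng = np.random.default_rng(2)
        traj = h.fixture_ensemble("newtonian_ring_small", seed=9)
        comp = h.cylindrical_decompose(traj)
        x = comp.r * np.cos(comp.theta_raw)
        y = comp.r * np.sin(comp.theta_raw)
        np.testing.assert_allclose(x, traj.positions[:, :, 0], atol=1e-12)
        np.testing.assert_allclose(y, traj.positions[:, :, 1], atol=1e-12)
        del rng

    def test_large_angular_step_rejected(self):
        theta = np.array([0.0, 2.5, 5.0])  # well under pi per step is ok
        theta_bad = np.array([0.0, 3.1, 6.2])  # steps approaching pi
        R = 5.0

        def traj_of(th):
            p = np.column_stack([R * np.cos(th), R * np.sin(th),
                                 np.zeros_like(th)])
            return make_traj(p, R_hat=R)

        h.cylindrical_decompose(traj_of(theta))
        with pytest.raises(ValueError, match="unwrap"):
            h.cylindrical_decompose(traj_of(theta_bad))


class TestLagGrid:
    def test_structure(self):
        lags = make_lag_grid(5000)
        assert lags[0] == 0
        assert np.all(np.diff(lags) > 0)
        np.testing.assert_array_equal(lags[:17], np.arange(17))
        assert lags[-1] <= 4999
        ratios = lags[18:] / lags[17:-1]
        assert ratios.max() <= 1.3


class TestMSD:
    def test_deterministic_ramp(self):
        v, dt = 1.7, 0.1
        x = v * np.arange(200) * dt
        lag_ints = np.array([1, 5, 20])
        vals, _, _ = h.msd(x, lag_ints)
        np.testing.assert_allclose(vals, (v * lag_ints * dt) ** 2, rtol=1e-12)

    def test_iid_series_plateau(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((64, 400)) * 2.0
        vals, se, _ = h.msd(x, np.array([1, 3, 10]))
        np.testing.assert_allclose(vals, 8.0, rtol=0.05)

    def test_brute_force_oracle_short_series(self):
        """All-pairs estimator agrees exactly with the O(N^2) double loop."""
        rng = np.random.default_rng(4)
        x = np.cumsum(rng.standard_normal((3, 64)), axis=1)
        lag_ints = make_lag_grid(64)
        vals, _, n_pairs = h.msd(x, lag_ints)
        for i, k in enumerate(lag_ints):
            acc, cnt = 0.0, 0
            for p in range(3):
                for t0 in range(64 - k):
                    acc += (x[p, t0 + k] - x[p, t0]) ** 2
                    cnt += 1
            if k == 0:
                assert vals[i] == 0.0
            else:
                assert vals[i] == pytest.approx(acc / cnt, rel=1e-12)
                assert n_pairs[i] == cnt

    def test_lag_beyond_series_rejected(self):
        with pytest.raises(ValueError):
            h.msd(np.zeros(10), np.array([10]))


class TestNormalisedCorrelations:
    def test_npaf_is_one_at_zero_lag(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((4, 100))
        vals, _, _ = h.npaf(x, np.array([0, 1, 2]))
        assert vals[0] == pytest.approx(1.0)

    def test_ou_autocorrelation_decay(self, ou_fixture):
        """Unit-stiffness OU: A(t) = exp(-t) within Monte-Carlo error."""
        z = ou_fixture.positions[:, :, 2]
        lag_ints = h.make_lag_grid(z.shape[1], max_lag=300)
        vals, se, _ = h.npaf(z, lag_ints)
        t = lag_ints * ou_fixture.dt_sample
        zscore = np.abs(vals - np.exp(-t)) / np.maximum(se, 1e-12)
        assert np.max(zscore[1:]) < 4.5

    def test_pi_equals_one_minus_a(self, ou_fixture):
        """Stationarity identity Pi = 1 - A, checked with independent estimators."""
        z = ou_fixture.positions[:, :, 2]
        lag_ints = h.make_lag_grid(z.shape[1], max_lag=1000)
        a_vals, a_se, _ = h.npaf(z, lag_ints)
        p_vals, p_se, _ = h.nmsd(z, lag_ints)
        resid = np.abs(p_vals - (1 - a_vals))
        se = np.maximum(np.hypot(a_se, p_se), 1e-12)
        assert np.max(resid[1:] / se[1:]) < 3.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            h.npaf(np.zeros(50), np.array([0, 1]))


def analytic_ou_corrset(kz_over_kr, lags):
    """CorrelationSet built from the OU closed forms (axial channel only)."""
    n = lags.size
    var = 1.0 / kz_over_kr
    msd_z = 2 * var * (1 - np.exp(-kz_over_kr * lags))
    npaf_z = np.exp(-kz_over_kr * lags)
    zeros = np.zeros(n)
    return CorrelationSet(
        lags=lags, msd_r=zeros, msd_z=msd_z, msd_theta=zeros,
        npaf_r=zeros, npaf_z=npaf_z, nmsd_r=zeros, nmsd_z=1 - npaf_z,
        n_pairs=np.ones(n, dtype=int),
        stderr={k: zeros for k in CorrelationSet.COMPONENTS})


class TestMasterCurves:
    lags = np.linspace(0.0, 60.0, 400)

    def test_single_ratio_is_identity(self):
        cs = analytic_ou_corrset(1.0, self.lags)
        mc = h.master_curve_axial([cs], [1.0])
        assert mc.collapse_msd == 0.0
        np.testing.assert_allclose(mc.u[0], self.lags)

    def test_analytic_curves_collapse_exactly(self):
        """Closed-form OU curves sampled on matched rescaled grids collapse
        to machine precision; mismatched grids only to interpolation error."""
        ratios = [1.0 / 9.0, 1.0 / 3.0, 1.0, 3.0]
        base_u = np.linspace(0.0, 6.0, 400)
        sets = [analytic_ou_corrset(r, base_u / r) for r in ratios]
        mc = h.master_curve_axial(sets, ratios)
        assert mc.collapse_msd < 1e-12
        assert mc.collapse_npaf < 1e-12
        sets = [analytic_ou_corrset(r, self.lags) for r in ratios]
        mc = h.master_curve_axial(sets, ratios)
        assert mc.collapse_msd < 0.05

    def test_non_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            _collapse_metric([np.array([0.0, 1.0, 2.0]),
                              np.array([10.0, 20.0, 30.0])],
                             [np.ones(3), np.ones(3)])


class TestRadialAnisotropy:
    def test_power_law_recovery_on_synthetic_plateaus(self):
        lags = np.linspace(0, 100, 200)
        R_values = [5.0, 10.0, 20.0]
        sets = []
        for R in R_values:
            plateau = 1.0 / R**2
            npaf_r = plateau + (1 - plateau) * np.exp(-lags)
            cs = analytic_ou_corrset(1.0, lags)
            cs.npaf_r = npaf_r
            cs.stderr["npaf_r"] = np.full_like(lags, 1e-6)
            sets.append(cs)
        res = h.radial_anisotropy(sets, R_values)
        assert res.exponent == pytest.approx(-2.0, abs=1e-3)

    def test_refuses_non_plateaued_tail(self):
        lags = np.linspace(0, 10, 200)
        sets = []
        for R in [5.0, 10.0, 20.0]:
            cs = analytic_ou_corrset(1.0, lags)
            cs.npaf_r = np.exp(-lags / 1.5)  # still decaying at the end
            cs.stderr["npaf_r"] = np.full_like(lags, 1e-9)
            sets.append(cs)
        with pytest.raises(ValueError, match="plateau"):
            h.radial_anisotropy(sets, [5.0, 10.0, 20.0])


class TestAnnulusAreaRatio:
    def test_limits_and_midpoint(self):
        assert annulus_area_ratio(1.0, 1.0) == pytest.approx(1.0 / 3.0)
        assert annulus_area_ratio(1e6, 1.0) == pytest.approx(1.0, abs=1e-5)
        assert annulus_area_ratio(1.5, 1.0) == pytest.approx(0.5)

    def test_self_intersecting_rejected(self):
        with pytest.raises(ValueError):
            annulus_area_ratio(0.5, 1.0)


class TestGeometryProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.floats(min_value=1.0, max_value=1e6),
           st.floats(min_value=1e-3, max_value=1.0))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_area_ratio_bounded_and_monotone(self, scale, b_over_R):
        """Ai/Ao lies in [1/3, 1) and grows with R/b."""
        R = scale
        b = b_over_R * R
        ratio = annulus_area_ratio(R, b)
        assert 1.0 / 3.0 <= ratio < 1.0
        assert annulus_area_ratio(2 * R, b) >= ratio
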