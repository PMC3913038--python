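"""Targeting kinetics: closed form, fitting, bulk time, bridge counts, flux."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ldbridges.bridge_kinetics import (
    GeometryParams,
    TimeCourse,
    bulk_time,
    closed_form_N,
    estimate_connections,
    fit_targeting,
    simulate_flux,
)
from ldbridges.errors import FitConvergenceError
from ldbridges.synthetic_data import gen_timecourse


class TestClosedForm:
    def test_zero_at_and_before_lag(self):
        assert closed_form_N(5.0, tau=3.6, lag=5.0) == 0.0
        assert closed_form_N(2.0, tau=3.6, lag=5.0) == 0.0

    def test_one_tau_after_lag(self):
        got = closed_form_N(8.6, tau=3.6, lag=5.0, plateau=2.0)
        assert got == pytest.approx(2.0 * (1 - np.exp(-1)))

    def test_saturates_at_plateau(self):
        assert closed_form_N(1e6, tau=3.6, lag=5.0, plateau=0.7) == pytest.approx(0.7)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        tau=st.floats(0.5, 20.0),
        lag=st.floats(0.0, 25.0),
        plateau=st.floats(0.1, 10.0),
    )
    def test_monotone_and_bounded(self, tau, lag, plateau):
        t = np.linspace(0, lag + 10 * tau, 200)
        y = closed_form_N(t, tau, lag, plateau)
        assert np.all(np.diff(y) >= 0)
        assert np.all(y <= plateau + 1e-12)


class TestFitTargeting:
    def test_noiseless_curve_recovered_exactly(self):
        tc = gen_timecourse(tau=3.6, lag=5.0, plateau=1.0, noise_sd=0.0)
        fit = fit_targeting(tc)
        assert fit.tau_min == pytest.approx(3.6, rel=1e-6)
        assert fit.lag_min == pytest.approx(5.0, rel=1e-6)
        assert fit.plateau == pytest.approx(1.0, rel=1e-6)

    def test_nine_noisy_curves_recover_tau_within_ten_percent(self):
        # mirrors nine independent fusion experiments at 5% noise
        taus = []
        for i in range(9):
            tc = gen_timecourse(tau=3.6, lag=1.0 + 2.5 * i, plateau=1.0, noise_sd=0.05, seed=100 + i)
            taus.append(fit_targeting(tc).tau_min)
        assert np.mean(taus) == pytest.approx(3.6, rel=0.10)

    def test_truncated_curve_flags_wide_se(self):
        # observation window ends at half a time constant: tau barely constrained
        t = np.linspace(0, 1.8, 10)
        tc = gen_timecourse(tau=3.6, lag=0.0, plateau=1.0, t_grid=t, noise_sd=0.005, seed=5)
        fit = fit_targeting(tc)  # fit succeeds, not rejected
        full = gen_timecourse(tau=3.6, lag=0.0, plateau=1.0, noise_sd=0.005, seed=5)
        fit_full = fit_targeting(full)
        # relative uncertainty blows up by an order of magnitude vs a full window
        assert fit.tau_se / fit.tau_min > 10 * fit_full.tau_se / fit_full.tau_min

    def test_too_few_points_rejected(self):
        tc = TimeCourse(np.arange(5.0), np.zeros(5))
        with pytest.raises(ValueError, match="6 time points"):
            fit_targeting(tc)


class TestBulkTime:
    def test_hand_arithmetic_reference(self):
        g = GeometryParams(R_um=1.0, D_um2_s=0.035, l_over_L=2.0)
        assert bulk_time(g) == pytest.approx(8 * np.pi / 0.035 / 60, rel=1e-12)  # ~11.97 min

    def test_inverse_in_diffusion_coefficient(self):
        g1 = GeometryParams(R_um=1.5, D_um2_s=0.02)
        g2 = GeometryParams(R_um=1.5, D_um2_s=0.04)
        assert bulk_time(g1) == pytest.approx(2 * bulk_time(g2))

    def test_geometry_ratio_spread(self):
        lo = GeometryParams(R_um=1.0, l_over_L=1.5)
        hi = GeometryParams(R_um=1.0, l_over_L=3.0)
        assert bulk_time(hi) == pytest.approx(2 * bulk_time(lo))


class TestConnections:
    @pytest.mark.parametrize(
        "tau_bulk,expected", [(21.0, 21 / 3.6), (31.0, 31 / 3.6), (3.6, 1.0)]
    )
    def test_point_estimates(self, tau_bulk, expected):
        est = estimate_connections(3.6, tau_bulk)
        assert est.n_c_point == pytest.approx(expected)

    def test_range_propagates_bounds(self):
        est = estimate_connections(3.6, (21.0, 31.0))
        assert est.n_c_range[0] == pytest.approx(21 / 3.6)
        assert est.n_c_range[1] == pytest.approx(31 / 3.6)

    def test_strictly_decreasing_in_tau_fit(self):
        taus = np.linspace(1.0, 10.0, 15)
        points = [estimate_connections(t, 24.0).n_c_point for t in taus]
        assert np.all(np.diff(points) < 0)

    def test_unidentifiable_tau_refused(self):
        tc = gen_timecourse(tau=3.6, lag=0.0, plateau=1.0, noise_sd=0.0)
        fit = fit_targeting(tc)
        fit.tau_se = 10 * fit.tau_min
        with pytest.raises(FitConvergenceError, match="identifiable"):
            estimate_connections(fit, 24.0)


class TestSimulateFlux:
    def test_ode_matches_closed_form(self, rng):
        # the module's primary oracle: numerical integration vs the solution
        for _ in range(20):
            g = GeometryParams(
                R_um=rng.uniform(0.5, 3.0),
                D_um2_s=rng.uniform(0.01, 0.1),
                l_over_L=rng.uniform(1.5, 3.0),
            )
            n_c = rng.integers(1, 12)
            C0 = rng.uniform(0.5, 5.0)
            tau = g.l_over_L * g.surface_um2 / (n_c * g.D_um2_s) / 60
            t = np.linspace(0.0, 5 * tau, 40)
            ode = simulate_flux(n_c, g, C0, t, mode="ode")
            want = closed_form_N(t, tau, 0.0, C0 * g.surface_um2)
            np.testing.assert_allclose(ode.intensity[1:], want[1:], rtol=1e-6)

    def test_zero_bridges_no_flux(self):
        g = GeometryParams(R_um=1.0)
        tc = simulate_flux(0, g, 1.0, np.linspace(0, 10, 11))
        assert np.all(tc.intensity == 0)

    def test_particle_mode_agrees_with_ode(self):
        g = GeometryParams(R_um=1.0)
        t = np.linspace(0.0, 30.0, 16)
        ode = simulate_flux(5, g, 1.0, t, mode="ode")
        n_rep, n_part = 200, 400
        curves = np.stack(
            [
                simulate_flux(5, g, 1.0, t, mode="particle", seed=s, n_particles=n_part).intensity
                for s in range(n_rep)
            ]
        )
        mean = curves.mean(axis=0)
        plateau = 4 * np.pi
        p = np.clip(ode.intensity / plateau, 1e-9, 1 - 1e-9)
        se = plateau * np.sqrt(p * (1 - p) / (n_rep * n_part))
        assert np.all(np.abs(mean[1:] - ode.intensity[1:]) < 3 * se[1:])
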