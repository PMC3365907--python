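"""Taylor-series integration: coefficients, steps, dense output, events."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hrsweep.model import preset, rhs
from hrsweep.polyfield import PolynomialField
from hrsweep.taylor import (
    DivergenceError,
    EventSpec,
    IntegratorOptions,
    integrate,
    integrate_endpoint,
    integrate_variational,
    locate_events,
    select_step,
    taylor_coefficients,
)

P27 = preset("square_wave")

EXP_FIELD = PolynomialField(1, [(0, 1.0, {0: 1})])  # u' = u
HARMONIC = PolynomialField(2, [(0, 1.0, {1: 1}), (1, -1.0, {0: 1})])  # circle flow
LINEAR_DIAG = PolynomialField(
    3, [(0, -1.0, {0: 1}), (1, -2.0, {1: 1}), (2, -3.0, {2: 1})]
)


class TestCoefficients:
    def test_order_one_equals_rhs(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            s = rng.uniform(-2, 2, 3)
            c = taylor_coefficients(s, P27, 3)
            assert np.allclose(c[:, 0], s)
            assert np.allclose(c[:, 1], rhs(s, P27), atol=1e-13)

    def test_second_order_at_origin(self):
        # hand second derivatives at (0,0,0): x'' = y' - z' = 0.936,
        # y'' = -y' = -1, z'' = eps*(s*x' - z') = 0.15936; series halves them
        c = taylor_coefficients([0, 0, 0], P27, 2)
        assert np.allclose(c[:, 2], [0.468, -0.5, 0.07968], atol=1e-14)

    def test_exponential_series(self):
        c = taylor_coefficients([1.0], EXP_FIELD, 15)
        expect = [1.0 / math.factorial(j) for j in range(16)]
        assert np.allclose(c[0], expect, rtol=1e-13)

    def test_rejects_bad_order(self):
        with pytest.raises(ValueError):
            taylor_coefficients([0, 0, 0], P27, 0)


class TestStepSelection:
    def test_exponential_series_closed_form(self):
        """Two-term tail rule on the exponential series, order 15.

        Closed-form inversion of the tail terms: h = 0.9 * min over
        j in {14, 15} of (tol * j!)^(1/j); the order-14 term is the binding
        one for this series.
        """
        c = taylor_coefficients([1.0], EXP_FIELD, 15)
        expect = 0.9 * min(
            (1e-12 * math.factorial(14)) ** (1 / 14),
            (1e-12 * math.factorial(15)) ** (1 / 15),
        )
        assert select_step(c, IntegratorOptions()) == pytest.approx(expect, rel=1e-12)

    def test_monotone_in_tolerance(self):
        c = taylor_coefficients([1.0], EXP_FIELD, 15)
        h1 = select_step(c, IntegratorOptions(tol=1e-12))
        h2 = select_step(c, IntegratorOptions(tol=2e-12))
        assert h2 > h1

    def test_zero_tail_gives_max_step(self):
        c = np.zeros((1, 16))
        c[0, 0] = 1.0  # constant solution
        assert select_step(c, IntegratorOptions(max_step=7.5)) == 7.5

    def test_local_error_within_tolerance_budget(self):
        """Chosen steps never exceed 10x the tolerance vs refined re-integration."""
        rng = np.random.default_rng(17)
        opts = IntegratorOptions()
        fine = IntegratorOptions(tol=1e-15)
        for _ in range(25):
            s = rng.uniform(-1.5, 1.5, 3)
            c = taylor_coefficients(s, P27, opts.order)
            h = min(select_step(c, opts), 0.5)
            coarse = np.array([np.polynomial.polynomial.polyval(h, c[v]) for v in range(3)])
            ref, _ = integrate_endpoint(s, P27, h, fine)
            assert np.max(np.abs(coarse - ref)) <= 10 * opts.tol * (1 + np.max(np.abs(ref)))


class TestIntegrate:
    def test_exponential_endpoint(self):
        traj = integrate([1.0], EXP_FIELD, 1.0)
        assert traj.endpoint[0] == pytest.approx(math.e, abs=1e-12)

    def test_harmonic_energy_conservation(self):
        traj = integrate([0.0, 1.0], HARMONIC, 100.0)
        t, s = traj.sample(2000)
        energy = s[:, 0] ** 2 + s[:, 1] ** 2
        assert np.max(np.abs(energy - 1.0)) < 1e-10

    def test_against_adaptive_rk_oracle(self):
        t_end = 100.0
        traj = integrate([0.0, 0.0, 0.0], P27, t_end)
        sol = solve_ivp(
            lambda t, y: rhs(y, P27),
            (0, t_end),
            [0.0, 0.0, 0.0],
            method="DOP853",
            rtol=1e-12,
            atol=1e-12,
        )
        assert np.max(np.abs(traj.endpoint - sol.y[:, -1])) < 1e-6

    def test_halving_tolerance_reduces_error(self):
        """Accuracy is monotone in the tolerance (vs a much finer run)."""
        ref, _ = integrate_endpoint(np.zeros(3), P27, 50.0, IntegratorOptions(tol=1e-15))
        errs = []
        for tol in (1e-6, 1e-9, 1e-12):
            end, _ = integrate_endpoint(np.zeros(3), P27, 50.0, IntegratorOptions(tol=tol))
            errs.append(np.max(np.abs(end - ref)))
        assert errs[0] > errs[1] > errs[2] or errs[2] < 1e-12

    def test_blowup_reports_reached_time(self):
        cubic_growth = PolynomialField(1, [(0, 1.0, {0: 3})])  # u' = u^3, blows up
        with pytest.raises(DivergenceError) as err:
            integrate([2.0], cubic_growth, 10.0)
        assert 0 < err.value.t_reached <= 10.0

    def test_bad_span_rejected(self):
        with pytest.raises(ValueError):
            integrate([0, 0, 0], P27, 0.0)


class TestDenseOutput:
    def test_initial_state_exact(self):
        traj = integrate([0.5, -0.5, 1.0], P27, 10.0)
        assert np.array_equal(traj.eval(0.0), np.array([0.5, -0.5, 1.0]))

    def test_knot_continuity(self):
        traj = integrate([0, 0, 0], P27, 200.0)
        tol = IntegratorOptions().tol
        for i in range(1, len(traj), 37):
            left = traj.segment(i - 1).eval(traj.ts[i])
            right = traj.coeffs[i, :, 0]
            scale = 1 + np.max(np.abs(right))
            assert np.max(np.abs(left - right)) <= 10 * tol * scale

    def test_midpoint_matches_fresh_integration(self):
        traj = integrate([0, 0, 0], P27, 20.0)
        i = len(traj) // 2
        t_mid = traj.ts[i] + 0.5 * traj.hs[i]
        fresh, _ = integrate_endpoint(np.zeros(3), P27, t_mid)
        assert np.max(np.abs(traj.eval(t_mid) - fresh)) < 1e-10

    def test_out_of_span_rejected(self):
        traj = integrate([0, 0, 0], P27, 5.0)
        with pytest.raises(ValueError):
            traj.eval(5.5)
        with pytest.raises(ValueError):
            traj.eval(-0.1)

    def test_integral_of_series(self):
        traj = integrate([0.0, 1.0], HARMONIC, 10.0)
        # integral of x = sin(t) over [0, pi] is 2
        assert traj.integral(0, 0.0, np.pi) == pytest.approx(2.0, abs=1e-10)


class TestEvents:
    def test_sine_maxima_count_and_location(self):
        traj = integrate([0.0, 1.0], HARMONIC, 100.0)
        t, v = locate_events(traj, EventSpec.maximum(0))
        expect = np.pi / 2 + 2 * np.pi * np.arange(16)
        assert len(t) == 16
        assert np.max(np.abs(t - expect)) < 1e-8
        assert np.allclose(v, 1.0, atol=1e-10)

    def test_monotone_trace_has_no_extrema(self):
        traj = integrate([1.0], EXP_FIELD, 2.0)
        t, _ = locate_events(traj, EventSpec.maximum(0))
        assert len(t) == 0

    def test_crossing_directions(self):
        traj = integrate([0.0, 1.0], HARMONIC, 4 * np.pi)
        up, _ = locate_events(traj, EventSpec.crossing(0, 0.5, +1))
        down, _ = locate_events(traj, EventSpec.crossing(0, 0.5, -1))
        both, _ = locate_events(traj, EventSpec.crossing(0, 0.5, 0))
        assert len(up) == 2 and len(down) == 2
        assert len(both) == 4
        assert np.allclose(np.sin(up), 0.5, atol=1e-9)

    def test_spike_maxima_match_dense_sampling_oracle(self, square_wave_traj):
        """Root-found maxima agree with argmax refinement of dense sampling."""
        traj, _p, (t_lo, _t_hi) = square_wave_traj
        sub = traj.restrict(t_lo, t_lo + 300.0)
        t_ev, v_ev = locate_events(sub, EventSpec.maximum(0))
        keep = (t_ev > t_lo + 1) & (t_ev < t_lo + 299)
        t_ev, v_ev = t_ev[keep], v_ev[keep]
        ts = np.arange(t_lo, t_lo + 300.0, 1e-3)
        xs = np.array([sub.eval(t)[0] for t in ts])
        local = np.where((xs[1:-1] > xs[:-2]) & (xs[1:-1] >= xs[2:]))[0] + 1
        coarse = ts[local]
        coarse = coarse[(coarse > t_lo + 1) & (coarse < t_lo + 299)]
        assert len(coarse) == len(t_ev)
        assert np.max(np.abs(coarse - t_ev)) < 2e-3  # sampling-limited match


class TestVariational:
    def test_zero_time_returns_basis(self):
        _traj, M = integrate_variational([0, 0, 0], np.eye(3), P27, 0.0)
        assert np.array_equal(M, np.eye(3))

    def test_linear_field_closed_form(self):
        t = 2.0
        _traj, M = integrate_variational([1, 1, 1], np.eye(3), LINEAR_DIAG, t)
        expect = np.diag([np.exp(-t), np.exp(-2 * t), np.exp(-3 * t)])
        assert np.max(np.abs(M - expect)) < 1e-10

    def test_abel_liouville_determinant(self):
        """det M(t) = exp(integral of trace J) along an HR trajectory."""
        t_end = 50.0
        traj, M = integrate_variational([0.1, 0.2, 2.0], np.eye(3), P27, t_end)
        # quadrature of trace J = -3a x^2 + 2b x - 1 - eps over the dense x
        ts = np.linspace(0, t_end, 60001)
        xs = np.array([traj.eval(t)[0] for t in ts])
        tr = -3 * P27.a * xs**2 + 2 * P27.b * xs - 1 - P27.eps
        integral = np.trapezoid(tr, ts)
        assert np.linalg.det(M) == pytest.approx(np.exp(integral), rel=1e-6)

    def test_singular_basis_rejected(self):
        with pytest.raises(ValueError):
            integrate_variational([0, 0, 0], np.zeros((3, 3)), P27, 1.0)
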