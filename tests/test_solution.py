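"""Closed-form fields: mode algebra, boundary/initial behaviour, limits."""

import math

import numpy as np
import pytest

import ternaflow as tf
from conftest import make_params


class TestModeCoefficients:
    def test_lambda_zero_first_mode_symbolic(self, pure_fluid):
        import sympy as sp

        _, params = make_params(phi=0.0, lam=0.0)
        mc = tf.mode_coefficients(params, 1)
        # symbolic substitution of the printed definitions
        B0, B3, a, s = sp.symbols("B0 B3 a s", positive=True)
        r2 = a / (1 - a)
        r6 = B0 / (1 - a)
        r7 = r6 + s ** 2
        r8 = r2 * s ** 2 / r7
        subs = {B0: params.B0, B3: params.B3, a: params.alpha, s: sp.pi}
        assert mc.r7 == pytest.approx(float(r7.subs(subs)), rel=1e-12)
        assert mc.r8 == pytest.approx(float(r8.subs(subs)), rel=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 7, 40])
    @pytest.mark.parametrize("alpha", [0.3, 0.5, 0.9])
    def test_invariants_and_bounds(self, n, alpha):
        _, params = make_params(alpha=alpha)
        mc = tf.mode_coefficients(params, n)
        assert mc.r1 > 0 and mc.r6 > 0 and mc.r3 > 0 and mc.r7 > 0
        assert 0 <= mc.r4 < mc.r2 and 0 <= mc.r8 <= mc.r2
        assert mc.sigma == pytest.approx(n * math.pi)

    @pytest.mark.parametrize("n", [1, 3, 8])
    def test_buoyancy_amplitude_ratio(self, baseline, n):
        _, params = baseline
        mc = tf.mode_coefficients(params, n)
        assert mc.A3 / mc.A4 == pytest.approx(
            (mc.r2 - mc.r4) ** 2 / (mc.r2 - mc.r8) ** 2, rel=1e-12)

    def test_alpha_one_routes_to_classical(self):
        _, params = make_params(alpha=1.0)
        with pytest.raises(ValueError, match="classical"):
            tf.mode_coefficients(params, 1)


class TestBoundaryConditions:
    @pytest.mark.parametrize("tau", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("over", [dict(), dict(alpha=0.3),
                                      dict(alpha=0.9), dict(G=0.0, lam=0.0),
                                      dict(Gr=0.0), dict(Re=1.5)])
    def test_walls_pinned(self, tau, over):
        _, params = make_params(**over)
        x = np.linspace(0, 1, 11)
        th = tf.temperature_profile(params, tau, x)
        w = tf.velocity_profile(params, tau, x)
        assert th.values[0] == pytest.approx(1.0, abs=1e-6)
        assert th.values[-1] == pytest.approx(0.0, abs=1e-6)
        assert w.values[0] == pytest.approx(1.0, abs=1e-6)
        assert w.values[-1] == pytest.approx(0.0, abs=1e-6)

    def test_steady_velocity_walls(self):
        for lam in (0.0, 1.0, 3.0):
            _, params = make_params(lam=lam)
            vals = tf.steady_velocity(params, np.array([0.0, 1.0]))
            assert vals[0] == pytest.approx(1.0, abs=1e-14)
            assert vals[1] == pytest.approx(0.0, abs=1e-14)


class TestSeriesControl:
    def test_doubling_modes_changes_interior_below_tol(self, baseline):
        _, params = baseline
        x = np.linspace(0.05, 0.95, 19)
        tol = 1e-9
        a = tf.temperature_profile(params, 1.0, x,
                                   tf.SolutionConfig(series_tol=tol,
                                                     min_modes=150))
        b = tf.temperature_profile(params, 1.0, x,
                                   tf.SolutionConfig(series_tol=tol,
                                                     min_modes=300))
        assert np.max(np.abs(a.values - b.values)) < tol
        va = tf.velocity_profile(params, 1.0, x,
                                 tf.SolutionConfig(series_tol=tol,
                                                   min_modes=150))
        vb = tf.velocity_profile(params, 1.0, x,
                                 tf.SolutionConfig(series_tol=tol,
                                                   min_modes=300))
        assert np.max(np.abs(va.values - vb.values)) < tol

    def test_initial_condition_temperature_norm_shrinks(self, baseline):
        # interior temperature approaches the zero initial state as
        # tau -> 0+ up to the nonsingular-kernel jump, which is confined
        # to a hot-wall layer of width ~ 1/sqrt(r1); mid-channel values
        # are small and the interior norm shrinks monotonically
        _, params = baseline
        x = np.linspace(0.05, 0.95, 19)
        l1 = [np.mean(np.abs(tf.temperature_profile(params, t, x).values))
              for t in (1e-3, 1e-2, 0.1, 1.0)]
        assert l1[0] < l1[1] < l1[2] < l1[3]
        mid = tf.temperature_profile(params, 1e-3, np.array([0.5])).values[0]
        assert abs(mid) < 0.05

    def test_initial_condition_velocity_norm_nonincreasing(self, baseline):
        # the nonsingular-kernel velocity solution jumps at tau = 0+ to
        # near the permanent profile; the interior norm still decreases
        # monotonically toward that jump level as tau -> 0+
        _, params = baseline
        x = np.linspace(0.05, 0.95, 19)
        l1 = [np.mean(np.abs(tf.velocity_profile(params, t, x).values))
              for t in (1e-3, 1e-2, 0.1, 1.0)]
        assert l1[0] <= l1[1] <= l1[2] <= l1[3]

    def test_nonpositive_tau_rejected(self, baseline):
        _, params = baseline
        with pytest.raises(ValueError):
            tf.temperature_profile(params, 0.0)
        with pytest.raises(ValueError):
            tf.velocity_profile(params, -1.0)


class TestClassicalLimit:
    def test_continuity_in_alpha(self):
        _, p1 = make_params(alpha=1.0)
        t_cl = tf.classical_limit_profile(p1, 1.0)
        w_cl = tf.classical_limit_profile(p1, 1.0, field_kind="velocity")
        devs = []
        for a in (0.99, 0.999, 0.9999):
            _, p = make_params(alpha=a)
            dt = np.max(np.abs(tf.temperature_profile(p, 1.0).values
                               - t_cl.values))
            dw = np.max(np.abs(tf.velocity_profile(p, 1.0).values
                               - w_cl.values))
            devs.append((dt, dw))
        # deviations shrink ~ O(1 - alpha) and are below 1e-3 at 0.9999
        assert devs[0][0] > devs[1][0] > devs[2][0]
        assert devs[2][0] < 1e-3 and devs[2][1] < 1e-3

    def test_per_mode_exponential_decay_rates(self):
        # classical transients decay at sigma_n^2/B3 (temperature) and
        # (sigma_n^2 + lam sigma_n^4)/B0 (velocity); checked on mode 1 by
        # the log-ratio of the transient at two times
        _, params = make_params(alpha=1.0, G=0.0, Gr=0.0)
        x = np.linspace(0, 1, 41)
        t1, t2 = 1.0, 1.4
        r4 = math.pi ** 2 / params.B3
        # project the transient onto mode 1
        def mode1(profile):
            y = profile.values - (1.0 - x)
            return 2.0 * np.trapezoid(y * np.sin(math.pi * x), x)
        m1 = mode1(tf.classical_limit_profile(params, t1, x))
        m2 = mode1(tf.classical_limit_profile(params, t2, x))
        assert math.log(abs(m1 / m2)) / (t2 - t1) == pytest.approx(r4,
                                                                   rel=1e-3)

    def test_long_time_steady_conduction(self):
        _, params = make_params(alpha=1.0, phi=0.0)
        x = np.linspace(0, 1, 21)
        th = tf.classical_limit_profile(params, 80.0, x)
        assert np.max(np.abs(th.values - (1.0 - x))) < 1e-9
        w1 = tf.classical_limit_profile(params, 80.0, x, field_kind="velocity")
        w2 = tf.classical_limit_profile(params, 160.0, x, field_kind="velocity")
        assert np.max(np.abs(w1.values - w2.values)) < 1e-12

    def test_steady_parts_shared(self):
        _, params = make_params(alpha=1.0)
        x = np.linspace(0, 1, 11)
        assert tf.steady_velocity(params, x) == pytest.approx(
            tf.steady_velocity(params, x))


class TestTrends:
    """Monotone parameter responses of the closed-form fields.

    Asserted at xi = 0.5 and the reference time tau = 1.  The
    fractional-order response is asserted on alpha in {0.3, 0.5, 0.7},
    the range covered by the model's quantitative wall-transfer
    tabulation; nearer alpha = 1 the fractional curves cross.
    """

    @staticmethod
    def field_at(field, xi=0.5, tau=1.0, phi=0.02, **over):
        mix, params = make_params(phi=phi, **over)
        fn = (tf.temperature_profile if field == "temperature"
              else tf.velocity_profile)
        return fn(params, tau, np.array([xi])).values[0]

    def test_temperature_rises_with_fraction(self):
        v = [self.field_at("temperature", phi=p) for p in (0.0, 0.01, 0.02, 0.04)]
        assert np.all(np.diff(v) > 0)

    def test_temperature_rises_with_order(self):
        v = [self.field_at("temperature", alpha=a) for a in (0.3, 0.5, 0.7)]
        assert np.all(np.diff(v) > 0)

    def test_temperature_falls_with_reynolds_and_prandtl(self):
        v = [self.field_at("temperature", Re=r) for r in (1.2, 1.5, 2.0)]
        assert np.all(np.diff(v) < 0)
        v = [self.field_at("temperature", Pr=p) for p in (15.0, 21.0, 25.0)]
        assert np.all(np.diff(v) < 0)

    def test_velocity_rises_with_grashof_and_pressure(self):
        v = [self.field_at("velocity", Gr=g) for g in (2.0, 4.0, 6.0)]
        assert np.all(np.diff(v) > 0)
        v = [self.field_at("velocity", G=g) for g in (0.0, 2.0, 4.0)]
        assert np.all(np.diff(v) > 0)

    def test_velocity_falls_with_couple_stress(self):
        v = [self.field_at("velocity", lam=l) for l in (1.0, 3.0, 5.0)]
        assert np.all(np.diff(v) < 0)

    def test_velocity_falls_with_reynolds_and_prandtl(self):
        v = [self.field_at("velocity", Re=r) for r in (1.2, 1.5, 2.0)]
        assert np.all(np.diff(v) < 0)
        v = [self.field_at("velocity", Pr=p) for p in (15.0, 21.0, 25.0)]
        assert np.all(np.diff(v) < 0)


class TestFieldProfileIO:
    def test_csv_round_trip_and_determinism(self, tmp_path, baseline):
        _, params = baseline
        prof = tf.temperature_profile(params, 1.0, np.linspace(0, 1, 11))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        prof.to_csv(p1)
        prof.to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = tf.FieldProfile.from_csv(p1)
        assert back.field_kind == "temperature"
        assert back.tau == 1.0
        assert back.values == pytest.approx(prof.values, rel=1e-11)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            tf.FieldProfile(np.array([-0.1, 0.5]), np.array([1.0, 1.0]),
                            1.0, "temperature")
        with pytest.raises(ValueError):
            tf.FieldProfile(np.array([0.0, 0.5]), np.array([np.nan, 1.0]),
                            1.0, "temperature")
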