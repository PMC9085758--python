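"""Embedded Euler/midpoint pair and the adaptive error controller."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from mesocell.integrator import (ControllerConfig, ErrorController,
                                 IntegrationError, Simulation, local_error,
                                 midpoint_step, module_error, observed_order)
from mesocell.kinetics import MassActionReaction
from mesocell.state import StateLayout


def decay_rhs(t, y):
    return -y


class TestMidpointStep:
    def test_constant_derivative_has_zero_local_error(self):
        d1, d2 = midpoint_step(np.array([1.0]), lambda t, y: np.array([3.0]),
                               0.25)
        assert d1 == pytest.approx(d2)
        assert module_error(d1, d2) == -np.inf

    def test_exponential_decay_hand_value(self):
        # dc/dt=-c, c=1, dt=0.1: midpoint delta = 0.1*(-(1-0.05)) = -0.095
        d1, d2 = midpoint_step(np.array([1.0]), decay_rhs, 0.1)
        assert d1[0] == pytest.approx(-0.1)
        assert d2[0] == pytest.approx(-0.095)

    def test_observed_convergence_order_is_two(self):
        def integrate(dt, T=1.0):
            y, t = np.array([1.0]), 0.0
            while t < T - 1e-12:
                h = min(dt, T - t)
                _, d2 = midpoint_step(y, decay_rhs, h, t)
                y = y + d2
                t += h
            return y[0]

        p = observed_order(integrate(0.02), integrate(0.01), integrate(0.005))
        assert 1.9 <= p <= 2.1

    def test_non_finite_rhs_rejected(self):
        with pytest.raises(FloatingPointError):
            midpoint_step(np.array([1.0]),
                          lambda t, y: np.array([np.nan]), 0.1)


class TestLocalError:
    def test_equal_deltas_score_minus_infinity(self):
        assert local_error(np.array([0.5]), np.array([0.5]))[0] == -np.inf

    def test_five_percent_pair_scores_log_of_005(self):
        # |1.05-1.00|/1.00 = 5%: exactly at the tau = log10(0.05) threshold
        e = local_error(np.array([1.05]), np.array([1.00]))[0]
        assert e == pytest.approx(np.log10(0.05), abs=1e-12)

    def test_lost_delta_scores_plus_infinity(self):
        assert local_error(np.array([1.0]), np.array([0.0]))[0] == np.inf

    def test_module_error_equals_brute_force_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            d1 = rng.normal(size=40)
            d2 = rng.normal(size=40)
            want = np.max([np.log10(abs(a - b) / abs(b))
                           for a, b in zip(d1, d2)])
            assert module_error(d1, d2) == pytest.approx(want)
        # fast path agrees with the elementwise reference on mixed floors
        d1 = np.array([1e-9, 2.0, 0.5])
        d2 = np.array([2e-9, 1.9, 0.5])
        assert module_error(d1, d2, floor=1e-6) == pytest.approx(
            float(np.max(local_error(d1, d2, floor=1e-6))))


class TestController:
    def test_step_increase_bound_is_two_and_a_half_percent(self):
        ctl = ErrorController(ControllerConfig())   # tau=log10(0.05), theta=0.5
        assert ctl.increase_bound() == pytest.approx(0.025)
        assert ctl.local_bound() == pytest.approx(0.05)

    def test_error_above_threshold_forces_retry_at_half_dt(self):
        lay = StateLayout()
        lay.add("A", 1)
        lay.add("B", 1)
        # k=1000: at dt_init=1e-3 the relative local error is ~50% >> 5%
        mods = [MassActionReaction("f", lay, 1000.0, [(0, 1)], [(1, 1)])]
        sim = Simulation(lay, np.array([1.0, 0.0]), mods,
                         ErrorController(ControllerConfig(dt_init=1e-3)))
        dt_taken = sim.step()
        assert dt_taken < 1e-3
        assert sim.controller.n_rejected > 0

    def test_all_perfect_errors_accept_and_increase(self):
        lay = StateLayout()
        lay.add("A", 1)
        sim = Simulation(lay, np.array([1.0]), [],
                         ErrorController(ControllerConfig(dt_init=1e-3)))
        sim.step()
        assert sim.controller.dt == pytest.approx(2e-3)

    def test_dt_underflow_aborts_naming_module(self):
        lay = StateLayout()
        lay.add("A", 1)

        class Bad:
            name = "pathological"
            calls = 0

            def rhs(self, t, y):
                # alternating sign: Euler and midpoint never agree,
                # whatever the step size
                self.calls += 1
                return np.array([1.0 if self.calls % 2 else -1.0])

        cfg = ControllerConfig(dt_init=1e-3, dt_min=1e-6)
        sim = Simulation(lay, np.array([1.0]), [Bad()], ErrorController(cfg))
        with pytest.raises(IntegrationError, match="pathological"):
            for _ in range(200):
                sim.step()

    def test_stiff_pair_never_exceeds_five_percent_local_error(self):
        lay = StateLayout()
        lay.add("A", 1)
        lay.add("B", 1)
        mods = [MassActionReaction("f", lay, 1000.0, [(0, 1)], [(1, 1)]),
                MassActionReaction("b", lay, 1000.0, [(1, 1)], [(0, 1)])]
        sim = Simulation(lay, np.array([1.0, 0.0]), mods,
                         ErrorController(ControllerConfig(dt_init=1e-5)))
        sim.run_until(0.05)
        assert sim.controller.max_accepted_local_rel <= 0.05
        assert sim.controller.n_accepted > 100

    def test_stiff_trajectory_matches_reference_solver(self):
        """Accepted adaptive trajectory of the stiff reversible pair agrees
        with a tight-tolerance reference integration to <5%."""
        lay = StateLayout()
        lay.add("A", 1)
        lay.add("B", 1)
        k1, k2 = 1000.0, 1000.0
        mods = [MassActionReaction("f", lay, k1, [(0, 1)], [(1, 1)]),
                MassActionReaction("b", lay, k2, [(1, 1)], [(0, 1)])]
        sim = Simulation(lay, np.array([1.0, 0.0]), mods,
                         ErrorController(ControllerConfig(dt_init=1e-6)))
        checkpoints = [2e-4, 1e-3, 5e-3, 0.02]
        ref = solve_ivp(lambda t, y: np.array([-k1 * y[0] + k2 * y[1],
                                               k1 * y[0] - k2 * y[1]]),
                        (0, 0.02), [1.0, 0.0], method="LSODA",
                        rtol=1e-10, atol=1e-12, t_eval=checkpoints)
        for t_stop, want in zip(checkpoints, ref.y.T):
            sim.run_until(t_stop)
            assert sim.y == pytest.approx(want, rel=0.05)

    def test_controller_is_deterministic(self):
        def make():
            lay = StateLayout()
            lay.add("A", 1)
            lay.add("B", 1)
            mods = [MassActionReaction("f", lay, 50.0, [(0, 1)], [(1, 1)]),
                    MassActionReaction("b", lay, 10.0, [(1, 1)], [(0, 1)])]
            sim = Simulation(lay, np.array([1.0, 0.0]), mods,
                             ErrorController(ControllerConfig(dt_init=1e-4)))
            sim.run_until(1.0)
            return [dt for _, dt, _, _ in sim.step_log], sim.y

        (dts1, y1), (dts2, y2) = make(), make()
        assert dts1 == dts2
        assert np.array_equal(y1, y2)

    def test_total_error_skip_rearms_after_increase(self):
        ctl = ErrorController(ControllerConfig())
        ctl.record_total(0.0)           # negligible: skipping engages
        assert ctl.skip_total
        assert not ctl.total_due()
        ctl.steps_since_reject = 10 ** 9
        ctl.maybe_increase(True)        # a step increase re-arms the pass
        assert not ctl.skip_total
        assert ctl.total_due()

    def test_total_error_backup_interval_forces_reevaluation(self):
        ctl = ErrorController(ControllerConfig(backup_interval=10))
        ctl.record_total(0.0)
        ctl.steps_since_total = 11
        assert ctl.total_due()
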