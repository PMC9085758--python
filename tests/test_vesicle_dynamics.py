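"""Brownian motion, filament transport, state changes, pits, and fusion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mesocell.agents import Filament, Vesicle
from mesocell.integrator import ControllerConfig, ErrorController, Simulation
from mesocell.space import Membrane, Region, SimulationSpace
from mesocell.state import StateLayout
from mesocell.vesicle_dynamics import (BoostSpec, EndocytosisManager,
                                       EndocytosisParams, FusionManager,
                                       FusionParams, MotorSpec,
                                       StateChangeSpec, VesicleEngine,
                                       brownian_displacement,
                                       cargo_addition_rate, filament_advance,
                                       snare_pair_count)


class TestBrownian:
    def test_zero_diffusivity_means_no_motion(self):
        dp = brownian_displacement(0.0, 0.1, np.array([1.3, -0.7]))
        assert np.all(dp == 0.0)

    def test_ensemble_msd_recovers_diffusivity(self):
        # vesicles diffuse at 0.13 um^2/s; MSD/(4 dt) estimates D within 3 SE
        rng = np.random.default_rng(42)
        D, dt, n = 0.13, 0.1, 10 ** 4
        xi = rng.standard_normal((n, 2))
        msd = (brownian_displacement(D, dt, xi.T) ** 2).sum(axis=0)
        D_hat = msd.mean() / (4 * dt)
        se = msd.std(ddof=1) / math.sqrt(n) / (4 * dt)
        assert abs(D_hat - D) <= 3 * se

    def test_fixed_seed_reproduces_trajectory_bitwise(self):
        def trajectory():
            space = SimulationSpace(np.zeros((8, 8), int), [Region("c")], 1.0)
            cfg = ControllerConfig(dt_init=0.01, dt_max=0.05)
            eng = VesicleEngine(space, cfg, seed=5, brownian_D=0.13)
            for k in range(6):
                eng.add_vesicle(Vesicle(-1, [1.5 + k, 4.0], 0.3))
            lay = StateLayout()
            lay.add("x", 1)
            sim = Simulation(lay, lay.zeros(), [], ErrorController(cfg),
                             agents=eng)
            sim.run_until(2.0)
            return np.array([eng.vesicles[k].position for k in
                             sorted(eng.vesicles)])

        assert np.array_equal(trajectory(), trajectory())


class TestFilamentTransport:
    def test_advance_along_straight_filament(self):
        f = Filament([(0, 0), (10, 0)])
        pos, seg = filament_advance(f, 0, np.array([2.0, 0.0]), 0.08, True)
        assert pos == pytest.approx([2.08, 0.0])
        assert seg == 0

    def test_rollover_at_vertex(self):
        f = Filament([(0, 0), (1, 0), (1, 1)])
        pos, seg = filament_advance(f, 0, np.array([0.9, 0.0]), 0.3, True)
        assert pos == pytest.approx([1.0, 0.2])
        assert seg == 1

    def test_end_of_filament_signals_detach(self):
        f = Filament([(0, 0), (1, 0)])
        pos, seg = filament_advance(f, 0, np.array([0.9, 0.0]), 0.5, True)
        assert seg is None
        assert pos == pytest.approx([1.0, 0.0])


class TestCargoRate:
    def test_limits_of_the_regulated_rate(self):
        assert cargo_addition_rate(1.0, 0.0, 2.0) == pytest.approx(2.0)
        assert cargo_addition_rate(0.5, 0.5, 2.0) == pytest.approx(1.0)
        assert cargo_addition_rate(0.0, 1.0, 2.0) == pytest.approx(0.0)
        assert cargo_addition_rate(0.0, 0.0, 2.0) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 10), st.floats(0, 10), st.floats(0.01, 5))
    def test_rate_bounded_and_monotone(self, cat, inh, kb):
        k = cargo_addition_rate(cat, inh, kb)
        assert 0.0 <= k <= kb
        assert cargo_addition_rate(cat + 1, inh, kb) >= k
        assert cargo_addition_rate(cat, inh + 1, kb) <= k


def make_patch(ds=0.1, n_faces=20):
    ids = np.zeros((2, n_faces), int)
    ids[0, :] = 1
    space = SimulationSpace(ids, [Region("out"), Region("in")], ds)
    mem = space.add_membrane("apical")
    return space, mem


class TestEndocytosis:
    def params(self, **kw):
        base = dict(k_p=1.0, k_b=2.0, t_cp=5.0, c_cp=1.0, t_m=3.0,
                    cargo_entity="AQP2", vesicle_radius=0.05)
        base.update(kw)
        return EndocytosisParams(**base)

    def test_pit_matures_after_checkpoint_plus_maturation(self):
        space, mem = make_patch()
        mem.set_uniform("AQP2", 50.0)
        mgr = EndocytosisManager(mem, self.params(),
                                 np.random.default_rng(0), space)
        t, dt = 0.0, 0.1
        vesicles = []
        while t < 20.0 and not vesicles:
            vesicles = mgr.step(t, dt)
            t += dt
        assert vesicles, "no pit matured"
        assert mgr.lifetimes_productive[0] >= mgr.p.t_m
        v = vesicles[0]
        assert v.membrane["AQP2"] >= mgr.p.c_cp

    def test_abortive_pit_returns_all_cargo(self):
        space, mem = make_patch()
        mem.set_uniform("AQP2", 0.05)    # far too little to reach c_cp
        total0 = mem.total_amount("AQP2")
        mgr = EndocytosisManager(mem, self.params(),
                                 np.random.default_rng(1), space)
        t, dt = 0.0, 0.1
        while t < 12.0:
            assert not mgr.step(t, dt)
            t += dt
        assert mgr.lifetimes_abortive, "expected aborts"
        assert all(life <= mgr.p.t_cp + dt + 1e-9
                   for life in mgr.lifetimes_abortive)
        # conservation: membrane + outstanding pit cargo equals the start
        drained = sum(p.cargo.get("AQP2", 0.0) for p in mgr.pits)
        assert mem.total_amount("AQP2") + drained == pytest.approx(
            total0, rel=1e-12)

    def test_absorption_never_exceeds_available_cargo(self):
        space, mem = make_patch()
        mem.set_uniform("AQP2", 1e-3)
        mgr = EndocytosisManager(mem, self.params(k_b=1e6),
                                 np.random.default_rng(2), space)
        for k in range(50):
            mgr.step(k * 0.1, 0.1)
            assert np.all(mem.conc("AQP2") >= -1e-15)


class TestFusion:
    def setup(self):
        pass

    def make(self, rsnare, qsnare=10.0, n_p=3):
        space, mem = make_patch(ds=0.5, n_faces=6)
        mem.set_uniform("QSNARE", qsnare)
        params = FusionParams(t_f=1.0, d_a=0.2, n_p=n_p)
        mgr = FusionManager(mem, params, space)
        v = Vesicle(7, [1.5, 0.55], 0.05, state="tethered",
                    membrane={"RSNARE": rsnare, "AQP2": 4.0})
        return mgr, mem, v

    def test_too_few_rsnares_block_initiation(self):
        # 2 R-SNARE molecules < n_p = 3: gating refuses fusion
        area = 4 * math.pi * 0.05 ** 2
        density_two = 2.0 / (area * 602.214076)
        mgr, mem, v = self.make(rsnare=density_two)
        assert snare_pair_count(density_two, area) == 2
        assert not mgr.try_initiate(v, 0.0)

    def test_completed_fusion_conserves_species_amounts(self):
        mgr, mem, v = self.make(rsnare=5.0)
        aqp0 = v.membrane_amount("AQP2") + mem.total_amount("AQP2")
        assert mgr.try_initiate(v, 0.0)
        assert v.state == "fusing"
        removed = mgr.step(1.0, 0.1, {7: v})
        assert removed == [7]
        assert mem.total_amount("AQP2") == pytest.approx(aqp0, rel=1e-12)

    def test_fusion_appears_as_discrete_membrane_jump(self):
        mgr, mem, v = self.make(rsnare=5.0)
        before = mem.conc("AQP2").copy() if mem.conc("AQP2") is not None \
            else np.zeros(mem.n_faces)
        mgr.try_initiate(v, 0.0)
        mgr.step(1.0, 0.1, {7: v})
        after = mem.conc("AQP2")
        assert np.count_nonzero(after - before) == 1
        assert after.max() > 0


class TestStateChanges:
    def test_chance_rule_fires_at_configured_frequency(self):
        # p = f*dt; over many trials the firing rate matches binomially
        space, _ = make_patch()
        cfg = ControllerConfig()
        eng = VesicleEngine(space, cfg, seed=3)
        f, dt, n = 0.5, 0.1, 10 ** 5
        spec = StateChangeSpec(("a",), "b", "chance", value=f)
        v = Vesicle(0, [0.5, 0.1], 0.04, state="a")
        fired = 0
        for _ in range(n):
            v.state = "a"
            if eng._condition_met(v, spec, dt):
                fired += 1
        p_hat = fired / n
        se = math.sqrt(f * dt * (1 - f * dt) / n)
        assert abs(p_hat - f * dt) <= 3 * se

    def test_chance_frequency_above_unity_requests_step_decrease(self):
        space, _ = make_patch()
        cfg = ControllerConfig()
        eng = VesicleEngine(space, cfg, seed=3, state_changes=[
            StateChangeSpec(("a",), "b", "chance", value=100.0)])
        prop = eng.propose(0.0, 0.5)   # f*dt = 50 > 1
        assert prop.needs_decrease
        assert prop.reason == "chance-frequency"

    def test_near_filament_attachment(self):
        space, _ = make_patch(ds=0.5, n_faces=10)
        cfg = ControllerConfig()
        eng = VesicleEngine(space, cfg, seed=1, state_changes=[
            StateChangeSpec(("unattached",), "actin_attached",
                            "near_filament", value=0.05,
                            filament_kind="actin")])
        eng.filaments = [Filament([(0.0, 0.6), (5.0, 0.6)], kind="actin")]
        v = eng.add_vesicle(Vesicle(-1, [2.0, 0.5], 0.06, state="unattached"))
        eng._apply_state_changes(0.0, 0.01)
        assert v.state == "actin_attached"
        assert v.filament is eng.filaments[0]
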