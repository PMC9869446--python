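import math

import numpy as np
import pytest

from hiveforage import (
    Allocation,
    ColonyParams,
    ColonyState,
    ConfigurationError,
    LearningCurveParams,
    SwitchSchedule,
    advance,
    check_feasible,
    simulate,
    step_intake,
)

C0 = 10.0 + 100.0 / (1.0 + math.exp(10.0))  # naive complex reward, defaults


def all_zero(T: int) -> SwitchSchedule:
    return SwitchSchedule.all_simple(T)


def schedule_with(T: int, **at) -> SwitchSchedule:
    m = np.zeros(T)
    for t, v in at.items():
        m[int(t)] = v
    return SwitchSchedule(m)


class TestColonyParams:
    def test_defaults(self, cp_default):
        assert cp_default.n_foragers == 100
        assert cp_default.n_sedentary == 0
        assert cp_default.step_mortality == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [dict(N=0), dict(r=1.0), dict(r=-0.1), dict(q=0.0), dict(T=0),
         dict(survival=0.0), dict(survival=1.5), dict(initial_stores=-1.0)],
    )
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            ColonyParams(**kwargs)

    def test_sedentary_rounding_half_away_from_zero(self):
        assert ColonyParams(N=25, r=0.1).n_sedentary == 3  # 2.5 -> 3
        assert ColonyParams(N=100, r=0.2).n_sedentary == 20

    def test_per_step_hazard_closed_form(self):
        cp = ColonyParams(survival=0.5, T=100)
        assert 1.0 - cp.step_mortality == pytest.approx(0.5 ** (1 / 100), abs=1e-12)

    def test_starvation_precheck(self, lc_default):
        check_feasible(ColonyParams(), lc_default)  # fine: 100*50 >= 100*30
        with pytest.raises(ConfigurationError):
            check_feasible(ColonyParams(r=0.5), lc_default)  # 50*50 < 100*30


class TestStepIntake:
    def test_all_simple(self, cp_default, lc_default):
        state = ColonyState.initial(cp_default)
        a = Allocation(np.zeros_like(state.h))
        assert step_intake(state, a, lc_default) == pytest.approx(5000.0)

    def test_half_naive_complex(self, cp_default, lc_default):
        state = ColonyState.initial(cp_default)
        a = np.zeros_like(state.h)
        a[0] = 50
        expected = 2500.0 + 50.0 * C0
        assert step_intake(state, Allocation(a), lc_default) == pytest.approx(expected)

    def test_empty_colony(self, lc_default):
        state = ColonyState(t=0, h=np.zeros(5), B=0.0)
        assert step_intake(state, Allocation(np.zeros(5)), lc_default) == 0.0

    def test_overallocation_rejected(self, cp_default, lc_default):
        state = ColonyState.initial(cp_default)
        a = np.zeros_like(state.h)
        a[0] = 101
        with pytest.raises(ValueError):
            step_intake(state, Allocation(a), lc_default)


class TestAdvance:
    def test_all_simple_step_from_empty_stores(self, cp_default, lc_default):
        state = ColonyState.initial(cp_default)
        new, intake, feasible = advance(
            state, Allocation(np.zeros_like(state.h)), cp_default, lc_default
        )
        assert feasible and intake == pytest.approx(5000.0)
        assert new.B == pytest.approx(2000.0)
        assert new.t == 1

    def test_no_mortality_preserves_composition(self, cp_default, lc_default):
        state = ColonyState.initial(cp_default)
        a = np.zeros_like(state.h)
        a[0] = 30
        new, _, _ = advance(state, Allocation(a), cp_default, lc_default)
        assert new.h[0] == pytest.approx(70.0)
        assert new.h[1] == pytest.approx(30.0)
        assert new.h.sum() == pytest.approx(cp_default.n_foragers, abs=1e-9)

    def test_expected_mortality_moves_mass_to_naive_bin(self, lc_default):
        cp = ColonyParams(survival=0.5, T=100)
        state = ColonyState.initial(cp)
        a = np.zeros_like(state.h)
        a[0] = 100
        new, _, _ = advance(state, Allocation(a), cp, lc_default)
        retain = 0.5 ** (1 / 100)
        assert new.h[1] == pytest.approx(100.0 * retain)
        assert new.h[0] == pytest.approx(100.0 * (1 - retain))
        assert new.h.sum() == pytest.approx(100.0, abs=1e-9)

    def test_stochastic_mode_reproducible_and_mass_exact(self, lc_default):
        cp = ColonyParams(N=50, survival=0.5, T=10)
        state = ColonyState.initial(cp)
        a = np.zeros_like(state.h)
        a[0] = 20
        out1, _, _ = advance(state, Allocation(a), cp, lc_default,
                             mode="stochastic", rng=np.random.default_rng(5))
        out2, _, _ = advance(state, Allocation(a), cp, lc_default,
                             mode="stochastic", rng=np.random.default_rng(5))
        assert np.array_equal(out1.h, out2.h)
        assert out1.h.sum() == 50.0  # exact in stochastic mode

    def test_no_forgetting(self, lc_default):
        # mass above any experience level never drops faster than mortality
        cp = ColonyParams(N=40, survival=0.7, T=20)
        rng = np.random.default_rng(11)
        state = ColonyState.initial(cp)
        for _ in range(10):
            a = np.floor(state.h * rng.uniform(0, 1, size=state.h.shape))
            new, _, _ = advance(state, Allocation(a), cp, lc_default)
            retain = 1.0 - cp.step_mortality
            for e in range(1, len(state.h)):
                assert new.h[e:].sum() >= retain * state.h[e:].sum() - 1e-9
            state = new


class TestSimulate:
    def test_all_simple_schedule(self, cp_default, lc_default):
        traj = simulate(all_zero(100), cp_default, lc_default)
        assert traj.feasible
        assert traj.final_stores == pytest.approx(200_000.0)
        assert traj.objective == pytest.approx(200_000.0)

    def test_budget_bound_at_step_zero(self, cp_default, lc_default):
        # 51 naive switchers overdraw the stores; 50 just squeak by
        bad = simulate(schedule_with(100, **{"0": 51}), cp_default, lc_default)
        assert not bad.feasible
        assert bad.steps["stores"].iloc[0] == pytest.approx(
            49 * 50.0 + 51 * C0 - 3000.0
        )
        good = simulate(schedule_with(100, **{"0": 50}), cp_default, lc_default)
        assert good.feasible
        assert good.steps["stores"].iloc[0] == pytest.approx(50 * 50.0 + 50 * C0 - 3000.0)

    def test_store_bookkeeping_is_conservative(self, cp_default, lc_default):
        sched = schedule_with(100, **{"0": 30, "5": 10, "40": 20})
        traj = simulate(sched, cp_default, lc_default)
        st = traj.steps
        db = np.diff(st["stores"].to_numpy())
        expected = st["intake"].to_numpy()[1:] - 3000.0
        assert np.allclose(db, expected, atol=1e-9)
        assert st["stores"].iloc[0] == pytest.approx(st["intake"].iloc[0] - 3000.0)

    def test_mass_conservation_under_mortality(self, lc_default):
        cp = ColonyParams(survival=0.4)
        traj = simulate(schedule_with(100, **{"0": 50, "10": 20}), cp, lc_default)
        st = traj.steps
        total = st["n_simple"] + st["n_complex"]
        assert np.allclose(total, cp.n_foragers, atol=1e-9)

    def test_overdrawn_pool_raises(self, cp_default, lc_default):
        with pytest.raises(ValueError, match="unswitched"):
            simulate(schedule_with(100, **{"0": 60, "1": 60}),
                     cp_default, lc_default)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            SwitchSchedule(np.array([-1.0, 0.0]))

    def test_expected_mode_is_mean_of_stochastic(self, lc_default):
        cp = ColonyParams(N=10, T=10, survival=0.6)
        sched = schedule_with(10, **{"0": 3, "2": 1})
        exp = simulate(sched, cp, lc_default, mode="expected")
        reps = [
            simulate(sched, cp, lc_default, mode="stochastic", seed=s)
            for s in range(1000)
        ]
        mc = np.stack([r.steps["n_complex"].to_numpy() for r in reps])
        mean, se = mc.mean(axis=0), mc.std(axis=0) / np.sqrt(len(reps))
        diff = np.abs(mean - exp.steps["n_complex"].to_numpy())
        assert np.all(diff <= 4 * se + 1e-9)
        mc_b = np.stack([r.steps["stores"].to_numpy() for r in reps])
        se_b = mc_b.std(axis=0) / np.sqrt(len(reps))
        assert np.all(
            np.abs(mc_b.mean(axis=0) - exp.steps["stores"].to_numpy())
            <= 4 * se_b + 1e-6
        )

    def test_trajectory_csv_round_trip(self, cp_default, lc_default, tmp_path):
        import pandas as pd

        traj = simulate(schedule_with(100, **{"0": 50}), cp_default, lc_default)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, traj.steps, check_dtype=False)
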