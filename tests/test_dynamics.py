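"""Trajectory integration, catastrophe statistics and protocol battery."""

import numpy as np
import pytest

from nutriredox.model import ContractViolationError, NutrientEnvironment, RedoxState, STATE_NAMES
from nutriredox.dynamics import (
    Trajectory,
    catastrophe_time,
    decline_time,
    run_protocol,
    simulate,
    steady_initial_state,
)


class TestSimulate:
    def test_fixed_point_persists(self, params, env, high_state):
        traj = simulate(high_state, env, params, t_end=1000.0, sampling=50.0,
                        rtol=1e-10, atol=1e-13)
        dev = np.abs(traj.states - high_state.to_array()[None, :])
        rel = dev / np.maximum(np.abs(high_state.to_array()), 1e-6)[None, :]
        assert rel.max() < 1e-6

    def test_sampling_refinement_consistency(self, params, high_state, deprivation):
        sched = deprivation(50.0)
        a = simulate(high_state, sched, params, t_end=60.0, sampling=2.0)
        b = simulate(high_state, sched, params, t_end=60.0, sampling=1.0)
        common = np.isin(b.times, a.times)
        rel = np.abs(b.states[common] - a.states) / np.maximum(np.abs(a.states), 1e-9)
        assert rel.max() < 1e-6

    def test_schedule_switch_times_included_in_samples(self, params, high_state, env):
        sched = NutrientEnvironment(env.glc_ext, env.gln_ext, env.cys2_ext,
                                    schedule=((12.5, 0.0, env.gln_ext, env.cys2_ext),))
        traj = simulate(high_state, sched, params, t_end=30.0, sampling=4.0)
        assert 12.5 in traj.times

    def test_nonnegativity_along_collapse(self, params, high_state, deprivation):
        traj = simulate(high_state, deprivation(0.0), params, t_end=200.0, sampling=1.0)
        assert traj.states.min() > -1e-9


class TestCatastropheTime:
    def test_constant_ros_trajectory_returns_none(self, params, env, high_state):
        traj = simulate(high_state, env, params, t_end=120.0, sampling=5.0)
        assert catastrophe_time(traj) is None

    def test_logistic_inflection_recovered(self, params, env):
        """A ROS time course with known inflection at t*=47 min."""
        times = np.linspace(0.0, 120.0, 241)
        k, t_star = 0.25, 47.0
        ros = 5.0 / (1.0 + np.exp(-k * (times - t_star)))

        class _Injected(Trajectory):
            def ros_rate(self):
                return k * ros * (1.0 - ros / 5.0)  # analytic logistic rate

        states = np.ones((len(times), 10))
        states[:, STATE_NAMES.index("ros")] = ros
        traj = _Injected(times=times, states=states, protocol=env, params=params)
        assert catastrophe_time(traj) == pytest.approx(t_star, abs=0.5)

    def test_catastrophe_times_increase_with_residual_glucose(
            self, params, high_state, deprivation):
        tcs = []
        for g in (0.0, 6.0, 12.0):
            traj = simulate(high_state, deprivation(g), params, t_end=400.0, sampling=1.0)
            tc = catastrophe_time(traj)
            assert tc is not None
            tcs.append(tc)
        assert tcs[0] < tcs[1] < tcs[2]


class TestDeclineTime:
    def test_linear_interpolation_exact(self, params, env):
        times = np.array([0.0, 10.0, 20.0])
        states = np.ones((3, 10))
        i = STATE_NAMES.index("gsh")
        states[:, i] = [100.0, 100.0, 0.0]
        traj = Trajectory(times=times, states=states, protocol=env, params=params)
        # 90% decline -> level 10, crossed linearly between t=10 and t=20
        assert decline_time(traj, "gsh", 0.9) == pytest.approx(19.0)

    def test_monotone_increase_returns_none(self, params, env):
        times = np.linspace(0, 50, 6)
        states = np.ones((6, 10))
        states[:, STATE_NAMES.index("cys2_in")] = np.linspace(1, 10, 6)
        traj = Trajectory(times=times, states=states, protocol=env, params=params)
        assert decline_time(traj, "cys2_in", 0.5) is None

    def test_unknown_species_rejected(self, params, env):
        traj = Trajectory(times=np.array([0.0, 1.0]), states=np.ones((2, 10)),
                          protocol=env, params=params)
        with pytest.raises(ContractViolationError):
            decline_time(traj, "glucose", 0.5)


class TestSteadyInitialState:
    def test_low_branch_absent_above_window(self, params, env):
        with pytest.raises(ContractViolationError, match="high_gsh"):
            steady_initial_state(env, params, branch="low_gsh", n_starts=64)

    def test_both_branches_inside_window(self, params, env):
        e = NutrientEnvironment(30.0, env.gln_ext, env.cys2_ext)
        hi = steady_initial_state(e, params, branch="high_gsh", n_starts=64)
        lo = steady_initial_state(e, params, branch="low_gsh", n_starts=64)
        assert hi.gsh > 5 * lo.gsh


class TestHysteresis:
    def test_branch_membership_depends_on_initial_condition(self, params, env):
        e = NutrientEnvironment(30.0, env.gln_ext, env.cys2_ext)
        hi = steady_initial_state(e, params, branch="high_gsh", n_starts=64)
        lo = steady_initial_state(e, params, branch="low_gsh", n_starts=64)
        for s0 in (hi, lo):
            # 1% multiplicative perturbation must relax back to the same branch
            y = s0.to_array() * 1.01
            y[3] = min(y[3], params.NADP_total * 0.999)
            y[8] = min(y[8], params.PPTase_total * 0.999)
            y[9] = min(y[9], params.TK_total * 0.999)
            traj = simulate(RedoxState.from_array(y), e, params, t_end=500.0,
                            sampling=25.0)
            assert traj.states[-1, 4] == pytest.approx(s0.gsh, rel=0.05)

    def test_addback_protocol_reversal_depends_on_level(self, params, env):
        _, summary = run_protocol("glucose_addback", params, env,
                                  glc_addback=(25.0, 200.0), sampling=2.0)
        by_level = summary.set_index("glc_addback_uM")["reverted"]
        assert not by_level[25.0]   # inside the bistable window: stays oxidized
        assert by_level[200.0]      # above the upper fold: returns to reduced


class TestProtocols:
    def test_unknown_protocol_lists_registry(self, params, env):
        with pytest.raises(ContractViolationError, match="glucose_deprivation"):
            run_protocol("nope", params, env)

    def test_deprivation_summary_rates_anticorrelate_with_catastrophe_time(
            self, params, env):
        _, summary = run_protocol("glucose_deprivation", params, env,
                                  glc_levels=(0.0, 6.0, 12.0), t_end=400.0)
        t = summary["catastrophe_time_min"].astype(float)
        # catastrophe comes earlier the faster NADPH is lost / cystine builds up
        assert np.all(np.diff(t) > 0)
        assert np.all(np.diff(summary["nadph_depletion_rate_uM_per_min"]) < 0)
        assert np.all(np.diff(summary["cys2_accumulation_rate_uM_per_min"]) < 0)

    def test_nadph_pool_drop_thresholds(self, params, env):
        _, summary = run_protocol("nadph_pool", params, env,
                                  totals=(0.05, 0.1, 0.2), t_end=400.0, sampling=2.0)
        flags = summary.set_index("nadp_total_uM")["catastrophe"]
        assert flags[0.05] and flags[0.1]
        assert not flags[0.2]

    def test_enlarged_pool_rescues_deprivation(self, params, env):
        _, summary = run_protocol("nadph_pool", params, env, totals=(1.3,),
                                  deprive=True, t_end=600.0, sampling=2.0)
        assert not summary["catastrophe"].iloc[0]

    def test_cystine_dilution_rescues_but_codilution_does_not(self, params, env):
        _, cys = run_protocol("cystine_titration", params, env, folds=(0.125,),
                              t_end=600.0, sampling=2.0)
        assert cys["rescued"].iloc[0]
        _, co = run_protocol("cys_gln_cotitration", params, env, folds=(0.25,),
                             t_end=600.0, sampling=2.0)
        assert not co["rescued"].iloc[0]

    def test_cystine_fold_accelerates_intracellular_accumulation(
            self, params, high_state, deprivation):
        """Higher extracellular cystine -> faster cystine buildup under
        deprivation (ordering of times to reach a fixed increment)."""
        t_half = []
        for fold in (0.5, 1.0, 2.0):
            traj = simulate(high_state, deprivation(0.0, cys2_fold=fold), params,
                            t_end=150.0, sampling=1.0)
            c = traj.series("cys2_in")
            target = c[0] + 200.0
            idx = np.nonzero(c >= target)[0]
            t_half.append(traj.times[idx[0]] if len(idx) else np.inf)
        assert t_half[0] > t_half[1] > t_half[2]


class TestConservation:
    def test_glutathione_moiety_conserved_without_synthesis_and_degradation(
            self, params, env, high_state):
        p = params.replace(k_gsh_degradation=0.0, k_gsh_production=0.0)
        traj = simulate(high_state, env, p, t_end=1000.0, sampling=100.0,
                        rtol=1e-10, atol=1e-13)
        total = traj.series("gsh") + 2 * traj.series("gssg")
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-6
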