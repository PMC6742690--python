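"""Tests for integration mechanics, dosing impulses and outcome logic."""

import numpy as np
import pytest

from t1dsim import (
    BALBC,
    NOD,
    DoseSchedule,
    ParameterSet,
    StateVector,
    classify_outcome,
    detect_threshold_crossing,
    simulate,
)
from t1dsim.core_model import STATE_NAMES
from t1dsim.simulator import (
    Trajectory,
    equilibrate_initial_state,
    steady_state,
    topp_glucose_equilibrium,
)


def synthetic_glucose_trajectory(times, glucose, params):
    """Sampled-only trajectory with a prescribed glucose time course."""
    states = np.zeros((len(times), 12))
    states[:, STATE_NAMES.index("G")] = glucose
    return Trajectory(times=np.asarray(times, dtype=float), states=states,
                      params=params)


class TestDoseSchedule:
    def test_requires_increasing_times_and_positive_doses(self):
        with pytest.raises(ValueError):
            DoseSchedule([(7.0, 1e5), (7.0, 1e5)])
        with pytest.raises(ValueError):
            DoseSchedule([(7.0, 0.0)])

    def test_warns_outside_studied_range(self):
        with pytest.warns(UserWarning, match="outside the studied range"):
            DoseSchedule([(7.0, 1e8)])

    def test_weekly_fractionation_splits_evenly(self):
        s = DoseSchedule.weekly(28.0, 2e6, n_doses=4)
        assert [t for t, _ in s.events] == [28.0, 35.0, 42.0, 49.0]
        assert all(d == pytest.approx(5e5) for _, d in s.events)


class TestImpulseDosing:
    def test_dose_jump_is_dose_over_qpanc(self, nod_params, nod_init):
        """An injection instantaneously raises tD by dose/Qpanc."""
        dose = 2e5
        t0 = 10.0
        sched = DoseSchedule.single(t0, dose)
        traj = simulate(nod_params, schedule=sched, horizon=12.0,
                        init=nod_init, wave_scale=0.0)
        before = traj.state_at(t0 - 1e-6).tD
        after = traj.state_at(t0 + 1e-6).tD
        # tD drifts at O(1e5 cells/ml/day) around the impulse, so comparing
        # samples 2e-6 days apart carries that much continuous motion
        assert after - before == pytest.approx(dose / nod_params.Qpanc,
                                               rel=1e-4)

    def test_overflow_truncated_to_capacity(self, nod_params, nod_init):
        big = 5e6  # dose/Qpanc far beyond the resident pool
        traj = simulate(nod_params, schedule=DoseSchedule.single(5.0, big),
                        horizon=7.0, init=nod_init, wave_scale=0.0)
        s = traj.state_at(5.0 + 1e-9)
        assert s.D + s.tD <= nod_params.Dss * (1 + 1e-9)
        assert any("truncated" in f for f in traj.flags)

    def test_stop_restart_composition(self, nod_params, nod_init):
        """Dosing mid-run equals integrating to the dose time, adding the
        impulse by hand, and integrating on."""
        dose, t0, t1 = 1e5, 8.0, 20.0
        sched = DoseSchedule.single(t0, dose)
        a = simulate(nod_params, schedule=sched, horizon=t1, init=nod_init,
                     wave_scale=0.0)
        first = simulate(nod_params, horizon=t0, init=nod_init,
                         wave_scale=0.0)
        y = first.states[-1].copy()
        y[STATE_NAMES.index("tD")] += dose / nod_params.Qpanc
        second = simulate(nod_params, horizon=t1 - t0,
                          init=StateVector.from_array(y), wave_scale=0.0,
                          # restarted clock: shift the wave-free system is
                          # time-inhomogeneous only through eta_e and W
                          )
        # compare glucose, the slowest-moving readout, at the horizon
        assert a.state_at(t1).G == pytest.approx(
            second.states[-1][STATE_NAMES.index("G")], rel=5e-3)


class TestSimulateBasics:
    def test_rejects_bad_horizon_and_late_doses(self, nod_params, nod_init):
        with pytest.raises(ValueError):
            simulate(nod_params, horizon=-1.0, init=nod_init)
        with pytest.raises(ValueError):
            simulate(nod_params, schedule=DoseSchedule.single(50.0, 1e5),
                     horizon=40.0, init=nod_init)

    def test_determinism(self, nod_params, nod_init):
        a = simulate(nod_params, horizon=60.0, init=nod_init, wave_scale=0.75)
        b = simulate(nod_params, horizon=60.0, init=nod_init, wave_scale=0.75)
        assert np.array_equal(a.states, b.states)

    def test_trajectory_frame_has_states_and_ratios(self, nod_params,
                                                    nod_init):
        traj = simulate(nod_params, horizon=10.0, init=nod_init)
        df = traj.to_frame()
        assert df.shape[1] == 16  # time + 12 states + 3 ratios
        assert list(df.columns[:2]) == ["time_days", "M"]

    def test_nonnegativity_and_pool_bound_long_run(self, nod_params,
                                                   nod_init):
        """Over 1,000 days no compartment leaves the positive orthant and
        the DC pool stays within its resident capacity."""
        traj = simulate(nod_params, horizon=1000.0, init=nod_init,
                        wave_scale=0.75)
        assert traj.states.min() > -1e-3
        pool = traj["D"] + traj["tD"]
        assert pool.max() <= nod_params.Dss * (1 + 1e-6)


class TestThresholdDetection:
    def test_constant_glucose_never_crosses(self, params):
        traj = synthetic_glucose_trajectory(
            np.arange(0, 100.0), np.full(100, 89.0), params)
        assert detect_threshold_crossing(traj) is None

    def test_known_crossing_located_within_one_step(self, params):
        t = np.arange(0.0, 300.0)
        g = 80.0 + t  # crosses 250 at exactly t = 170
        traj = synthetic_glucose_trajectory(t, g, params)
        assert detect_threshold_crossing(traj) == pytest.approx(170.0 / 7.0,
                                                                abs=1.0 / 7.0)

    def test_downward_crossings_ignored(self, params):
        t = np.arange(0.0, 100.0)
        g = np.full(100, 300.0)
        g[50:] = 100.0  # falls through the threshold, never rises through it
        traj = synthetic_glucose_trajectory(t, g, params)
        assert detect_threshold_crossing(traj) == 0.0  # already diabetic

    def test_dense_refinement_consistent_with_samples(self, nod_params,
                                                      nod_init):
        traj = simulate(nod_params, horizon=300.0, init=nod_init,
                        wave_scale=0.75)
        cross = detect_threshold_crossing(traj)
        if cross is not None:
            i = np.searchsorted(traj.times, cross * 7.0)
            assert traj["G"][max(i - 1, 0)] <= 250.0 <= traj["G"][min(
                i + 1, len(traj.times) - 1)] + 1e-9


class TestOutcomeClassification:
    def test_recovered_episode_is_region_two(self, params):
        t = np.arange(0.0, 701.0)
        g = np.full_like(t, 120.0)
        g[(t > 100) & (t < 200)] = 300.0
        traj = synthetic_glucose_trajectory(t, g, params)
        rec = classify_outcome(traj, eval_time_weeks=100.0)
        assert rec.region == "II"
        assert rec.terminal_glucose < 250.0
        assert rec.first_crossing_weeks == pytest.approx(100.0 / 7.0, abs=0.2)

    def test_terminal_at_threshold_counts_diabetic(self, params):
        t = np.arange(0.0, 701.0)
        g = np.linspace(100.0, 250.0, len(t))
        traj = synthetic_glucose_trajectory(t, g, params)
        assert classify_outcome(traj, eval_time_weeks=100.0).region == "III"

    def test_never_crossing_is_region_one(self, params):
        t = np.arange(0.0, 701.0)
        traj = synthetic_glucose_trajectory(t, np.full_like(t, 89.0), params)
        assert classify_outcome(traj, eval_time_weeks=100.0).region == "I"

    def test_short_horizon_rejected(self, params):
        traj = synthetic_glucose_trajectory(
            np.arange(0.0, 10.0), np.full(10, 89.0), params)
        with pytest.raises(ValueError):
            classify_outcome(traj, eval_time_weeks=52.0)


class TestSteadyStateAndInit:
    def test_metabolic_subsystem_matches_algebraic_root(self, params):
        """With the immune system silenced, the glucose/insulin/β block must
        settle onto the algebraic Topp fixed point."""
        p = params.replace(eta=0.0, Tnaive=0.0, aE=0.0, aR=0.0)
        init = equilibrate_initial_state(p)
        ss, converged = steady_state(p, init=init, wave_scale=0.0)
        G_alg, I_alg = topp_glucose_equilibrium(p, ss.B)
        assert converged
        assert ss.G == pytest.approx(G_alg, rel=1e-6)
        assert ss.I == pytest.approx(I_alg, rel=1e-6)

    def test_equilibrated_init_preserves_beta_mass(self, nod_params):
        init = equilibrate_initial_state(nod_params, B0=2.0)
        assert init.B == 2.0
        assert init.M > 0 and init.G > 0
        init.validate(nod_params.Dss, tol=1e-6)

    def test_grid_refinement_stability(self, nod_params, nod_init):
        """Halving solver tolerances moves the crossing time by < 0.1 day."""
        a = simulate(nod_params, horizon=250.0, init=nod_init,
                     wave_scale=0.75, rtol=1e-8)
        b = simulate(nod_params, horizon=250.0, init=nod_init,
                     wave_scale=0.75, rtol=5e-9)
        ca, cb = (detect_threshold_crossing(x) for x in (a, b))
        if ca is None:
            assert cb is None
        else:
            assert abs(ca - cb) * 7.0 < 0.1
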