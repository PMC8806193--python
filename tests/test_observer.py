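import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from driftbandit.observer import (
    ObserverConfig,
    ObserverState,
    change_point_probability,
    observer_step,
    prediction_error,
    run_observer,
)
from driftbandit.task_env import TaskConfig, generate_session
from driftbandit.linking import LinkingParams, simulate_linked_subject


def oracle_trace(choices, rewards, config):
    """Straight-from-the-equations recomputation of the observer.

    Written independently of the package implementation: a plain loop
    applying, in order, the prediction error, the change-point probability
    likelihood ratio, the adaptive learning rate, the two belief updates,
    the relative-uncertainty recursion, and the predictive variance.
    """
    sn2 = config.sigma_n**2
    E_r = 0.5 * (config.expected_rewards[0] + config.expected_rewards[1])
    lo, hi = config.uniform_support
    H = config.hazard
    B = np.array([E_r, E_r], dtype=float)
    phi = config.phi_init
    sigma_t2 = sn2 + (1 - phi) * sn2 / phi
    rows = []
    for c, r in zip(choices, rewards):
        delta = r - B[c]
        rc = min(max(r, lo), hi)
        U = 1.0 / (hi - lo)
        Nd = np.exp(-((rc - B[c]) ** 2) / (2 * sigma_t2)) / np.sqrt(
            2 * np.pi * sigma_t2
        )
        omega = (U * H) / (U * H + Nd * (1 - H)) if (U * H + Nd * (1 - H)) > 0 else float(H > 0)
        alpha = omega + (1 - omega) * (1 - phi)
        B[c] = B[c] + alpha * delta
        B[1 - c] = B[1 - c] * (1 - omega) + omega * E_r
        num = (
            omega * sn2
            + (1 - omega) * (1 - phi) * sn2
            + omega * (1 - omega) * (delta * phi) ** 2
        )
        RU = num / (num + sn2)
        phi = 1 - RU
        sigma_t2 = sn2 + (1 - phi) * sn2 / phi
        rows.append((B[0], B[1], omega, alpha, delta, phi, sigma_t2))
    return np.array(rows)


class TestPredictionError:
    @pytest.mark.parametrize(
        "r, b, expected", [(3.0, 1.0, 2.0), (2.25, 2.25, 0.0), (0.0, 2.25, -2.25)]
    )
    def test_arithmetic(self, r, b, expected):
        assert prediction_error(r, b) == expected


class TestChangePointProbability:
    def test_degenerate_hazards(self):
        assert change_point_probability(3.0, 2.0, 2.0, 0.0, (0, 6)) == 0.0
        assert change_point_probability(3.0, 2.0, 2.0, 1.0, (0, 6)) == 1.0

    def test_surprising_outcome_flags_change(self):
        # reward six predictive SDs from belief: change is the likelier source
        sigma_t2 = 1.0
        r = 2.0 + 6.0
        omega = change_point_probability(r, 2.0, sigma_t2, 0.04, (0, 16))
        # hand computation of the likelihood ratio
        U = 1 / 16
        Nd = np.exp(-36 / 2) / np.sqrt(2 * np.pi)
        expected = U * 0.04 / (U * 0.04 + Nd * 0.96)
        assert omega == pytest.approx(expected, abs=1e-12)
        assert omega > 0.5

    def test_invalid_hazard(self):
        with pytest.raises(ValueError):
            change_point_probability(3.0, 2.0, 1.0, 1.5, (0, 6))


class TestObserverStep:
    def setup_method(self):
        self.config = ObserverConfig(
            sigma_n=1.0, hazard=0.04, expected_rewards=(2.25, 0.75)
        )

    def test_zero_omega_leaves_unchosen_untouched(self):
        cfg = ObserverConfig(sigma_n=1.0, hazard=0.0, expected_rewards=(2.25, 0.75))
        state = ObserverState.initial(cfg)
        b_u = state.B[1]
        new = observer_step(state, cfg, chosen=0, reward=2.0)
        assert new.omega == 0.0
        assert new.B[1] == b_u

    def test_certain_change_resets_unchosen_and_learning(self):
        cfg = ObserverConfig(sigma_n=1.0, hazard=1.0, expected_rewards=(2.25, 0.75))
        state = ObserverState.initial(cfg)
        new = observer_step(state, cfg, chosen=0, reward=3.0)
        assert new.omega == 1.0
        assert new.alpha_t == 1.0
        assert new.B[1] == cfg.pooled_expected_reward

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(0)
        choices = rng.integers(0, 2, 10)
        rewards = rng.choice([0.0, 2.0, 3.0, 4.0], 10)
        expected = oracle_trace(choices, rewards, self.config)
        state = ObserverState.initial(self.config)
        for t, (c, r) in enumerate(zip(choices, rewards)):
            state = observer_step(state, self.config, int(c), float(r))
            np.testing.assert_allclose(
                [state.B[0], state.B[1], state.omega, state.alpha_t,
                 state.delta, state.phi, state.sigma_t2],
                expected[t],
                atol=1e-12,
                rtol=0,
            )

    def test_oracle_equivalence_many_random_streams(self):
        # the acceptance-level contract at unit scale: exact agreement with
        # the independent recomputation on arbitrary streams
        rng = np.random.default_rng(1)
        for _ in range(20):
            choices = rng.integers(0, 2, 50)
            rewards = rng.uniform(0, 6, 50)
            expected = oracle_trace(choices, rewards, self.config)
            state = ObserverState.initial(self.config)
            got = []
            for c, r in zip(choices, rewards):
                state = observer_step(state, self.config, int(c), float(r))
                got.append(
                    [state.B[0], state.B[1], state.omega, state.alpha_t,
                     state.delta, state.phi, state.sigma_t2]
                )
            np.testing.assert_allclose(got, expected, atol=1e-12, rtol=0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=1),
                st.floats(min_value=-2.0, max_value=10.0, allow_nan=False),
            ),
            min_size=1,
            max_size=40,
        ),
        hazard=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_probability_invariants_on_arbitrary_streams(self, data, hazard):
        cfg = ObserverConfig(
            sigma_n=1.0, hazard=hazard, expected_rewards=(2.25, 0.75)
        )
        state = ObserverState.initial(cfg)
        sn2 = cfg.sigma_n**2
        for c, r in data:
            phi_pre = state.phi
            state = observer_step(state, cfg, c, r)
            for q in (state.omega, state.phi, state.alpha_t, state.RU):
                assert -1e-12 <= q <= 1 + 1e-12
            assert state.sigma_t2 >= sn2 - 1e-12
            # adaptive learning-rate identity (with the confidence that
            # entered the trial) holds exactly
            assert state.alpha_t == state.omega + (1 - state.omega) * (
                1 - phi_pre
            )


class TestRunObserver:
    def test_emits_pre_trial_state(self):
        task = TaskConfig(lambda_mean=25, n_trials=80, seed=3)
        s = generate_session(task)
        s["choice"] = s["optimal_id"].astype(float)
        cfg = ObserverConfig.from_task(task)
        out = run_observer(s, cfg)
        # first row is the initial state: symmetric beliefs, no surprise yet
        assert out["delta_B"].iloc[0] == 0.0
        assert out["omega"].iloc[0] == 0.0

    def test_missing_choice_carries_state_forward(self):
        task = TaskConfig(lambda_mean=25, n_trials=30, seed=4)
        s = generate_session(task)
        s["choice"] = s["optimal_id"].astype(float)
        s.loc[10, "choice"] = np.nan
        cfg = ObserverConfig.from_task(task)
        out = run_observer(s, cfg)
        assert out["missing_choice"].iloc[10]
        np.testing.assert_array_equal(
            out.iloc[11][["B0", "B1"]].to_numpy(),
            out.iloc[10][["B0", "B1"]].to_numpy(),
        )

    def test_identical_rewards_converge_without_changes(self):
        import pandas as pd

        n = 200
        s = pd.DataFrame(
            {
                "trial": np.arange(n),
                "optimal_id": 0,
                "is_change_point": False,
                "reward_available_0": True,
                "reward_available_1": True,
                "points": 3,
                "choice": 0.0,
                "rt": 0.5,
                "correct": 1.0,
            }
        )
        cfg = ObserverConfig(sigma_n=1.0, hazard=0.0, expected_rewards=(3.0, 3.0))
        out = run_observer(s, cfg)
        assert (out["omega"] == 0).all()
        assert abs(out["B0"].iloc[-1] - 3.0) < 1e-6

    def test_belief_difference_tracks_change_points(self):
        # peri-change-point averages: delta_B dips at the switch, omega spikes
        task = TaskConfig(
            lambda_mean=25, p_optimal=0.85, n_trials=1500, rt_bounds=(0.1, 2.5)
        )
        obs = ObserverConfig.from_task(task)
        link = LinkingParams(v0=0.5, a0=0.8, beta_v=0.6, beta_a=0.1)
        data = simulate_linked_subject(task, obs, link, np.random.default_rng(6))
        cps = np.flatnonzero(data["is_change_point"].to_numpy())
        cps = cps[(cps > 5) & (cps < len(data) - 5)]
        dB = data["delta_B"].to_numpy()
        om = data["omega"].to_numpy()
        pre = np.mean([dB[c - 1] for c in cps])
        at = np.mean([dB[c + 1] for c in cps])
        assert at < pre  # belief collapses after the contingency switch
        om_spike = np.mean([om[c + 1] for c in cps])
        om_base = np.mean([om[c - 1] for c in cps])
        assert om_spike > om_base  # change-point probability spikes
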