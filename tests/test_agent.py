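"""Hybrid learner: update rules, choice rule, simulation, likelihood."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from metacontrol.agent import (
    BEHAVIOR_COLUMNS,
    ModelParams,
    SessionData,
    choice_probabilities,
    init_agent_state,
    log_likelihood,
    mb_first_stage_values,
    mf_update,
    simulate_agent,
    transition_update,
)
from metacontrol.task import TaskLayout, generate_trial_plan, study2_layout

from _oracles import (
    oracle_loglik_from_table,
    oracle_mf_episode,
    oracle_softmax,
    oracle_transition_episode,
)


def long_stable_layout(n=10_000):
    return TaskLayout("study2", n, n, ("stable",))


class TestInitialization:
    def test_fresh_state(self, s2_layout):
        st_ = init_agent_state(s2_layout)
        assert np.all(st_.q_mf1 == 4.5) and np.all(st_.q_mf2 == 4.5)
        assert np.all(st_.trans == 0.5)
        assert np.all(st_.elig1 == 0) and np.all(st_.elig2 == 0)
        # per (s1, a1) the two planets' probabilities sum to 1 by construction
        assert np.allclose(st_.trans + (1 - st_.trans), 1.0)

    def test_instructed_transitions(self, s2_layout):
        true_map = np.array([[0, 1], [1, 0]])
        st_ = init_agent_state(s2_layout, true_map=true_map)
        assert np.array_equal(st_.trans, np.array([[1.0, 0.0], [0.0, 1.0]]))


class TestMFUpdate:
    def test_zero_learning_rate(self, s2_layout):
        st_ = init_agent_state(s2_layout)
        mf_update(st_, 2, 0, 0, 9.0, 0.0, alpha=0.0, lam=0.5)
        assert np.all(st_.q_mf1 == 4.5) and np.all(st_.q_mf2 == 4.5)

    def test_full_update_reaches_reward(self, s2_layout):
        st_ = init_agent_state(s2_layout)
        mf_update(st_, 2, 0, 0, 9.0, 0.0, alpha=1.0, lam=0.5)
        assert st_.q_mf2[0] == pytest.approx(9.0)  # 4.5 + (9 - 4.5)

    def test_random_episode_matches_replay_oracle(self, s2_layout):
        rng = np.random.default_rng(14)
        episode = [
            (int(rng.integers(2)), int(rng.integers(2)), int(rng.integers(2)),
             int(rng.integers(0, 10)))
            for _ in range(50)
        ]
        alpha, lam = 0.3, 0.6
        st_ = init_agent_state(s2_layout)
        for (s1, a1, s2, r) in episode:
            st_.elig1[:] = 0.0
            st_.elig2[:] = 0.0
            mf_update(st_, 1, s1, a1, 0.0, st_.q_mf2[s2], alpha, lam)
            mf_update(st_, 2, s2, 0, float(r), 0.0, alpha, lam)
        q = oracle_mf_episode(episode, alpha, lam)
        for s in (0, 1):
            for a in (0, 1):
                assert st_.q_mf1[s, a] == pytest.approx(q[("s1", s, a)], abs=1e-12)
        for p in (0, 1):
            assert st_.q_mf2[p] == pytest.approx(q[("s2", p)], abs=1e-12)

    @given(
        alpha=st.floats(0, 1), lam=st.floats(0, 1),
        rewards=st.lists(st.integers(0, 9), min_size=1, max_size=30),
        seed=st.integers(0, 1000),
    )
    def test_values_bounded_by_reward_range(self, alpha, lam, rewards, seed):
        rng = np.random.default_rng(seed)
        st_ = init_agent_state(study2_layout())
        for r in rewards:
            s1, a1, s2 = int(rng.integers(2)), int(rng.integers(2)), int(rng.integers(2))
            st_.elig1[:] = 0.0
            st_.elig2[:] = 0.0
            mf_update(st_, 1, s1, a1, 0.0, st_.q_mf2[s2], alpha, lam)
            mf_update(st_, 2, s2, 0, float(r), 0.0, alpha, lam)
        assert np.all(st_.q_mf1 >= 0) and np.all(st_.q_mf1 <= 9)
        assert np.all(st_.q_mf2 >= 0) and np.all(st_.q_mf2 <= 9)


class TestTransitionUpdate:
    def test_full_rate_pins_observation(self, s2_layout):
        st_ = init_agent_state(s2_layout)
        transition_update(st_, 0, 0, observed_planet=0, eta=1.0, eta_cf=1.0)
        assert st_.trans[0, 0] == 1.0
        assert st_.trans[0, 1] == 0.0  # counterfactual: other action → purple

    def test_zero_rates_leave_state_unchanged(self, s2_layout):
        st_ = init_agent_state(s2_layout)
        transition_update(st_, 1, 0, observed_planet=1, eta=0.0, eta_cf=0.0)
        assert np.all(st_.trans == 0.5)

    def test_half_rate_hand_values(self, s2_layout):
        # 0.5 + 0.5 * (1 - 0.5) = 0.75 for the observed planet, 0.25 complement
        st_ = init_agent_state(s2_layout)
        transition_update(st_, 0, 1, observed_planet=0, eta=0.5, eta_cf=0.0)
        assert st_.trans[0, 1] == pytest.approx(0.75)
        assert 1 - st_.trans[0, 1] == pytest.approx(0.25)

    @given(
        eta=st.floats(0, 1), eta_cf=st.floats(0, 1),
        obs=st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1),
                               st.integers(0, 1)), min_size=1, max_size=40),
    )
    def test_probabilities_stay_normalized(self, eta, eta_cf, obs):
        st_ = init_agent_state(study2_layout())
        for (s1, a1, p) in obs:
            transition_update(st_, s1, a1, p, eta, eta_cf)
        assert np.all(st_.trans >= 0) and np.all(st_.trans <= 1)

    def test_sequence_matches_dict_oracle(self, s2_layout):
        rng = np.random.default_rng(9)
        episode = [
            (int(rng.integers(2)), int(rng.integers(2)), int(rng.integers(2)))
            for _ in range(30)
        ]
        st_ = init_agent_state(s2_layout)
        for (s1, a1, p) in episode:
            transition_update(st_, s1, a1, p, 0.35, 0.2)
        T = oracle_transition_episode(episode, 0.35, 0.2)
        for s in (0, 1):
            for a in (0, 1):
                assert st_.trans[s, a] == pytest.approx(T[(s, a, 0)], abs=1e-12)


class TestModelBasedValues:
    def test_uniform_mixture(self, s2_layout):
        st_ = init_agent_state(s2_layout)
        st_.q_mf2[:] = [3.0, 7.0]
        assert np.allclose(mb_first_stage_values(st_), 5.0)

    def test_deterministic_transition(self, s2_layout):
        st_ = init_agent_state(s2_layout)
        st_.trans[0, 0] = 1.0
        st_.q_mf2[:] = [8.0, 0.0]
        assert mb_first_stage_values(st_)[0, 0] == pytest.approx(8.0)

    def test_random_state_matches_enumeration(self, s2_layout):
        rng = np.random.default_rng(3)
        st_ = init_agent_state(s2_layout)
        st_.trans[:] = rng.random((2, 2))
        st_.q_mf2[:] = rng.uniform(0, 9, 2)
        expected = np.empty((2, 2))
        for s in (0, 1):
            for a in (0, 1):
                expected[s, a] = sum(
                    (st_.trans[s, a] if p == 0 else 1 - st_.trans[s, a])
                    * st_.q_mf2[p]
                    for p in (0, 1)
                )
        assert np.allclose(mb_first_stage_values(st_), expected, atol=1e-14)


class TestChoiceRule:
    def test_flat_softmax_at_zero_beta(self, s2_layout, s2_params):
        st_ = init_agent_state(s2_layout)
        st_.q_mf1[0] = [9.0, 0.0]
        p = choice_probabilities(
            st_, 0, "low",
            ModelParams(alpha=0.5, beta=0.0, omega={"low": 0.5, "high": 0.5}),
        )
        assert np.allclose(p, 0.5)

    def test_pure_model_based_ignores_cached_values(self, s2_layout):
        params = ModelParams(alpha=0.5, beta=2.0, omega={"low": 1.0, "high": 1.0})
        st_ = init_agent_state(s2_layout)
        st_.trans[0] = [0.9, 0.1]
        st_.q_mf2[:] = [7.0, 2.0]
        p1 = choice_probabilities(st_, 0, "low", params)
        st_.q_mf1[0] = [0.0, 99.0]
        p2 = choice_probabilities(st_, 0, "low", params)
        assert np.allclose(p1, p2)

    def test_unknown_cell_rejected(self, s2_layout, s2_params):
        st_ = init_agent_state(s2_layout)
        with pytest.raises(ValueError):
            choice_probabilities(st_, 0, "no_such_cell", s2_params)

    def test_matches_formula_oracle(self, s2_layout):
        rng = np.random.default_rng(8)
        params = ModelParams(
            alpha=0.5, beta=1.7, omega={"low": 0.35, "high": 0.8}, pi=0.4, rho=-0.6
        )
        for trial in range(20):
            st_ = init_agent_state(s2_layout)
            st_.q_mf1[:] = rng.uniform(0, 9, (2, 2))
            st_.q_mf2[:] = rng.uniform(0, 9, 2)
            st_.trans[:] = rng.random((2, 2))
            s1 = int(rng.integers(2))
            st_.prev_state = int(rng.integers(-1, 2))
            st_.prev_action = int(rng.integers(2)) if st_.prev_state >= 0 else -1
            st_.prev_key = int(rng.integers(-1, 2))
            left = int(rng.integers(2))
            p = choice_probabilities(st_, s1, "high", params, left_action=left)
            rep = [
                1.0 if (st_.prev_state == s1 and st_.prev_action == a) else 0.0
                for a in (0, 1)
            ]
            resp = [
                1.0 if (st_.prev_key >= 0
                        and (0 if a == left else 1) == st_.prev_key) else 0.0
                for a in (0, 1)
            ]
            q_mb = mb_first_stage_values(st_)[s1]
            expected = oracle_softmax(
                st_.q_mf1[s1], q_mb, params.omega["high"], params.beta,
                params.pi, params.rho, rep, resp,
            )
            assert np.allclose(p, expected, atol=1e-12)


class TestSimulation:
    def test_deterministic_given_seed(self, s2_params, s2_plan):
        b1 = simulate_agent(s2_params, s2_plan, seed=5, missing_rate=0.05)
        b2 = simulate_agent(s2_params, s2_plan, seed=5, missing_rate=0.05)
        assert b1.equals(b2)

    def test_flat_policy_choice_frequency(self):
        layout = long_stable_layout()
        plan = generate_trial_plan(layout, 0, seed=2)
        params = ModelParams(alpha=0.5, beta=0.0, omega={"low": 0.5, "high": 0.5})
        beh = simulate_agent(params, plan, seed=6)
        assert abs((beh["a1"] == 0).mean() - 0.5) < 0.02

    def test_planner_beats_baseline(self, s2_plan, s2_layout):
        from metacontrol.metrics import task_performance

        params = ModelParams(alpha=0.7, beta=8.0, omega={"low": 1.0, "high": 1.0})
        beh = simulate_agent(params, s2_plan, seed=9)
        perf = task_performance(beh, s2_plan)
        assert (perf["mean_corrected_reward"] > 0).all()

    def test_points_apply_stakes_multiplier(self, s2_behavior):
        got = s2_behavior[~s2_behavior["missing_stage2"] & (s2_behavior["a1"] >= 0)]
        mult = got["stakes"].map({"low": 1, "high": 5})
        assert (got["points"] == got["reward"] * mult).all()

    def test_layout_mismatch_rejected(self, s2_plan):
        bad = ModelParams(alpha=0.5, beta=1.0, omega={"stable_low": 0.5})
        with pytest.raises(ValueError):
            simulate_agent(bad, s2_plan, seed=0)


class TestLikelihood:
    def test_flat_policy_closed_form(self, s2_behavior, s2_layout):
        params = ModelParams(alpha=0.5, beta=0.0, omega={"low": 0.5, "high": 0.5})
        n_valid = int((s2_behavior["a1"] >= 0).sum())
        ll = log_likelihood(params, s2_behavior, s2_layout)
        assert ll == pytest.approx(n_valid * math.log(0.5), abs=1e-12)

    def test_replay_matches_simulation_engine(self, s2_params, s2_plan, s2_layout):
        beh = simulate_agent(s2_params, s2_plan, seed=13, missing_rate=0.05,
                             record_probs=True)
        ll, trace = log_likelihood(s2_params, beh, s2_layout, return_trace=True)
        recorded = beh["p_choice"].dropna().to_numpy()
        assert np.allclose(trace, recorded, atol=1e-12)
        assert ll == pytest.approx(np.log(recorded).sum(), abs=1e-10)

    @pytest.mark.parametrize("fixture", ["s1", "s2"])
    def test_matches_independent_replay_oracle(self, fixture, request):
        params = request.getfixturevalue(f"{fixture}_params")
        beh = request.getfixturevalue(f"{fixture}_behavior")
        layout = request.getfixturevalue(f"{fixture}_layout")
        ll = log_likelihood(params, beh, layout)
        assert ll == pytest.approx(oracle_loglik_from_table(beh, params, layout),
                                   abs=1e-10)

    def test_two_trial_hand_transcript(self, s2_layout):
        # trial 1: fresh symmetric state → p = 1/2 exactly; updates with
        # alpha = 0.5, lam = 0.5, reward 9 at the red planet give
        # q2[red] = 6.75 and q1[0,0] = 5.625 (trace credit 0.5*0.5*4.5)
        # trial 2: T(red|0,0) = 1 (instructed map), so Q_MB = (6.75, 4.5);
        # with omega = 0.5: v = (6.1875, 4.5); +pi on a0 (repeat), +rho on
        # a0 (same key) → gap 1.9875; choosing a1 has p = 1/(1+e^{0.3*1.9875})
        params = ModelParams(alpha=0.5, beta=0.3, lam=0.5, pi=0.2, rho=0.1,
                             omega={"low": 0.5, "high": 0.5})
        rows = [
            [0, 0, "stable", "low", 0, 0, 0, 0, 9, 9, False, False, 0],
            [1, 0, "stable", "low", 0, 1, 1, 1, 4, 4, False, False, 0],
        ]
        beh = pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS)
        gap = (0.5 * 5.625 + 0.5 * 6.75 + 0.2 + 0.1) - (0.5 * 4.5 + 0.5 * 4.5)
        expected = math.log(0.5) + math.log(1.0 / (1.0 + math.exp(0.3 * gap)))
        ll = log_likelihood(params, beh, s2_layout)
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_likelihood_peaks_near_generating_beta(self, s2_plan, s2_layout):
        truth = ModelParams(alpha=0.5, beta=1.5, omega={"low": 0.3, "high": 0.7})
        worse = truth.copy()
        worse.beta = 4.5
        diffs = []
        for seed in range(30):
            beh = simulate_agent(truth, s2_plan, seed=100 + seed)
            sd = SessionData(beh, s2_layout)
            diffs.append(log_likelihood(truth, sd) - log_likelihood(worse, sd))
        assert np.mean(diffs) > 0

    def test_missing_and_error_handling(self, s2_layout, s2_params):
        with pytest.raises(ValueError):
            log_likelihood(s2_params, pd.DataFrame(columns=BEHAVIOR_COLUMNS),
                           s2_layout)
        bad = s2_params.copy()
        bad.pi = float("nan")
        beh = pd.DataFrame(
            [[0, 0, "stable", "low", 0, 0, 0, 0, 5, 5, False, False, 0],
             [1, 0, "stable", "high", 1, 1, 1, 1, 3, 15, False, False, 0]],
            columns=BEHAVIOR_COLUMNS,
        )
        with pytest.raises(ValueError):
            log_likelihood(bad, beh, s2_layout)


class TestSingleStrategyLimits:
    """omega = 0 is a pure TD learner; omega = 1 a pure planner."""

    def _mf_only_loglik(self, beh, params, layout):
        q1 = np.full((2, 2), 4.5)
        q2 = np.full(2, 4.5)
        prev = (-1, -1, -1)
        ll = 0.0
        for rec in beh.to_dict("records"):
            if rec["a1"] < 0:
                prev = (-1, -1, -1)
                continue
            s1, a1 = rec["s1"], rec["a1"]
            v = q1[s1].astype(float).copy()
            if prev[0] == s1:
                v[prev[1]] += params.pi
            if prev[2] >= 0:
                for a in (0, 1):
                    if (0 if a == rec["left_action"] else 1) == prev[2]:
                        v[a] += params.rho
            x = params.beta * v
            p = np.exp(x - x.max())
            p /= p.sum()
            ll += np.log(p[a1])
            s2 = rec["s2"]
            q1[s1, a1] += params.alpha * (q2[s2] - q1[s1, a1])
            if not rec["missing_stage2"]:
                d2 = rec["reward"] - q2[s2]
                q2[s2] += params.alpha * d2
                q1[s1, a1] += params.alpha * params.lam * d2
            prev = (s1, a1, 0 if a1 == rec["left_action"] else 1)
        return ll

    def test_pure_td_limit(self, s2_plan, s2_layout):
        params = ModelParams(alpha=0.4, beta=1.3, lam=0.7, pi=0.2, rho=0.1,
                             omega={"low": 0.0, "high": 0.0})
        beh = simulate_agent(params, s2_plan, seed=17, missing_rate=0.02)
        assert log_likelihood(params, beh, s2_layout) == pytest.approx(
            self._mf_only_loglik(beh, params, s2_layout), abs=1e-10
        )

    def test_pure_planner_limit(self, s2_plan, s2_layout):
        from metacontrol.agent import infer_static_map

        params = ModelParams(alpha=0.4, beta=1.3, pi=0.0, rho=0.0,
                             omega={"low": 1.0, "high": 1.0})
        beh = simulate_agent(params, s2_plan, seed=18)
        true_map = infer_static_map(beh)
        q2 = np.full(2, 4.5)
        ll = 0.0
        for rec in beh.to_dict("records"):
            s1, a1, s2 = rec["s1"], rec["a1"], rec["s2"]
            v = np.array([q2[true_map[s1, a]] for a in (0, 1)], float)
            x = params.beta * v
            p = np.exp(x - x.max())
            p /= p.sum()
            ll += np.log(p[a1])
            q2[s2] += params.alpha * (rec["reward"] - q2[s2])
        assert log_likelihood(params, beh, s2_layout) == pytest.approx(ll, abs=1e-10)
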