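"""Update rules, policy, reductions, and analytic oracles for the four agents."""

import numpy as np
import pytest

from noisynav import (
    AgentParams,
    analytic_successor,
    chain_1d,
    decay_epsilon,
    epsilon_floor_episode,
    epsilon_greedy,
    make_agent,
    one_hot,
    pf_step,
    q_lambda_update,
    q_update,
    sf_step,
)
from noisynav.agents import decode_observation


class TestEpsilonGreedy:
    def test_pure_greedy(self, rng):
        assert epsilon_greedy([0.1, 0.9], 0.0, rng) == 1

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            epsilon_greedy([], 0.5, rng)
        with pytest.raises(ValueError):
            epsilon_greedy([1.0, 2.0], 1.5, rng)

    def test_uniform_when_fully_random(self, rng):
        n = 100_000
        counts = np.bincount(
            [epsilon_greedy([0.0, 1.0, 2.0], 1.0, rng) for _ in range(n)], minlength=3
        )
        # 3-sigma binomial band around n/3
        sd = np.sqrt(n * (1 / 3) * (2 / 3))
        assert np.all(np.abs(counts - n / 3) < 3 * sd)

    def test_tie_symmetry(self, rng):
        n = 20_000
        picks = np.array([epsilon_greedy([0.5, 0.5], 0.0, rng) for _ in range(n)])
        sd = np.sqrt(n * 0.25)
        assert abs(picks.sum() - n / 2) < 4 * sd

    def test_nan_values_fall_back_to_random(self, rng):
        picks = {epsilon_greedy([np.nan, np.nan], 0.0, rng) for _ in range(50)}
        assert picks == {0, 1}


class TestEpsilonSchedule:
    @pytest.mark.parametrize(
        "eps,expected", [(1.0, 0.99), (0.01, 0.01), (0.012, 0.01188)]
    )
    def test_decay_examples(self, params, eps, expected):
        assert decay_epsilon(eps, params) == pytest.approx(expected)

    def test_monotone_and_floor(self, params):
        eps, seen = params.epsilon0, []
        for _ in range(600):
            seen.append(eps)
            eps = decay_epsilon(eps, params)
        assert all(a >= b for a, b in zip(seen, seen[1:]))
        assert min(seen) == params.epsilon_floor

    def test_floor_reached_at_closed_form_episode(self, params):
        """First floored episode = ceil(log(floor)/log(decay)) + 1 = 460."""
        k = epsilon_floor_episode(params)
        assert k == int(np.ceil(np.log(0.01) / np.log(0.99))) + 1 == 460
        eps = params.epsilon0
        for episode in range(1, 600):
            if eps == params.epsilon_floor:
                assert episode == k
                break
            eps = decay_epsilon(eps, params)
        else:
            pytest.fail("floor never reached")


class TestQUpdates:
    def test_terminal_reward_moves_taken_action(self, params):
        W = np.zeros((2, 20))
        o, o2 = one_hot(3, 20), one_hot(4, 20)
        q_update(W, o, 1, 1.0, o2, True, params)
        assert W[1, 3] == pytest.approx(0.1)
        assert np.count_nonzero(W) == 1

    def test_zero_td_error_leaves_weights(self, params):
        W = np.zeros((2, 20))
        q_update(W, one_hot(3, 20), 0, 0.0, one_hot(4, 20), False, params)
        assert not W.any()

    def test_bootstrap_from_next_max(self, params):
        W = np.zeros((2, 20))
        W[0, 4] = 1.0  # max next value = 1
        q_update(W, one_hot(3, 20), 1, 0.0, one_hot(4, 20), False, params)
        assert W[1, 3] == pytest.approx(0.095)

    def test_shape_mismatch_rejected(self, params):
        with pytest.raises(ValueError):
            q_update(np.zeros((2, 20)), one_hot(3, 19), 0, 0.0, one_hot(4, 19), False, params)

    def test_lambda_zero_reduces_to_q(self, params, rng):
        pl = AgentParams(lam=0.0)
        Wq = np.zeros((2, 20))
        Wl = np.zeros((2, 20))
        trace = np.zeros((2, 20))
        for _ in range(200):
            o = rng.standard_normal(20) * 0.3
            o[rng.randint(20)] += 1
            o2 = rng.standard_normal(20) * 0.3
            o2[rng.randint(20)] += 1
            a = rng.randint(2)
            r = float(rng.rand() < 0.1)
            term = bool(rng.rand() < 0.05)
            q_update(Wq, o, a, r, o2, term, pl)
            q_lambda_update(Wl, trace, o, a, r, o2, term, pl)
            if term:
                trace[:] = 0.0
        assert np.array_equal(Wq, Wl)

    def test_trace_decays_geometrically(self, rng):
        p = AgentParams(lam=0.8)
        W = np.zeros((2, 20))
        e = np.zeros((2, 20))
        o = one_hot(0, 20)
        q_lambda_update(W, e, o, 0, 0.0, one_hot(1, 20), False, p)
        first = e[0, 0]
        for k in range(1, 4):
            q_lambda_update(W, e, one_hot(5 + k, 20), 1, 0.0, one_hot(6 + k, 20), False, p)
            assert e[0, 0] == pytest.approx(first * (p.gamma * p.lam) ** k)

    def test_two_step_chain_credits_earlier_state(self):
        """With a terminal reward, the state two steps back gets ~gamma*lambda credit."""
        p = AgentParams(lam=0.8)
        W = np.zeros((2, 20))
        e = np.zeros((2, 20))
        q_lambda_update(W, e, one_hot(0, 20), 1, 0.0, one_hot(1, 20), False, p)
        q_lambda_update(W, e, one_hot(1, 20), 1, 1.0, one_hot(2, 20), True, p)
        # delta at the final step is 1; trace carries gamma*lambda for state 0
        assert W[1, 1] == pytest.approx(p.alpha * 1.0)
        assert W[1, 0] == pytest.approx(p.alpha * 1.0 * p.gamma * p.lam)


class TestSFUpdates:
    def test_zero_init_self_occupancy(self, params):
        W = np.zeros((2, 20, 20))
        w_r = np.zeros(20)
        sf_step(W, w_r, one_hot(3, 20), 1, 0.0, one_hot(4, 20), False, params)
        assert W[1, 3, 3] == pytest.approx(0.1)  # delta = phi(s), outer with phi(s)
        assert np.count_nonzero(W) == 1

    def test_reward_weight_delta_rule(self, params):
        W = np.zeros((2, 20, 20))
        w_r = np.zeros(20)
        sf_step(W, w_r, one_hot(18, 20), 1, 1.0, one_hot(19, 20), True, params)
        assert w_r[19] == pytest.approx(0.1)

    def test_pf_lambda_zero_identical_to_sf(self, rng):
        p = AgentParams(lam=0.0)
        W1 = np.zeros((2, 20, 20)); wr1 = np.zeros(20)
        W2 = np.zeros((2, 20, 20)); wr2 = np.zeros(20)
        trace = np.zeros(20)
        for _ in range(200):
            o = rng.standard_normal(20) * 0.3
            o[rng.randint(20)] += 1
            o2 = rng.standard_normal(20) * 0.3
            o2[rng.randint(20)] += 1
            a = rng.randint(2)
            r = float(rng.rand() < 0.1)
            term = bool(rng.rand() < 0.05)
            sf_step(W1, wr1, o, a, r, o2, term, p)
            pf_step(W2, wr2, trace, o, a, r, o2, term, p)
            if term:
                trace[:] = 0.0
        assert np.array_equal(W1, W2) and np.array_equal(wr1, wr2)

    def test_pf_credits_predecessor_column(self):
        """Visiting s0 then s1: the update at s1 touches column s0 at weight
        gamma*lambda relative to column s1."""
        p = AgentParams(lam=0.8)
        W = np.zeros((2, 20, 20)); w_r = np.zeros(20)
        trace = np.zeros(20)
        pf_step(W, w_r, trace, one_hot(0, 20), 1, 0.0, one_hot(1, 20), False, p)
        W_before = W.copy()
        pf_step(W, w_r, trace, one_hot(1, 20), 1, 0.0, one_hot(2, 20), False, p)
        upd = W[1] - W_before[1]
        col1 = upd[:, 1]
        col0 = upd[:, 0]
        assert np.allclose(col0, p.gamma * p.lam * col1)
        assert col1[1] != 0.0

    def test_pf_trace_geometric_bound(self):
        p = AgentParams(lam=0.9)
        W = np.zeros((2, 20, 20)); w_r = np.zeros(20)
        trace = np.zeros(20)
        k = 15
        for i in range(k):
            pf_step(W, w_r, trace, one_hot(i, 20), 1, 0.0, one_hot(i + 1, 20), False, p)
        bound = sum((p.gamma * p.lam) ** i for i in range(k))
        assert trace.sum() <= bound + 1e-12

    def test_frozen_policy_matches_analytic_occupancy(self, chain, params):
        """sigma=0, always-right policy: learned psi rows -> (I - gamma P)^-1.

        P is the policy's transition matrix with the terminal (goal) row
        zeroed; comparison on visited states, sup-norm < 0.05.
        """
        dim = chain.observation_dim
        W = np.zeros((2, dim, dim)); w_r = np.zeros(dim)
        for _ in range(2000):
            for s in range(dim - 1):
                terminal = s + 1 == chain.goal_index
                sf_step(
                    W, w_r,
                    one_hot(s, dim), 1, float(terminal), one_hot(s + 1, dim),
                    terminal, params, next_action=1,
                )
        P = np.zeros((dim, dim))
        for s in range(dim - 1):
            P[s, s + 1] = 1.0
        M = analytic_successor(P, params.gamma)
        learned = np.array([W[1] @ one_hot(s, dim) for s in range(dim - 1)])
        assert np.abs(learned - M[: dim - 1]).max() < 0.05

    def test_reward_weights_recover_goal_vector(self, chain, params):
        """sigma=0: w_r converges entrywise to the true reward one-hot."""
        dim = chain.observation_dim
        W = np.zeros((2, dim, dim)); w_r = np.zeros(dim)
        for _ in range(200):
            for s in range(dim - 1):
                terminal = s + 1 == chain.goal_index
                sf_step(W, w_r, one_hot(s, dim), 1, float(terminal),
                        one_hot(s + 1, dim), terminal, params)
        target = one_hot(chain.goal_index, dim)
        assert np.abs(w_r - target).max() < 0.01


class TestActionValuesAndAgents:
    def test_zero_weights_zero_values(self, params):
        agent = make_agent("sf", params, 2, 20)
        assert np.array_equal(agent.action_values(one_hot(3, 20)), np.zeros(2))

    def test_identity_composition(self, params):
        agent = make_agent("sf", params, 2, 20, observation_mode="linear")
        agent.W[:] = np.eye(20)
        agent.w_r[:] = one_hot(19, 20)
        o = np.linspace(0, 1, 20)
        assert np.allclose(agent.action_values(o), o[19])

    def test_decoded_percept_is_ml_estimate(self):
        o = np.array([0.2, 1.3, -0.1, 0.9])
        assert np.array_equal(decode_observation(o), [0.0, 1.0, 0.0, 0.0])

    def test_default_observation_modes(self, params):
        assert make_agent("q", params, 2, 20).observation_mode == "linear"
        assert make_agent("q_lambda", params, 2, 20).observation_mode == "linear"
        assert make_agent("sf", params, 2, 20).observation_mode == "decoded"
        assert make_agent("pf", params, 2, 20).observation_mode == "decoded"

    def test_invalid_kind_and_mode_rejected(self, params):
        with pytest.raises(ValueError):
            make_agent("dyna", params, 2, 20)
        with pytest.raises(ValueError):
            make_agent("q", params, 2, 20, observation_mode="fuzzy")

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            AgentParams(alpha=0.0)
        with pytest.raises(ValueError):
            AgentParams(gamma=1.0)
        with pytest.raises(ValueError):
            AgentParams(lam=1.5)
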