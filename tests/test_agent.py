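"""The offline discrete-action DDPG agent: network contracts, gradient
correctness, TD targets, soft updates, training behavior, and policy
recommendation."""

import numpy as np
import pytest

from sepsisrl import nn
from sepsisrl.agent import (
    Actor,
    AgentConfig,
    DuelingCritic,
    Networks,
    PolicyArtifact,
    init_networks,
    one_hot,
    recommend,
    td_target,
    train,
)
from sepsisrl.errors import ContractError, TrainingError
from tests.toy_mdp import STATES, toy_agent_config, toy_pool, value_iteration

SMALL = AgentConfig(state_dim=6, n_actions=4, hidden_sizes=(8, 8), seed=0)


def _params_equal(a, b):
    return all(np.array_equal(x, y) for x, y in zip(a, b))


class TestInitialization:
    def test_targets_start_equal_to_online(self):
        nets = init_networks(SMALL)
        assert _params_equal(nets.actor.parameters(), nets.actor_target.parameters())
        assert _params_equal(nets.critic.parameters(), nets.critic_target.parameters())

    def test_seeded_init_reproducible(self):
        a = init_networks(SMALL)
        b = init_networks(SMALL)
        assert _params_equal(a.actor.parameters(), b.actor.parameters())
        assert _params_equal(a.critic.parameters(), b.critic.parameters())

    def test_critic_signature(self):
        nets = init_networks(SMALL)
        q = nets.critic.forward(np.zeros((3, 6)), one_hot(np.array([0, 1, 2]), 4))
        assert q.shape == (3,)
        with pytest.raises(ContractError):
            nets.critic.forward(np.zeros((3, 6)), np.zeros((3, 5)))


class TestActor:
    def test_probabilities_normalized(self):
        actor = init_networks(SMALL).actor
        probs = actor.forward(np.random.default_rng(0).normal(size=(5, 6)))
        assert (probs >= 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_uniform_logits_break_ties_to_zero(self):
        actor = init_networks(SMALL).actor
        final = actor.net.linears()[-1]
        final.W[...] = 0.0
        final.b[...] = 0.0
        assert (actor.greedy(np.random.default_rng(1).normal(size=(4, 6))) == 0).all()

    def test_greedy_deterministic(self):
        actor = init_networks(SMALL).actor
        s = np.random.default_rng(2).normal(size=(3, 6))
        np.testing.assert_array_equal(actor.greedy(s), actor.greedy(s))

    def test_non_finite_state_rejected(self):
        actor = init_networks(SMALL).actor
        bad = np.full((1, 6), np.nan)
        with pytest.raises(ContractError):
            actor.forward(bad)


class TestDuelingCombination:
    def test_constant_advantage_shift_leaves_q_unchanged(self):
        critic = init_networks(SMALL).critic
        s = np.random.default_rng(3).normal(size=(4, 6))
        a = one_hot(np.array([0, 1, 2, 3]), 4)
        q0 = critic.forward(s, a)
        critic.a_head.b += 7.5  # uniform shift across all advantage outputs
        np.testing.assert_allclose(critic.forward(s, a), q0, atol=1e-10)

    def test_zero_advantage_stream_gives_v(self):
        critic = init_networks(SMALL).critic
        for lin in critic.a_stream.linears():
            lin.W[...] = 0.0
            lin.b[...] = 0.0
        s = np.random.default_rng(4).normal(size=(3, 6))
        t = critic.shared.forward(s)
        v = critic.v_stream.forward(t)[:, 0]
        for action in range(4):
            q = critic.forward(s, one_hot(np.full(3, action), 4))
            np.testing.assert_allclose(q, v, atol=1e-12)

    def test_stub_network_arithmetic(self):
        critic = init_networks(SMALL).critic
        # force V(s) = 1 and A(s, .) = [1, 2, 3, 4] for every state
        for stream in (critic.v_stream, critic.a_stream):
            for lin in stream.linears():
                lin.W[...] = 0.0
                lin.b[...] = 0.0
        critic.v_stream.linears()[-1].b[...] = 1.0
        adv = np.array([1.0, 2.0, 3.0, 4.0])
        critic.a_stream.linears()[-1].b[...] = adv
        q = critic.forward(np.zeros((1, 6)), one_hot(np.array([2]), 4))
        assert q[0] == pytest.approx(1.0 + 3.0 - adv.mean())


class TestGradients:
    def _check(self, loss_fn, param_layers, grads_computed, rng):
        for lin in param_layers:
            for p, g in zip(lin.params(), lin.grads()):
                for _ in range(6):
                    idx = tuple(rng.integers(0, s) for s in p.shape) if p.ndim else ()
                    eps = 1e-6
                    old = p[idx]
                    p[idx] = old + eps
                    lp = loss_fn()
                    p[idx] = old - eps
                    lm = loss_fn()
                    p[idx] = old
                    numeric = (lp - lm) / (2 * eps)
                    assert numeric == pytest.approx(g[idx], rel=1e-4, abs=1e-8)

    def test_critic_backward_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        critic = DuelingCritic(SMALL, rng)
        S = rng.normal(size=(5, 6))
        A = one_hot(rng.integers(0, 4, 5), 4)
        y = rng.normal(size=5)

        def loss():
            return float(np.mean((critic.forward(S, A) - y) ** 2))

        q = critic.forward(S, A)
        critic.backward(2 * (q - y) / 5)
        self._check(loss, critic.linears(), None, rng)

    def test_actor_backward_matches_finite_differences(self):
        rng = np.random.default_rng(6)
        actor = Actor(SMALL, rng)
        S = rng.normal(size=(5, 6))
        adv = rng.normal(size=(5, 4))
        beta = 0.5

        def loss():
            pr = actor.forward(S)
            return float(
                np.mean(-(adv * pr).sum(axis=1))
                + beta * np.mean((pr * np.log(pr)).sum(axis=1))
            )

        pr = actor.forward(S)
        actor.backward_from_probs(-adv / 5 + beta * (np.log(pr) + 1) / 5)
        self._check(loss, actor.linears(), None, rng)


class TestTdTarget:
    def _batch(self, n=4, dim=6):
        rng = np.random.default_rng(7)
        return (
            rng.normal(size=n),  # rewards
            rng.normal(size=(n, dim)),  # next states
            rng.integers(0, 4, n),  # next actions
        )

    def test_done_masks_bootstrap(self):
        r, s2, a2 = self._batch()
        nets = init_networks(SMALL)
        y = td_target(r, s2, a2, np.ones(4, dtype=bool), nets, SMALL)
        np.testing.assert_allclose(y, r)

    def test_gamma_zero_gives_reward(self):
        cfg = SMALL.model_copy(update={"gamma": 0.0})
        r, s2, a2 = self._batch()
        y = td_target(r, s2, a2, np.zeros(4, dtype=bool), init_networks(cfg), cfg)
        np.testing.assert_allclose(y, r)

    def test_stubbed_target_critic(self):
        cfg = SMALL.model_copy(update={"gamma": 1.0})
        nets = init_networks(cfg)
        for stream in (nets.critic_target.v_stream, nets.critic_target.a_stream):
            for lin in stream.linears():
                lin.W[...] = 0.0
                lin.b[...] = 0.0
        nets.critic_target.v_stream.linears()[-1].b[...] = 2.0  # Q_target = 2
        y = td_target(np.ones(3), np.zeros((3, 6)), np.zeros(3, dtype=int),
                      np.zeros(3, dtype=bool), nets, cfg)
        np.testing.assert_allclose(y, 3.0)

    def test_both_target_modes_run(self):
        r, s2, a2 = self._batch()
        for mode in ("recorded_next_action", "target_actor_action"):
            cfg = SMALL.model_copy(update={"target_mode": mode})
            y = td_target(r, s2, a2, np.zeros(4, dtype=bool), init_networks(cfg), cfg)
            assert np.isfinite(y).all()


class TestSoftUpdate:
    def test_tau_one_copies(self):
        a = [np.array([2.0, 4.0])]
        b = [np.array([0.0, 0.0])]
        nn.soft_update(a, b, 1.0)
        np.testing.assert_array_equal(b[0], a[0])

    def test_tau_half_scalar(self):
        b = [np.array([0.0])]
        nn.soft_update([np.array([2.0])], b, 0.5)
        assert b[0][0] == pytest.approx(1.0)

    def test_geometric_convergence(self):
        online = [np.array([1.0])]
        target = [np.array([0.0])]
        for _ in range(200):
            nn.soft_update(online, target, 0.1)
        assert target[0][0] == pytest.approx(1.0, abs=1e-8)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ContractError):
            nn.soft_update([np.zeros(2)], [np.zeros(3)], 0.5)

    def test_target_moves_along_segment_during_training(self):
        pool = toy_pool()
        cfg = toy_agent_config(seed=0, train_steps=1)
        art = train(pool, cfg)
        nets = art.rebuild()
        # after one step, each target parameter lies between its initial
        # value (== the online init) and the current online value
        init = init_networks(cfg)
        for p0, po, pt in zip(
            init.critic.parameters(),
            nets.critic.parameters(),
            nets.critic_target.parameters(),
        ):
            lo = np.minimum(p0, po) - 1e-12
            hi = np.maximum(p0, po) + 1e-12
            assert ((pt >= lo) & (pt <= hi)).all()


class TestTraining:
    def test_zero_steps_returns_initial_parameters(self):
        pool = toy_pool()
        cfg = toy_agent_config(seed=3, train_steps=0)
        art = train(pool, cfg)
        assert art.td_history == []
        init = init_networks(cfg)
        nets = art.rebuild()
        assert all(
            np.array_equal(a, b)
            for a, b in zip(init.actor.parameters(), nets.actor.parameters())
        )

    def test_same_seed_same_artifact(self):
        pool = toy_pool()
        cfg = toy_agent_config(seed=4, train_steps=50)
        a = train(pool, cfg)
        b = train(pool, cfg)
        assert a.td_history == b.td_history
        assert all(np.array_equal(a.params[k], b.params[k]) for k in a.params)

    def test_td_error_decreases_on_toy_pool(self):
        art = train(toy_pool(), toy_agent_config(seed=5, train_steps=2000))
        assert art.td_history[-1] < art.td_history[0]
        assert all(np.isfinite(x) for x in art.td_history)

    def test_divergence_reported_with_step(self):
        cfg = toy_agent_config(seed=6, train_steps=500).model_copy(
            update={"critic_lr": 50.0}
        )
        with pytest.raises(TrainingError, match=r"step \d+"):
            train(toy_pool(), cfg)

    def test_actor_improves_against_frozen_critic(self):
        """With the critic held fixed, policy-gradient steps must not
        decrease the mean Q of the actor's own action distribution."""
        rng = np.random.default_rng(8)
        cfg = toy_agent_config(seed=8)
        nets = init_networks(cfg)
        # pretrained critic stub: make advantages state-dependent and fixed
        S = np.vstack([STATES, STATES])
        opt = nn.MomentumSGD(nets.actor.linears(), lr=1e-2)
        adv = nets.critic.advantage(S)

        def mean_q():
            probs = nets.actor.forward(S)
            return float(np.mean((adv * probs).sum(axis=1)))

        history = [mean_q()]
        for _ in range(100):
            probs = nets.actor.forward(S)
            nets.actor.backward_from_probs(-adv / len(S))
            opt.step()
            history.append(mean_q())
        assert history[-1] >= history[0]
        assert np.diff(history).min() > -1e-8


class TestRecommendAndArtifact:
    def test_recommend_pure_and_batch_consistent(self):
        art = train(toy_pool(), toy_agent_config(seed=9, train_steps=100))
        s = np.vstack([STATES, STATES[::-1]])
        a1 = recommend(s, art)
        a2 = recommend(s, art)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(
            np.concatenate([recommend(STATES, art), recommend(STATES[::-1], art)]), a1
        )

    def test_artifact_save_load_bit_identical(self, tmp_path):
        art = train(toy_pool(), toy_agent_config(seed=10, train_steps=100))
        path = tmp_path / "policy.npz"
        art.save(path)
        loaded = PolicyArtifact.load(path)
        np.testing.assert_array_equal(recommend(STATES, loaded), recommend(STATES, art))
        assert loaded.config == art.config
        assert loaded.td_history == pytest.approx(art.td_history)

    def test_dimension_mismatch_rejected(self):
        art = train(toy_pool(), toy_agent_config(seed=11, train_steps=10))
        with pytest.raises(ContractError):
            recommend(np.zeros((1, 7)), art)

    def test_trained_policy_matches_value_iteration_argmax(self):
        art = train(toy_pool(), toy_agent_config(seed=12))
        np.testing.assert_array_equal(
            recommend(STATES, art), value_iteration().argmax(axis=1)
        )
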