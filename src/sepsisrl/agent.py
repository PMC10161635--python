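"""Offline discrete-action DDPG with a dueling critic.

Four networks: an online and a target actor emitting softmax
probabilities over the 25 joint dose actions, and an online and a target
critic that decompose Q into a state-value stream V(s) and a
mean-centered advantage stream A(s, .):

    Q(s, a_vec) = V(s) + a_vec . A(s, .) - mean_a A(s, a)

The critic consumes a 25-dim action vector: a one-hot for recorded
clinician actions, or the actor's full probability vector during the
policy-gradient step (a differentiable relaxation of the deterministic
policy). Because Q is linear in the action vector, dQ/d(a_vec) is simply
the advantage vector, which is what the actor's gradient ascends.

Training is purely offline: batches come from the reward-weighted
experience pool, never from environment interaction. The TD target is

    y = r + gamma * (1 - done) * Q_target(s', a')

where a' is, per ``target_mode``, either the one-hot of the *recorded*
next clinician action ("recorded_next_action", the default modification)
or the target actor's greedy action ("target_actor_action", the
classical flow). Both targets are masked to y = r at terminal
transitions. Target networks start equal to the online ones and track
them by soft (Polyak) updates with rate tau.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import nn
from .errors import ContractError, TrainingError
from .replay import ReplayPool, sample_batch

__all__ = [
    "AgentConfig",
    "Actor",
    "DuelingCritic",
    "Networks",
    "init_networks",
    "td_target",
    "train",
    "recommend",
    "PolicyArtifact",
]

TARGET_MODES = ("recorded_next_action", "target_actor_action")


class AgentConfig(BaseModel):
    """Hyperparameters of the offline agent; every field has a default."""

    model_config = ConfigDict(extra="forbid")

    state_dim: int = Field(default=200, ge=1)
    n_actions: int = Field(default=25, ge=2)
    hidden_sizes: tuple[int, int] = (128, 128)
    leaky_slope: float = Field(default=0.01, gt=0.0, lt=1.0)
    actor_lr: float = Field(default=1e-3, gt=0)
    entropy_coef: float = Field(default=0.5, ge=0.0)
    adv_decay: float = Field(default=0.3, ge=0.0)
    critic_lr: float = Field(default=1e-3, gt=0)
    momentum: float = Field(default=0.9, ge=0.0, lt=1.0)
    optimizer: str = Field(default="adam")  # "adam" or "sgd" (mini-batch w/ momentum)
    gamma: float = Field(default=0.99, ge=0.0, le=1.0)
    tau: float = Field(default=0.001, gt=0.0, le=1.0)
    batch_size: int = Field(default=64, ge=1)
    train_steps: int = Field(default=5000, ge=0)
    episode_len: int = Field(default=50, ge=1)
    target_mode: str = Field(default="recorded_next_action")
    seed: int = 0

    def model_post_init(self, __context) -> None:
        if self.target_mode not in TARGET_MODES:
            raise ValueError(f"target_mode must be one of {TARGET_MODES}")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")


class Actor:
    """State -> softmax probabilities over the joint dose actions."""

    def __init__(self, config: AgentConfig, rng: np.random.Generator):
        h1, h2 = config.hidden_sizes
        self.net = nn.MLP(
            [config.state_dim, h1, h2, config.n_actions], config.leaky_slope, rng
        )
        self.n_actions = config.n_actions

    def forward(self, states: np.ndarray) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=float))
        if not np.isfinite(states).all():
            raise ContractError("non-finite state passed to actor")
        self._probs = nn.softmax(self.net.forward(states))
        return self._probs

    def greedy(self, states: np.ndarray) -> np.ndarray:
        """Argmax action per state; ties resolve to the lowest index."""
        return np.argmax(self.forward(states), axis=1)

    def backward_from_probs(self, dprobs: np.ndarray) -> None:
        self.net.backward(nn.softmax_backward(self._probs, dprobs))

    def parameters(self):
        return self.net.parameters()

    def linears(self):
        return self.net.linears()


class DuelingCritic:
    """Q(s, a_vec) = V(s) + a_vec . A(s,.) - mean_a A(s, a).

    A shared first hidden layer feeds two separate streams — state value
    and advantage — each with its own second hidden layer, so the
    advantage stream can shape sharp per-action structure independently
    of the (much larger scale) state-value fit.
    """

    def __init__(self, config: AgentConfig, rng: np.random.Generator):
        h1, h2 = config.hidden_sizes
        slope = config.leaky_slope
        self.shared = nn.MLP([config.state_dim, h1], slope, rng, activate_last=True)
        self.v_stream = nn.MLP([h1, h2, 1], slope, rng)
        self.a_stream = nn.MLP([h1, h2, config.n_actions], slope, rng)
        self.n_actions = config.n_actions

    @property
    def a_head(self) -> nn.Linear:
        """Final linear layer of the advantage stream (decay target)."""
        return self.a_stream.linears()[-1]

    def forward(self, states: np.ndarray, action_vecs: np.ndarray) -> np.ndarray:
        states = np.atleast_2d(np.asarray(states, dtype=float))
        action_vecs = np.atleast_2d(np.asarray(action_vecs, dtype=float))
        if action_vecs.shape[1] != self.n_actions:
            raise ContractError(
                f"action vector must be {self.n_actions}-dim, got {action_vecs.shape[1]}"
            )
        t = self.shared.forward(states)
        self._v = self.v_stream.forward(t)[:, 0]
        self._adv = self.a_stream.forward(t)
        self._a_vec = action_vecs
        return self._v + (self._adv * action_vecs).sum(axis=1) - self._adv.mean(axis=1)

    def advantage(self, states: np.ndarray) -> np.ndarray:
        """A(s, .) alone — the gradient of Q with respect to the action vector."""
        states = np.atleast_2d(np.asarray(states, dtype=float))
        return self.a_stream.forward(self.shared.forward(states))

    def backward(self, dq: np.ndarray) -> None:
        """Backprop d(loss)/dQ (shape (B,)) into parameter gradients."""
        dq = np.asarray(dq, dtype=float)
        dt = self.v_stream.backward(dq[:, None])
        dt = dt + self.a_stream.backward(
            dq[:, None] * (self._a_vec - 1.0 / self.n_actions)
        )
        self.shared.backward(dt)

    def parameters(self):
        return (
            self.shared.parameters()
            + self.v_stream.parameters()
            + self.a_stream.parameters()
        )

    def linears(self):
        return self.shared.linears() + self.v_stream.linears() + self.a_stream.linears()


@dataclass
class Networks:
    actor: Actor
    actor_target: Actor
    critic: DuelingCritic
    critic_target: DuelingCritic


def init_networks(config: AgentConfig) -> Networks:
    """Seeded online networks; targets start as exact copies."""
    rng = np.random.default_rng(config.seed)
    actor = Actor(config, rng)
    critic = DuelingCritic(config, rng)
    return Networks(
        actor=actor,
        actor_target=nn.clone_network(actor),
        critic=critic,
        critic_target=nn.clone_network(critic),
    )


def one_hot(indices: np.ndarray, n: int) -> np.ndarray:
    indices = np.asarray(indices)
    out = np.zeros((indices.shape[0], n))
    valid = (indices >= 0) & (indices < n)
    out[np.arange(indices.shape[0])[valid], indices[valid]] = 1.0
    return out


def td_target(
    rewards: np.ndarray,
    next_states: np.ndarray,
    next_actions: np.ndarray,
    dones: np.ndarray,
    networks: Networks,
    config: AgentConfig,
) -> np.ndarray:
    """y = r + gamma * (1 - done) * Q_target(s', a'); a' per target_mode."""
    if config.target_mode == "recorded_next_action":
        a_vec = one_hot(next_actions, config.n_actions)
    else:
        greedy = networks.actor_target.greedy(next_states)
        a_vec = one_hot(greedy, config.n_actions)
    q_next = networks.critic_target.forward(next_states, a_vec)
    return rewards + config.gamma * (1.0 - dones.astype(float)) * q_next


@dataclass
class PolicyArtifact:
    """Serialized agent: parameters of all four networks, config echo,
    per-episode TD-error history, and an encoder reference tag."""

    config: AgentConfig
    params: dict[str, np.ndarray]
    td_history: list[float]
    encoder_ref: str = ""

    _actor_cache: Actor | None = field(default=None, repr=False, compare=False)

    @staticmethod
    def _collect(networks: Networks, config: AgentConfig) -> dict[str, np.ndarray]:
        out = {}
        groups = {
            "actor": networks.actor.parameters(),
            "actor_target": networks.actor_target.parameters(),
            "critic": networks.critic.parameters(),
            "critic_target": networks.critic_target.parameters(),
        }
        for name, params in groups.items():
            for i, p in enumerate(params):
                out[f"{name}.{i}"] = p.copy()
        return out

    def rebuild(self) -> Networks:
        nets = init_networks(self.config)
        groups = {
            "actor": nets.actor.parameters(),
            "actor_target": nets.actor_target.parameters(),
            "critic": nets.critic.parameters(),
            "critic_target": nets.critic_target.parameters(),
        }
        for name, params in groups.items():
            for i, p in enumerate(params):
                p[...] = self.params[f"{name}.{i}"]
        return nets

    def actor(self) -> Actor:
        if self._actor_cache is None:
            self._actor_cache = self.rebuild().actor
        return self._actor_cache

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = dict(self.params)
        arrays["__td_history__"] = np.asarray(self.td_history, dtype=float)
        meta = {"config": self.config.model_dump(), "encoder_ref": self.encoder_ref}
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "PolicyArtifact":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {
            k: data[k] for k in data.files if not k.startswith("__")
        }
        return cls(
            config=AgentConfig(**meta["config"]),
            params=params,
            td_history=[float(x) for x in data["__td_history__"]],
            encoder_ref=meta["encoder_ref"],
        )


def train(pool: ReplayPool, config: AgentConfig, encoder_ref: str = "") -> PolicyArtifact:
    """Offline training loop.

    Each step: draw a reward-weighted batch; critic step on the mean
    squared TD residual for the recorded (one-hot) actions; actor step
    ascending mean Q of the actor's probability vector with the critic
    frozen; soft-update both targets. The critic loss (squared TD error)
    is averaged over each episode of ``episode_len`` steps and recorded
    as the TD-error history.
    """
    if config.train_steps > 0 and len(pool) == 0:
        raise ContractError("cannot train on an empty pool")
    if len(pool) and pool.state_dim != config.state_dim:
        raise ContractError(
            f"pool state dim {pool.state_dim} != config.state_dim {config.state_dim}"
        )
    networks = init_networks(config)
    rng = np.random.default_rng(config.seed)
    critic_opt = nn.make_optimizer(
        config.optimizer, networks.critic.linears(), config.critic_lr, config.momentum
    )
    actor_opt = nn.make_optimizer(
        config.optimizer, networks.actor.linears(), config.actor_lr, config.momentum
    )

    td_history: list[float] = []
    episode_losses: list[float] = []
    for step in range(config.train_steps):
        idx = sample_batch(pool, config.batch_size, rng)
        S = pool.states[idx]
        A = pool.actions[idx]
        R = pool.rewards[idx]
        S2 = pool.next_states[idx]
        A2 = pool.next_actions[idx]
        D = pool.dones[idx]

        y = td_target(R, S2, A2, D, networks, config)

        # Critic regression toward the TD target on recorded actions.
        q = networks.critic.forward(S, one_hot(A, config.n_actions))
        residual = q - y
        loss = float(np.mean(residual**2))
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite critic loss at step {step}")
        networks.critic.backward(2.0 * residual / len(idx))
        # Shrink advantage-head weights toward zero: actions rarely seen in
        # the offline pool keep near-zero advantage instead of arbitrary
        # extrapolations, a conservative regularization for offline data.
        if config.adv_decay > 0:
            networks.critic.a_head.gW += config.adv_decay * networks.critic.a_head.W
        critic_opt.step()

        # Actor ascent on mean Q(s, pi(s)) + entropy bonus; critic
        # parameters frozen, so only the advantage vector (dQ/d a_vec) is
        # needed. The entropy term keeps the softmax from saturating to a
        # state-independent action before the critic differentiates.
        probs = networks.actor.forward(S)
        adv = networks.critic.advantage(S)
        dprobs = -adv / len(idx)
        if config.entropy_coef > 0:
            dprobs += config.entropy_coef * (np.log(np.clip(probs, 1e-12, None)) + 1.0) / len(idx)
        networks.actor.backward_from_probs(dprobs)
        actor_opt.step()

        nn.soft_update(networks.critic.parameters(), networks.critic_target.parameters(), config.tau)
        nn.soft_update(networks.actor.parameters(), networks.actor_target.parameters(), config.tau)

        episode_losses.append(loss)
        if len(episode_losses) == config.episode_len:
            td_history.append(float(np.mean(episode_losses)))
            episode_losses = []
    if episode_losses:
        td_history.append(float(np.mean(episode_losses)))

    return PolicyArtifact(
        config=config,
        params=PolicyArtifact._collect(networks, config),
        td_history=td_history,
        encoder_ref=encoder_ref,
    )


def recommend(states: np.ndarray, artifact: PolicyArtifact) -> np.ndarray:
    """Greedy action indices under the trained online actor."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    actor = artifact.actor()
    if states.shape[1] != artifact.config.state_dim:
        raise ContractError(
            f"states are {states.shape[1]}-dim but the policy expects "
            f"{artifact.config.state_dim}"
        )
    return actor.greedy(states)
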