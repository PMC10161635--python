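"""A deterministic 2-state, 2-action MDP with a tabular value-iteration
oracle, used to validate the critic against ground-truth Q values.

    s0: a0 -> s0, r = -1.0    s0: a1 -> s1, r = +1.0
    s1: a0 -> s0, r = +2.0    s1: a1 -> s1, r = -0.5

States are one-hot encoded; the pool enumerates every (s, a) pair several
times so each is well covered under reward-weighted sampling.
"""

import numpy as np

from sepsisrl.replay import ReplayPool, Transition

NEXT = {(0, 0): 0, (0, 1): 1, (1, 0): 0, (1, 1): 1}
REWARD = {(0, 0): -1.0, (0, 1): 1.0, (1, 0): 2.0, (1, 1): -0.5}
GAMMA = 0.9
STATES = np.eye(2)


def value_iteration(tol: float = 1e-12) -> np.ndarray:
    """Tabular optimal Q via dynamic programming (the independent oracle)."""
    Q = np.zeros((2, 2))
    while True:
        Qn = np.array(
            [
                [REWARD[(s, a)] + GAMMA * Q[NEXT[(s, a)]].max() for a in range(2)]
                for s in range(2)
            ]
        )
        if np.abs(Qn - Q).max() < tol:
            return Qn
        Q = Qn


def toy_pool(copies: int = 8) -> ReplayPool:
    transitions = []
    for _ in range(copies):
        for (s, a), s_next in NEXT.items():
            transitions.append(
                Transition(
                    state=STATES[s],
                    action=a,
                    reward=REWARD[(s, a)],
                    next_state=STATES[s_next],
                    next_action=0,
                    done=False,
                    survived=True,
                    patient_id="toy",
                    step=0,
                )
            )
    return ReplayPool(transitions)


def toy_agent_config(seed: int, train_steps: int = 6000):
    from sepsisrl.agent import AgentConfig

    return AgentConfig(
        state_dim=2,
        n_actions=2,
        hidden_sizes=(32, 32),
        critic_lr=5e-3,
        actor_lr=1e-3,
        gamma=GAMMA,
        tau=0.01,
        batch_size=32,
        train_steps=train_steps,
        target_mode="target_actor_action",
        optimizer="sgd",
        adv_decay=0.0,
        seed=seed,
    )
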