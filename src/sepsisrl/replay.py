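"""Experience pool: trajectories -> transitions, with reward-magnitude-
weighted sampling.

Each consecutive bin pair of a trajectory yields one non-terminal
transition, and every trajectory additionally contributes one terminal
transition from its last recorded state (zero next state, sentinel next
action, reward carrying the +/-15 survival adjustment). Sampling is with
replacement, with probability proportional to |reward| + eps; the small
floor keeps zero-reward transitions reachable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .actions import RewardParams, action_index, discretize_iv, discretize_vp, reward
from .cohort import PatientTrajectory
from .errors import ContractError
from .preprocess import StateEncoder

__all__ = ["Transition", "ReplayPool", "build_pool", "sample_batch", "WEIGHT_EPS",
           "NEXT_ACTION_SENTINEL"]

WEIGHT_EPS = 1e-3
NEXT_ACTION_SENTINEL = -1


@dataclass
class Transition:
    """One (s, a, r, s', a', done) record with outcome bookkeeping."""

    state: np.ndarray
    action: int
    reward: float
    next_state: np.ndarray
    next_action: int  # NEXT_ACTION_SENTINEL when done
    done: bool
    survived: bool
    patient_id: str
    step: int


class ReplayPool:
    """Array-backed collection of transitions with static sampling weights."""

    def __init__(self, transitions: list[Transition], eps: float = WEIGHT_EPS):
        self.eps = eps
        n = len(transitions)
        dim = transitions[0].state.shape[0] if n else 0
        self.states = np.zeros((n, dim))
        self.next_states = np.zeros((n, dim))
        self.actions = np.zeros(n, dtype=int)
        self.next_actions = np.zeros(n, dtype=int)
        self.rewards = np.zeros(n)
        self.dones = np.zeros(n, dtype=bool)
        self.survived = np.zeros(n, dtype=bool)
        self.patient_ids: list[str] = []
        self.steps = np.zeros(n, dtype=int)
        for i, t in enumerate(transitions):
            self.states[i] = t.state
            self.next_states[i] = t.next_state
            self.actions[i] = t.action
            self.next_actions[i] = t.next_action
            self.rewards[i] = t.reward
            self.dones[i] = t.done
            self.survived[i] = t.survived
            self.patient_ids.append(t.patient_id)
            self.steps[i] = t.step

    def __len__(self) -> int:
        return len(self.rewards)

    @property
    def state_dim(self) -> int:
        return self.states.shape[1]

    def probabilities(self) -> np.ndarray:
        """P(i) = (|r_i| + eps) / sum_j (|r_j| + eps); strictly positive."""
        w = np.abs(self.rewards) + self.eps
        return w / w.sum()

    def save(self, path) -> None:
        np.savez(
            path,
            states=self.states,
            next_states=self.next_states,
            actions=self.actions,
            next_actions=self.next_actions,
            rewards=self.rewards,
            dones=self.dones,
            survived=self.survived,
            patient_ids=np.array(self.patient_ids),
            steps=self.steps,
            eps=np.array(self.eps),
        )

    @classmethod
    def load(cls, path) -> "ReplayPool":
        data = np.load(path, allow_pickle=False)
        pool = cls([], eps=float(data["eps"]))
        pool.states = data["states"]
        pool.next_states = data["next_states"]
        pool.actions = data["actions"]
        pool.next_actions = data["next_actions"]
        pool.rewards = data["rewards"]
        pool.dones = data["dones"]
        pool.survived = data["survived"]
        pool.patient_ids = [str(p) for p in data["patient_ids"]]
        pool.steps = data["steps"]
        return pool


def build_pool(
    cohort: list[PatientTrajectory],
    encoder: StateEncoder,
    params: RewardParams | None = None,
    eps: float = WEIGHT_EPS,
) -> ReplayPool:
    """Encode a cohort into transitions.

    An L-step trajectory yields L-1 non-terminal transitions plus one
    terminal transition whose reward is evaluated on the final snapshot
    against itself (no further observation exists) plus the survival
    bonus; its next state is all-zeros and its next action the sentinel.
    """
    if params is None:
        params = RewardParams()
    transitions: list[Transition] = []
    for traj in cohort:
        if len(traj) < 1:
            warnings.warn(f"skipping empty trajectory {traj.patient_id}", stacklevel=2)
            continue
        encoded = encoder.transform(np.vstack([s.features for s in traj.steps]))
        acts = [
            action_index(discretize_iv(iv), discretize_vp(vp)) for iv, vp in traj.doses
        ]
        zeros = np.zeros(encoder.dim)
        for t in range(len(traj) - 1):
            r = reward(
                traj.steps[t].sofa,
                traj.steps[t].lactate,
                traj.steps[t + 1].sofa,
                traj.steps[t + 1].lactate,
                params=params,
            )
            transitions.append(
                Transition(
                    state=encoded[t],
                    action=acts[t],
                    reward=r,
                    next_state=encoded[t + 1],
                    next_action=acts[t + 1],
                    done=False,
                    survived=traj.survived,
                    patient_id=traj.patient_id,
                    step=t,
                )
            )
        last = len(traj) - 1
        r_term = reward(
            traj.steps[last].sofa,
            traj.steps[last].lactate,
            traj.steps[last].sofa,
            traj.steps[last].lactate,
            terminal=True,
            survived=traj.survived,
            params=params,
        )
        transitions.append(
            Transition(
                state=encoded[last],
                action=acts[last],
                reward=r_term,
                next_state=zeros.copy(),
                next_action=NEXT_ACTION_SENTINEL,
                done=True,
                survived=traj.survived,
                patient_id=traj.patient_id,
                step=last,
            )
        )
    return ReplayPool(transitions, eps=eps)


def sample_batch(
    pool: ReplayPool, batch_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw transition indices with replacement, weighted by |reward| + eps."""
    if batch_size <= 0:
        raise ContractError(f"batch_size must be >= 1, got {batch_size}")
    if len(pool) == 0:
        raise ContractError("cannot sample from an empty pool")
    return rng.choice(len(pool), size=batch_size, replace=True, p=pool.probabilities())
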