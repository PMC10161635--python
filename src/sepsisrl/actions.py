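"""Dose discretization and clinical reward shaping.

Treatments are intravenous (IV) fluids in ml/h and vasopressors (VP) in
ug/kg/min. Each drug is mapped to one of five integer dosing levels
(level 0 = no drug), giving a 5x5 joint action grid flattened IV-major to
an index in {0..24}.

Level thresholds (left-closed: a rate equal to a printed threshold bumps
the level):

    IV (ml/h):       0 | [1, 50) | [50, 180) | [180, 530) | >= 530
    VP (ug/kg/min):  0 | (0, 0.08) | [0.08, 0.22) | [0.22, 0.45) | >= 0.45

The per-transition reward combines the change in SOFA score (organ
failure, 0-24) and blood lactate (cellular hypoxia, mmol/L):

    r(s_t, s_{t+1}) = c0 * 1[SOFA unchanged and > 0]
                    + c1 * (SOFA_{t+1} - SOFA_t)
                    + c2 * tanh(lactate_{t+1} - lactate_t)

with defaults c0 = -0.025, c1 = -0.125, c2 = -2. At the final transition
the reward is additionally increased by 15 if the patient survived to
discharge and decreased by 15 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict

from .errors import ContractError

N_LEVELS = 5
N_ACTIONS = N_LEVELS * N_LEVELS

IV_THRESHOLDS = (50.0, 180.0, 530.0)
VP_THRESHOLDS = (0.08, 0.22, 0.45)


class RewardParams(BaseModel):
    """Constants of the SOFA/lactate reward and the terminal adjustment."""

    model_config = ConfigDict(extra="forbid")

    c0: float = -0.025
    c1: float = -0.125
    c2: float = -2.0
    terminal_bonus: float = 15.0


@dataclass(frozen=True)
class Action:
    """A joint (IV level, VP level) dose with its flat index."""

    iv_level: int
    vp_level: int

    def __post_init__(self):
        if not (0 <= self.iv_level < N_LEVELS and 0 <= self.vp_level < N_LEVELS):
            raise ContractError(
                f"levels must lie in [0, {N_LEVELS}), got "
                f"({self.iv_level}, {self.vp_level})"
            )

    @property
    def index(self) -> int:
        return action_index(self.iv_level, self.vp_level)

    @classmethod
    def from_index(cls, index: int) -> "Action":
        return cls(*index_to_action(index))


def _discretize(rate: float, thresholds: tuple[float, ...], drug: str) -> int:
    if not np.isfinite(rate) or rate < 0:
        raise ContractError(f"{drug} rate must be a finite non-negative number, got {rate}")
    if rate == 0:
        return 0
    return 1 + sum(rate >= t for t in thresholds)


def discretize_iv(rate: float) -> int:
    """IV fluid rate (ml/h) -> dosing level in {0..4}."""
    return _discretize(float(rate), IV_THRESHOLDS, "IV")


def discretize_vp(rate: float) -> int:
    """Vasopressor rate (ug/kg/min) -> dosing level in {0..4}."""
    return _discretize(float(rate), VP_THRESHOLDS, "VP")


def action_index(iv_level: int, vp_level: int) -> int:
    """Flatten (iv, vp) levels IV-major into {0..24}."""
    if not (0 <= iv_level < N_LEVELS and 0 <= vp_level < N_LEVELS):
        raise ContractError(f"levels out of range: ({iv_level}, {vp_level})")
    return N_LEVELS * iv_level + vp_level


def index_to_action(index: int) -> tuple[int, int]:
    """Inverse of :func:`action_index`."""
    if not (0 <= index < N_ACTIONS):
        raise ContractError(f"action index out of range: {index}")
    return divmod(index, N_LEVELS)


def reward(
    prev_sofa: int,
    prev_lactate: float,
    next_sofa: int,
    next_lactate: float,
    terminal: bool = False,
    survived: bool | None = None,
    params: RewardParams | None = None,
) -> float:
    """Per-transition reward from consecutive SOFA/lactate readings.

    ``survived`` must be supplied exactly when ``terminal`` is true; the
    terminal bonus is added on top of (not substituted for) the shaped term.
    """
    if params is None:
        params = RewardParams()
    if terminal and survived is None:
        raise ContractError("terminal transition requires a survived flag")
    if not terminal and survived is not None:
        raise ContractError("survived flag only applies to terminal transitions")
    for name, s in (("prev", prev_sofa), ("next", next_sofa)):
        if not 0 <= s <= 24:
            raise ContractError(f"{name} SOFA must lie in [0, 24], got {s}")
    if prev_lactate <= 0 or next_lactate <= 0:
        raise ContractError("lactate must be strictly positive")

    unchanged_and_positive = (next_sofa == prev_sofa) and (next_sofa > 0)
    r = (
        params.c0 * float(unchanged_and_positive)
        + params.c1 * (next_sofa - prev_sofa)
        + params.c2 * np.tanh(next_lactate - prev_lactate)
    )
    if terminal:
        r += params.terminal_bonus if survived else -params.terminal_bonus
    return float(r)


def reward_bound(params: RewardParams | None = None) -> float:
    """Upper bound on |reward| over valid snapshots."""
    if params is None:
        params = RewardParams()
    return (
        abs(params.c0) + 24 * abs(params.c1) + abs(params.c2) + abs(params.terminal_bonus)
    )
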