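"""Outcome-association analyses of a trained dosing policy.

All analyses compare the clinician's recorded dose levels with the
policy's greedy recommendation per transition, using the signed
difference d = clinician_level - model_level per drug (d in [-4, 4]).
Every transition inherits its patient's final survived/died outcome, so
"mortality" of a cell is the death fraction of the transitions that fall
in it.

The U-curve plots per-difference mortality for one drug; the 9x9
heatmap/3-D histogram crosses both drugs and drops cells with fewer than
``min_count`` transitions (default 50) as too sparse to interpret; the
region summary pools cells into named boxes around the diagonal
(defaults: "brown" = exact agreement (0,0), "red" = Chebyshev distance 1,
"white" = Chebyshev distance 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .actions import index_to_action
from .agent import PolicyArtifact, recommend
from .errors import ConfigurationError
from .replay import ReplayPool

__all__ = [
    "DoseDiffCell",
    "dose_differences",
    "ucurve",
    "dose_diff_grid",
    "heatmap",
    "region_stats",
    "default_regions",
    "iv_marginal_at_zero_vp",
]


@dataclass
class DoseDiffCell:
    """Aggregate over transitions with a given (d_iv, d_vp) difference."""

    d_iv: int
    d_vp: int
    n: int
    deaths: int

    @property
    def mortality(self) -> float:
        return self.deaths / self.n if self.n else float("nan")

    def sample_proportion(self, total: int) -> float:
        return self.n / total if total else float("nan")


def dose_differences(
    pool: ReplayPool, artifact: PolicyArtifact
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-transition (d_iv, d_vp, died) with d = clinician - model."""
    model_actions = recommend(pool.states, artifact)
    clin = np.array([index_to_action(a) for a in pool.actions], dtype=int)
    model = np.array([index_to_action(a) for a in model_actions], dtype=int)
    d_iv = clin[:, 0] - model[:, 0]
    d_vp = clin[:, 1] - model[:, 1]
    died = ~pool.survived
    return d_iv, d_vp, died


def ucurve(
    differences: np.ndarray, died: np.ndarray, min_count: int = 1
) -> dict[int, dict[str, float]]:
    """Mortality per distinct signed difference of one drug.

    Returns {d: {"n": ..., "deaths": ..., "mortality": ...}}, omitting
    differences observed fewer than ``min_count`` times.
    """
    differences = np.asarray(differences)
    died = np.asarray(died, dtype=bool)
    out: dict[int, dict[str, float]] = {}
    for d in sorted(set(differences.tolist())):
        mask = differences == d
        n = int(mask.sum())
        if n < min_count:
            continue
        deaths = int(died[mask].sum())
        out[int(d)] = {"n": n, "deaths": deaths, "mortality": deaths / n}
    return out


def dose_diff_grid(
    d_iv: np.ndarray, d_vp: np.ndarray, died: np.ndarray
) -> list[DoseDiffCell]:
    """All 81 (d_iv, d_vp) cells with counts and deaths (unfiltered)."""
    d_iv = np.asarray(d_iv)
    d_vp = np.asarray(d_vp)
    died = np.asarray(died, dtype=bool)
    cells = []
    for di in range(-4, 5):
        for dv in range(-4, 5):
            mask = (d_iv == di) & (d_vp == dv)
            cells.append(DoseDiffCell(di, dv, int(mask.sum()), int(died[mask].sum())))
    return cells


def heatmap(
    d_iv: np.ndarray, d_vp: np.ndarray, died: np.ndarray, min_count: int = 50
) -> pd.DataFrame:
    """Long-format grid of populated cells with n >= min_count.

    ``proportion`` is relative to ALL evaluated transitions (the
    unfiltered total), so proportions of the surviving cells need not sum
    to one.
    """
    total = len(np.asarray(d_iv))
    rows = [
        {
            "d_iv": c.d_iv,
            "d_vp": c.d_vp,
            "n": c.n,
            "deaths": c.deaths,
            "mortality": c.mortality,
            "proportion": c.sample_proportion(total),
        }
        for c in dose_diff_grid(d_iv, d_vp, died)
        if c.n >= min_count
    ]
    return pd.DataFrame(rows, columns=["d_iv", "d_vp", "n", "deaths", "mortality", "proportion"])


def default_regions() -> dict[str, set[tuple[int, int]]]:
    """Brown = exact agreement; red = Chebyshev ring 1; white = ring 2."""
    regions: dict[str, set[tuple[int, int]]] = {"brown": set(), "red": set(), "white": set()}
    for di in range(-4, 5):
        for dv in range(-4, 5):
            cheb = max(abs(di), abs(dv))
            if cheb == 0:
                regions["brown"].add((di, dv))
            elif cheb == 1:
                regions["red"].add((di, dv))
            elif cheb == 2:
                regions["white"].add((di, dv))
    return regions


def region_stats(
    cells: list[DoseDiffCell],
    regions: dict[str, set[tuple[int, int]]] | None = None,
    total: int | None = None,
) -> pd.DataFrame:
    """Pooled sample size, proportion, and mortality per named region."""
    if regions is None:
        regions = default_regions()
    seen: set[tuple[int, int]] = set()
    for name, members in regions.items():
        overlap = seen & members
        if overlap:
            raise ConfigurationError(f"region {name} overlaps earlier regions at {sorted(overlap)}")
        seen |= members
    if total is None:
        total = sum(c.n for c in cells)
    by_key = {(c.d_iv, c.d_vp): c for c in cells}
    rows = []
    for name, members in regions.items():
        n = sum(by_key[m].n for m in members if m in by_key)
        deaths = sum(by_key[m].deaths for m in members if m in by_key)
        rows.append(
            {
                "region": name,
                "n": n,
                "proportion": n / total if total else float("nan"),
                "mortality": deaths / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["region", "n", "proportion", "mortality"])


def iv_marginal_at_zero_vp(d_iv: np.ndarray, d_vp: np.ndarray) -> dict[int, int]:
    """Histogram of IV dose differences among transitions where the VP
    difference is zero."""
    d_iv = np.asarray(d_iv)
    d_vp = np.asarray(d_vp)
    sel = d_iv[d_vp == 0]
    return {int(d): int((sel == d).sum()) for d in sorted(set(sel.tolist()))}
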