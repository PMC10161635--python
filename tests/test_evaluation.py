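"""Outcome-association analyses: dose differences, U-curves, heatmap
filtering, region statistics, and marginals."""

import numpy as np
import pytest

from sepsisrl.errors import ConfigurationError
from sepsisrl.evaluation import (
    DoseDiffCell,
    default_regions,
    dose_diff_grid,
    dose_differences,
    heatmap,
    iv_marginal_at_zero_vp,
    region_stats,
    ucurve,
)
from sepsisrl.agent import AgentConfig, PolicyArtifact, init_networks, train
from sepsisrl.replay import ReplayPool, Transition


def _stub_artifact(state_dim, favored_action):
    """An untrained policy whose actor always recommends one action."""
    cfg = AgentConfig(state_dim=state_dim, train_steps=0, seed=0)
    nets = init_networks(cfg)
    final = nets.actor.net.linears()[-1]
    final.W[...] = 0.0
    final.b[...] = 0.0
    final.b[favored_action] = 10.0
    # mirror into the target actor so the artifact is self-consistent
    tfinal = nets.actor_target.net.linears()[-1]
    tfinal.W[...] = final.W
    tfinal.b[...] = final.b
    return PolicyArtifact(
        config=cfg,
        params=PolicyArtifact._collect(nets, cfg),
        td_history=[],
    )


def _pool(records, dim=3):
    """records: list of (action_index, survived)."""
    transitions = [
        Transition(
            state=np.zeros(dim),
            action=a,
            reward=0.0,
            next_state=np.zeros(dim),
            next_action=0,
            done=False,
            survived=surv,
            patient_id=f"p{i}",
            step=0,
        )
        for i, (a, surv) in enumerate(records)
    ]
    return ReplayPool(transitions)


class TestDoseDifferences:
    def test_sign_convention_clinician_minus_model(self):
        # model always recommends (2, 1) -> index 11
        art = _stub_artifact(3, favored_action=11)
        pool = _pool([(11, True), (0, True), (24, False), (16, True)])
        d_iv, d_vp, died = dose_differences(pool, art)
        np.testing.assert_array_equal(d_iv, [0, -2, 2, 1])  # clinician iv - 2
        np.testing.assert_array_equal(d_vp, [0, -1, 3, 0])  # clinician vp - 1
        np.testing.assert_array_equal(died, [False, False, True, False])

    def test_extreme_difference(self):
        art = _stub_artifact(3, favored_action=24)  # model at (4, 4)
        pool = _pool([(0, True)])
        d_iv, d_vp, _ = dose_differences(pool, art)
        assert (d_iv[0], d_vp[0]) == (-4, -4)


class TestUcurve:
    def test_hand_counted_curve(self):
        curve = ucurve(np.array([0, 0, 1, 1]), np.array([False, False, True, False]))
        assert curve == {
            0: {"n": 2, "deaths": 0, "mortality": 0.0},
            1: {"n": 2, "deaths": 1, "mortality": 0.5},
        }

    def test_all_survivors(self):
        curve = ucurve(np.array([-1, 0, 2]), np.zeros(3, dtype=bool))
        assert all(v["mortality"] == 0.0 for v in curve.values())

    def test_single_point_curve(self):
        curve = ucurve(np.array([3, 3]), np.array([True, False]))
        assert list(curve) == [3]
        assert curve[3]["mortality"] == 0.5

    def test_min_count_filters(self):
        curve = ucurve(np.array([0, 0, 1]), np.zeros(3, dtype=bool), min_count=2)
        assert list(curve) == [0]

    def test_empty_input(self):
        assert ucurve(np.array([]), np.array([])) == {}


class TestHeatmap:
    def _diffs(self, n_zero, n_one):
        d_iv = np.concatenate([np.zeros(n_zero, int), np.ones(n_one, int)])
        d_vp = np.zeros(n_zero + n_one, int)
        died = np.zeros(n_zero + n_one, bool)
        return d_iv, d_vp, died

    def test_min_count_boundary(self):
        d_iv, d_vp, died = self._diffs(50, 49)
        hm = heatmap(d_iv, d_vp, died, min_count=50)
        cells = set(zip(hm.d_iv, hm.d_vp))
        assert (0, 0) in cells
        assert (1, 0) not in cells

    def test_unfiltered_proportions_sum_to_one(self):
        rng = np.random.default_rng(0)
        d_iv = rng.integers(-4, 5, 500)
        d_vp = rng.integers(-4, 5, 500)
        died = rng.random(500) < 0.2
        grid = dose_diff_grid(d_iv, d_vp, died)
        assert sum(c.n for c in grid) == 500
        assert sum(c.sample_proportion(500) for c in grid) == pytest.approx(1.0)
        assert all(c.deaths <= c.n for c in grid)

    def test_raising_min_count_never_adds_cells(self):
        rng = np.random.default_rng(1)
        d_iv = rng.integers(-2, 3, 400)
        d_vp = rng.integers(-2, 3, 400)
        died = rng.random(400) < 0.3
        lo = heatmap(d_iv, d_vp, died, min_count=10)
        hi = heatmap(d_iv, d_vp, died, min_count=30)
        assert set(zip(hi.d_iv, hi.d_vp)) <= set(zip(lo.d_iv, lo.d_vp))


class TestRegions:
    def test_default_regions_disjoint_and_shaped(self):
        regions = default_regions()
        assert regions["brown"] == {(0, 0)}
        assert len(regions["red"]) == 8  # Chebyshev ring at distance 1
        assert len(regions["white"]) == 16  # ring at distance 2
        assert regions["brown"].isdisjoint(regions["red"])

    def test_single_cell_region(self):
        cells = [DoseDiffCell(0, 0, 120, 12), DoseDiffCell(1, 0, 30, 6)]
        out = region_stats(cells, {"brown": {(0, 0)}})
        row = out[out.region == "brown"].iloc[0]
        assert row["n"] == 120
        assert row["mortality"] == pytest.approx(0.1)
        assert row["proportion"] == pytest.approx(120 / 150)

    def test_toy_grid_hand_computation(self):
        cells = [
            DoseDiffCell(0, 0, 100, 10),
            DoseDiffCell(1, 0, 50, 10),
            DoseDiffCell(0, 1, 50, 20),
            DoseDiffCell(2, 2, 100, 50),
        ]
        out = region_stats(cells)
        red = out[out.region == "red"].iloc[0]
        assert red["n"] == 100  # the two ring-1 cells
        assert red["mortality"] == pytest.approx(30 / 100)
        white = out[out.region == "white"].iloc[0]
        assert white["n"] == 100
        assert white["mortality"] == pytest.approx(0.5)

    def test_empty_region_reported_missing(self):
        out = region_stats([DoseDiffCell(0, 0, 10, 1)], {"far": {(4, 4)}})
        assert out.iloc[0]["n"] == 0
        assert np.isnan(out.iloc[0]["mortality"])

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ConfigurationError):
            region_stats([], {"a": {(0, 0)}, "b": {(0, 0), (1, 1)}})


class TestIvMarginal:
    def test_hand_built_fixture(self):
        d_iv = np.array([0, 1, 1, -2, 3, 0])
        d_vp = np.array([0, 0, 1, 0, 0, 0])
        assert iv_marginal_at_zero_vp(d_iv, d_vp) == {-2: 1, 0: 2, 1: 1, 3: 1}

    def test_no_qualifying_transitions(self):
        assert iv_marginal_at_zero_vp(np.array([1]), np.array([2])) == {}

    def test_point_mass(self):
        out = iv_marginal_at_zero_vp(np.zeros(5, int), np.zeros(5, int))
        assert out == {0: 5}


def test_counting_conservation_on_real_pool(small_pool):
    art = _stub_artifact(small_pool.state_dim, favored_action=12)
    d_iv, d_vp, died = dose_differences(small_pool, art)
    grid = dose_diff_grid(d_iv, d_vp, died)
    assert sum(c.n for c in grid) == len(small_pool)
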