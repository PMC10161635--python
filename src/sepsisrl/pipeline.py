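"""End-to-end orchestration: simulate -> preprocess -> build pools ->
train -> evaluate, with a machine-readable JSON report.

The report is a pure function of the run configuration (no timestamps,
sorted keys), so two runs with the same config produce byte-identical
reports. Each stage's parameters and an SHA-256 hash of its main output
are logged under ``stages``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import evaluation as ev
from .agent import PolicyArtifact, train
from .cohort import cohort_mortality, generate_cohort, write_cohort
from .config import RunConfig
from .preprocess import fit_state_encoder, split_by_patient
from .replay import build_pool

__all__ = ["run_pipeline"]


def _hash_arrays(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def _stage(report: dict, name: str, params: dict, output_hash: str) -> None:
    report["stages"][name] = {"params": params, "output_sha256_16": output_hash}


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Run every stage in order; returns the run directory.

    On stage failure the exception is re-raised with the stage name
    prepended; outputs of completed stages are retained.
    """
    cfg = config.resolve_seeds()
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg.model_dump(), "stages": {}}

    stage = "simulate"
    try:
        cohort = generate_cohort(cfg.sim)
        write_cohort(cohort, out / "cohort.csv")
        report["cohort"] = {
            "n_patients": len(cohort),
            "mortality": cohort_mortality(cohort),
            "mean_length": float(np.mean([len(t) for t in cohort])),
        }
        _stage(report, stage, cfg.sim.model_dump(),
               _hash_arrays(np.vstack([s.features for t in cohort for s in t.steps])))

        stage = "preprocess"
        train_cohort, test_cohort = split_by_patient(
            cohort, cfg.evaluation.test_fraction, seed=cfg.preprocess.seed
        )
        encoder = fit_state_encoder(train_cohort, cfg.preprocess)
        encoder.save(out / "encoder.npz")
        report["preprocess"] = {
            "n_train_patients": len(train_cohort),
            "n_test_patients": len(test_cohort),
            "ae_loss_initial": encoder.autoencoder.loss_history[0],
            "ae_loss_final": encoder.autoencoder.loss_history[-1],
        }
        _stage(report, stage, cfg.preprocess.model_dump(),
               _hash_arrays(encoder.stats[0], encoder.stats[1]))

        stage = "build_pool"
        train_pool = build_pool(train_cohort, encoder, cfg.reward)
        test_pool = build_pool(test_cohort, encoder, cfg.reward)
        train_pool.save(out / "pool_train.npz")
        test_pool.save(out / "pool_test.npz")
        report["pool"] = {"n_train": len(train_pool), "n_test": len(test_pool)}
        _stage(report, stage, cfg.reward.model_dump(),
               _hash_arrays(train_pool.states, test_pool.states))

        stage = "train"
        agent_cfg = cfg.agent.model_copy(
            update={"state_dim": cfg.preprocess.encoder_dim}
        )
        artifact = train(train_pool, agent_cfg, encoder_ref="encoder.npz")
        artifact.save(out / "policy.npz")
        report["training"] = {
            "train_steps": agent_cfg.train_steps,
            "episodes": len(artifact.td_history),
            "td_error_first": artifact.td_history[0] if artifact.td_history else None,
            "td_error_last": artifact.td_history[-1] if artifact.td_history else None,
        }
        _stage(report, stage, agent_cfg.model_dump(),
               _hash_arrays(*artifact.params.values()))

        stage = "evaluate"
        d_iv, d_vp, died = ev.dose_differences(test_pool, artifact)
        grid = ev.dose_diff_grid(d_iv, d_vp, died)
        hm = ev.heatmap(d_iv, d_vp, died, min_count=cfg.evaluation.min_count)
        regions = ev.region_stats(grid, total=len(test_pool))
        uc_iv = ev.ucurve(d_iv, died)
        uc_vp = ev.ucurve(d_vp, died)
        marginal = ev.iv_marginal_at_zero_vp(d_iv, d_vp)
        hm.to_csv(out / "heatmap.csv", index=False)
        regions.to_csv(out / "regions.csv", index=False)
        _ucurve_to_csv(uc_iv, out / "ucurve_iv.csv")
        _ucurve_to_csv(uc_vp, out / "ucurve_vp.csv")
        report["evaluation"] = {
            "ucurve_iv": {str(k): v for k, v in uc_iv.items()},
            "ucurve_vp": {str(k): v for k, v in uc_vp.items()},
            "heatmap_cells": hm.to_dict(orient="records"),
            "regions": regions.to_dict(orient="records"),
            "iv_marginal_at_zero_vp": {str(k): v for k, v in marginal.items()},
        }
        _stage(report, stage, cfg.evaluation.model_dump(),
               _hash_arrays(d_iv, d_vp, died.astype(np.int8)))
    except Exception as exc:
        raise type(exc)(f"stage '{stage}' failed: {exc}") from exc

    (out / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2) + "\n"
    )
    return out


def _ucurve_to_csv(curve: dict, path: Path) -> None:
    import pandas as pd

    rows = [
        {"difference": d, "n": v["n"], "deaths": v["deaths"], "mortality": v["mortality"]}
        for d, v in sorted(curve.items())
    ]
    pd.DataFrame(rows, columns=["difference", "n", "deaths", "mortality"]).to_csv(
        path, index=False
    )
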