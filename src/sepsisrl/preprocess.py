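"""Feature preparation: 4-h binning, clinical-limit removal, KNN
imputation, z-scoring, and autoencoder expansion of the 48-dim per-bin
features into a 200-dim state representation.

Binning convention: bins are half-open [k*bin_hours, (k+1)*bin_hours)
with 0-based indices, so a measurement at exactly 4.0 h falls in bin 1.
Clinical limits are closed intervals: a value exactly at a bound is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from sklearn.impute import KNNImputer

from . import nn
from .cohort import PatientTrajectory
from .errors import ConfigurationError, ContractError, ImputationError

__all__ = [
    "PreprocessConfig",
    "bin_and_aggregate",
    "clip_clinical_limits",
    "impute_knn",
    "normalize",
    "denormalize",
    "Autoencoder",
    "train_autoencoder",
    "StateEncoder",
    "feature_matrix",
    "split_by_patient",
]


class PreprocessConfig(BaseModel):
    """Configuration for the feature-preparation stage."""

    model_config = ConfigDict(extra="forbid")

    bin_hours: int = Field(default=4, gt=0)
    aggregation_map: dict[str, str] | None = None
    clinical_limits: dict[str, tuple[float, float]] | None = None
    knn_k: int = Field(default=5, ge=1)
    normalization: str = "zscore"
    encoder_dim: int = Field(default=200, ge=1)
    encoder_hidden: int = Field(default=64, ge=1)
    encoder_epochs: int = Field(default=15, ge=0)
    encoder_lr: float = Field(default=1e-3, gt=0)
    encoder_batch: int = Field(default=128, ge=1)
    seed: int = 0


def bin_and_aggregate(
    measurements: pd.DataFrame,
    aggregation_map: dict[str, str],
    bin_hours: float = 4.0,
    n_bins: int | None = None,
) -> pd.DataFrame:
    """Collapse timestamped measurements into per-(patient, bin) rows.

    ``measurements`` has columns ``patient_id, time_h, variable, value``.
    Variables labeled ``mean`` are averaged within each half-open bin,
    variables labeled ``sum`` are totaled; (patient, bin) cells with no
    data are NaN. The output covers bins 0..n_bins-1 for every patient
    (default: up to the largest observed bin).
    """
    required = {"patient_id", "time_h", "variable", "value"}
    if not required.issubset(measurements.columns):
        raise ConfigurationError(f"measurements need columns {sorted(required)}")
    unknown = set(measurements["variable"]) - set(aggregation_map)
    if unknown:
        raise ConfigurationError(f"variables missing from aggregation_map: {sorted(unknown)}")
    bad = {v: a for v, a in aggregation_map.items() if a not in ("mean", "sum")}
    if bad:
        raise ConfigurationError(f"aggregation labels must be mean or sum: {bad}")

    df = measurements.copy()
    df["bin_index"] = np.floor(df["time_h"] / bin_hours).astype(int)
    if (df["bin_index"] < 0).any():
        raise ConfigurationError("negative timestamps are not allowed")
    if n_bins is None:
        n_bins = int(df["bin_index"].max()) + 1 if len(df) else 0

    pieces = []
    for var, agg in aggregation_map.items():
        sub = df[df["variable"] == var]
        g = sub.groupby(["patient_id", "bin_index"])["value"].agg(agg)
        pieces.append(g.rename(var))
    wide = pd.concat(pieces, axis=1)

    patients = measurements["patient_id"].unique()
    full_index = pd.MultiIndex.from_product(
        [patients, range(n_bins)], names=["patient_id", "bin_index"]
    )
    return wide.reindex(full_index).reset_index()


def clip_clinical_limits(
    matrix: pd.DataFrame | np.ndarray,
    limits: dict[str | int, tuple[float, float]],
) -> pd.DataFrame | np.ndarray:
    """Set cells outside closed limit intervals to missing (NaN)."""
    for col, (lo, hi) in limits.items():
        if lo > hi:
            raise ConfigurationError(f"limits for {col}: lower {lo} > upper {hi}")
    out = matrix.copy()
    if isinstance(out, pd.DataFrame):
        for col, (lo, hi) in limits.items():
            if col in out.columns:
                vals = out[col]
                out.loc[(vals < lo) | (vals > hi), col] = np.nan
    else:
        out = np.asarray(out, dtype=float).copy()
        for col, (lo, hi) in limits.items():
            vals = out[:, col]
            vals[(vals < lo) | (vals > hi)] = np.nan
    return out


def impute_knn(matrix: np.ndarray, k: int = 5) -> np.ndarray:
    """Fill missing cells with the column mean over the k nearest rows.

    Distances are Euclidean over mutually observed columns, computed on
    per-column standardized values (observed-cell statistics); observed
    cells pass through unchanged.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ContractError("impute_knn expects a 2-D matrix")
    if not np.isnan(X).any():
        return X.copy()
    if k >= X.shape[0]:
        raise ImputationError(f"k={k} exceeds the {X.shape[0]} available rows")
    observed = (~np.isnan(X)).sum(axis=0)
    dead = np.where(observed == 0)[0]
    if dead.size:
        raise ImputationError(f"column {dead[0]} has no observed values")
    short = np.where(observed < k)[0]
    if short.size:
        raise ImputationError(
            f"column {short[0]} has only {observed[short[0]]} observed rows (< k={k})"
        )
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    filled = KNNImputer(n_neighbors=k, weights="uniform").fit_transform(Z)
    out = filled * sd + mu
    keep = ~np.isnan(X)
    out[keep] = X[keep]  # guard against float drift on observed cells
    return out


def normalize(
    matrix: np.ndarray, stats: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Z-score per column; constant columns map to zero.

    With ``stats`` supplied (test mode), the given (mean, std) are applied;
    otherwise they are computed from the input (train mode, population std).
    """
    X = np.asarray(matrix, dtype=float)
    if np.isnan(X).any():
        raise ContractError("normalize requires a complete matrix")
    if stats is None:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std == 0, 1.0, std)
        stats = (mean, std)
    mean, std = stats
    return (X - mean) / std, stats


def denormalize(Z: np.ndarray, stats: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    mean, std = stats
    return Z * std + mean


# ---------------------------------------------------------------------------
# Autoencoder: expand normalized 48-dim rows into a 200-dim representation.
# ---------------------------------------------------------------------------


class Autoencoder:
    """Encoder n_in -> hidden -> code, mirrored decoder, MSE objective."""

    def __init__(self, n_in: int, hidden: int, code: int, rng: np.random.Generator,
                 slope: float = 0.01):
        self.n_in = n_in
        self.code = code
        self.encoder = nn.MLP([n_in, hidden, code], slope, rng)
        self.decoder = nn.MLP([code, hidden, n_in], slope, rng)
        self.loss_history: list[float] = []

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_in:
            raise ContractError(f"expected {self.n_in}-dim rows, got {X.shape[1]}")
        if not np.isfinite(X).all():
            raise ContractError("non-finite values in encoder input")
        return self.encoder.forward(X)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.decoder.forward(self.encode(X))

    def reconstruction_loss(self, X: np.ndarray) -> float:
        R = self.reconstruct(X)
        return float(np.mean((R - X) ** 2))


def train_autoencoder(X: np.ndarray, config: PreprocessConfig) -> Autoencoder:
    """Fit the autoencoder on normalized rows; loss history includes the
    pre-training loss at index 0."""
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ContractError("non-finite values in autoencoder input")
    rng = np.random.default_rng(config.seed)
    ae = Autoencoder(X.shape[1], config.encoder_hidden, config.encoder_dim, rng)
    opt = nn.MomentumSGD(
        ae.encoder.linears() + ae.decoder.linears(), lr=config.encoder_lr, momentum=0.9
    )
    ae.loss_history.append(ae.reconstruction_loss(X))
    n = X.shape[0]
    for _ in range(config.encoder_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.encoder_batch):
            idx = order[start : start + config.encoder_batch]
            batch = X[idx]
            code = ae.encoder.forward(batch)
            recon = ae.decoder.forward(code)
            g = 2.0 * (recon - batch) / batch.shape[0]
            ae.encoder.backward(ae.decoder.backward(g))
            opt.step()
        ae.loss_history.append(ae.reconstruction_loss(X))
    return ae


# ---------------------------------------------------------------------------
# StateEncoder: the fitted (stats, autoencoder) pair applied to raw features.
# ---------------------------------------------------------------------------


@dataclass
class StateEncoder:
    """Normalization statistics plus a trained autoencoder; maps raw
    per-bin feature rows to encoded state vectors."""

    stats: tuple[np.ndarray, np.ndarray]
    autoencoder: Autoencoder

    @property
    def dim(self) -> int:
        return self.autoencoder.code

    def transform(self, raw_features: np.ndarray) -> np.ndarray:
        Z, _ = normalize(np.atleast_2d(raw_features), self.stats)
        return self.autoencoder.encode(Z)

    def save(self, path) -> None:
        enc = self.autoencoder
        hidden = enc.encoder.linears()[0].W.shape[1]
        arrays = {
            "mean": self.stats[0],
            "std": self.stats[1],
            "dims": np.array([enc.n_in, hidden, enc.code]),
            "loss_history": np.asarray(enc.loss_history, dtype=float),
        }
        for net_name, net in (("enc", enc.encoder), ("dec", enc.decoder)):
            for i, lin in enumerate(net.linears()):
                arrays[f"{net_name}{i}.W"] = lin.W
                arrays[f"{net_name}{i}.b"] = lin.b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "StateEncoder":
        data = np.load(path, allow_pickle=False)
        n_in, hidden, code = (int(x) for x in data["dims"])
        ae = Autoencoder(n_in, hidden, code, np.random.default_rng(0))
        for net_name, net in (("enc", ae.encoder), ("dec", ae.decoder)):
            for i, lin in enumerate(net.linears()):
                lin.W[...] = data[f"{net_name}{i}.W"]
                lin.b[...] = data[f"{net_name}{i}.b"]
        ae.loss_history = [float(x) for x in data["loss_history"]]
        return cls(stats=(data["mean"], data["std"]), autoencoder=ae)


def feature_matrix(cohort: list[PatientTrajectory]) -> np.ndarray:
    """Stack every per-bin feature row of a cohort into one matrix."""
    rows = [snap.features for traj in cohort for snap in traj.steps]
    if not rows:
        return np.zeros((0, 0))
    return np.vstack(rows)


def split_by_patient(
    cohort: list[PatientTrajectory], test_fraction: float = 0.2, seed: int = 0
) -> tuple[list[PatientTrajectory], list[PatientTrajectory]]:
    """Deterministic train/test split at the patient level."""
    if not 0 <= test_fraction < 1:
        raise ContractError("test_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    n_test = int(round(test_fraction * len(cohort)))
    test_idx = set(order[:n_test].tolist())
    train = [t for i, t in enumerate(cohort) if i not in test_idx]
    test = [t for i, t in enumerate(cohort) if i in test_idx]
    return train, test


def fit_state_encoder(
    cohort: list[PatientTrajectory], config: PreprocessConfig
) -> StateEncoder:
    """Convenience: compute train-set stats, fit the autoencoder, bundle both."""
    X = feature_matrix(cohort)
    Z, stats = normalize(X)
    ae = train_autoencoder(Z, config)
    return StateEncoder(stats=stats, autoencoder=ae)
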