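"""Synthetic sepsis-like ICU cohort generator.

Emulates the statistical structure the dosing pipeline assumes: 72-hour
stays split into 4-hour bins, a 48-dimensional per-bin feature vector,
SOFA and lactate co-evolving with a latent severity in [0, 1], a
stochastic clinician dosing policy over the five IV/VP levels, and a
terminal survived/died outcome driven by how well administered doses
track a latent optimal dose.

Dynamics (per 4-h bin k):

    severity_{k+1} = clip(severity_k + drift - dose_effect * match_k
                          + Normal(0, noise_sd), 0, 1)

where ``match_k`` is 1 iff the clinician's IV and VP levels both equal the
latent optimal level, a staircase function of severity
(``min(4, floor(5*severity))``). The stay ends in death once severity
reaches ``mortality_threshold``, in discharge once severity reaches 0, or
in discharge at the end of the horizon. SOFA is a rounded noisy rescaling
of severity to 0-24; lactate is a noisy log-linear transform into a
plausible mmol/L range; the 48 features are a fixed random linear map of
(severity, SOFA, log lactate, elapsed-stay fraction) plus independent
noise, with the map drawn once per cohort from the seed. The elapsed-stay
signal mirrors the time-anchored charting of real ICU records and makes
end-of-stay states identifiable, without which the terminal survival
bonus is an irreducible target ambiguity for any value estimator.

The clinician administers the optimal level with a per-stay probability
skill_i — drawn once per patient, uniform on ``clinician_skill`` +/-
``skill_spread`` and clipped to [0, 1] — and otherwise picks uniformly
among the other four levels, independently per drug; the continuous
rate is then drawn uniformly inside the chosen level's band so
discretization recovers the level exactly. Between-stay variation in
care quality is what gives dose-difference bins their outcome
association in real cohorts: patients whose dosing tracks the optimum
poorly both fill the far difference bins and die more often.
``skill_spread=0`` recovers a homogeneous behavior policy.

This generator targets qualitative structure (a learnable dose-outcome
signal, a U-shaped mortality-vs-dose-difference relationship), not
physiological realism or any real cohort's magnitudes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ParameterError, ParseError

__all__ = [
    "SimParams",
    "StateSnapshot",
    "PatientTrajectory",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "optimal_level",
    "cohort_mortality",
]

# Continuous-rate bands per dosing level, half-open on the right and chosen
# so discretize_iv/discretize_vp invert the draw. Level 0 is exactly zero.
IV_BANDS = ((0.0, 0.0), (1.0, 50.0), (50.0, 180.0), (180.0, 530.0), (530.0, 1000.0))
VP_BANDS = ((0.0, 0.0), (0.001, 0.08), (0.08, 0.22), (0.22, 0.45), (0.45, 1.0))

# Severity range patients start in: ill enough for a dosing problem to
# exist, never terminal at admission.
_INIT_SEVERITY = (0.25, 0.70)

# Observation-model constants: SOFA ~ round(24*sev + N(0, sofa_noise)),
# lactate = exp(a + b*sev + N(0, lact_noise)) spanning roughly 1-12 mmol/L.
_SOFA_NOISE = 1.0
_LACT_A, _LACT_B, _LACT_NOISE = 0.2, 2.2, 0.15
_FEATURE_NOISE = 0.3


class SimParams(BaseModel):
    """Knobs of the synthetic cohort; defaults define the study conditions."""

    model_config = ConfigDict(extra="forbid")

    n_patients: int = Field(gt=0)
    horizon_bins: int = Field(default=18, ge=2)
    n_features: int = Field(default=48, ge=1)
    severity_drift: float = 0.04
    dose_effect: float = 0.08
    noise_sd: float = Field(default=0.05, ge=0.0)
    mortality_threshold: float = Field(default=0.92, gt=0.0, le=1.0)
    clinician_skill: float = Field(default=0.7, ge=0.0, le=1.0)
    skill_spread: float = Field(default=0.25, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        return self


@dataclass
class StateSnapshot:
    """One 4-h bin of one patient: observed features plus the latent severity."""

    bin_index: int
    features: np.ndarray
    sofa: int
    lactate: float
    severity: float

    def __eq__(self, other):
        if not isinstance(other, StateSnapshot):
            return NotImplemented
        return (
            self.bin_index == other.bin_index
            and self.sofa == other.sofa
            and self.lactate == other.lactate
            and self.severity == other.severity
            and np.array_equal(self.features, other.features)
        )


@dataclass
class PatientTrajectory:
    """One stay: per-bin snapshots, aligned (iv_rate, vp_rate) doses, outcome."""

    patient_id: str
    steps: list[StateSnapshot]
    doses: list[tuple[float, float]]
    survived: bool

    def __post_init__(self):
        if len(self.steps) != len(self.doses):
            raise ParameterError(
                f"{self.patient_id}: {len(self.steps)} steps vs {len(self.doses)} doses"
            )

    def __len__(self) -> int:
        return len(self.steps)

    def __eq__(self, other):
        if not isinstance(other, PatientTrajectory):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.survived == other.survived
            and self.doses == other.doses
            and self.steps == other.steps
        )


def optimal_level(severity: float) -> int:
    """Latent optimal dosing level: staircase of severity onto {0..4}."""
    return min(4, int(math.floor(5.0 * severity)))


def _draw_rate(level: int, bands, rng: np.random.Generator) -> float:
    lo, hi = bands[level]
    if level == 0:
        return 0.0
    return float(rng.uniform(lo, hi))


def _clinician_level(opt: int, skill: float, rng: np.random.Generator) -> int:
    if rng.random() < skill:
        return opt
    others = [l for l in range(5) if l != opt]
    return int(others[rng.integers(len(others))])


def generate_cohort(params: SimParams) -> list[PatientTrajectory]:
    """Simulate ``params.n_patients`` trajectories; bit-identical per seed."""
    if not isinstance(params, SimParams):
        params = SimParams(**params)
    rng = np.random.default_rng(params.seed)
    # One fixed linear map (severity, sofa/24, log lactate, stay fraction)
    # -> features.
    feature_map = rng.normal(size=(4, params.n_features))

    cohort: list[PatientTrajectory] = []
    for i in range(params.n_patients):
        pid = f"p{i:05d}"
        severity = float(rng.uniform(*_INIT_SEVERITY))
        skill = float(
            np.clip(
                rng.uniform(
                    params.clinician_skill - params.skill_spread,
                    params.clinician_skill + params.skill_spread,
                ),
                0.0,
                1.0,
            )
        )
        steps: list[StateSnapshot] = []
        doses: list[tuple[float, float]] = []
        survived = True
        for k in range(params.horizon_bins):
            sofa = int(np.clip(round(24.0 * severity + rng.normal(0.0, _SOFA_NOISE)), 0, 24))
            lactate = float(
                np.exp(_LACT_A + _LACT_B * severity + rng.normal(0.0, _LACT_NOISE))
            )
            base = np.array(
                [severity, sofa / 24.0, math.log(lactate), k / (params.horizon_bins - 1)]
            )
            features = base @ feature_map + rng.normal(
                0.0, _FEATURE_NOISE, params.n_features
            )
            opt = optimal_level(severity)
            iv_level = _clinician_level(opt, skill, rng)
            vp_level = _clinician_level(opt, skill, rng)
            iv_rate = _draw_rate(iv_level, IV_BANDS, rng)
            vp_rate = _draw_rate(vp_level, VP_BANDS, rng)
            steps.append(StateSnapshot(k, features, sofa, lactate, severity))
            doses.append((iv_rate, vp_rate))

            if severity >= params.mortality_threshold:
                survived = False
                break
            if k > 0 and severity <= 0.0:
                break  # early discharge, recovered
            match = (iv_level == opt) and (vp_level == opt)
            severity = float(
                np.clip(
                    severity
                    + params.severity_drift
                    - params.dose_effect * float(match)
                    + rng.normal(0.0, params.noise_sd),
                    0.0,
                    1.0,
                )
            )
        cohort.append(PatientTrajectory(pid, steps, doses, survived))
    return cohort


def cohort_mortality(cohort: list[PatientTrajectory]) -> float:
    """Fraction of patients who died."""
    if not cohort:
        return float("nan")
    return sum(not t.survived for t in cohort) / len(cohort)


# ---------------------------------------------------------------------------
# Persistence: one CSV of per-bin rows plus a JSONL sidecar of outcomes.
# ---------------------------------------------------------------------------

_BASE_COLUMNS = ["patient_id", "bin_index", "iv_rate", "vp_rate", "sofa", "lactate", "severity"]


def _feature_columns(n: int) -> list[str]:
    return [f"f{j}" for j in range(n)]


def write_cohort(cohort: list[PatientTrajectory], path: str | Path) -> None:
    """Write per-bin rows to ``<path>`` (CSV) and outcomes to ``<path stem>.outcomes.jsonl``."""
    path = Path(path)
    n_feat = len(cohort[0].steps[0].features) if cohort and cohort[0].steps else 0
    rows = []
    for traj in cohort:
        for snap, (iv, vp) in zip(traj.steps, traj.doses):
            rows.append(
                [traj.patient_id, snap.bin_index, iv, vp, snap.sofa, snap.lactate, snap.severity]
                + list(snap.features)
            )
    df = pd.DataFrame(rows, columns=_BASE_COLUMNS + _feature_columns(n_feat))
    for col in df.columns:
        if col == "patient_id":
            continue
        df[col] = df[col].astype(int if col in ("bin_index", "sofa") else float)
    # %.17g guarantees exact float64 round-trips through the text file
    df.to_csv(path, index=False, float_format="%.17g")
    with open(_outcomes_path(path), "w") as fh:
        for traj in cohort:
            fh.write(json.dumps({"patient_id": traj.patient_id, "survived": traj.survived}) + "\n")


def _outcomes_path(path: Path) -> Path:
    return path.with_suffix(".outcomes.jsonl")


def read_cohort(path: str | Path) -> list[PatientTrajectory]:
    """Inverse of :func:`write_cohort`; validates invariants cell by cell."""
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        return []
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    feat_cols.sort(key=lambda c: int(c[1:]))

    outcomes: dict[str, bool] = {}
    opath = _outcomes_path(path)
    if opath.exists():
        with open(opath) as fh:
            for lineno, line in enumerate(fh):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                    outcomes[rec["patient_id"]] = bool(rec["survived"])
                except (json.JSONDecodeError, KeyError) as exc:
                    raise ParseError(f"{opath}: line {lineno}: {exc}") from exc

    cohort: list[PatientTrajectory] = []
    for pid, group in df.groupby("patient_id", sort=False):
        steps, doses = [], []
        for row_idx, row in group.iterrows():
            for col in ("iv_rate", "vp_rate"):
                if row[col] < 0:
                    raise ParseError(f"{path}: row {row_idx}, column {col}: negative rate {row[col]}")
            if not 0 <= row["sofa"] <= 24:
                raise ParseError(f"{path}: row {row_idx}, column sofa: {row['sofa']} outside [0, 24]")
            if row["lactate"] <= 0:
                raise ParseError(
                    f"{path}: row {row_idx}, column lactate: {row['lactate']} not positive"
                )
            steps.append(
                StateSnapshot(
                    bin_index=int(row["bin_index"]),
                    features=row[feat_cols].to_numpy(dtype=float),
                    sofa=int(row["sofa"]),
                    lactate=float(row["lactate"]),
                    severity=float(row["severity"]),
                )
            )
            doses.append((float(row["iv_rate"]), float(row["vp_rate"])))
        cohort.append(PatientTrajectory(str(pid), steps, doses, outcomes.get(str(pid), True)))
    return cohort
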