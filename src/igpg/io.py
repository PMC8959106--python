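"""File formats and run configuration.

Gait CSV: header ``percent_cycle,hip_L,knee_L,ankle_L,hip_R,knee_R,ankle_R``,
one row per grid point, angles in degrees (6 decimals on write).  Subject,
trial and speed metadata live in a ``<stem>.meta.json`` sidecar; without
one, the filename pattern ``<subject>__<trial>.csv`` is used.

Body parameters: JSON object (one subject) or CSV (one row per subject)
keyed by the canonical slot names, any key/column order.

Clinical sessions: CSV with
``subject_id,session,spo2_before,spo2_after,hr_before,hr_after``.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anthropometry import BodyParameters, validate_body
from .clinical import SessionRecord
from .codec import JOINT_IDS, GaitPattern, JointCycle
from .pipeline import PipelineConfig

GAIT_COLUMNS = ("percent_cycle",) + JOINT_IDS

_ANGLE_DECIMALS = 6


class ParseError(ValueError):
    pass


def _metadata_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_gait_csv(pattern: GaitPattern, path: str | Path) -> None:
    path = Path(path)
    n = pattern.cycle_length
    df = pd.DataFrame({"percent_cycle": np.round(100.0 * np.arange(n) / n, _ANGLE_DECIMALS)})
    for j in JOINT_IDS:
        df[j] = np.round(pattern.cycles[j].angles, _ANGLE_DECIMALS)
    df.to_csv(path, index=False)
    meta = {
        "subject_id": pattern.subject_id,
        "trial_id": pattern.trial_id,
        "walking_speed": pattern.walking_speed,
    }
    _metadata_path(path).write_text(json.dumps(meta))


def read_gait_csv(path: str | Path) -> GaitPattern:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in GAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # header is line 1
        raise ParseError(f"{path}: malformed row at line {bad}")

    meta_path = _metadata_path(path)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        subject_id = str(meta.get("subject_id", path.stem))
        trial_id = str(meta.get("trial_id", "0"))
        speed = meta.get("walking_speed")
    else:
        stem = path.stem
        subject_id, _, trial_id = stem.partition("__")
        trial_id = trial_id or "0"
        speed = None
    cycles = {j: JointCycle(j, df[j].to_numpy(dtype=float)) for j in JOINT_IDS}
    return GaitPattern(
        subject_id=subject_id,
        trial_id=trial_id,
        cycles=cycles,
        walking_speed=None if speed is None else float(speed),
    )


def write_body_json(body: BodyParameters, path: str | Path) -> None:
    payload = body.as_dict()
    if body.subject_id:
        payload["subject_id"] = body.subject_id
    Path(path).write_text(json.dumps(payload, indent=1))


def read_body_json(path: str | Path) -> BodyParameters:
    try:
        record = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(record, dict) or not record:
        raise ParseError(f"{path}: expected a non-empty JSON object")
    return validate_body(record)


def read_bodies_csv(path: str | Path) -> list[BodyParameters]:
    df = pd.read_csv(path)
    if df.empty:
        raise ParseError(f"{path}: no body-parameter rows")
    return [validate_body(row.to_dict()) for _, row in df.iterrows()]


def write_bodies_csv(bodies: list[BodyParameters], path: str | Path) -> None:
    rows = []
    for b in bodies:
        row = {"subject_id": b.subject_id, **b.as_dict()}
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


SESSION_COLUMNS = (
    "subject_id", "session", "spo2_before", "spo2_after", "hr_before", "hr_after",
)


def read_sessions_csv(path: str | Path) -> list[SessionRecord]:
    df = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise ParseError(f"{path}: no session rows")
    return [
        SessionRecord(
            subject_id=str(r.subject_id),
            session=str(r.session),
            spo2_before=float(r.spo2_before),
            spo2_after=float(r.spo2_after),
            hr_before=float(r.hr_before),
            hr_after=float(r.hr_after),
        )
        for r in df.itertuples()
    ]


def write_sessions_csv(records: list[SessionRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in records])[list(SESSION_COLUMNS)].to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Schema-validated run settings (YAML or JSON on disk)."""

    seed: int = 0
    l0: int = 101
    n_harmonics: int = 3
    n_restarts: int = 5
    ard: bool = False
    resample_method: str = "linear"
    speed_bins: list[tuple[float, float]] | None = None
    log_level: str = "INFO"

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            l0=self.l0,
            n_harmonics=self.n_harmonics,
            seed=self.seed,
            n_restarts=self.n_restarts,
            ard=self.ard,
            resample_method=self.resample_method,
            speed_bins=self.speed_bins,
        )


def load_run_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig, rejecting unknown keys."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ParseError(f"{path}: unknown config key(s) {unknown}")
    if "speed_bins" in raw and raw["speed_bins"] is not None:
        raw["speed_bins"] = [tuple(b) for b in raw["speed_bins"]]
    return RunConfig(**raw)
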