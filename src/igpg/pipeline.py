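"""End-to-end individualized gait pattern generation.

Training pairs each subject's 28 body parameters with their recorded gait
cycles.  Cycles are Fourier-encoded per joint; for each joint the mean term
and the Cartesian harmonic components (c_h = a_h cos phi_h,
s_h = a_h sin phi_h) become independent regression targets — phases are
never regressed directly because the 2-pi wrap would put a discontinuity
in an otherwise smooth anthropometry-to-feature map.  One GP per
joint-target (6 joints x 7 targets = 42 models for 3 harmonics) maps the
z-scored body parameters to the features; generation runs the bank on a
new subject's parameters and reconstructs six joint-angle cycles.

Training data may be partitioned into walking-speed sets, each with its
own normalizer and model bank; the default is a single set covering all
speeds.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import gpr
from .anthropometry import (
    BodyParameters,
    NormalizationStats,
    fit_normalizer,
    normalize,
    normalize_cohort,
)
from .codec import (
    DEFAULT_L0,
    DEFAULT_N_HARMONICS,
    JOINT_IDS,
    GaitPattern,
    JointCycle,
    JointFeatureVector,
    ValidationError,
    extract_features,
    reconstruct_cycle,
    resample_cycle,
)

FORMAT_VERSION = 1

DEFAULT_SPEED_SET = "all"


@dataclass
class PipelineConfig:
    """Settings shared by training, generation and cross-validation."""

    l0: int = DEFAULT_L0
    n_harmonics: int = DEFAULT_N_HARMONICS
    seed: int = 0
    n_restarts: int = 5
    ard: bool = False
    resample_method: str = "linear"
    speed_bins: list[tuple[float, float]] | None = None  # [min, max) in m/s

    @property
    def n_targets(self) -> int:
        return 2 * self.n_harmonics + 1

    def target_names(self) -> tuple[str, ...]:
        names = ["a0"]
        for h in range(1, self.n_harmonics + 1):
            names += [f"c{h}", f"s{h}"]
        return tuple(names)


@dataclass
class TrainingDataset:
    """Paired anthropometry and gait recordings for a cohort."""

    pairs: list[tuple[BodyParameters, GaitPattern]]

    def __post_init__(self) -> None:
        if not all(isinstance(b, BodyParameters) for b, _ in self.pairs):
            raise ValidationError("first element of each pair must be BodyParameters")

    def __len__(self) -> int:
        return len(self.pairs)

    def subject_ids(self) -> list[str]:
        """Distinct subject ids in first-appearance order."""
        seen: dict[str, None] = {}
        for _, p in self.pairs:
            seen.setdefault(p.subject_id, None)
        return list(seen)


def speed_set_label(speed: float | None, config: PipelineConfig) -> str:
    """Which speed set a trial belongs to under the configured binning."""
    if config.speed_bins is None:
        return DEFAULT_SPEED_SET
    if speed is None:
        raise ValueError("trial has no walking speed but speed bins are configured")
    for lo, hi in config.speed_bins:
        if lo <= speed < hi:
            return f"{lo:g}-{hi:g}"
    raise ValueError(f"walking speed {speed} m/s falls in no configured bin")


def features_to_targets(fv: JointFeatureVector) -> np.ndarray:
    """(a0, c1, s1, ..., cn, sn) regression targets from canonical features."""
    out = np.empty(2 * fv.n_harmonics + 1)
    out[0] = fv.a[0]
    out[1::2] = fv.a[1:] * np.cos(fv.phi)
    out[2::2] = fv.a[1:] * np.sin(fv.phi)
    return out


def targets_to_features(targets: np.ndarray) -> JointFeatureVector:
    """Inverse of :func:`features_to_targets` (canonicalized on construction)."""
    targets = np.asarray(targets, dtype=float)
    if targets.size % 2 != 1:
        raise ValueError("target vector must have odd length (a0 + c/s pairs)")
    c = targets[1::2]
    s = targets[2::2]
    a = np.concatenate([[targets[0]], np.hypot(c, s)])
    phi = np.arctan2(s, c)
    return JointFeatureVector(a=a, phi=phi)


def build_training_targets(
    dataset: TrainingDataset, config: PipelineConfig
) -> dict[str, np.ndarray]:
    """Per-joint (n_pairs, n_targets) matrices of Fourier regression targets."""
    out = {j: np.empty((len(dataset), config.n_targets)) for j in JOINT_IDS}
    for i, (_, pattern) in enumerate(dataset.pairs):
        for j in JOINT_IDS:
            try:
                cyc = resample_cycle(
                    pattern.cycles[j], config.l0, method=config.resample_method
                )
                fv = extract_features(cyc, config.n_harmonics)
            except (ValueError, ValidationError) as exc:
                raise ValueError(
                    f"codec failure for subject {pattern.subject_id!r} "
                    f"trial {pattern.trial_id!r} joint {j}: {exc}"
                ) from exc
            out[j][i] = features_to_targets(fv)
    return out


@dataclass
class SpeedSetModel:
    """Normalizer plus the 6 x (2n+1) GP bank for one walking-speed set."""

    stats: NormalizationStats
    models: dict[tuple[str, str], gpr.GPRModel]  # (joint_id, target_name) -> GP


@dataclass
class GeneratorModel:
    """A trained individualized-gait generator."""

    speed_sets: dict[str, SpeedSetModel]
    config: PipelineConfig

    def __post_init__(self) -> None:
        want = len(JOINT_IDS) * self.config.n_targets
        for label, ssm in self.speed_sets.items():
            if len(ssm.models) != want:
                raise ValidationError(
                    f"speed set {label!r} has {len(ssm.models)} models, expected {want}"
                )


def _model_seed(base_seed: int, set_idx: int, joint_idx: int, target_idx: int) -> int:
    ss = np.random.SeedSequence([base_seed, set_idx, joint_idx, target_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def train_generator(dataset: TrainingDataset, config: PipelineConfig) -> GeneratorModel:
    """Fit normalizers and the full GP bank, one speed set at a time."""
    groups: dict[str, list[int]] = {}
    for i, (_, pattern) in enumerate(dataset.pairs):
        label = speed_set_label(pattern.walking_speed, config)
        groups.setdefault(label, []).append(i)

    target_names = config.target_names()
    all_targets = build_training_targets(dataset, config)
    speed_sets: dict[str, SpeedSetModel] = {}
    for set_idx, (label, idx) in enumerate(sorted(groups.items())):
        if len(idx) < 2:
            raise ValueError(
                f"speed set {label!r} has only {len(idx)} pair(s); need >= 2"
            )
        bodies = [dataset.pairs[i][0] for i in idx]
        stats = fit_normalizer(bodies)
        X = normalize_cohort(bodies, stats)
        models: dict[tuple[str, str], gpr.GPRModel] = {}
        for joint_idx, joint in enumerate(JOINT_IDS):
            Y = all_targets[joint][idx]
            for target_idx, tname in enumerate(target_names):
                kcfg = gpr.KernelConfig(
                    ard=config.ard,
                    n_restarts=config.n_restarts,
                    seed=_model_seed(config.seed, set_idx, joint_idx, target_idx),
                )
                models[(joint, tname)] = gpr.fit(X, Y[:, target_idx], kcfg)
        speed_sets[label] = SpeedSetModel(stats=stats, models=models)
    return GeneratorModel(speed_sets=speed_sets, config=config)


def generate_gait(
    model: GeneratorModel,
    body: BodyParameters,
    speed_set: str = DEFAULT_SPEED_SET,
    subject_id: str | None = None,
    trial_id: str = "generated",
) -> GaitPattern:
    """Predict a six-joint gait pattern from body parameters alone."""
    if speed_set not in model.speed_sets:
        raise ValueError(
            f"unknown speed set {speed_set!r}; trained sets: {sorted(model.speed_sets)}"
        )
    ssm = model.speed_sets[speed_set]
    z = normalize(body, ssm.stats)[None, :]
    cfg = model.config
    cycles: dict[str, JointCycle] = {}
    for joint in JOINT_IDS:
        targets = np.empty(cfg.n_targets)
        for k, tname in enumerate(cfg.target_names()):
            mean, _ = gpr.predict(ssm.models[(joint, tname)], z)
            targets[k] = mean[0]
        fv = targets_to_features(targets)
        cycles[joint] = reconstruct_cycle(fv, cfg.l0, joint_id=joint)
    sid = subject_id if subject_id is not None else (body.subject_id or "generated")
    return GaitPattern(sid, trial_id, cycles)


def export_trajectory(
    pattern: GaitPattern, sample_rate_hz: float, cycle_duration_s: float
):
    """Time-stamped joint trajectory over one gait cycle.

    Returns a pandas DataFrame with a ``time_s`` column and one column per
    joint, resampled by periodic linear interpolation to the requested
    controller rate (e.g. 1000 Hz for an exoskeleton control loop).
    """
    import pandas as pd

    if sample_rate_hz <= 0 or cycle_duration_s <= 0:
        raise ValueError("sample rate and cycle duration must be positive")
    n = int(round(sample_rate_hz * cycle_duration_s))
    if n < 1:
        raise ValueError("requested trajectory has no samples")
    t = np.arange(n) / sample_rate_hz
    u = (t / cycle_duration_s) % 1.0
    data = {"time_s": t}
    L = pattern.cycle_length
    xp = np.arange(L + 1) / L
    for joint in JOINT_IDS:
        fp = np.concatenate([pattern.cycles[joint].angles, pattern.cycles[joint].angles[:1]])
        data[joint] = np.interp(u, xp, fp)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# serialization

def generator_to_dict(model: GeneratorModel) -> dict:
    cfg = model.config
    payload = {
        "format_version": FORMAT_VERSION,
        "config": {
            "l0": cfg.l0,
            "n_harmonics": cfg.n_harmonics,
            "seed": cfg.seed,
            "n_restarts": cfg.n_restarts,
            "ard": cfg.ard,
            "resample_method": cfg.resample_method,
            "speed_bins": cfg.speed_bins,
        },
        "speed_sets": {},
    }
    for label, ssm in model.speed_sets.items():
        payload["speed_sets"][label] = {
            "normalization": {
                "mean": ssm.stats.mean.tolist(),
                "scale": ssm.stats.scale.tolist(),
                "constant": ssm.stats.constant.astype(bool).tolist(),
            },
            "models": {
                f"{joint}:{tname}": gpr.model_to_dict(m)
                for (joint, tname), m in ssm.models.items()
            },
        }
    return payload


def generator_from_dict(payload: dict) -> GeneratorModel:
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {payload.get('format_version')!r}"
        )
    c = payload["config"]
    config = PipelineConfig(
        l0=c["l0"],
        n_harmonics=c["n_harmonics"],
        seed=c["seed"],
        n_restarts=c["n_restarts"],
        ard=c["ard"],
        resample_method=c["resample_method"],
        speed_bins=[tuple(b) for b in c["speed_bins"]] if c["speed_bins"] else None,
    )
    speed_sets = {}
    for label, raw in payload["speed_sets"].items():
        norm = raw["normalization"]
        stats = NormalizationStats(
            mean=np.asarray(norm["mean"], dtype=float),
            scale=np.asarray(norm["scale"], dtype=float),
            constant=np.asarray(norm["constant"], dtype=bool),
        )
        models = {}
        for key, m in raw["models"].items():
            joint, tname = key.split(":")
            models[(joint, tname)] = gpr.model_from_dict(m)
        speed_sets[label] = SpeedSetModel(stats=stats, models=models)
    return GeneratorModel(speed_sets=speed_sets, config=config)


def save_generator(model: GeneratorModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(generator_to_dict(model)))


def load_generator(path: str | Path) -> GeneratorModel:
    return generator_from_dict(json.loads(Path(path).read_text()))
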