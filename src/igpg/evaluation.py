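"""Performance metrics and the leave-one-out validation protocol.

Two metrics compare a predicted joint-angle cycle against the measured one
after both are resampled to the same fixed length L0: the mean absolute
error in degrees and the Pearson correlation coefficient.  Leave-one-out
cross-validation holds out one subject at a time, trains the full
generator on the rest, predicts the held-out subject's six cycles from
body parameters alone, and reports per-joint mean(SD) of both metrics
across subjects.  A population-mean baseline (every held-out subject
predicted with the training-mean feature vector — the analogue of guiding
everyone with the same population-average gait) is reported alongside.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .codec import JOINT_IDS, JOINT_LABELS, reconstruct_cycle, resample_cycle
from .pipeline import (
    PipelineConfig,
    TrainingDataset,
    build_training_targets,
    generate_gait,
    speed_set_label,
    targets_to_features,
    train_generator,
)


class ConstantInputError(ValueError):
    """Pearson correlation is undefined for a constant sequence."""


def mae(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Mean absolute pointwise error between two equal-length cycles (degrees)."""
    actual = np.asarray(actual, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if actual.size != predicted.size:
        raise ValueError(f"length mismatch: {actual.size} vs {predicted.size}")
    if actual.size < 1:
        raise ValueError("cycles must be non-empty")
    return float(np.mean(np.abs(predicted - actual)))


def pearson(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Pearson correlation cov(x, y) / sqrt(var(x) var(y)) of two cycles."""
    x = np.asarray(actual, dtype=float).ravel()
    y = np.asarray(predicted, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        raise ConstantInputError("correlation undefined for a constant cycle")
    rho = float(xc @ yc) / np.sqrt(vx * vy)
    return float(np.clip(rho, -1.0, 1.0))


def _subject_metrics(
    actual_cycles: dict[str, np.ndarray], predicted_cycles: dict[str, np.ndarray]
) -> dict[str, tuple[float, float]]:
    """Per-joint (MAE, rho) for one subject/trial."""
    out = {}
    for j in JOINT_IDS:
        out[j] = (
            mae(actual_cycles[j], predicted_cycles[j]),
            pearson(actual_cycles[j], predicted_cycles[j]),
        )
    return out


def loocv(
    dataset: TrainingDataset,
    config: PipelineConfig,
    include_baseline: bool = True,
) -> pd.DataFrame:
    """Leave-one-subject-out validation of the full generation pipeline.

    Returns a six-row DataFrame (rows in the conventional joint order)
    with columns ``joint, label, mae_mean, mae_sd, rho_mean, rho_sd`` and,
    when ``include_baseline``, ``baseline_mae_mean, baseline_mae_sd``:
    the same metrics for the training-mean-feature predictor.

    A subject's trials are scored individually and averaged before the
    across-subject mean/SD (sample, n-1 denominator) is taken.
    """
    subject_ids = dataset.subject_ids()
    if len(subject_ids) < 3:
        raise ValueError(f"need >= 3 subjects for leave-one-out, got {len(subject_ids)}")

    per_subject: dict[str, dict[str, list[tuple[float, float]]]] = {
        j: {} for j in JOINT_IDS
    }
    base_per_subject: dict[str, dict[str, list[float]]] = {j: {} for j in JOINT_IDS}

    for held_out in subject_ids:
        train_pairs = [p for p in dataset.pairs if p[1].subject_id != held_out]
        test_pairs = [p for p in dataset.pairs if p[1].subject_id == held_out]
        train_ds = TrainingDataset(train_pairs)
        model = train_generator(train_ds, config)

        baseline_cycles_by_set: dict[str, dict[str, np.ndarray]] = {}
        if include_baseline:
            train_targets = build_training_targets(train_ds, config)
            labels = [
                speed_set_label(p.walking_speed, config) for _, p in train_pairs
            ]
            for set_label in set(labels):
                idx = [i for i, lab in enumerate(labels) if lab == set_label]
                baseline_cycles_by_set[set_label] = {
                    j: reconstruct_cycle(
                        targets_to_features(train_targets[j][idx].mean(axis=0)),
                        config.l0,
                        joint_id=j,
                    ).angles
                    for j in JOINT_IDS
                }

        for body, pattern in test_pairs:
            set_label = speed_set_label(pattern.walking_speed, config)
            predicted = generate_gait(model, body, speed_set=set_label)
            actual = {
                j: resample_cycle(
                    pattern.cycles[j], config.l0, method=config.resample_method
                ).angles
                for j in JOINT_IDS
            }
            pred = {j: predicted.cycles[j].angles for j in JOINT_IDS}
            metrics = _subject_metrics(actual, pred)
            for j in JOINT_IDS:
                per_subject[j].setdefault(held_out, []).append(metrics[j])
            if include_baseline:
                base = baseline_cycles_by_set[set_label]
                for j in JOINT_IDS:
                    base_per_subject[j].setdefault(held_out, []).append(
                        mae(actual[j], base[j])
                    )

    rows = []
    for j in JOINT_IDS:
        subj_mae = np.array(
            [np.mean([m for m, _ in per_subject[j][s]]) for s in subject_ids]
        )
        subj_rho = np.array(
            [np.mean([r for _, r in per_subject[j][s]]) for s in subject_ids]
        )
        row = {
            "joint": j,
            "label": JOINT_LABELS[j],
            "mae_mean": subj_mae.mean(),
            "mae_sd": subj_mae.std(ddof=1),
            "rho_mean": subj_rho.mean(),
            "rho_sd": subj_rho.std(ddof=1),
        }
        if include_baseline:
            subj_base = np.array(
                [np.mean(base_per_subject[j][s]) for s in subject_ids]
            )
            row["baseline_mae_mean"] = subj_base.mean()
            row["baseline_mae_sd"] = subj_base.std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)


def format_loocv_table(report: pd.DataFrame) -> str:
    """Aligned-text rendering in the conventional mean(SD) per-joint layout."""
    lines = []
    has_base = "baseline_mae_mean" in report.columns
    header = f"{'Joints':<10}{'GPR MAE (deg)':<16}{'GPR rho':<14}"
    if has_base:
        header += f"{'Baseline MAE (deg)':<20}"
    lines.append(header)
    for _, r in report.iterrows():
        mae_cell = f"{r['mae_mean']:.2f}({r['mae_sd']:.2f})"
        rho_cell = f"{r['rho_mean']:.2f}({r['rho_sd']:.2f})"
        line = f"{r['label']:<10}" + mae_cell.ljust(16) + rho_cell.ljust(14)
        if has_base:
            line += f"{r['baseline_mae_mean']:.2f}({r['baseline_mae_sd']:.2f})"
        lines.append(line.rstrip())
    return "\n".join(lines) + "\n"


def write_loocv_report(report: pd.DataFrame, path, fmt: str = "csv") -> None:
    """Write the LOOCV summary as CSV or aligned text."""
    if fmt == "csv":
        report.to_csv(path, index=False)
    elif fmt == "txt":
        with open(path, "w") as fh:
            fh.write(format_loocv_table(report))
    else:
        raise ValueError(f"unknown report format {fmt!r}")
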