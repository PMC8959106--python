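"""The 28-slot anthropometric parameter vector and its cohort normalization.

Twenty-three slots are classical anthropometric measurements (leg length,
knee diameter, trunk length, ...); the remaining five default to height,
weight, age, sex and self-selected walking speed, and can be re-registered
for cohorts that record something else.  Lengths, widths, heights and
circumferences are centimetres; weight kilograms; age years; sex coded
0/1; walking speed m/s.

Body parameters are z-scored against a training cohort before entering
the regression; slots that are constant across the cohort carry no
information and are flagged and dropped from the model input.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .codec import ValidationError

#: Named measurement slots (centimetres unless noted).
MEASUREMENT_SLOTS: tuple[str, ...] = (
    "leg_length",
    "knee_diameter",
    "malleolus_width",
    "acromion_height",
    "elbow_width",
    "wrist_width",
    "palm_height",
    "head_length",
    "neck_length",
    "trunk_length",
    "biacromion_width",
    "brachium_length",
    "antebrachium_length",
    "biiliac_width",
    "thigh_length",
    "calf_length",
    "malleolus_height",
    "foot_length",
    "palm_length",
    "biposterior_iliac_width",
    "foot_width",
    "bitrochanteric_width",
    "waist_circumference",
)

#: Default identity of the five configurable slots.
DEFAULT_EXTRA_SLOTS: tuple[str, ...] = ("height", "weight", "age", "sex", "walking_speed")

#: Canonical slot order: height and weight lead, the 23 measurements follow,
#: then age, sex and walking speed.
SLOT_NAMES: tuple[str, ...] = (
    ("height", "weight") + MEASUREMENT_SLOTS + ("age", "sex", "walking_speed")
)

N_SLOTS = len(SLOT_NAMES)
assert N_SLOTS == 28

#: Slots that must be strictly positive (physical dimensions and speed).
POSITIVE_SLOTS: frozenset[str] = frozenset(
    MEASUREMENT_SLOTS + ("height", "weight", "walking_speed")
)

_CONST_TOL = 1e-12


@dataclass(frozen=True)
class BodyParameters:
    """Canonically ordered 28-vector of body parameters for one subject."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_SLOTS,):
            raise ValidationError(f"expected {N_SLOTS} slots, got shape {v.shape}")
        for name, x in zip(SLOT_NAMES, v):
            if not np.isfinite(x):
                raise ValidationError(f"slot {name!r} is not finite")
            if name in POSITIVE_SLOTS and x <= 0:
                raise ValidationError(f"slot {name!r} must be > 0, got {x}")
        object.__setattr__(self, "values", v)

    def __getitem__(self, slot: str) -> float:
        return float(self.values[SLOT_NAMES.index(slot)])

    def as_dict(self) -> dict[str, float]:
        return {name: float(x) for name, x in zip(SLOT_NAMES, self.values)}


def validate_body(record: Mapping[str, float], subject_id: str = "") -> BodyParameters:
    """Build a canonical BodyParameters vector from a named record.

    Accepts any key order; every one of the 28 canonical slots must be
    present.  Raises :class:`ValidationError` naming the offending slot.
    """
    missing = [name for name in SLOT_NAMES if name not in record]
    if missing:
        raise ValidationError(f"missing body-parameter slot(s): {missing}")
    values = np.array([float(record[name]) for name in SLOT_NAMES])
    sid = subject_id or str(record.get("subject_id", ""))
    return BodyParameters(values=values, subject_id=sid)


@dataclass(frozen=True)
class NormalizationStats:
    """Per-slot location/scale of a training cohort (population convention).

    ``constant`` flags slots whose cohort scale is (numerically) zero; those
    slots are excluded from the model input rather than divided by zero.
    """

    mean: np.ndarray
    scale: np.ndarray
    constant: np.ndarray  # bool mask

    def __post_init__(self) -> None:
        for name in ("mean", "scale", "constant"):
            v = np.asarray(getattr(self, name))
            if v.shape != (N_SLOTS,):
                raise ValidationError(f"{name} must have shape ({N_SLOTS},)")
            object.__setattr__(self, name, v)
        if np.any(self.scale[~self.constant] <= 0):
            raise ValidationError("non-constant slot with non-positive scale")

    @property
    def retained_slots(self) -> tuple[str, ...]:
        return tuple(n for n, c in zip(SLOT_NAMES, self.constant) if not c)


def fit_normalizer(cohort: Sequence[BodyParameters]) -> NormalizationStats:
    """Per-slot mean and population standard deviation over a cohort."""
    if len(cohort) < 2:
        raise ValueError(f"need at least 2 subjects to fit a normalizer, got {len(cohort)}")
    mat = np.stack([b.values for b in cohort])
    mean = mat.mean(axis=0)
    scale = mat.std(axis=0)  # population (1/N) convention
    constant = scale <= _CONST_TOL * np.maximum(1.0, np.abs(mean))
    safe_scale = np.where(constant, 1.0, scale)
    return NormalizationStats(mean=mean, scale=safe_scale, constant=constant)


def normalize(body: BodyParameters, stats: NormalizationStats) -> np.ndarray:
    """Z-score the retained (non-constant) slots, in canonical order."""
    z = (body.values - stats.mean) / stats.scale
    return z[~stats.constant]


def normalize_cohort(
    cohort: Iterable[BodyParameters], stats: NormalizationStats
) -> np.ndarray:
    """Stack normalized vectors into an (n_subjects, n_retained) matrix."""
    return np.stack([normalize(b, stats) for b in cohort])


def denormalize(z: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Invert :func:`normalize`; constant slots are filled with the cohort mean."""
    z = np.asarray(z, dtype=float)
    retained = ~stats.constant
    if z.shape != (int(retained.sum()),):
        raise ValueError(
            f"expected {int(retained.sum())} retained values, got shape {z.shape}"
        )
    out = stats.mean.copy()
    out[retained] = stats.mean[retained] + z * stats.scale[retained]
    return out
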