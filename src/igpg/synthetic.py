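"""Synthetic cohorts with a known anthropometry-to-gait mapping, plus the
packaged clinical trial records.

Real paired anthropometry/gait databases are rarely shareable, so the test
harness for the generation pipeline is a simulator with a ground truth the
pipeline is supposed to recover: each subject's body parameters are drawn
uniformly from plausible adult ranges, their true Fourier coefficients are
a canonical-walk template plus configured smooth effects of (centred) body
parameters, and the observed cycles are the reconstructed waveforms plus
i.i.d. Gaussian measurement noise per sample.

The template coefficient bank is a synthetic stand-in shaped like normal
sagittal-plane walking (hip flexion dominated by the stride fundamental,
knee flexion with a strong second harmonic from the swing-phase peak,
ankle excursion of roughly +/-15 degrees); it is an implementation
constant, not measured data.

The module also generates paired before/after clinical session records
(for power and type-I-error checks of the clinical statistics) and loads
the packaged nine-subject trial tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .anthropometry import SLOT_NAMES, BodyParameters
from .clinical import SessionRecord
from .codec import (
    DEFAULT_L0,
    JOINT_IDS,
    GaitPattern,
    JointCycle,
    JointFeatureVector,
)
from .pipeline import TrainingDataset

# ---------------------------------------------------------------------------
# body-parameter sampling ranges (cm / kg / years / m/s); spans chosen to
# cover the demographics of a small adult rehabilitation cohort
DEFAULT_SLOT_RANGES: dict[str, tuple[float, float]] = {
    "height": (153.0, 174.0),
    "weight": (51.0, 90.0),
    "leg_length": (78.0, 95.0),
    "knee_diameter": (8.0, 12.0),
    "malleolus_width": (6.0, 8.0),
    "acromion_height": (125.0, 148.0),
    "elbow_width": (6.0, 8.0),
    "wrist_width": (4.5, 6.5),
    "palm_height": (9.0, 12.0),
    "head_length": (17.0, 21.0),
    "neck_length": (9.0, 13.0),
    "trunk_length": (45.0, 58.0),
    "biacromion_width": (32.0, 42.0),
    "brachium_length": (28.0, 36.0),
    "antebrachium_length": (22.0, 29.0),
    "biiliac_width": (24.0, 32.0),
    "thigh_length": (38.0, 50.0),
    "calf_length": (34.0, 44.0),
    "malleolus_height": (5.0, 8.0),
    "foot_length": (22.0, 28.0),
    "palm_length": (15.0, 20.0),
    "biposterior_iliac_width": (8.0, 12.0),
    "foot_width": (8.0, 11.0),
    "bitrochanteric_width": (28.0, 36.0),
    "waist_circumference": (65.0, 105.0),
    "age": (33.0, 69.0),
    "sex": (0.0, 1.0),  # sampled as 0/1
    "walking_speed": (0.5, 1.2),
}

#: Synthetic canonical-walk template: (a0, a1, a2, a3) degrees and
#: (phi1, phi2, phi3) radians per joint.  Left/right differ slightly so the
#: sides are distinguishable in tests.
SYNTHETIC_TEMPLATES: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "hip_L": ((10.0, 22.0, 4.0, 1.5), (0.30, -1.20, 0.80)),
    "knee_L": ((25.0, 18.0, 12.0, 3.0), (1.00, -0.50, 1.80)),
    "ankle_L": ((2.0, 8.0, 5.0, 2.0), (-0.80, 1.20, -2.00)),
    "hip_R": ((10.5, 21.5, 4.2, 1.4), (0.35, -1.15, 0.85)),
    "knee_R": ((24.5, 18.5, 11.5, 3.2), (1.05, -0.45, 1.75)),
    "ankle_R": ((2.2, 7.8, 5.2, 1.9), (-0.75, 1.25, -1.95)),
}

_COEFF_NAMES = ("a0", "a1", "a2", "a3", "phi1", "phi2", "phi3")


@dataclass(frozen=True)
class Effect:
    """A smooth dependence of one Fourier coefficient on one body slot.

    ``slope`` is degrees (or radians, for phases) per unit of the centred
    slot; ``kind='linear'`` applies slope * (x - centre), ``kind='quadratic'``
    applies slope * (x - centre)^2 / half_range to exercise nonlinearity
    while keeping the magnitude comparable.
    """

    slot: str
    joint_id: str
    coeff: str  # one of a0..a3, phi1..phi3
    slope: float
    kind: str = "linear"

    def __post_init__(self) -> None:
        if self.slot not in SLOT_NAMES:
            raise ValueError(f"effect references unknown slot {self.slot!r}")
        if self.joint_id not in JOINT_IDS:
            raise ValueError(f"effect references unknown joint {self.joint_id!r}")
        if self.coeff not in _COEFF_NAMES:
            raise ValueError(f"effect references unknown coefficient {self.coeff!r}")
        if self.kind not in ("linear", "quadratic"):
            raise ValueError(f"unknown effect kind {self.kind!r}")


def _both_sides(slot: str, joint: str, coeff: str, slope: float) -> list[Effect]:
    return [
        Effect(slot, f"{joint}_L", coeff, slope),
        Effect(slot, f"{joint}_R", coeff, slope),
    ]


#: Default effect map: longer legs lengthen and amplify hip motion, longer
#: thighs amplify knee flexion, shank/foot geometry drives the ankle, and
#: faster walking amplifies everything; age damps hip excursion.
DEFAULT_EFFECTS: tuple[Effect, ...] = tuple(
    _both_sides("leg_length", "hip", "a1", 0.25)
    + _both_sides("leg_length", "hip", "a0", 0.10)
    + _both_sides("thigh_length", "knee", "a1", 0.50)
    + _both_sides("thigh_length", "knee", "a2", 0.20)
    + _both_sides("calf_length", "ankle", "a1", 0.20)
    + _both_sides("foot_length", "ankle", "a2", 0.15)
    + _both_sides("walking_speed", "hip", "a1", 6.0)
    + _both_sides("walking_speed", "knee", "a1", 8.0)
    + _both_sides("walking_speed", "ankle", "a1", 3.0)
    + _both_sides("height", "knee", "a0", 0.08)
    + _both_sides("age", "hip", "a1", -0.05)
)


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort."""

    n_subjects: int = 20
    seed: int = 0
    slot_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SLOT_RANGES)
    )
    effects: tuple[Effect, ...] = DEFAULT_EFFECTS
    noise_sd: float = 0.5  # degrees per sample
    trials_per_subject: int = 1
    cycle_length: int = DEFAULT_L0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        missing = [s for s in SLOT_NAMES if s not in self.slot_ranges]
        if missing:
            raise ValueError(f"slot_ranges missing slots: {missing}")


def _true_features(
    body: BodyParameters, config: CohortConfig
) -> dict[str, JointFeatureVector]:
    """Template + effect-map coefficients for one subject (canonical form)."""
    coeffs = {
        j: {n: v for n, v in zip(_COEFF_NAMES, a + phi)}
        for j, (a, phi) in SYNTHETIC_TEMPLATES.items()
    }
    for eff in config.effects:
        lo, hi = config.slot_ranges[eff.slot]
        centre = 0.5 * (lo + hi)
        x = body[eff.slot] - centre
        if eff.kind == "quadratic":
            half = max(0.5 * (hi - lo), 1e-12)
            delta = eff.slope * x * x / half
        else:
            delta = eff.slope * x
        coeffs[eff.joint_id][eff.coeff] += delta
    return {
        j: JointFeatureVector(
            a=np.array([c["a0"], c["a1"], c["a2"], c["a3"]]),
            phi=np.array([c["phi1"], c["phi2"], c["phi3"]]),
        )
        for j, c in coeffs.items()
    }


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[TrainingDataset, dict[str, dict[str, JointFeatureVector]]]:
    """Draw a cohort and its noisy gait recordings.

    Returns the training dataset and the noise-free ground-truth feature
    table (subject_id -> joint_id -> JointFeatureVector) for recovery tests.
    Fully reproducible from ``config.seed``.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_subjects - 1))
    pairs: list[tuple[BodyParameters, GaitPattern]] = []
    truth: dict[str, dict[str, JointFeatureVector]] = {}
    u = np.arange(config.cycle_length) / config.cycle_length

    for i in range(config.n_subjects):
        sid = f"S{i:0{width}d}"
        values = np.empty(len(SLOT_NAMES))
        for k, slot in enumerate(SLOT_NAMES):
            lo, hi = config.slot_ranges[slot]
            if slot == "sex":
                values[k] = float(rng.integers(0, 2))
            else:
                values[k] = rng.uniform(lo, hi)
        body = BodyParameters(values=values, subject_id=sid)
        feats = _true_features(body, config)
        truth[sid] = feats
        for t in range(config.trials_per_subject):
            cycles = {}
            for j in JOINT_IDS:
                clean = feats[j].evaluate(u)
                noise = rng.normal(0.0, config.noise_sd, size=clean.size)
                cycles[j] = JointCycle(j, clean + noise)
            pattern = GaitPattern(
                subject_id=sid,
                trial_id=f"T{t}",
                cycles=cycles,
                walking_speed=body["walking_speed"],
            )
            pairs.append((body, pattern))
    return TrainingDataset(pairs), truth


# ---------------------------------------------------------------------------
# synthetic clinical sessions

@dataclass
class TrialEffectConfig:
    """Distribution of before/after changes for the two training conditions.

    Defaults are calibrated to the packaged nine-subject trial: SpO2 falls
    by 2.33% (general guidance) vs 0.78% (individualized), HR rises by
    10.78 vs 5.67 bpm, with the session SDs recomputed from the per-subject
    variations.  ``correlation`` is the within-subject correlation of
    changes across the two sessions (a subject-level responsiveness shared
    between days); the published tables only constrain the marginals.
    """

    spo2_mean: dict[str, float] = field(
        default_factory=lambda: {"general": -2.33, "individualized": -0.78}
    )
    spo2_sd: dict[str, float] = field(
        default_factory=lambda: {"general": float(np.sqrt(2.0)), "individualized": 0.972}
    )
    hr_mean: dict[str, float] = field(
        default_factory=lambda: {"general": 10.78, "individualized": 5.67}
    )
    hr_sd: dict[str, float] = field(
        default_factory=lambda: {"general": 6.553, "individualized": 5.979}
    )
    correlation: float = 0.6

    @classmethod
    def zero_effect(cls) -> "TrialEffectConfig":
        """Both conditions share one change distribution (null hypothesis true)."""
        cfg = cls()
        for d in (cfg.spo2_mean, cfg.hr_mean):
            d["general"] = d["individualized"] = 0.0
        for d in (cfg.spo2_sd, cfg.hr_sd):
            sd = 0.5 * (d["general"] + d["individualized"])
            d["general"] = d["individualized"] = sd
        return cfg


def _correlated_pair(
    rng: np.random.Generator, mu: dict[str, float], sd: dict[str, float], rho: float
) -> tuple[float, float]:
    z_shared = rng.normal()
    zg, zi = rng.normal(), rng.normal()
    a = np.sqrt(max(rho, 0.0))
    b = np.sqrt(max(1.0 - rho, 0.0))
    return (
        mu["general"] + sd["general"] * (a * z_shared + b * zg),
        mu["individualized"] + sd["individualized"] * (a * z_shared + b * zi),
    )


def generate_trial_records(
    effects: TrialEffectConfig | None = None,
    n_subjects: int = 9,
    seed: int = 0,
) -> tuple[list[SessionRecord], list[SessionRecord]]:
    """Paired synthetic (general, individualized) session records.

    Baselines are drawn per session (SpO2 uniform 97-99%, HR uniform
    75-105 bpm); changes follow the configured session distributions with
    the configured between-session correlation.  SpO2 values are clipped
    to the physical ceiling of 100%.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    effects = effects or TrialEffectConfig()
    rng = np.random.default_rng(seed)
    general: list[SessionRecord] = []
    individualized: list[SessionRecord] = []
    for i in range(n_subjects):
        sid = f"P{i + 1}"
        d_spo2 = _correlated_pair(rng, effects.spo2_mean, effects.spo2_sd, effects.correlation)
        d_hr = _correlated_pair(rng, effects.hr_mean, effects.hr_sd, effects.correlation)
        for session, records, k in (
            ("general", general, 0),
            ("individualized", individualized, 1),
        ):
            spo2_before = rng.uniform(97.0, 99.0)
            hr_before = rng.uniform(75.0, 105.0)
            records.append(
                SessionRecord(
                    subject_id=sid,
                    session=session,
                    spo2_before=spo2_before,
                    spo2_after=float(np.clip(spo2_before + d_spo2[k], 70.0, 100.0)),
                    hr_before=hr_before,
                    hr_after=float(np.clip(hr_before + d_hr[k], 31.0, 219.0)),
                )
            )
    return general, individualized


# ---------------------------------------------------------------------------
# packaged trial fixtures

FIXTURE_IDS = ("demographics", "general", "individualized")

_FIXTURE_FILES = {
    "demographics": "demographics.csv",
    "general": "sessions_general.csv",
    "individualized": "sessions_individualized.csv",
}

#: Published per-session summary statistics (mean, SD) of the variations.
#: The general-session SpO2 SD was printed as 1.1414 but recomputes to
#: sqrt(2) from its own per-subject values; the printed value is kept here
#: verbatim so reports can flag the inconsistency.
PUBLISHED_SUMMARY: dict[tuple[str, str], tuple[float, float]] = {
    ("general", "spo2"): (-2.33, 1.1414),
    ("individualized", "spo2"): (-0.78, 0.972),
    ("general", "hr"): (10.78, 6.553),
    ("individualized", "hr"): (5.67, 5.979),
}


def _fixture_frame(table_id: str) -> pd.DataFrame:
    path = resources.files("igpg.data").joinpath(_FIXTURE_FILES[table_id])
    with resources.as_file(path) as p:
        return pd.read_csv(p)


def load_fixture(table_id: str):
    """Packaged nine-subject trial tables.

    ``'demographics'`` returns a DataFrame; ``'general'`` and
    ``'individualized'`` return lists of :class:`SessionRecord`.
    """
    if table_id not in FIXTURE_IDS:
        raise ValueError(f"unknown fixture {table_id!r}; expected one of {FIXTURE_IDS}")
    df = _fixture_frame(table_id)
    if table_id == "demographics":
        return df
    return [
        SessionRecord(
            subject_id=str(r.subject_id),
            session=r.session,
            spo2_before=float(r.spo2_before),
            spo2_after=float(r.spo2_after),
            hr_before=float(r.hr_before),
            hr_after=float(r.hr_after),
        )
        for r in df.itertuples()
    ]
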