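"""Gait-cycle containers and the truncated Fourier codec.

A gait cycle is one full stride of a single joint, sampled uniformly over
0-100% of the cycle on a half-open grid (the first sample is at 0%, the
last one step before 100%; the 100% sample would duplicate the 0% one and
is never stored).  Six sagittal-plane joints are modelled: left/right hip,
knee and ankle flexion angles in degrees.

Each cycle is compressed to an amplitude-phase cosine series

    theta(u) = a0 + sum_{h=1..n} a_h * cos(2*pi*h*u - phi_h),   u in [0, 1)

with ``n`` harmonics of the gait-cycle fundamental (default 3).  The
coefficient vector (a0, a1..an, phi1..phin) is the per-joint gait feature
that downstream regression predicts from body parameters; reconstruction
is plain evaluation of the series on a fixed-length grid.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.signal import resample as _fourier_resample

JOINT_IDS: tuple[str, ...] = (
    "hip_L", "knee_L", "ankle_L", "hip_R", "knee_R", "ankle_R",
)

#: Display labels in the conventional report ordering (left side first).
JOINT_LABELS: dict[str, str] = {
    "hip_L": "Hip(L)", "knee_L": "Knee(L)", "ankle_L": "Ankle(L)",
    "hip_R": "Hip(R)", "knee_R": "Knee(R)", "ankle_R": "Ankle(R)",
}

#: Default number of samples per normalized gait cycle (percent grid 0..100,
#: exclusive of 100).
DEFAULT_L0 = 101

#: Default number of harmonics retained by the codec.
DEFAULT_N_HARMONICS = 3

MIN_CYCLE_LEN = 8


class ValidationError(ValueError):
    """Raised when an input container violates its invariants."""


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phases to the half-open interval (-pi, pi]."""
    return np.mod(np.asarray(phi, dtype=float) - np.pi, -2.0 * np.pi) + np.pi


def canonicalize(a: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return the canonical (a, phi) pair describing the same waveform.

    Harmonic amplitudes are made non-negative (a negative amplitude is a
    half-turn phase shift) and phases are wrapped to (-pi, pi].  The mean
    term ``a[0]`` is left signed.
    """
    a = np.array(a, dtype=float)
    phi = np.array(phi, dtype=float)
    neg = a[1:] < 0
    a[1:] = np.abs(a[1:])
    phi = phi + np.pi * neg
    return a, _wrap_phase(phi)


@dataclass(frozen=True)
class JointCycle:
    """One joint's rotation angle over exactly one gait cycle.

    ``angles`` are degrees sampled uniformly on the half-open grid
    u_i = i / L for i = 0..L-1 (percent-of-cycle 0 inclusive, 100 exclusive).
    """

    joint_id: str
    angles: np.ndarray

    def __post_init__(self) -> None:
        if self.joint_id not in JOINT_IDS:
            raise ValidationError(
                f"unknown joint_id {self.joint_id!r}; expected one of {JOINT_IDS}"
            )
        angles = np.asarray(self.angles, dtype=float)
        if angles.ndim != 1:
            raise ValidationError("angles must be a 1-D sequence")
        if angles.size < MIN_CYCLE_LEN:
            raise ValidationError(
                f"cycle must have at least {MIN_CYCLE_LEN} samples, got {angles.size}"
            )
        if not np.all(np.isfinite(angles)):
            raise ValidationError(f"non-finite angle in cycle for {self.joint_id}")
        object.__setattr__(self, "angles", angles)

    def __len__(self) -> int:
        return self.angles.size

    @property
    def grid(self) -> np.ndarray:
        """Percent-of-cycle positions of the samples (0 <= u < 100)."""
        n = self.angles.size
        return 100.0 * np.arange(n) / n


@dataclass(frozen=True)
class GaitPattern:
    """Six-joint gait cycles for one subject/trial."""

    subject_id: str
    trial_id: str
    cycles: Mapping[str, JointCycle]
    walking_speed: float | None = None  # m/s

    def __post_init__(self) -> None:
        missing = [j for j in JOINT_IDS if j not in self.cycles]
        if missing:
            raise ValidationError(f"missing joints in gait pattern: {missing}")
        extra = [j for j in self.cycles if j not in JOINT_IDS]
        if extra:
            raise ValidationError(f"unknown joints in gait pattern: {extra}")
        lengths = {len(c) for c in self.cycles.values()}
        if len(lengths) != 1:
            raise ValidationError(f"cycles have inconsistent lengths: {sorted(lengths)}")
        for joint_id, cyc in self.cycles.items():
            if cyc.joint_id != joint_id:
                raise ValidationError(
                    f"cycle stored under {joint_id!r} has joint_id {cyc.joint_id!r}"
                )
        object.__setattr__(self, "cycles", dict(self.cycles))

    @property
    def cycle_length(self) -> int:
        return len(next(iter(self.cycles.values())))


@dataclass(frozen=True)
class JointFeatureVector:
    """Canonical Fourier features of one joint cycle.

    ``a`` holds (a0, a1, ..., an) in degrees, ``phi`` holds (phi1, ..., phin)
    in radians.  The phase of the mean term is identically zero and is not
    stored.  The constructor canonicalizes: harmonic amplitudes >= 0, phases
    in (-pi, pi].
    """

    a: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        phi = np.asarray(self.phi, dtype=float)
        if a.ndim != 1 or phi.ndim != 1 or a.size != phi.size + 1:
            raise ValidationError(
                f"need len(a) == len(phi) + 1, got {a.size} and {phi.size}"
            )
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(phi))):
            raise ValidationError("non-finite Fourier feature")
        a, phi = canonicalize(a, phi)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "phi", phi)

    @property
    def n_harmonics(self) -> int:
        return self.phi.size

    def evaluate(self, u: np.ndarray) -> np.ndarray:
        """Evaluate the cosine series at cycle phases ``u`` (fractions of a cycle)."""
        u = np.asarray(u, dtype=float)
        h = np.arange(1, self.n_harmonics + 1)
        return self.a[0] + np.sum(
            self.a[1:, None] * np.cos(2.0 * np.pi * h[:, None] * u[None, :]
                                      - self.phi[:, None]),
            axis=0,
        )


@dataclass(frozen=True)
class GaitFeatureSet:
    """Fourier features for all six joints of one gait pattern."""

    features: Mapping[str, JointFeatureVector]
    cycle_length: int = DEFAULT_L0

    def __post_init__(self) -> None:
        missing = [j for j in JOINT_IDS if j not in self.features]
        if missing:
            raise ValidationError(f"missing joints in feature set: {missing}")
        n = {f.n_harmonics for f in self.features.values()}
        if len(n) != 1:
            raise ValidationError("inconsistent harmonic counts across joints")
        n_harm = n.pop()
        if self.cycle_length < 2 * n_harm + 2:
            raise ValidationError(
                f"cycle_length {self.cycle_length} too short for {n_harm} harmonics"
            )
        object.__setattr__(self, "features", dict(self.features))

    @property
    def n_harmonics(self) -> int:
        return next(iter(self.features.values())).n_harmonics


def resample_cycle(cycle: JointCycle, l0: int, method: str = "linear") -> JointCycle:
    """Resample a cycle onto the uniform ``l0``-point grid over one period.

    ``method='linear'`` interpolates periodically between samples (robust
    for short, noisy cycles); ``method='fourier'`` uses FFT-based band-limited
    resampling (exact for band-limited signals).
    """
    if l0 < MIN_CYCLE_LEN:
        raise ValueError(f"l0 must be >= {MIN_CYCLE_LEN}, got {l0}")
    src = cycle.angles
    if src.size == l0:
        return JointCycle(cycle.joint_id, src.copy())
    if method == "linear":
        m = src.size
        xp = np.arange(m + 1) / m
        fp = np.concatenate([src, src[:1]])  # close the period
        u = np.arange(l0) / l0
        out = np.interp(u, xp, fp)
    elif method == "fourier":
        out = _fourier_resample(src, l0)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    return JointCycle(cycle.joint_id, out)


def extract_features(
    cycle: JointCycle, n_harmonics: int = DEFAULT_N_HARMONICS
) -> JointFeatureVector:
    """Truncated Fourier features of a cycle via the discrete Fourier transform.

    On a uniform grid the DFT coefficients coincide with the least-squares
    projection onto the cosine/sine basis, so ``a0`` is the sample mean,
    ``a_h = 2|X_h| / L`` and ``phi_h = -arg(X_h)`` for the chosen series
    convention.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    L = len(cycle)
    if L < 2 * n_harmonics + 2:
        raise ValueError(
            f"cycle length {L} too short for {n_harmonics} harmonics "
            f"(need >= {2 * n_harmonics + 2})"
        )
    spec = np.fft.rfft(cycle.angles)
    a = np.empty(n_harmonics + 1)
    a[0] = spec[0].real / L
    a[1:] = 2.0 * np.abs(spec[1 : n_harmonics + 1]) / L
    phi = -np.angle(spec[1 : n_harmonics + 1])
    return JointFeatureVector(a=a, phi=phi)


def reconstruct_cycle(
    features: JointFeatureVector, l0: int = DEFAULT_L0, joint_id: str = "hip_L"
) -> JointCycle:
    """Evaluate the Fourier series on the uniform ``l0``-point cycle grid."""
    if l0 < MIN_CYCLE_LEN:
        raise ValueError(f"l0 must be >= {MIN_CYCLE_LEN}, got {l0}")
    u = np.arange(l0) / l0
    return JointCycle(joint_id, features.evaluate(u))


def extract_pattern_features(
    pattern: GaitPattern,
    l0: int = DEFAULT_L0,
    n_harmonics: int = DEFAULT_N_HARMONICS,
    method: str = "linear",
) -> GaitFeatureSet:
    """Resample every joint cycle to ``l0`` and extract its Fourier features."""
    feats = {
        j: extract_features(resample_cycle(c, l0, method=method), n_harmonics)
        for j, c in pattern.cycles.items()
    }
    return GaitFeatureSet(features=feats, cycle_length=l0)


def reconstruct_pattern(
    feature_set: GaitFeatureSet,
    subject_id: str = "reconstructed",
    trial_id: str = "0",
    walking_speed: float | None = None,
) -> GaitPattern:
    """Rebuild a six-joint gait pattern from a feature set."""
    cycles = {
        j: reconstruct_cycle(f, feature_set.cycle_length, joint_id=j)
        for j, f in feature_set.features.items()
    }
    return GaitPattern(subject_id, trial_id, cycles, walking_speed)
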