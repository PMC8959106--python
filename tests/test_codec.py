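"""Fourier codec: resampling, extraction, reconstruction and their invariants."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igpg.codec import (
    JOINT_IDS,
    GaitPattern,
    JointCycle,
    JointFeatureVector,
    ValidationError,
    canonicalize,
    extract_features,
    extract_pattern_features,
    reconstruct_cycle,
    reconstruct_pattern,
    resample_cycle,
)


def _cycle(values, joint="hip_L"):
    return JointCycle(joint, np.asarray(values, dtype=float))


class TestContainers:
    def test_rejects_short_and_nonfinite_cycles(self):
        with pytest.raises(ValidationError):
            _cycle(np.zeros(5))
        with pytest.raises(ValidationError):
            _cycle([1.0] * 9 + [np.nan])
        with pytest.raises(ValidationError):
            JointCycle("spine", np.zeros(16))

    def test_pattern_requires_all_six_joints_same_length(self):
        cycles = {j: _cycle(np.zeros(16), j) for j in JOINT_IDS}
        GaitPattern("s", "t", cycles)  # valid
        with pytest.raises(ValidationError):
            GaitPattern("s", "t", {k: v for k, v in cycles.items() if k != "knee_R"})
        bad = dict(cycles)
        bad["knee_R"] = _cycle(np.zeros(32), "knee_R")
        with pytest.raises(ValidationError):
            GaitPattern("s", "t", bad)


class TestResample:
    def test_constant_cycle_is_fixed_point(self):
        out = resample_cycle(_cycle(np.full(64, 20.0)), 101)
        assert np.allclose(out.angles, 20.0)
        assert out.joint_id == "hip_L"

    def test_identity_when_already_at_target_length(self):
        src = _cycle(np.sin(np.linspace(0, 5, 101)))
        out = resample_cycle(src, 101)
        assert np.max(np.abs(out.angles - src.angles)) < 1e-9

    def test_cosine_matches_trigonometric_oracle(self):
        # band-limited resampling of cos(2*pi*t) sampled at 50 points
        t50 = np.arange(50) / 50
        src = _cycle(np.cos(2 * np.pi * t50))
        out = resample_cycle(src, 101, method="fourier")
        t101 = np.arange(101) / 101
        assert np.max(np.abs(out.angles - np.cos(2 * np.pi * t101))) < 1e-6

    def test_linear_resampling_is_periodic_not_clamped(self):
        # last target sample sits between the last and the (wrapped) first source sample
        src = _cycle(np.array([0.0, 1, 2, 3, 4, 5, 6, 7], dtype=float))
        out = resample_cycle(src, 16)
        assert out.angles[-1] == pytest.approx(0.5 * (7.0 + 0.0), abs=1e-12)

    def test_l0_too_small_rejected(self):
        with pytest.raises(ValueError):
            resample_cycle(_cycle(np.zeros(16)), 4)


class TestExtract:
    def test_constant_cycle_is_dc_only(self):
        fv = extract_features(_cycle(np.full(32, 5.0)))
        assert np.allclose(fv.a, [5.0, 0, 0, 0], atol=1e-12)
        assert np.allclose(fv.phi, 0.0, atol=1e-12)

    def test_single_harmonic_recovered(self):
        u = np.arange(101) / 101
        fv = extract_features(_cycle(10 * np.cos(2 * np.pi * u)))
        assert abs(fv.a[0]) < 1e-9
        assert fv.a[1] == pytest.approx(10.0, abs=1e-9)
        assert fv.phi[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(fv.a[2:] < 1e-9)

    def test_matches_projection_oracle(self):
        # least-squares projection oracle: explicit inner products with the
        # cos/sin basis on the uniform grid
        rng = np.random.default_rng(11)
        a = np.array([rng.normal(5, 3), *rng.uniform(0.5, 10, 3)])
        phi = rng.uniform(-3, 3, 3)
        L = 101
        u = np.arange(L) / L
        theta = a[0] + sum(
            a[h] * np.cos(2 * np.pi * h * u - phi[h - 1]) for h in (1, 2, 3)
        )
        fv = extract_features(_cycle(theta))

        a_ref = np.empty(4)
        phi_ref = np.empty(3)
        a_ref[0] = theta.mean()
        for h in (1, 2, 3):
            c = 2.0 / L * theta @ np.cos(2 * np.pi * h * u)
            s = 2.0 / L * theta @ np.sin(2 * np.pi * h * u)
            a_ref[h] = np.hypot(c, s)
            phi_ref[h - 1] = np.arctan2(s, c)
        assert np.max(np.abs(fv.a - a_ref)) < 1e-9
        assert np.max(np.abs(fv.phi - phi_ref)) < 1e-9
        # and the generating coefficients themselves are recovered
        _, phi_canon = canonicalize(a.copy(), phi.copy())
        assert np.max(np.abs(fv.a - a)) < 1e-9
        assert np.max(np.abs(fv.phi - phi_canon)) < 1e-9

    def test_too_short_for_harmonics_rejected(self):
        with pytest.raises(ValueError):
            extract_features(_cycle(np.zeros(8)), n_harmonics=4)


class TestReconstruct:
    def test_zero_features_give_zero_cycle(self):
        fv = JointFeatureVector(a=np.zeros(4), phi=np.zeros(3))
        assert np.allclose(reconstruct_cycle(fv, 64).angles, 0.0)

    def test_truncation_error_monotone_in_harmonics(self):
        # realistic multi-harmonic knee-like waveform; brute-force MAE of the
        # n=2 and n=3 truncations
        u = np.arange(101) / 101
        theta = (
            25
            + 18 * np.cos(2 * np.pi * u - 1.0)
            + 12 * np.cos(4 * np.pi * u + 0.5)
            + 3 * np.cos(6 * np.pi * u - 1.8)
            + 1.2 * np.cos(8 * np.pi * u + 0.3)
        )
        cyc = _cycle(theta, "knee_L")
        maes = {}
        for n in (2, 3):
            rec = reconstruct_cycle(extract_features(cyc, n_harmonics=n), 101)
            maes[n] = np.mean(np.abs(rec.angles - theta))
        assert maes[3] <= maes[2]


@st.composite
def band_limited_features(draw):
    a0 = draw(st.floats(-30, 30))
    amps = [draw(st.floats(0, 25)) for _ in range(3)]
    phis = [draw(st.floats(-3.1, 3.14)) for _ in range(3)]
    return JointFeatureVector(a=np.array([a0, *amps]), phi=np.array(phis))


class TestProperties:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(band_limited_features())
    def test_round_trip_exact_for_band_limited(self, fv):
        cyc = reconstruct_cycle(fv, 101)
        rec = reconstruct_cycle(extract_features(cyc), 101)
        assert np.max(np.abs(rec.angles - cyc.angles)) < 1e-9

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(band_limited_features())
    def test_codec_idempotent_on_canonical_features(self, fv):
        fv2 = extract_features(reconstruct_cycle(fv, 101))
        assert np.max(np.abs(fv2.a - fv.a)) < 1e-9
        # phase of a (near-)zero harmonic is arbitrary; compare waveforms instead
        u = np.arange(101) / 101
        assert np.max(np.abs(fv2.evaluate(u) - fv.evaluate(u))) < 1e-9

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(-40, 40), min_size=4, max_size=4),
        st.lists(st.floats(-12, 12), min_size=3, max_size=3),
    )
    def test_canonicalization_preserves_waveform(self, a, phi):
        a = np.asarray(a)
        phi = np.asarray(phi)
        a_c, phi_c = canonicalize(a, phi)
        assert np.all(a_c[1:] >= 0)
        assert np.all((phi_c > -np.pi) & (phi_c <= np.pi))
        u = np.arange(64) / 64
        h = np.arange(1, 4)

        def ev(aa, pp):
            return aa[0] + np.sum(
                aa[1:, None] * np.cos(2 * np.pi * h[:, None] * u[None, :] - pp[:, None]),
                axis=0,
            )

        assert np.max(np.abs(ev(a, phi) - ev(a_c, phi_c))) < 1e-12

    def test_residual_rms_nonincreasing_in_harmonics(self):
        rng = np.random.default_rng(5)
        theta = rng.normal(0, 10, 64)
        cyc = _cycle(theta)
        prev = np.inf
        for n in (1, 2, 3, 4, 5):
            rec = reconstruct_cycle(extract_features(cyc, n_harmonics=n), 64)
            rms = np.sqrt(np.mean((rec.angles - theta) ** 2))
            assert rms <= prev + 1e-12
            prev = rms


def test_pattern_level_helpers_round_trip():
    rng = np.random.default_rng(2)
    cycles = {}
    for j in JOINT_IDS:
        fv = JointFeatureVector(
            a=np.array([rng.normal(10, 5), *rng.uniform(1, 15, 3)]),
            phi=rng.uniform(-3, 3, 3),
        )
        cycles[j] = reconstruct_cycle(fv, 101, joint_id=j)
    pattern = GaitPattern("s1", "t1", cycles, walking_speed=1.0)
    fs = extract_pattern_features(pattern)
    rebuilt = reconstruct_pattern(fs, subject_id="s1")
    for j in JOINT_IDS:
        assert np.max(np.abs(rebuilt.cycles[j].angles - cycles[j].angles)) < 1e-9
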