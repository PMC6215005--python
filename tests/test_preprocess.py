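"""Artifact rejection, CSD transform, ERP averaging and quantification."""

import dataclasses

import numpy as np
import pytest
from scipy.special import sph_harm_y

from nogodecode.montage import default_channels, fibonacci_sphere, unit_sphere_positions
from nogodecode.preprocess import (CSDParams, ERPSet, average_erp,
                                   baseline_correct, csd_matrix,
                                   csd_transform, detect_local_peak,
                                   mean_amplitude, preprocess_subject,
                                   reject_artifact_trials,
                                   validate_electrode_choice)
from nogodecode.synthetic_data import EpochCohort, SubjectEpochs

FS = 64.0
CH16 = default_channels(16)


def make_subject(data, fs=FS, channels=None, labels=None):
    data = np.asarray(data, dtype=np.float32)
    n_trials, n_ch, n_s = data.shape
    channels = tuple(channels or CH16[:n_ch])
    times = (np.arange(n_s) - n_s // 2) * 1000.0 / fs
    if labels is None:
        labels = np.array(["nogo_correct"] * n_trials, dtype="U12")
    return SubjectEpochs("S0", data, labels, channels, fs, times)


def brute_force_reject(x, fs, max_diff_uv=200.0, max_diff_ms=100.0,
                       min_act_uv=0.5, min_act_ms=200.0):
    """Independent oracle: explicit loop over every window position."""
    n_s = x.shape[-1]
    reasons = {}
    for w, check, reason in (
        (max(2, round(max_diff_ms * fs / 1000.0)),
         lambda r: r > max_diff_uv, "max_diff"),
        (max(2, round(min_act_ms * fs / 1000.0)),
         lambda r: r < min_act_uv, "low_activity"),
    ):
        for tr in range(x.shape[0]):
            if tr in reasons:
                continue
            hit = False
            for ch in range(x.shape[1]):
                for start in range(n_s - w + 1):
                    seg = x[tr, ch, start:start + w]
                    if check(seg.max() - seg.min()):
                        hit = True
                        break
                if hit:
                    break
            if hit:
                reasons[tr] = reason
    return reasons


class TestRejection:
    def test_large_step_rejected(self):
        data = np.zeros((2, 16, 160))
        data[0, 3, 80:] = 250.0
        data[1] = 10 * np.sin(np.arange(160) / 3.0)[None, :]
        cleaned, log = reject_artifact_trials(make_subject(data))
        assert cleaned.n_trials == 1
        assert log.iloc[0]["reason"] == "max_diff"

    def test_flat_trial_rejected(self):
        data = 10 * np.sin(np.arange(160) / 3.0) * np.ones((2, 16, 160))
        data[1, 5, :] = 0.0
        cleaned, log = reject_artifact_trials(make_subject(data))
        assert cleaned.n_trials == 1
        assert log.iloc[0]["reason"] == "low_activity"
        assert log.iloc[0]["channel"] == CH16[5]

    def test_smooth_signal_retained(self):
        t = np.arange(160) / FS
        data = np.tile(10 * np.sin(2 * np.pi * 5 * t), (3, 16, 1))
        cleaned, log = reject_artifact_trials(make_subject(data))
        assert cleaned.n_trials == 3 and len(log) == 0

    def test_matches_brute_force_oracle(self, rng):
        data = rng.normal(0, 30, size=(12, 4, 90)).astype(np.float32)
        data[2, 1, 40:] += 260            # step
        data[5, 0, :] = 0.01              # flat channel
        data[7, 3, 10:20] += 300          # short spike
        sub = make_subject(data, channels=CH16[:4])
        cleaned, log = reject_artifact_trials(sub)
        expected = brute_force_reject(data.astype(np.float64), FS)
        assert set(log["trial"]) == set(expected)
        for _, row in log.iterrows():
            assert expected[row["trial"]] == row["reason"]

    def test_idempotent(self, tiny_cohort):
        cohort, _, _ = tiny_cohort
        sub = cohort.subjects[0]
        once, _ = reject_artifact_trials(sub)
        twice, log2 = reject_artifact_trials(once)
        assert twice.n_trials == once.n_trials and len(log2) == 0

    def test_window_longer_than_epoch(self):
        sub = make_subject(np.zeros((1, 16, 20)))
        with pytest.raises(ValueError):
            reject_artifact_trials(sub, min_activity_window_ms=2000.0)


class TestBaseline:
    def test_constant_trace_zeroed(self):
        sub = make_subject(np.full((2, 16, 160), 7.0))
        out = baseline_correct(sub, (-200.0, 0.0))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-6)

    def test_offset_invariance(self, rng):
        data = rng.normal(size=(2, 16, 160)).astype(np.float32)
        out1 = baseline_correct(make_subject(data))
        out2 = baseline_correct(make_subject(data + 5.0))
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-5)

    def test_ramp_closed_form(self):
        sub = make_subject(np.zeros((1, 16, 160)))
        ramp = np.linspace(0.0, 10.0, 160)
        sub = dataclasses.replace(sub, data=np.tile(
            ramp, (1, 16, 1)).astype(np.float32))
        out = baseline_correct(sub, (-200.0, 0.0))
        sel = (sub.times_ms >= -200) & (sub.times_ms <= 0)
        expected = ramp - ramp[sel].mean()
        np.testing.assert_allclose(out.data[0, 0], expected, atol=1e-5)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            baseline_correct(make_subject(np.zeros((1, 16, 160))),
                             (2000.0, 2100.0))


class TestCSD:
    positions = unit_sphere_positions(CH16)

    def test_reference_invariance(self, rng):
        data = rng.normal(size=(2, 16, 40)).astype(np.float32)
        shifted = data + 11.0
        out1 = csd_transform(make_subject(data), self.positions)
        out2 = csd_transform(make_subject(shifted), self.positions)
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-3)

    def test_uniform_potential_maps_to_zero(self):
        data = np.full((1, 16, 10), 3.0, dtype=np.float32)
        out = csd_transform(make_subject(data), self.positions)
        assert np.max(np.abs(out.data)) < 1e-3

    def test_spherical_harmonic_eigenvalue(self):
        """Surface Laplacian of a degree-l harmonic is l(l+1) times itself
        on a dense montage (analytic oracle)."""
        pos = fibonacci_sphere(300)
        mat = csd_matrix(pos, CSDParams(smoothing_lambda=1e-9))
        theta = np.arccos(np.clip(pos[:, 2], -1, 1))
        phi = np.arctan2(pos[:, 1], pos[:, 0])
        for ell in (1, 2, 3, 4):
            y = sph_harm_y(ell, min(ell, 1), theta, phi).real
            out = mat @ y
            ratio = np.dot(out, y) / np.dot(y, y)
            assert abs(ratio - ell * (ell + 1)) / (ell * (ell + 1)) < 0.01

    def test_units_and_errors(self):
        out = csd_transform(make_subject(np.zeros((1, 16, 5))),
                            self.positions)
        assert out.units == "uV/m2"
        with pytest.raises(ValueError, match="16"):
            csd_matrix(self.positions[:8])
        dup = self.positions.copy()
        dup[1] = dup[0]
        with pytest.raises(ValueError, match="duplicate"):
            csd_matrix(dup)

    def test_commutes_with_baseline(self, rng):
        data = rng.normal(size=(2, 16, 160)).astype(np.float32)
        sub = make_subject(data)
        a = baseline_correct(csd_transform(sub, self.positions))
        b = csd_transform(baseline_correct(sub), self.positions)
        np.testing.assert_allclose(a.data, b.data, atol=1e-3)


class TestAveraging:
    def test_identical_trials_average_to_themselves(self):
        trial = np.arange(16.0 * 30).reshape(16, 30)
        sub = make_subject(np.stack([trial, trial]))
        cohort = EpochCohort([sub], sub.channel_names, FS, sub.times_ms)
        erp = average_erp(cohort, "nogo_correct")
        np.testing.assert_allclose(erp.data[0], trial, rtol=1e-6)
        assert erp.n_trials_averaged[0] == 2

    def test_antisymmetric_trials_cancel(self, rng):
        trial = rng.normal(size=(16, 30))
        sub = make_subject(np.stack([trial, -trial]))
        cohort = EpochCohort([sub], sub.channel_names, FS, sub.times_ms)
        erp = average_erp(cohort, "nogo_correct")
        np.testing.assert_allclose(erp.data[0], 0.0, atol=1e-6)

    def test_noisy_average_recovers_template(self, rng):
        times = -1000.0 + np.arange(160) * 1000.0 / FS
        template = 8.0 * np.exp(-0.5 * ((times - 300) / 40) ** 2)
        data = template[None, None, :] + rng.normal(
            0, 5, size=(100, 16, 160))
        sub = make_subject(data)
        cohort = EpochCohort([sub], sub.channel_names, FS, sub.times_ms)
        erp = average_erp(cohort, "nogo_correct")
        r = np.corrcoef(erp.data[0, 0], template)[0, 1]
        assert r > 0.9

    def test_zero_trials_flagged_not_nan(self):
        sub = make_subject(np.zeros((2, 16, 30)),
                           labels=np.array(["go_correct"] * 2, dtype="U12"))
        ok = make_subject(np.zeros((2, 16, 30)))
        ok = dataclasses.replace(ok, subject_id="S1")
        cohort = EpochCohort([sub, ok], sub.channel_names, FS, sub.times_ms)
        erp = average_erp(cohort, "nogo_correct")
        assert erp.dropped_subjects == ["S0"]
        assert not np.isnan(erp.data).any()


def make_erp(data, fs=FS, channels=None, t0=None):
    data = np.asarray(data, dtype=float)
    channels = tuple(channels or CH16[:data.shape[1]])
    t0 = -500.0 if fs > 100 else -1000.0
    times = t0 + np.arange(data.shape[2]) * 1000.0 / fs
    return ERPSet(data, [f"S{i}" for i in range(len(data))], channels,
                  times, "nogo_correct", np.ones(len(data)))


class TestQuantification:
    def test_parabola_peak_latency(self):
        fs = 256.0
        times = -500.0 + np.arange(400) * 1000.0 / fs
        data = np.zeros((1, 16, 400))
        data[0, 0] = -(times - 100.0) ** 2 / 1e3
        res = detect_local_peak(make_erp(data, fs=fs), CH16[0],
                                (90.0, 110.0), +1)[0]
        assert abs(res.latency_ms - 100.0) < 1000.0 / fs
        assert not res.fallback

    def test_monotone_ramp_falls_back_to_edge(self):
        data = np.tile(np.linspace(0, 1, 160), (1, 16, 1))
        res = detect_local_peak(make_erp(data), CH16[0], (90.0, 110.0), +1)[0]
        assert res.fallback
        sel = res.window_ms
        assert res.latency_ms == pytest.approx(109.375)  # window edge sample

    def test_peak_search_restricted_to_window(self):
        times = -1000.0 + np.arange(160) * 1000.0 / FS
        data = np.zeros((1, 16, 160))  # axis matches make_erp at 64 Hz
        data[0, 0] = np.exp(-0.5 * ((times - 100) / 5) ** 2)       # in-window
        data[0, 0] += 50 * np.exp(-0.5 * ((times - 400) / 5) ** 2)  # outside
        res = detect_local_peak(make_erp(data), CH16[0], (90.0, 110.0), +1)[0]
        assert 90 <= res.latency_ms <= 110

    def test_unknown_electrode(self):
        with pytest.raises(KeyError):
            detect_local_peak(make_erp(np.zeros((1, 16, 30))), "XX",
                              (90.0, 110.0))

    def test_mean_amplitude_cases(self):
        data = np.full((2, 16, 160), 5.0)
        erp = make_erp(data)
        np.testing.assert_allclose(
            mean_amplitude(erp, ["Cz"], (250.0, 280.0)), 5.0)
        # linear trace: mean over the window equals the midpoint value
        times = erp.times_ms
        lin = np.tile(times, (1, 16, 1))
        erp2 = make_erp(lin)
        sel = (times >= 250) & (times <= 280)
        np.testing.assert_allclose(
            mean_amplitude(erp2, ["Cz"], (250.0, 280.0))[0],
            times[sel].mean())
        with pytest.raises(ValueError):
            mean_amplitude(erp, [], (250.0, 280.0))

    def test_electrode_validation_recovers_planted_site(self, rng):
        data = rng.normal(size=(50, 16, 40))
        data[:, 4, 10:20] += 5.0
        erp = make_erp(data)
        w = (erp.times_ms[10], erp.times_ms[19])
        selected = validate_electrode_choice(erp, w, alpha=0.0007)
        assert CH16[4] in selected

    def test_electrode_validation_null_rate(self, rng):
        hits = 0
        reps, alpha = 60, 0.05
        for _ in range(reps):
            erp = make_erp(rng.normal(size=(20, 8, 10)),
                           channels=CH16[:8])
            hits += len(validate_electrode_choice(
                erp, (erp.times_ms[0], erp.times_ms[-1]), alpha=alpha))
        rate = hits / (reps * 8)
        assert rate < 3 * alpha   # one-sided test, conservative bound

    def test_electrode_validation_input_checks(self):
        with pytest.raises(ValueError):
            validate_electrode_choice(make_erp(np.zeros((2, 16, 10))),
                                      (0.0, 50.0))


def test_preprocess_subject_stage_order(tiny_cohort):
    cohort, _, _ = tiny_cohort
    sub = cohort.subjects[0]
    positions = unit_sphere_positions(sub.channel_names)
    out, log = preprocess_subject(sub, positions)
    assert out.units == "uV/m2"
    sel = (out.times_ms >= -200) & (out.times_ms <= 0)
    np.testing.assert_allclose(out.data[..., sel].mean(axis=-1), 0.0,
                               atol=1e-3)
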