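"""Cohort generator: determinism, structure, planted ground truth."""

import dataclasses

import numpy as np
import pytest

from nogodecode.behavior import compute_ratio, group_labels, median_split
from nogodecode.montage import default_channels
from nogodecode.preprocess import average_erp
from nogodecode.synthetic_data import (NOGO_CORRECT, ComponentSpec, SimConfig,
                                       amplitude_slope, demo_config,
                                       generate_cohort, generate_subject,
                                       iter_subjects, recovery_components,
                                       simulate_behavior)
from nogodecode.tfr import morlet_kernel, morlet_params, subject_total_power


def small_config(**kw):
    base = dict(n_subjects=4, channels=default_channels(16), fs=64.0,
                epoch_window_ms=(-1000.0, 1500.0), n_trials=40, seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_bit_identical(self, tiny_config, tiny_cohort):
        cohort1, behavior1, man1 = tiny_cohort
        cohort2, behavior2, man2 = generate_cohort(tiny_config)
        for s1, s2 in zip(cohort1, cohort2):
            np.testing.assert_array_equal(s1.data, s2.data)
            np.testing.assert_array_equal(s1.labels, s2.labels)
        assert behavior1.equals(behavior2)
        assert man1["subjects"] == man2["subjects"]

    def test_different_seed_differs(self, tiny_config, tiny_cohort):
        cohort1, _, _ = tiny_cohort
        cohort2, _, _ = generate_cohort(tiny_config.replace(seed=4))
        assert not np.array_equal(cohort1.subjects[0].data,
                                  cohort2.subjects[0].data)

    def test_behavior_only_matches_full_generation(self, tiny_config,
                                                   tiny_cohort):
        _, behavior, _ = tiny_cohort
        assert simulate_behavior(tiny_config).equals(behavior)

    def test_nogo_only_synthesis_keeps_behavior(self):
        cfg = small_config()
        full = simulate_behavior(cfg)
        restricted = simulate_behavior(
            cfg.replace(synthesize_conditions=("nogo",)))
        assert full.equals(restricted)
        epochs, row, _ = next(iter_subjects(
            cfg.replace(synthesize_conditions=("nogo",))))
        assert set(np.unique(epochs.labels)) <= {"nogo_correct", "nogo_fa"}


class TestStructure:
    def test_cohort_shapes_and_axes(self, tiny_config, tiny_cohort):
        cohort, behavior, _ = tiny_cohort
        assert len(cohort) == tiny_config.n_subjects
        sub = cohort.subjects[0]
        assert sub.data.shape == (tiny_config.n_trials, 16,
                                  tiny_config.n_samples)
        assert len(sub.labels) == sub.n_trials
        assert np.all(np.diff(sub.times_ms) > 0) and 0 in sub.times_ms
        assert len(behavior) == tiny_config.n_subjects

    def test_trial_condition_proportions(self):
        cfg = small_config(n_trials=450)
        labels = next(iter_subjects(cfg, with_epochs=False))
        beh = simulate_behavior(cfg)
        n_go = beh["n_go_correct"] / (1 - beh["miss_rate"])
        # ~315 Go / ~135 Nogo in expectation; allow 4 binomial sigmas
        sd = np.sqrt(450 * 0.7 * 0.3)
        assert np.all(np.abs(n_go - 315) < 4 * sd)

    def test_behavior_matches_study_conditions(self):
        beh = simulate_behavior(small_config(n_subjects=60, n_trials=450))
        assert abs(beh["mean_go_rt_ms"].mean() - 348) < 15
        assert abs(beh["fa_rate"].mean() - 0.12) < 0.03
        assert beh["miss_rate"].mean() < 0.05

    def test_go_fraction_one_breaks_nogo_analyses(self):
        cfg = small_config(go_fraction=1.0, components=())
        cohort, _, _ = generate_cohort(cfg)
        with pytest.raises(ValueError, match="nogo"):
            average_erp(cohort, NOGO_CORRECT)


class TestValidation:
    def test_component_latency_outside_epoch_rejected(self):
        with pytest.raises(ValueError, match="latency"):
            small_config(components=(
                ComponentSpec("Cz", 2500, "transient", 50, 1.0),))

    def test_oscillation_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="fs"):
            small_config(fs=16.0, components=(
                ComponentSpec("Cz", 100, "oscillation", 100, 1.0,
                              center_freq_hz=9.0),))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="n_subjects"):
            list(iter_subjects(small_config(n_subjects=3)))

    def test_effect_size_beyond_median_split_limit(self):
        with pytest.raises(ValueError, match="effect_size"):
            amplitude_slope(3.0, 0.4)


class TestPlantedGroundTruth:
    def test_null_effect_has_no_group_difference(self):
        """With effect_size=0 the planted amplitudes carry no information
        about the behavioral groups (expected standardized difference 0)."""
        cfg = demo_config(n_subjects=120, effect_size=0.0, seed=9)
        amps, rows = [], []
        for _, row, man in iter_subjects(cfg, with_epochs=False):
            amps.append(man["component_amplitudes_uv"][7])
            rows.append(row)
        import pandas as pd

        table = pd.DataFrame(rows)
        labels = group_labels(median_split(table))
        amps = np.asarray(amps)
        pooled = np.sqrt(0.5 * (amps[labels == 1].var(ddof=1)
                                + amps[labels == 0].var(ddof=1)))
        d = (amps[labels == 1].mean() - amps[labels == 0].mean()) / pooled
        assert abs(d) < 0.5   # ~4 sigma at n=120

    def test_effect_size_two_recovered_within_half(self):
        """Cohen's d of the planted C3 amplitude between the assigned
        groups approximates the configured effect size."""
        cfg = demo_config(n_subjects=60, n_trials=450, effect_size=2.0,
                          components=recovery_components(), seed=21)
        amps, rows = [], []
        for _, row, man in iter_subjects(cfg, with_epochs=False):
            amps.append(man["component_amplitudes_uv"][7])
            rows.append(row)
        import pandas as pd

        labels = group_labels(median_split(pd.DataFrame(rows)))
        amps = np.asarray(amps)
        pooled = np.sqrt(0.5 * (amps[labels == 1].var(ddof=1)
                                + amps[labels == 0].var(ddof=1)))
        d = (amps[labels == 1].mean() - amps[labels == 0].mean()) / pooled
        assert abs(d - 2.0) <= 0.5

    def test_ratio_correlates_with_latent_score(self):
        cfg = demo_config(n_subjects=150, n_trials=450, seed=13)
        lat, rows = [], []
        for _, row, man in iter_subjects(cfg, with_epochs=False):
            lat.append(man["latent_score"])
            rows.append(row)
        import pandas as pd

        t = pd.DataFrame(rows)
        ratio = compute_ratio(t["fa_rate"].to_numpy(),
                              t["mean_go_rt_ms"].to_numpy())
        assert np.corrcoef(ratio, lat)[0, 1] > 0.8


class TestPlantedWaveforms:
    def _noiseless_burst_config(self, amplitude=5.0):
        return small_config(
            noise_pink_uv=0.0, noise_white_uv=0.0, effect_size=0.0,
            n_trials=10, miss_rate_mean=1e-5,
            epoch_window_ms=(-2000.0, 2000.0),
            components=(ComponentSpec("T7", 207, "oscillation", 200,
                                      amplitude, center_freq_hz=9.0,
                                      condition="nogo"),))

    def test_burst_power_peaks_at_plant_location(self):
        """A noiseless 9 Hz burst at T7/207 ms shows its total-power
        maximum at T7 within ±30 ms and within one spectral width."""
        cfg = self._noiseless_burst_config()
        epochs, _, _ = generate_subject(cfg, 0.0, 7)
        nogo = epochs.select(NOGO_CORRECT)
        freqs = np.arange(1.0, 19.0)
        power = subject_total_power(nogo.astype(np.float64), cfg.fs, freqs)
        ch = np.argmax(power.max(axis=(0, 2)))
        assert cfg.channels[ch] == "T7"
        fi, ti = np.unravel_index(np.argmax(power[:, ch, :]),
                                  power[:, ch, :].shape)
        assert abs(cfg.times_ms[ti] - 207) <= 30
        assert abs(freqs[fi] - 9) <= 2 * np.sqrt(2) * morlet_params(9.0).sigma_f

    def test_burst_power_matches_direct_convolution(self):
        cfg = self._noiseless_burst_config()
        epochs, _, _ = generate_subject(cfg, 0.0, 7)
        trial = epochs.select(NOGO_CORRECT)[0].astype(np.float64)
        ch = list(cfg.channels).index("T7")
        power = subject_total_power(trial[None], cfg.fs, [9.0])[0, ch]
        k = morlet_kernel(9.0, cfg.fs)
        half = (len(k) - 1) // 2
        w = np.convolve(trial[ch], k, mode="full")[half:half + trial.shape[-1]]
        np.testing.assert_allclose(power, np.abs(w) ** 2, rtol=1e-10)

    def test_power_scales_quadratically_with_amplitude(self):
        powers = []
        for amp in (2.0, 4.0, 8.0):
            cfg = self._noiseless_burst_config(amplitude=amp)
            epochs, _, _ = generate_subject(cfg, 0.0, 11)
            nogo = epochs.select(NOGO_CORRECT).astype(np.float64)
            ch = list(cfg.channels).index("T7")
            p = subject_total_power(nogo, cfg.fs, [9.0])[0, ch]
            powers.append(p.max())
        np.testing.assert_allclose(powers[1] / powers[0], 4.0, rtol=1e-3)
        np.testing.assert_allclose(powers[2] / powers[1], 4.0, rtol=1e-3)

    def test_artifact_injection_is_detectable(self):
        cfg = small_config(artifact_rate=0.5, n_trials=30)
        epochs, _, _ = generate_subject(cfg, 0.0, 3)
        rng_trial = epochs.data.max(axis=(1, 2)) - epochs.data.min(axis=(1, 2))
        assert (rng_trial > 200).any() or np.any(
            np.ptp(epochs.data, axis=2) < 0.5)
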