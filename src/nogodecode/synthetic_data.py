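"""Synthetic Go/Nogo EEG cohorts with a known ground truth.

The generator emulates the data structure of a visual Go/Nogo experiment:
per subject, stimulus-locked epochs (trials x channels x samples) of
band-limited scalp EEG plus a matched behavioral record (Go hit reaction
times, false-alarm and miss rates).  A latent "performance" score per
subject drives both the behavior (lower false-alarm rate and faster Go
responses for higher scores) and the amplitude of group-modulated EEG
components, so that the downstream decoding pipeline has a recoverable
ground truth.

Epochs are emitted already cleaned and band-limited (0.5-18 Hz), i.e. the
generator stands in for a recording that has been downsampled, filtered
and ICA-cleaned offline; only gross single-trial artifacts (which the
rejection stage must catch) are optionally injected.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning: one child stream per subject,
which itself splits into a behavioral stream and an epoch-synthesis
stream.  Behavioral records are therefore bit-identical whether or not
the EEG of a subject is materialized.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .montage import default_channels

Condition = Literal["go", "nogo", "both"]

#: trial outcome labels
GO_CORRECT = "go_correct"
GO_MISS = "go_miss"
NOGO_CORRECT = "nogo_correct"
NOGO_FA = "nogo_fa"

BEHAVIOR_COLUMNS = [
    "subject_id", "mean_go_rt_ms", "fa_rate", "miss_rate",
    "n_go_correct", "n_nogo_correct",
]


@dataclass(frozen=True)
class ComponentSpec:
    """One plantable EEG component.

    ``kind="transient"`` is a Gaussian-windowed monophasic deflection
    (sigma = duration/4), phase-locked to the stimulus; ``kind="oscillation"``
    is a Hann-windowed sinusoid of ``center_freq_hz`` with a random phase
    per trial (induced, non-phase-locked activity that survives only in
    single-trial total power).  ``group_modulation`` scales how strongly
    the subject's latent performance score modulates the amplitude
    (0 = group-neutral, 1 = full planted effect).

    A component is not confined to its nominal electrode: volume-conducted
    scalp topographies are smooth, so the waveform loads on every channel
    with a spherical Gaussian profile (``spatial_sigma_rad`` great-circle
    radians, loading 1 at the nominal channel).  A spatially smooth source
    is also what keeps the surface Laplacian well behaved; a single-channel
    delta would alias into high spatial frequencies on a sparse montage.
    """

    channel: str
    latency_ms: float
    kind: Literal["transient", "oscillation"]
    duration_ms: float
    amplitude_uv: float
    center_freq_hz: float | None = None
    group_modulation: float = 0.0
    condition: Condition = "both"
    spatial_sigma_rad: float = 0.45

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.kind == "oscillation":
            if self.center_freq_hz is None or self.center_freq_hz < 1.0:
                raise ValueError("oscillation requires center_freq_hz >= 1")
        elif self.kind != "transient":
            raise ValueError(f"unknown component kind {self.kind!r}")


def default_components() -> tuple[ComponentSpec, ...]:
    """Default component set: the classical visual/inhibition ERP
    repertoire plus three group-modulated plants (a centro-lateral
    transient at C3/322 ms, a 4 Hz theta burst at C3/324 ms and a 9 Hz
    alpha burst at T7/207 ms, all on Nogo trials)."""
    return (
        ComponentSpec("PO9", 100, "transient", 60, 6.0),
        ComponentSpec("PO10", 100, "transient", 60, 6.0),
        ComponentSpec("PO9", 180, "transient", 80, -6.0),
        ComponentSpec("PO10", 180, "transient", 80, -6.0),
        ComponentSpec("Cz", 265, "transient", 80, -5.0, condition="nogo"),
        ComponentSpec("FC1", 390, "transient", 120, 8.0, condition="nogo"),
        ComponentSpec("P1", 390, "transient", 120, 6.0, condition="go"),
        ComponentSpec("C3", 322, "transient", 80, 10.0,
                      group_modulation=1.0, condition="nogo",
                      spatial_sigma_rad=0.35),
        ComponentSpec("C3", 324, "oscillation", 500, 20.0, center_freq_hz=4.0,
                      group_modulation=1.0, condition="nogo",
                      spatial_sigma_rad=0.35),
        ComponentSpec("T7", 207, "oscillation", 250, 8.0, center_freq_hz=9.0,
                      group_modulation=1.0, condition="nogo",
                      spatial_sigma_rad=0.35),
    )


def recovery_components() -> tuple[ComponentSpec, ...]:
    """Component set with exactly one group-modulated ERP plant
    (C3/322 ms) and one group-modulated time-frequency plant
    (C3/4 Hz/324 ms); the group-neutral background repertoire is kept."""
    return tuple(
        c for c in default_components()
        if not (c.group_modulation and c.channel == "T7")
    )


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults reproduce the emulated study conditions: 240 subjects,
    64-channel 10/20 montage, 256 Hz, epochs -2000..+2000 ms, 450 trials
    at 70:30 Go:Nogo, mean Go RT 348 ms, mean false-alarm rate 12%.
    """

    n_subjects: int = 240
    channels: tuple[str, ...] = field(default_factory=lambda: default_channels(64))
    fs: float = 256.0
    epoch_window_ms: tuple[float, float] = (-2000.0, 2000.0)
    n_trials: int = 450
    go_fraction: float = 0.70
    noise_pink_uv: float = 8.0
    noise_white_uv: float = 3.0
    effect_size: float = 1.0
    amp_subject_cv: float = 0.4
    rt_mean_ms: float = 348.0
    rt_sd_ms: float = 30.0
    rt_trial_sd_ms: float = 50.0
    fa_rate_mean: float = 0.12
    fa_rate_sd: float = 0.05
    miss_rate_mean: float = 0.0125
    artifact_rate: float = 0.0
    dropout_rate_mean: float = 0.0
    dropout_rate_sd: float = 0.0
    components: tuple[ComponentSpec, ...] = field(default_factory=default_components)
    #: which trial conditions get EEG synthesized ("go", "nogo"); behavior
    #: is always simulated for all trials and is unaffected by this choice
    synthesize_conditions: tuple[str, ...] = ("go", "nogo")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.go_fraction <= 1.0:
            raise ValueError("go_fraction must be in (0, 1]")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lo, hi = self.epoch_window_ms
        if not lo < 0.0 < hi:
            raise ValueError("epoch window must bracket the stimulus at 0 ms")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.rt_mean_ms <= 0:
            raise ValueError("rt_mean_ms must be positive")
        if not 0 <= self.fa_rate_mean <= 1:
            raise ValueError("fa_rate_mean must be a proportion")
        names = set(self.channels)
        if len(names) != len(self.channels):
            raise ValueError("duplicate channel names")
        if not set(self.synthesize_conditions) <= {"go", "nogo"}:
            raise ValueError("synthesize_conditions entries must be go/nogo")
        for comp in self.components:
            if comp.channel not in names:
                raise ValueError(f"component channel {comp.channel!r} not in montage")
            if not lo < comp.latency_ms < hi:
                raise ValueError(
                    f"component latency {comp.latency_ms} ms outside epoch window")
            if comp.kind == "oscillation" and comp.center_freq_hz >= self.fs / 2:
                raise ValueError(
                    f"oscillation at {comp.center_freq_hz} Hz needs fs > "
                    f"{2 * comp.center_freq_hz} Hz")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        lo, hi = self.epoch_window_ms
        return int(round((hi - lo) * self.fs / 1000.0)) + 1

    @property
    def times_ms(self) -> np.ndarray:
        lo, _ = self.epoch_window_ms
        return lo + np.arange(self.n_samples) * 1000.0 / self.fs

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def demo_config(**kw) -> SimConfig:
    """Reduced-scale configuration (16 channels, 64 Hz, 120 trials) used
    for fast end-to-end runs; all other conditions as at full scale."""
    base = dict(channels=default_channels(16), fs=64.0, n_trials=120)
    base.update(kw)
    return SimConfig(**base)


@dataclass
class SubjectEpochs:
    """Condition-labeled stimulus-locked epochs of one subject."""

    subject_id: str
    data: np.ndarray          # (n_trials, n_channels, n_samples)
    labels: np.ndarray        # (n_trials,) outcome strings
    channel_names: tuple[str, ...]
    fs: float
    times_ms: np.ndarray      # (n_samples,) relative to stimulus at 0
    units: str = "uV"

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.labels):
            raise ValueError("condition label count must equal trial count")
        if not np.all(np.diff(self.times_ms) > 0) or not np.any(self.times_ms == 0):
            raise ValueError("time axis must be strictly increasing and contain 0")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, label: str) -> np.ndarray:
        return self.data[self.labels == label]


@dataclass
class EpochCohort:
    subjects: list[SubjectEpochs]
    channel_names: tuple[str, ...]
    fs: float
    times_ms: np.ndarray
    units: str = "uV"

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def __iter__(self) -> Iterator[SubjectEpochs]:
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)


# --- latent-score coupling -------------------------------------------------

_HALF_NORMAL_MEAN = np.sqrt(2.0 / np.pi)          # E[z | z > 0]
_HALF_NORMAL_VAR = 1.0 - 2.0 / np.pi              # Var[z | z > 0]


def amplitude_slope(effect_size: float, amp_subject_cv: float) -> float:
    """Per-unit-latent-score relative amplitude slope gamma such that the
    standardized difference (Cohen's d) of component amplitude between the
    two halves of an ideal median split of the latent score equals
    ``effect_size``.

    With amplitude a = A0 (1 + gamma z + cv eta), z ~ N(0,1) split at its
    median and eta independent N(0,1):
    d = 1.5958 gamma / sqrt(0.3634 gamma^2 + cv^2).
    """
    d = float(effect_size)
    if d == 0.0:
        return 0.0
    dz = 2.0 * _HALF_NORMAL_MEAN
    denom = dz**2 - _HALF_NORMAL_VAR * d**2
    if denom <= 0:
        raise ValueError(
            f"effect_size must be < {dz / np.sqrt(_HALF_NORMAL_VAR):.3f} "
            "for a median-split design")
    return d * amp_subject_cv / np.sqrt(denom)


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# --- per-subject simulation ------------------------------------------------

def _subject_trials(config: SimConfig, latent: float, rng: np.random.Generator):
    """Simulate trial conditions and outcomes; returns (labels, go_rts).

    FA rate: logistic(logit(fa_mean) - a*z + noise), RT: rt_mean - b*z +
    noise.  The latent trait carries 0.9 of the configured between-subject
    SDs (slope share); idiosyncratic noise fills the rest, and binomial /
    per-trial sampling error comes on top.  The speed-accuracy ratio is
    therefore monotone in the latent score with corr ~0.9 at full trial
    counts.
    """
    p = min(max(config.fa_rate_mean, 1e-4), 1 - 1e-4)
    g = p * (1.0 - p)  # logistic derivative at the mean
    a = 0.9 * config.fa_rate_sd / g
    sd_l = 0.2 * config.fa_rate_sd / g
    fa_true = float(np.clip(
        _inv_logit(_logit(p) - a * latent + sd_l * rng.standard_normal()),
        1e-4, 1 - 1e-4))

    b = 0.9 * config.rt_sd_ms
    sd_r = 0.44 * config.rt_sd_ms
    rt_true = max(config.rt_mean_ms - b * latent + sd_r * rng.standard_normal(),
                  120.0)

    m = min(max(config.miss_rate_mean, 1e-5), 1 - 1e-5)
    miss_true = float(np.clip(
        _inv_logit(_logit(m) - 0.3 * latent + 0.3 * rng.standard_normal()),
        1e-5, 0.5))

    is_go = rng.random(config.n_trials) < config.go_fraction
    u = rng.random(config.n_trials)
    labels = np.where(
        is_go,
        np.where(u < miss_true, GO_MISS, GO_CORRECT),
        np.where(u < fa_true, NOGO_FA, NOGO_CORRECT),
    ).astype("U12")
    go_rts = np.full(config.n_trials, np.nan)
    n_go_c = int(np.sum(labels == GO_CORRECT))
    go_rts[labels == GO_CORRECT] = np.clip(
        rt_true + config.rt_trial_sd_ms * rng.standard_normal(n_go_c),
        120.0, 1200.0)
    return labels, go_rts


def _behavior_row(subject_id: str, labels: np.ndarray, go_rts: np.ndarray) -> dict:
    n_go = int(np.sum((labels == GO_CORRECT) | (labels == GO_MISS)))
    n_nogo = len(labels) - n_go
    n_go_c = int(np.sum(labels == GO_CORRECT))
    n_nogo_c = int(np.sum(labels == NOGO_CORRECT))
    return {
        "subject_id": subject_id,
        "mean_go_rt_ms": float(np.nanmean(go_rts)) if n_go_c else np.nan,
        "fa_rate": (n_nogo - n_nogo_c) / n_nogo if n_nogo else np.nan,
        "miss_rate": (n_go - n_go_c) / n_go if n_go else np.nan,
        "n_go_correct": n_go_c,
        "n_nogo_correct": n_nogo_c,
    }


def _band_limited_noise(rng: np.random.Generator, shape: tuple, fs: float,
                        pink_uv: float, white_uv: float,
                        band: tuple[float, float] = (0.5, 18.0)) -> np.ndarray:
    """Gaussian 1/f-power ("pink") plus white noise, band-limited to
    ``band`` (mirrors an offline 0.5-18 Hz band-pass), RMS-calibrated."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    out = np.zeros(shape, dtype=np.float32)
    pink_gain = np.zeros(len(freqs))
    nz = mask & (freqs > 0)
    pink_gain[nz] = freqs[nz] ** -0.5
    for amp, gain in ((pink_uv, pink_gain), (white_uv, mask.astype(float))):
        if amp == 0.0:
            continue
        # spectral synthesis: complex Gaussian spectrum with the same
        # second-order statistics as rfft of filtered white noise
        g = gain.copy()
        g[0] = 0.0
        if n % 2 == 0:
            g[-1] = 0.0
        var = 2.0 * float(np.sum(g**2)) / n
        zshape = shape[:-1] + (len(freqs),)
        spec = (rng.standard_normal(zshape, dtype=np.float32)
                + 1j * rng.standard_normal(zshape, dtype=np.float32))
        spec *= (g * np.sqrt(n / 2.0)).astype(np.float32)
        out += np.float32(amp / np.sqrt(var)) * np.fft.irfft(
            spec, n=n, axis=-1).astype(np.float32)
    return out


#: residual component-specific amplitude variability on top of the shared
#: subject-level gain (anatomy/conductivity factors are common to all
#: components of a subject; component-specific state noise is smaller).
COMPONENT_JITTER_CV = 0.1


def _component_amplitudes(config: SimConfig, latent: float,
                          rng: np.random.Generator) -> np.ndarray:
    gamma = amplitude_slope(config.effect_size, config.amp_subject_cv)
    gain = config.amp_subject_cv * rng.standard_normal()
    amps = np.empty(len(config.components))
    for i, comp in enumerate(config.components):
        eta = rng.standard_normal()
        amps[i] = comp.amplitude_uv * (
            1.0 + comp.group_modulation * gamma * latent
            + gain + COMPONENT_JITTER_CV * eta)
    return amps


def component_loadings(config: SimConfig) -> np.ndarray:
    """Spatial loading of every component on every channel: (n_comp, n_ch),
    Gaussian in great-circle distance from the nominal electrode."""
    from .montage import unit_sphere_positions

    pos = unit_sphere_positions(config.channels)
    ch_index = {c: i for i, c in enumerate(config.channels)}
    out = np.empty((len(config.components), config.n_channels))
    for i, comp in enumerate(config.components):
        cos = np.clip(pos @ pos[ch_index[comp.channel]], -1.0, 1.0)
        ang = np.arccos(cos)
        out[i] = np.exp(-0.5 * (ang / comp.spatial_sigma_rad) ** 2)
    return out


def _synthesize_epochs(config: SimConfig, labels: np.ndarray,
                       amps: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    times = config.times_ms
    n_tr, n_ch, n_s = config.n_trials, config.n_channels, config.n_samples
    data = _band_limited_noise(rng, (n_tr, n_ch, n_s), config.fs,
                               config.noise_pink_uv, config.noise_white_uv)
    loadings = component_loadings(config)
    is_go = (labels == GO_CORRECT) | (labels == GO_MISS)
    for comp, amp, loading in zip(config.components, amps, loadings):
        if comp.condition == "go":
            rows = np.flatnonzero(is_go)
        elif comp.condition == "nogo":
            rows = np.flatnonzero(~is_go)
        else:
            rows = np.arange(n_tr)
        if len(rows) == 0:
            continue
        trel = times - comp.latency_ms
        if comp.kind == "transient":
            sigma = comp.duration_ms / 4.0
            wave = amp * np.exp(-0.5 * (trel / sigma) ** 2)
            data[rows] += loading[:, None] * wave[None, :]
        else:
            half = comp.duration_ms / 2.0
            sup = np.flatnonzero(np.abs(trel) <= half)
            hann = 0.5 * (1.0 + np.cos(np.pi * trel[sup] / half))
            phase = rng.uniform(0, 2 * np.pi, size=len(rows))
            carrier = np.cos(2 * np.pi * comp.center_freq_hz / 1000.0
                             * trel[sup][None, :] + phase[:, None])
            burst = amp * hann[None, :] * carrier        # (rows, sup)
            data[np.ix_(rows, np.arange(n_ch), sup)] += (
                loading[None, :, None] * burst[:, None, :])
    if config.artifact_rate > 0:
        bad = np.flatnonzero(rng.random(n_tr) < config.artifact_rate)
        for tr in bad:
            ch = int(rng.integers(n_ch))
            if rng.random() < 0.5:  # large step
                t0 = int(rng.integers(n_s // 4, 3 * n_s // 4))
                data[tr, ch, t0:] += np.sign(rng.standard_normal()) * 300.0
            else:                   # flat channel
                data[tr, ch, :] = 0.05 * rng.standard_normal(n_s)
    return data.astype(np.float32)


def generate_subject(config: SimConfig, latent: float,
                     seed: int | np.random.SeedSequence,
                     subject_id: str = "S000",
                     with_epochs: bool = True):
    """Simulate one subject; returns ``(SubjectEpochs | None, behavior_row,
    manifest_row)``, bit-reproducible from the seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    behav_ss, epoch_ss = ss.spawn(2)
    rng_b = np.random.default_rng(behav_ss)
    labels, go_rts = _subject_trials(config, latent, rng_b)
    if config.dropout_rate_sd > 0 or config.dropout_rate_mean > 0:
        rate = np.clip(config.dropout_rate_mean
                       + config.dropout_rate_sd * rng_b.standard_normal(), 0.0, 0.9)
        keep = rng_b.random(len(labels)) >= rate
        labels, go_rts = labels[keep], go_rts[keep]
    row = _behavior_row(subject_id, labels, go_rts)
    rng_e = np.random.default_rng(epoch_ss)
    amps = _component_amplitudes(config, latent, rng_e)
    manifest_row = {
        "subject_id": subject_id,
        "latent_score": float(latent),
        "component_amplitudes_uv": [float(a) for a in amps],
    }
    epochs = None
    if with_epochs:
        synth = labels
        if set(config.synthesize_conditions) != {"go", "nogo"}:
            is_go = (labels == GO_CORRECT) | (labels == GO_MISS)
            keep = is_go if config.synthesize_conditions == ("go",) else ~is_go
            synth = labels[keep]
        cfg = config if len(synth) == config.n_trials else config.replace(
            n_trials=max(len(synth), 1))
        data = _synthesize_epochs(cfg, synth, amps, rng_e)[:len(synth)]
        epochs = SubjectEpochs(subject_id, data, synth, tuple(config.channels),
                               config.fs, config.times_ms)
    return epochs, row, manifest_row


def iter_subjects(config: SimConfig, with_epochs: bool = True):
    """Stream subjects one at a time (memory-bounded cohort traversal)."""
    if config.n_subjects < 4:
        raise ValueError("need n_subjects >= 4 to form folds and groups")
    root = np.random.SeedSequence(config.seed)
    latent_rng = np.random.default_rng(root.spawn(1)[0])
    latents = latent_rng.standard_normal(config.n_subjects)
    subject_seeds = root.spawn(config.n_subjects + 1)[1:]
    width = len(str(config.n_subjects - 1))
    for i in range(config.n_subjects):
        sid = f"S{i:0{width}d}"
        yield generate_subject(config, latents[i], subject_seeds[i], sid,
                               with_epochs=with_epochs)


def generate_cohort(config: SimConfig):
    """Materialize the full cohort.

    Returns ``(EpochCohort, behavior BehaviorTable DataFrame, manifest)``;
    the manifest records per-subject latent scores and realized planted
    amplitudes for parameter-recovery tests.
    """
    subjects, rows, man_rows = [], [], []
    for epochs, row, man in iter_subjects(config):
        subjects.append(epochs)
        rows.append(row)
        man_rows.append(man)
    behavior = pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS)
    manifest = {
        "effect_size": config.effect_size,
        "seed": config.seed,
        "components": [dataclasses.asdict(c) for c in config.components],
        "subjects": man_rows,
    }
    cohort = EpochCohort(subjects, tuple(config.channels), config.fs,
                         config.times_ms)
    return cohort, behavior, manifest


def simulate_behavior(config: SimConfig) -> pd.DataFrame:
    """Behavioral table only (no EEG synthesis); identical to the table
    produced by :func:`generate_cohort` at the same seed."""
    rows = [row for _, row, _ in iter_subjects(config, with_epochs=False)]
    return pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS)
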