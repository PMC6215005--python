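"""Epoch-level preprocessing and classical ERP quantification.

The fixed stage order is: artifact rejection (on µV data), spherical-
spline current source density (CSD) re-referencing, baseline correction,
condition-wise averaging.  CSD and baseline correction are both linear
maps and commute; rejection must precede CSD because its thresholds are
voltage criteria.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.special import eval_legendre
from scipy.stats import ttest_rel

from .synthetic_data import EpochCohort, SubjectEpochs

REASON_MAX_DIFF = "max_diff"
REASON_LOW_ACTIVITY = "low_activity"


# --- artifact rejection ----------------------------------------------------

def _window_samples(window_ms: float, fs: float) -> int:
    return max(2, int(round(window_ms * fs / 1000.0)))


def reject_artifact_trials(subject: SubjectEpochs,
                           max_diff_uv: float = 200.0,
                           max_diff_window_ms: float = 100.0,
                           min_activity_uv: float = 0.5,
                           min_activity_window_ms: float = 200.0):
    """Drop trials with a peak-to-peak range above ``max_diff_uv`` inside
    any sliding ``max_diff_window_ms`` window, or below ``min_activity_uv``
    inside any ``min_activity_window_ms`` window, on any channel.

    Sliding windows advance one sample at a time.  Returns the cleaned
    ``SubjectEpochs`` plus a per-trial rejection log.
    """
    n_s = subject.data.shape[-1]
    w_hi = _window_samples(max_diff_window_ms, subject.fs)
    w_lo = _window_samples(min_activity_window_ms, subject.fs)
    if w_hi > n_s or w_lo > n_s:
        raise ValueError("rejection window longer than the epoch")
    x = subject.data
    rows = []
    keep = np.ones(subject.n_trials, dtype=bool)

    def windowed_hit(x2, w, bad):
        # exact: range within every fully-contained window of length w
        mx = maximum_filter1d(x2, size=w, axis=-1, mode="nearest")
        mn = minimum_filter1d(x2, size=w, axis=-1, mode="nearest")
        left, right = w // 2, w - 1 - w // 2
        return bad((mx - mn)[..., left:x2.shape[-1] - right]).any(axis=-1)

    # cheap necessary-condition screens; the exact sliding scan runs only
    # on trials the screens flag
    glob_rng = x.max(axis=-1) - x.min(axis=-1)           # (trials, channels)
    cand_hi = np.flatnonzero((glob_rng > max_diff_uv).any(axis=-1))
    hw = max(1, w_lo // 2)
    n_blk = n_s // hw
    blocks = x[..., :n_blk * hw].reshape(*x.shape[:-1], n_blk, hw)
    blk_rng = blocks.max(axis=-1) - blocks.min(axis=-1)
    tail_rng = x[..., n_blk * hw - hw:].max(axis=-1) -         x[..., n_blk * hw - hw:].min(axis=-1)
    low_screen = (blk_rng < min_activity_uv).any(axis=-1) |         (tail_rng < min_activity_uv)
    cand_lo = np.flatnonzero(low_screen.any(axis=-1))
    for cand, w, reason, bad in (
        (cand_hi, w_hi, REASON_MAX_DIFF, lambda r: r > max_diff_uv),
        (cand_lo, w_lo, REASON_LOW_ACTIVITY, lambda r: r < min_activity_uv),
    ):
        if len(cand) == 0:
            continue
        hit = windowed_hit(x[cand], w, bad)              # (cand, channels)
        for i, tr in enumerate(cand):
            if hit[i].any() and keep[tr]:
                keep[tr] = False
                rows.append({"trial": int(tr), "reason": reason,
                             "channel": subject.channel_names[
                                 int(np.argmax(hit[i]))]})
    log = pd.DataFrame(rows, columns=["trial", "reason", "channel"])
    cleaned = dataclasses.replace(subject, data=x[keep], labels=subject.labels[keep])
    return cleaned, log


# --- baseline --------------------------------------------------------------

def baseline_correct(subject: SubjectEpochs,
                     window_ms: tuple[float, float] = (-200.0, 0.0)) -> SubjectEpochs:
    """Subtract, per trial and channel, the mean over the baseline window."""
    lo, hi = window_ms
    sel = (subject.times_ms >= lo) & (subject.times_ms <= hi)
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    base = subject.data[..., sel].mean(axis=-1, keepdims=True)
    return dataclasses.replace(subject, data=subject.data - base)


# --- spherical-spline current source density -------------------------------

@dataclass(frozen=True)
class CSDParams:
    """Spherical-spline surface Laplacian settings (Perrin-style g/h
    expansion): spline order ``m``, Legendre truncation degree ``n``, and
    a ridge ``smoothing_lambda`` added to the diagonal of the spline
    system."""

    spline_order_m: int = 4
    legendre_max_n: int = 10
    smoothing_lambda: float = 1e-5

    def __post_init__(self) -> None:
        if self.spline_order_m < 2:
            raise ValueError("spline order m must be >= 2")
        if self.legendre_max_n < self.spline_order_m:
            raise ValueError("legendre_max_n must be >= spline_order_m")
        if self.smoothing_lambda < 0:
            raise ValueError("smoothing_lambda must be >= 0")


def _gh_kernels(cosang: np.ndarray, m: int, n_max: int):
    g = np.zeros_like(cosang)
    h = np.zeros_like(cosang)
    for n in range(1, n_max + 1):
        p = eval_legendre(n, cosang)
        denom = float(n * (n + 1))
        g += (2 * n + 1) / denom**m * p
        h += -(2 * n + 1) / denom ** (m - 1) * p
    return g / (4 * np.pi), h / (4 * np.pi)


@lru_cache(maxsize=16)
def _csd_matrix_cached(pos_key: tuple, m: int, n_max: int, lam: float) -> np.ndarray:
    pos = np.array(pos_key).reshape(-1, 3)
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    if np.any(cosang[~np.eye(len(pos), dtype=bool)] > 1.0 - 1e-10):
        raise ValueError("duplicate electrode positions")
    g, h = _gh_kernels(cosang, m, n_max)
    n = len(pos)
    a = np.zeros((n + 1, n + 1))
    a[:n, :n] = g + lam * np.eye(n)
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    inv = np.linalg.inv(a)
    # potentials v -> spline coefficients c (sum-to-zero enforced by the
    # bordered row); surface CSD = -H c so that a degree-l spherical
    # harmonic maps to +l(l+1) times itself.
    return -h @ inv[:n, :n]


def csd_matrix(positions: np.ndarray, params: CSDParams = CSDParams()) -> np.ndarray:
    """Channel-space CSD operator M: csd = potentials @ M.T (unit-sphere
    radius; output units µV per unit squared arc length)."""
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError("positions must be (n, 3)")
    if len(positions) < 16:
        raise ValueError("CSD needs at least 16 channels")
    return _csd_matrix_cached(tuple(positions.ravel()), params.spline_order_m,
                              params.legendre_max_n, params.smoothing_lambda)


def csd_transform(subject: SubjectEpochs, positions: np.ndarray,
                  params: CSDParams = CSDParams()) -> SubjectEpochs:
    """Re-reference epochs to reference-free current source density."""
    mat = csd_matrix(positions, params)
    data = np.einsum("ij,tjs->tis", mat, subject.data.astype(np.float64),
                     optimize=True)
    return dataclasses.replace(subject, data=data.astype(subject.data.dtype),
                               units="uV/m2")


# --- averaging and ERP quantification --------------------------------------

@dataclass
class ERPSet:
    """Per-subject condition averages: (n_subjects, n_channels, n_samples)."""

    data: np.ndarray
    subject_ids: list[str]
    channel_names: tuple[str, ...]
    times_ms: np.ndarray
    condition: str
    n_trials_averaged: np.ndarray
    units: str = "uV/m2"
    dropped_subjects: list[str] = field(default_factory=list)

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown electrode {name!r}") from None


def average_erp(cohort: EpochCohort, condition: str) -> ERPSet:
    """Average retained trials of ``condition`` per subject.

    Subjects with zero retained trials are excluded from the result and
    listed in ``dropped_subjects`` (never silently NaN-filled).
    """
    data, ids, counts, dropped = [], [], [], []
    for subject in cohort:
        trials = subject.select(condition)
        if len(trials) == 0:
            dropped.append(subject.subject_id)
            continue
        data.append(trials.mean(axis=0, dtype=np.float64))
        ids.append(subject.subject_id)
        counts.append(len(trials))
    if not data:
        raise ValueError(f"no subject has any {condition!r} trial")
    return ERPSet(np.stack(data), ids, cohort.channel_names,
                  cohort.times_ms, condition, np.asarray(counts),
                  units=cohort.subjects[0].units, dropped_subjects=dropped)


@dataclass
class PeakResult:
    subject_id: str
    electrode: str
    latency_ms: float
    amplitude: float
    window_ms: tuple[float, float]
    polarity: int
    fallback: bool  # no interior local extremum; window extremum reported


def detect_local_peak(erp: ERPSet, electrode: str,
                      window_ms: tuple[float, float],
                      polarity: int = 1) -> list[PeakResult]:
    """Local-extremum peak detection per subject inside ``window_ms``.

    ``polarity`` +1 finds maxima, -1 minima.  When the window contains no
    interior local extremum (monotone data) the window extremum is
    returned with ``fallback=True``.
    """
    if polarity not in (-1, 1):
        raise ValueError("polarity must be +1 or -1")
    ch = erp.channel_index(electrode)
    lo, hi = window_ms
    sel = np.flatnonzero((erp.times_ms >= lo) & (erp.times_ms <= hi))
    if len(sel) == 0:
        raise ValueError("window contains no samples")
    results = []
    for s, sid in enumerate(erp.subject_ids):
        y = polarity * erp.data[s, ch, sel]
        interior = np.flatnonzero(
            (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])) + 1 if len(y) > 2 else []
        if len(interior) > 0:
            idx = interior[np.argmax(y[interior])]
            fallback = False
        else:
            idx = int(np.argmax(y))
            fallback = True
        results.append(PeakResult(
            sid, electrode, float(erp.times_ms[sel[idx]]),
            float(erp.data[s, ch, sel[idx]]), (lo, hi), polarity, fallback))
    return results


def mean_amplitude(erp: ERPSet, electrodes, window_ms) -> np.ndarray:
    """Per-subject mean amplitude over the window, pooled over electrodes."""
    if isinstance(electrodes, str):
        electrodes = [electrodes]
    if len(electrodes) == 0:
        raise ValueError("empty electrode list")
    chs = [erp.channel_index(e) for e in electrodes]
    lo, hi = window_ms
    sel = (erp.times_ms >= lo) & (erp.times_ms <= hi)
    if not sel.any():
        raise ValueError("window contains no samples")
    return erp.data[:, chs][:, :, sel].mean(axis=(1, 2))


def validate_electrode_choice(erp: ERPSet, window_ms,
                              alpha: float = 0.0007) -> list[str]:
    """Select electrodes whose component amplitude stands out topographically.

    For each electrode, the per-subject mean |amplitude| inside the window
    is compared against the average of all other electrodes with a paired
    one-sided t-test; electrodes significantly larger at ``alpha``
    (a Bonferroni-style fixed threshold) are returned.
    """
    if len(erp.channel_names) < 2:
        raise ValueError("need at least 2 electrodes")
    if len(erp.subject_ids) < 3:
        raise ValueError("need at least 3 subjects")
    lo, hi = window_ms
    sel = (erp.times_ms >= lo) & (erp.times_ms <= hi)
    amp = np.abs(erp.data[:, :, sel].mean(axis=2))   # (subjects, electrodes)
    n_e = amp.shape[1]
    selected = []
    for e in range(n_e):
        others = amp[:, [j for j in range(n_e) if j != e]].mean(axis=1)
        res = ttest_rel(amp[:, e], others, alternative="greater")
        if res.pvalue < alpha:
            selected.append(erp.channel_names[e])
    return selected


def preprocess_subject(subject: SubjectEpochs, positions: np.ndarray,
                       csd_params: CSDParams = CSDParams(),
                       baseline_window_ms: tuple[float, float] = (-200.0, 0.0),
                       reject_kwargs: dict | None = None):
    """Fixed-order single-subject pipeline: reject -> CSD -> baseline.

    Returns (cleaned SubjectEpochs in µV/m², rejection log).
    """
    cleaned, log = reject_artifact_trials(subject, **(reject_kwargs or {}))
    cleaned = csd_transform(cleaned, positions, csd_params)
    cleaned = baseline_correct(cleaned, baseline_window_ms)
    return cleaned, log
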