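"""Subject x feature banks from ERP averages and total power.

Candidate features are every (channel, time point) of the trial-averaged
correct-Nogo ERP in a post-stimulus window (default 0..1.5 s inclusive at
sample resolution), and every (frequency, channel, time point) of the
correct-Nogo total power on the 1..18 Hz grid.  Features are z-scored
across subjects before selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .preprocess import ERPSet
from .tfr import TFRSet

logger = logging.getLogger(__name__)

DESCRIPTOR_COLUMNS = ["channel", "time_ms", "freq_hz", "edge"]


@dataclass
class FeatureBank:
    values: np.ndarray            # (n_subjects, n_features)
    descriptors: pd.DataFrame     # columns channel, time_ms, freq_hz, edge
    subject_ids: list[str]
    provenance: str               # "erp" | "tf"
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.descriptors):
            raise ValueError("descriptor count must equal column count")
        if np.isnan(self.values).any():
            raise ValueError("feature bank contains missing values")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_for(self, channel: str, time_ms: float,
                   freq_hz: float | None = None, atol_ms: float = 1e-6) -> int:
        """Column index of the descriptor matching (channel[, freq], time)."""
        d = self.descriptors
        mask = (d["channel"] == channel) & (np.abs(d["time_ms"] - time_ms) < atol_ms)
        if freq_hz is not None:
            mask &= d["freq_hz"] == freq_hz
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) != 1:
            raise KeyError(
                f"no unique column for ({channel}, {time_ms} ms, {freq_hz})")
        return int(idx[0])

    def drop_columns(self, columns) -> "FeatureBank":
        keep = np.setdiff1d(np.arange(self.n_features), np.asarray(columns))
        return replace(self, values=self.values[:, keep],
                       descriptors=self.descriptors.iloc[keep].reset_index(drop=True))


def _time_selection(times_ms: np.ndarray, tmin_ms: float, tmax_ms: float):
    sel = np.flatnonzero((times_ms >= tmin_ms) & (times_ms <= tmax_ms))
    if len(sel) == 0:
        raise ValueError("no samples in the feature time window")
    return sel


def build_erp_features(erp: ERPSet, tmin_ms: float = 0.0,
                       tmax_ms: float = 1500.0) -> FeatureBank:
    """One column per (channel, sample) with time in [tmin, tmax] ms;
    values are the subject's trial-averaged amplitudes."""
    sel = _time_selection(erp.times_ms, tmin_ms, tmax_ms)
    values = erp.data[:, :, sel].reshape(len(erp.subject_ids), -1)
    desc = pd.DataFrame({
        "channel": np.repeat(erp.channel_names, len(sel)),
        "time_ms": np.tile(erp.times_ms[sel], len(erp.channel_names)),
        "freq_hz": np.nan,
        "edge": False,
    })
    return FeatureBank(np.ascontiguousarray(values, dtype=np.float64), desc,
                       list(erp.subject_ids), "erp")


def build_tf_features(tfr: TFRSet, tmin_ms: float = 0.0,
                      tmax_ms: float = 1500.0,
                      include_edge_flagged: bool = True) -> FeatureBank:
    """One column per (frequency, channel, sample).

    Samples closer than one wavelet duration to an epoch boundary carry
    an ``edge`` flag in their descriptor; with
    ``include_edge_flagged=False`` they are omitted from the bank.
    """
    sel = _time_selection(tfr.times_ms, tmin_ms, tmax_ms)
    n_subj = len(tfr.subject_ids)
    n_f, n_ch = len(tfr.freqs), len(tfr.channel_names)
    values = tfr.data[:, :, :, sel].reshape(n_subj, -1)
    desc = pd.DataFrame({
        "channel": np.tile(np.repeat(tfr.channel_names, len(sel)), n_f),
        "time_ms": np.tile(tfr.times_ms[sel], n_f * n_ch),
        "freq_hz": np.repeat(tfr.freqs, n_ch * len(sel)),
        "edge": np.repeat(tfr.edge[:, sel], n_ch, axis=0).reshape(-1),
    })
    bank = FeatureBank(np.ascontiguousarray(values, dtype=np.float64), desc,
                       list(tfr.subject_ids), "tf")
    if not include_edge_flagged:
        bank = bank.drop_columns(np.flatnonzero(desc["edge"].to_numpy()))
    return bank


def zscore_features(bank: FeatureBank, ddof: int = 0,
                    stats_rows: np.ndarray | None = None) -> FeatureBank:
    """Normalize every column to mean 0, SD 1 across subjects.

    ``stats_rows`` restricts the rows used to estimate the mean/SD (e.g.
    training subjects in a nested protocol); the transform is applied to
    all rows.  Zero-variance columns are dropped with a log entry.
    Population SD (ddof=0) by default.
    """
    if bank.values.shape[0] < 2:
        raise ValueError("need at least 2 subjects to z-score")
    ref = bank.values if stats_rows is None else bank.values[stats_rows]
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=ddof)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance feature columns",
                       int((~keep).sum()))
    values = (bank.values[:, keep] - mean[keep]) / sd[keep]
    desc = bank.descriptors.loc[keep].reset_index(drop=True)
    return replace(bank, values=values, descriptors=desc, normalized=True)
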