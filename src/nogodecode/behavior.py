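"""Speed-accuracy performance ratio, exclusions, and the median split.

The behavioral criterion is the percentage of correctly inhibited Nogo
trials divided by the mean Go hit reaction time (percent per ms): larger
values mean better performance (more accurate and/or faster).  The cohort
is divided into equally large "low" and "high" performance groups at the
cohort median of this ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LOW, HIGH = "low", "high"


def compute_ratio(fa_rate, mean_go_rt_ms):
    """Performance ratio = 100 * (1 - fa_rate) / mean_go_rt_ms  [%/ms].

    Accepts scalars or aligned arrays.
    """
    fa = np.asarray(fa_rate, dtype=float)
    rt = np.asarray(mean_go_rt_ms, dtype=float)
    if np.any(rt <= 0):
        raise ValueError("mean_go_rt_ms must be positive")
    if np.any((fa < 0) | (fa > 1)):
        raise ValueError("fa_rate must lie in [0, 1]")
    out = 100.0 * (1.0 - fa) / rt
    return float(out) if out.ndim == 0 else out


def apply_exclusions(table: pd.DataFrame,
                     rt_sd_threshold: float = 3.0,
                     error_rate_threshold: float = 0.5) -> pd.DataFrame:
    """Flag subjects with Go RT above the cohort mean + 3 SD, or false
    alarms and/or misses at or above 50%.

    The RT mean and SD are computed over all subjects before any
    exclusion.  Returns a copy with ``ratio``, ``excluded`` and
    ``exclusion_reason`` columns.
    """
    if len(table) == 0:
        raise ValueError("empty behavior table")
    out = table.copy()
    out["ratio"] = compute_ratio(out["fa_rate"].to_numpy(),
                                 out["mean_go_rt_ms"].to_numpy())
    rt = out["mean_go_rt_ms"].to_numpy(dtype=float)
    rt_cut = (rt.mean() + rt_sd_threshold * rt.std(ddof=1)
              if len(rt) > 1 else np.inf)
    reasons = []
    for _, row in out.iterrows():
        why = []
        if row["mean_go_rt_ms"] > rt_cut:
            why.append("slow_rt")
        if row["fa_rate"] >= error_rate_threshold:
            why.append("high_fa")
        if row["miss_rate"] >= error_rate_threshold:
            why.append("high_miss")
        reasons.append("+".join(why))
    out["exclusion_reason"] = reasons
    out["excluded"] = out["exclusion_reason"] != ""
    return out


@dataclass
class GroupAssignment:
    """Median-split outcome: per-subject group labels and the split value."""

    table: pd.DataFrame        # subject_id, ratio, group
    split_value: float         # the median ratio

    @property
    def groups(self) -> pd.Series:
        return self.table.set_index("subject_id")["group"]


def median_split(table: pd.DataFrame) -> GroupAssignment:
    """Rank subjects by ratio and assign the lower half to "low", the
    upper half to "high" (equal sizes for even N; for odd N the low group
    receives the median subject).

    Ties at the median are broken by stable subject-ID order so that the
    two groups are always as equal as possible.  Excluded subjects (if an
    ``excluded`` column is present) do not participate.
    """
    work = table
    if "excluded" in work.columns:
        work = work.loc[~work["excluded"]]
    if "ratio" not in work.columns:
        work = work.copy()
        work["ratio"] = compute_ratio(work["fa_rate"].to_numpy(),
                                      work["mean_go_rt_ms"].to_numpy())
    if len(work) < 2:
        raise ValueError("need at least 2 non-excluded subjects")
    ratios = work["ratio"].to_numpy(dtype=float)
    if np.ptp(ratios) == 0:
        raise ValueError("degenerate split: all ratios identical")
    order = np.lexsort((work["subject_id"].to_numpy(), ratios))
    n = len(work)
    n_low = (n + 1) // 2
    group = np.empty(n, dtype=object)
    group[order[:n_low]] = LOW
    group[order[n_low:]] = HIGH
    out = work[["subject_id", "ratio"]].copy()
    out["group"] = group
    return GroupAssignment(out.reset_index(drop=True),
                           split_value=float(np.median(ratios)))


def group_labels(assignment: GroupAssignment) -> np.ndarray:
    """0/1 vector (0 = low, 1 = high) aligned to the assignment table."""
    return (assignment.table["group"].to_numpy() == HIGH).astype(int)
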