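"""Electrode montages and spherical coordinates.

Channel positions come from the standard 10/20 extended montage shipped
with :mod:`mne`.  For the spherical-spline current source density
transform every electrode is projected onto the unit sphere after
removing the best-fitting sphere's center, which is the geometry the
Perrin g/h expansion assumes.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

#: 64-channel extended 10/20 layout (FCz kept as a scalp channel; in the
#: emulated recording setup it is the interpolated former reference).
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fp2", "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO9", "PO7", "PO3", "POz", "PO4", "PO8", "PO10",
    "O1", "Oz", "O2", "Iz",
)

#: 16-channel reduced layout used for demonstration / fast runs.  It keeps
#: every electrode a default simulated component loads on (C3, T7, Cz,
#: FCz, FC1, P1, PO9, PO10).
CHANNELS_16: tuple[str, ...] = (
    "Fz", "F3", "F4", "FCz", "FC1", "FC2", "Cz", "C3",
    "C4", "T7", "T8", "CPz", "Pz", "P1", "PO9", "PO10",
)


@lru_cache(maxsize=8)
def _standard_positions_map() -> dict:
    import warnings

    import mne

    with warnings.catch_warnings():
        # montage name deprecation churn across mne releases
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1020")
    return {k: np.asarray(v, dtype=float)
            for k, v in montage.get_positions()["ch_pos"].items()}


def _fit_sphere_center(points: np.ndarray) -> np.ndarray:
    # Linear least squares: |p - c|^2 = r^2  =>  2 p.c + (r^2 - |c|^2) = |p|^2
    a = np.hstack([2.0 * points, np.ones((len(points), 1))])
    b = np.sum(points**2, axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    return sol[:3]


def unit_sphere_positions(channels: Sequence[str]) -> np.ndarray:
    """Unit-sphere electrode positions for ``channels``, shape (n, 3).

    Raises ``KeyError`` for channel names absent from the standard 10/20
    montage and ``ValueError`` for duplicate positions (which would make
    the CSD spline system singular).
    """
    pos_map = _standard_positions_map()
    missing = [c for c in channels if c not in pos_map]
    if missing:
        raise KeyError(f"channels not in standard 10/20 montage: {missing}")
    pts = np.array([pos_map[c] for c in channels], dtype=float)
    center = _fit_sphere_center(pts)
    pts = pts - center
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    cos = np.clip(pts @ pts.T, -1.0, 1.0)
    np.fill_diagonal(cos, -1.0)
    if np.any(cos > 1.0 - 1e-10):
        raise ValueError("duplicate electrode positions on the sphere")
    return pts


def default_channels(n_channels: int) -> tuple[str, ...]:
    """Canonical channel list for the two supported layout sizes."""
    if n_channels == 64:
        return CHANNELS_64
    if n_channels == 16:
        return CHANNELS_16
    raise ValueError(
        "no default layout for n_channels=%d; pass channel names explicitly"
        % n_channels
    )


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere point set (dense synthetic montages)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5**0.5) * i
    return np.c_[np.sin(phi) * np.cos(theta),
                 np.sin(phi) * np.sin(theta),
                 np.cos(phi)]
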