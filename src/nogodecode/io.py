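"""On-disk formats: HDF5 cohort/ERP/TFR containers, CSV tables, configs.

Cohort layout (HDF5):
    /subjects/<id>/epochs   float32 (trials, channels, samples)
    /subjects/<id>/labels   bytes   (trials,)
    attrs: fs, channel_names, time0_index, times_ms, units
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .preprocess import ERPSet
from .synthetic_data import EpochCohort, SubjectEpochs
from .tfr import TFRSet


class SchemaError(ValueError):
    """A stored container is missing a required field or is inconsistent."""


def save_cohort(path, cohort: EpochCohort) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = cohort.fs
        f.attrs["channel_names"] = list(cohort.channel_names)
        f.attrs["times_ms"] = cohort.times_ms
        f.attrs["time0_index"] = int(np.flatnonzero(cohort.times_ms == 0)[0])
        f.attrs["units"] = cohort.subjects[0].units if cohort.subjects else "uV"
        grp = f.create_group("subjects")
        for s in cohort:
            g = grp.create_group(s.subject_id)
            g.create_dataset("epochs", data=s.data.astype(np.float32),
                             compression="gzip", compression_opts=1)
            g.create_dataset("labels",
                             data=np.char.encode(s.labels.astype(str)))


def load_cohort(path) -> EpochCohort:
    with h5py.File(path, "r") as f:
        for attr in ("fs", "channel_names", "times_ms", "time0_index"):
            if attr not in f.attrs:
                raise SchemaError(f"cohort file missing attribute {attr!r}")
        fs = float(f.attrs["fs"])
        channels = tuple(str(c) for c in f.attrs["channel_names"])
        times = np.asarray(f.attrs["times_ms"], dtype=float)
        units = str(f.attrs.get("units", "uV"))
        if int(f.attrs["time0_index"]) >= len(times) or \
                times[int(f.attrs["time0_index"])] != 0:
            raise SchemaError("time0_index does not point at 0 ms")
        subjects = []
        for sid in sorted(f["subjects"]):
            g = f["subjects"][sid]
            data = np.asarray(g["epochs"], dtype=np.float32)
            labels = np.char.decode(np.asarray(g["labels"])).astype("U12")
            if data.shape[1] != len(channels):
                raise SchemaError(f"subject {sid}: channel count mismatch")
            if data.shape[2] != len(times):
                raise SchemaError(f"subject {sid}: sample count mismatch")
            subjects.append(SubjectEpochs(sid, data, labels, channels, fs,
                                          times, units=units))
    return EpochCohort(subjects, channels, fs, times, units=units)


def save_erpset(path, erp: ERPSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=erp.data)
        f.create_dataset("n_trials", data=erp.n_trials_averaged)
        f.attrs["subject_ids"] = erp.subject_ids
        f.attrs["channel_names"] = list(erp.channel_names)
        f.attrs["times_ms"] = erp.times_ms
        f.attrs["condition"] = erp.condition
        f.attrs["units"] = erp.units
        f.attrs["dropped_subjects"] = erp.dropped_subjects


def load_erpset(path) -> ERPSet:
    with h5py.File(path, "r") as f:
        return ERPSet(np.asarray(f["data"]),
                      [str(s) for s in f.attrs["subject_ids"]],
                      tuple(str(c) for c in f.attrs["channel_names"]),
                      np.asarray(f.attrs["times_ms"], dtype=float),
                      str(f.attrs["condition"]),
                      np.asarray(f["n_trials"]),
                      units=str(f.attrs["units"]),
                      dropped_subjects=[str(s) for s in
                                        f.attrs["dropped_subjects"]])


def save_tfrset(path, tfr: TFRSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=tfr.data.astype(np.float32))
        f.create_dataset("freqs", data=tfr.freqs)
        f.create_dataset("edge", data=tfr.edge)
        f.attrs["subject_ids"] = tfr.subject_ids
        f.attrs["channel_names"] = list(tfr.channel_names)
        f.attrs["times_ms"] = tfr.times_ms
        f.attrs["condition"] = tfr.condition
        f.attrs["units"] = tfr.units


def load_tfrset(path) -> TFRSet:
    with h5py.File(path, "r") as f:
        return TFRSet(np.asarray(f["data"], dtype=np.float64),
                      np.asarray(f["freqs"], dtype=float),
                      [str(s) for s in f.attrs["subject_ids"]],
                      tuple(str(c) for c in f.attrs["channel_names"]),
                      np.asarray(f.attrs["times_ms"], dtype=float),
                      str(f.attrs["condition"]),
                      np.asarray(f["edge"], dtype=bool),
                      units=str(f.attrs["units"]))


def save_feature_bank(path_h5, path_csv, bank) -> None:
    with h5py.File(path_h5, "w") as f:
        f.create_dataset("values", data=bank.values)
        f.attrs["subject_ids"] = bank.subject_ids
        f.attrs["provenance"] = bank.provenance
        f.attrs["normalized"] = bank.normalized
    bank.descriptors.to_csv(path_csv, index=False)


def load_feature_bank(path_h5, path_csv):
    from .features import FeatureBank

    with h5py.File(path_h5, "r") as f:
        values = np.asarray(f["values"])
        ids = [str(s) for s in f.attrs["subject_ids"]]
        provenance = str(f.attrs["provenance"])
        normalized = bool(f.attrs["normalized"])
    desc = pd.read_csv(path_csv)
    return FeatureBank(values, desc, ids, provenance, normalized)


def save_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2))


def load_config_file(path) -> dict:
    """Load a YAML or JSON pipeline configuration into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
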