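"""End-to-end pipeline driver.

Stages run in the fixed order simulate/load -> preprocess (reject, CSD,
baseline) -> ERP averaging + time-frequency total power -> feature banks
-> filter + SFFS selection -> train/validation verification.  Subjects
are processed one at a time so cohort-scale memory stays bounded; every
artifact is stamped with the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from .features import FeatureBank, build_erp_features, build_tf_features, zscore_features
from .montage import unit_sphere_positions
from .preprocess import (CSDParams, ERPSet, baseline_correct, csd_transform,
                         detect_local_peak, mean_amplitude,
                         reject_artifact_trials)
from .selection import (SelectionConfig, SelectionResult, selection_table,
                        sffs, ttest_filter)
from .synthetic_data import (NOGO_CORRECT, GO_CORRECT, SimConfig, demo_config,
                             iter_subjects)
from .tfr import TFRSet, edge_flags, subject_total_power
from .validation import ValidationReport, run_validation, split_train_validation

logger = logging.getLogger(__name__)

_ERP_COMPONENTS = (
    # name, electrodes, window_ms, kind, polarity
    ("P1", ("PO9", "PO10"), (90.0, 110.0), "peak", +1),
    ("N1", ("PO9", "PO10"), (170.0, 190.0), "peak", -1),
    ("N2", ("Cz",), (250.0, 280.0), "mean", -1),
    ("Nogo-P3", ("FC1",), (370.0, 410.0), "mean", +1),
    ("Go-P3", ("P1",), (370.0, 410.0), "mean", +1),
)


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (see ``from_dict``)."""

    sim: SimConfig = field(default_factory=SimConfig)
    csd: CSDParams = field(default_factory=CSDParams)
    reject: dict = field(default_factory=dict)
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    freqs: tuple[float, ...] = tuple(np.arange(1.0, 19.0))
    feature_window_ms: tuple[float, float] = (0.0, 1500.0)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    validation_frac: float = 0.7
    n_perm: int = 1000
    do_ablation: bool = False
    max_features: int | None = None
    mode: str = "paper"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("paper", "nested"):
            raise ValueError("mode must be 'paper' or 'nested'")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        """Build from a plain dict (YAML/JSON), rejecting unknown keys."""
        raw = dict(raw)
        kwargs: dict = {}
        sim_raw = dict(raw.pop("sim", {}))
        preset = sim_raw.pop("preset", "full")
        _check_keys(sim_raw, {f.name for f in dataclasses.fields(SimConfig)},
                    "sim")
        if "channels" in sim_raw:
            sim_raw["channels"] = tuple(sim_raw["channels"])
        if "components" in sim_raw:
            raise ValueError("components cannot be configured from file")
        kwargs["sim"] = (demo_config(**sim_raw) if preset == "demo"
                         else SimConfig(**sim_raw))
        if "csd" in raw:
            kwargs["csd"] = CSDParams(**raw.pop("csd"))
        if "selection" in raw:
            kwargs["selection"] = SelectionConfig(**raw.pop("selection"))
        for key in ("reject", "baseline_ms", "freqs", "feature_window_ms",
                    "validation_frac", "n_perm", "do_ablation",
                    "max_features", "mode", "seed"):
            if key in raw:
                val = raw.pop(key)
                if key in ("baseline_ms", "freqs", "feature_window_ms"):
                    val = tuple(val)
                kwargs[key] = val
        _check_keys(raw, set(), "run config")
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return float(o)
            raise TypeError(type(o))
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _check_keys(raw: dict, allowed: set, where: str) -> None:
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown {where} keys: {sorted(unknown)}")


@dataclass
class PipelineResult:
    behavior: pd.DataFrame
    groups: pd.DataFrame
    erp_components: pd.DataFrame
    erp_bank: FeatureBank
    tf_bank: FeatureBank
    selection_erp: SelectionResult | None
    selection_tf: SelectionResult | None
    report_erp: ValidationReport | None
    report_tf: ValidationReport | None
    labels: np.ndarray
    config_hash: str
    seed: int
    rejection_log: pd.DataFrame
    theta_band_power: pd.DataFrame | None = None


def reduce_cohort(config: RunConfig):
    """Stream subjects through preprocessing and reduction.

    Returns (behavior table, correct-Nogo ERPSet, correct-Go ERPSet,
    correct-Nogo TFRSet restricted to the feature window, rejection log).
    """
    sim = config.sim
    positions = unit_sphere_positions(sim.channels)
    out_idx = np.flatnonzero(
        (sim.times_ms >= config.feature_window_ms[0])
        & (sim.times_ms <= config.feature_window_ms[1]))
    freqs = np.asarray(config.freqs, dtype=float)
    rows, rej_rows = [], []
    erp_nogo, erp_go, tf_nogo, ids = [], [], [], []
    n_nogo_list, n_go_list = [], []
    t0 = time.time()
    for epochs, row, _man in iter_subjects(sim):
        rows.append(row)
        cleaned, rlog = reject_artifact_trials(epochs, **config.reject)
        if len(rlog):
            rlog = rlog.assign(subject_id=epochs.subject_id)
            rej_rows.append(rlog)
        cleaned = csd_transform(cleaned, positions, config.csd)
        cleaned = baseline_correct(cleaned, config.baseline_ms)
        nogo = cleaned.select(NOGO_CORRECT)
        go = cleaned.select(GO_CORRECT)
        if len(nogo) == 0 or len(go) == 0:
            raise ValueError(
                f"subject {epochs.subject_id} has no retained correct "
                f"{'Nogo' if len(nogo) == 0 else 'Go'} trials")
        ids.append(epochs.subject_id)
        erp_nogo.append(nogo.mean(axis=0, dtype=np.float64))
        erp_go.append(go.mean(axis=0, dtype=np.float64))
        n_nogo_list.append(len(nogo))
        n_go_list.append(len(go))
        tf_nogo.append(subject_total_power(nogo, sim.fs, freqs, out_idx))
    logger.info("reduced %d subjects in %.1f s", len(ids), time.time() - t0)
    behavior = pd.DataFrame(rows)
    erp_n = ERPSet(np.stack(erp_nogo), ids, tuple(sim.channels), sim.times_ms,
                   NOGO_CORRECT, np.asarray(n_nogo_list))
    erp_g = ERPSet(np.stack(erp_go), ids, tuple(sim.channels), sim.times_ms,
                   GO_CORRECT, np.asarray(n_go_list))
    tfr = TFRSet(np.stack(tf_nogo), freqs, ids, tuple(sim.channels),
                 sim.times_ms[out_idx], NOGO_CORRECT,
                 edge_flags(sim.times_ms, out_idx, freqs))
    rejection = (pd.concat(rej_rows, ignore_index=True) if rej_rows
                 else pd.DataFrame(columns=["trial", "reason", "channel",
                                            "subject_id"]))
    return behavior, erp_n, erp_g, tfr, rejection


def quantify_erp_components(erp_nogo: ERPSet, erp_go: ERPSet) -> pd.DataFrame:
    """Classical ERP quantification (peak P1/N1, mean-amplitude N2/P3)."""
    rows = []
    for name, electrodes, window, kind, polarity in _ERP_COMPONENTS:
        for cond_name, erp in (("nogo", erp_nogo), ("go", erp_go)):
            if kind == "peak":
                for el in electrodes:
                    for res in detect_local_peak(erp, el, window, polarity):
                        rows.append({
                            "component": name, "condition": cond_name,
                            "subject_id": res.subject_id, "electrode": el,
                            "latency_ms": res.latency_ms,
                            "amplitude": res.amplitude,
                            "fallback": res.fallback})
            else:
                amps = mean_amplitude(erp, list(electrodes), window)
                for sid, amp in zip(erp.subject_ids, amps):
                    rows.append({
                        "component": name, "condition": cond_name,
                        "subject_id": sid,
                        "electrode": "+".join(electrodes),
                        "latency_ms": float(np.mean(window)),
                        "amplitude": float(amp), "fallback": False})
    return pd.DataFrame(rows)


def _subset_bank(bank: FeatureBank, keep_ids: list[str]) -> FeatureBank:
    idx = [bank.subject_ids.index(s) for s in keep_ids]
    return dataclasses.replace(bank, values=bank.values[idx],
                               subject_ids=list(keep_ids))


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None,
                 select: bool = True, validate: bool = True) -> PipelineResult:
    """Execute the full analysis on a freshly simulated cohort."""
    cfg_hash = config.config_hash()
    behavior, erp_nogo, erp_go, tfr, rejection = reduce_cohort(config)
    behavior = beh.apply_exclusions(behavior)
    assignment = beh.median_split(behavior)
    keep_ids = assignment.table["subject_id"].tolist()
    labels = beh.group_labels(assignment)
    erp_components = quantify_erp_components(erp_nogo, erp_go)
    from .tfr import band_power
    theta = None
    if all(e in tfr.channel_names for e in ("FCz", "Cz")):
        theta = pd.DataFrame({
            "subject_id": tfr.subject_ids,
            "theta_power_nogo": band_power(tfr)})

    erp_bank = _subset_bank(build_erp_features(
        erp_nogo, *config.feature_window_ms), keep_ids)
    tf_bank = _subset_bank(build_tf_features(
        tfr, *config.feature_window_ms), keep_ids)
    sel_cfg = dataclasses.replace(config.selection, seed=config.seed)

    selections: dict[str, SelectionResult | None] = {"erp": None, "tf": None}
    reports: dict[str, ValidationReport | None] = {"erp": None, "tf": None}
    for name, bank in (("erp", erp_bank), ("tf", tf_bank)):
        if config.mode == "paper":
            bank_z = zscore_features(bank)
            if select:
                cand, pvals = ttest_filter(bank_z.values, labels,
                                           sel_cfg.filter_alpha,
                                           sel_cfg.equal_var)
                if len(cand):
                    selections[name] = sffs(bank_z.values, labels, cand,
                                            pvals, sel_cfg,
                                            max_features=config.max_features)
        else:
            train_idx, _ = split_train_validation(labels,
                                                  config.validation_frac,
                                                  config.seed)
            bank_z = zscore_features(bank, stats_rows=train_idx)
        if validate:
            reports[name], nested_sel = run_validation(
                bank_z, labels, sel_cfg, config.validation_frac,
                config.n_perm, config.max_features, config.seed,
                config.do_ablation, config.mode)
            if selections[name] is None:
                selections[name] = nested_sel

    result = PipelineResult(
        behavior=behavior, groups=assignment.table,
        erp_components=erp_components, erp_bank=erp_bank, tf_bank=tf_bank,
        selection_erp=selections["erp"], selection_tf=selections["tf"],
        report_erp=reports["erp"], report_tf=reports["tf"], labels=labels,
        config_hash=cfg_hash, seed=config.seed, rejection_log=rejection,
        theta_band_power=theta)
    if out_dir is not None:
        export_artifacts(result, config, erp_bank, tf_bank, Path(out_dir))
    return result


def export_artifacts(result: PipelineResult, config: RunConfig,
                     erp_bank: FeatureBank, tf_bank: FeatureBank,
                     out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": result.config_hash, "seed": result.seed}
    result.behavior.to_csv(out_dir / "behavior.csv", index=False)
    result.groups[["subject_id", "group", "ratio"]].to_csv(
        out_dir / "groups.csv", index=False)
    result.erp_components.to_csv(out_dir / "erp_components.csv", index=False)
    result.rejection_log.to_csv(out_dir / "rejection_log.csv", index=False)
    if result.theta_band_power is not None:
        result.theta_band_power.to_csv(out_dir / "theta_band_power.csv",
                                       index=False)
    for name, sel, bank in (("erp", result.selection_erp, erp_bank),
                            ("tf", result.selection_tf, tf_bank)):
        if sel is not None:
            table = selection_table(sel, bank.descriptors)
            table.to_csv(out_dir / f"selection_{name}.csv", index=False)
            payload = {"steps": [{
                "size": s.size, "subset": list(s.subset),
                "fold_accuracies": list(s.fold_accuracies),
                "mean_accuracy": s.mean_accuracy, "ci": list(s.ci),
                "classwise_accuracy": s.classwise_accuracy}
                for s in sel.steps], **stamp}
            (out_dir / f"selection_{name}.json").write_text(
                json.dumps(payload, indent=2))
        report = result.report_erp if name == "erp" else result.report_tf
        if report is not None:
            report.to_frame().to_csv(out_dir / f"validation_{name}.csv",
                                     index=False)
            payload = {**json.loads(report.to_json()), **stamp}
            (out_dir / f"validation_{name}.json").write_text(
                json.dumps(payload, indent=2))
    (out_dir / "run_stamp.json").write_text(json.dumps(stamp, indent=2))
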