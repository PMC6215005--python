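"""Planted-feature recovery and calibration studies.

These routines run the decoding pipeline end-to-end on synthetic cohorts
with known ground truth and measure how well the data-driven selection
recovers the planted features, how the null (no effect) behaves, and
whether ablating a planted feature returns accuracy to chance.  They are
the package's quantitative self-validation surface; the test suite and
``scripts/acceptance.py`` are thin wrappers around them.

The default study conditions: 240 subjects, one group-modulated ERP
plant (C3, 322 ms) and one group-modulated theta plant (C3, 4 Hz,
324 ms), standardized effect size 1.2, at the reduced demonstration
scale (16 channels, 64 Hz, 120 trials; EEG synthesized for Nogo trials
only, which is all the feature banks consume).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import behavior as beh
from .features import FeatureBank, build_erp_features, build_tf_features, zscore_features
from .montage import unit_sphere_positions
from .preprocess import (CSDParams, ERPSet, baseline_correct, csd_matrix,
                         csd_transform, reject_artifact_trials)
from .selection import SelectionConfig, sffs, ttest_filter
from .synthetic_data import (NOGO_CORRECT, SimConfig, component_loadings,
                             demo_config, iter_subjects, recovery_components)
from .tfr import TFRSet, edge_flags, morlet_params, subject_total_power
from .validation import ablation, run_validation

#: planted ground truth of the recovery study
ERP_PLANT = {"channel": "C3", "time_ms": 322.0}
TF_PLANT = {"channel": "C3", "time_ms": 324.0, "freq_hz": 4.0}


def recovery_sim(seed: int, n_subjects: int = 240, effect_size: float = 1.2,
                 n_trials: int = 120) -> SimConfig:
    """Demo-scale cohort with exactly one ERP and one theta plant."""
    return demo_config(n_subjects=n_subjects, n_trials=n_trials,
                       effect_size=effect_size,
                       components=recovery_components(),
                       synthesize_conditions=("nogo",), seed=seed)


def reduce_nogo(sim: SimConfig, freqs=None,
                feature_window_ms=(0.0, 1500.0),
                csd_params: CSDParams = CSDParams()):
    """Stream subjects through reject -> CSD -> baseline and reduce to the
    correct-Nogo ERP average and total power on the feature grid."""
    if freqs is None:
        freqs = np.arange(1.0, 19.0)
    freqs = np.asarray(freqs, dtype=float)
    positions = unit_sphere_positions(sim.channels)
    out_idx = np.flatnonzero((sim.times_ms >= feature_window_ms[0])
                             & (sim.times_ms <= feature_window_ms[1]))
    rows, erp, tfp, ids, counts = [], [], [], [], []
    for epochs, row, _man in iter_subjects(sim):
        rows.append(row)
        cleaned, _log = reject_artifact_trials(epochs)
        cleaned = csd_transform(cleaned, positions, csd_params)
        cleaned = baseline_correct(cleaned)
        nogo = cleaned.select(NOGO_CORRECT)
        if len(nogo) == 0:
            raise ValueError(f"subject {epochs.subject_id} has no correct "
                             "Nogo trials")
        erp.append(nogo.mean(axis=0, dtype=np.float64))
        tfp.append(subject_total_power(nogo, sim.fs, freqs, out_idx))
        ids.append(epochs.subject_id)
        counts.append(len(nogo))
    erp_set = ERPSet(np.stack(erp), ids, tuple(sim.channels), sim.times_ms,
                     NOGO_CORRECT, np.asarray(counts))
    tfr_set = TFRSet(np.stack(tfp), freqs, ids, tuple(sim.channels),
                     sim.times_ms[out_idx], NOGO_CORRECT,
                     edge_flags(sim.times_ms, out_idx, freqs))
    return pd.DataFrame(rows), erp_set, tfr_set


def _group_banks(behavior: pd.DataFrame, erp_set: ERPSet, tfr_set: TFRSet):
    behavior = beh.apply_exclusions(behavior)
    assignment = beh.median_split(behavior)
    labels = beh.group_labels(assignment)
    keep = assignment.table["subject_id"].tolist()

    def subset(bank: FeatureBank) -> FeatureBank:
        idx = [bank.subject_ids.index(s) for s in keep]
        return dataclasses.replace(bank, values=bank.values[idx],
                                   subject_ids=list(keep))

    erp_bank = subset(build_erp_features(erp_set))
    tf_bank = subset(build_tf_features(tfr_set))
    return labels, erp_bank, tf_bank


@dataclass
class FirstFeature:
    channel: str
    time_ms: float
    freq_hz: float | None
    accuracy: float

    def offsets(self, plant: dict) -> dict:
        out = {"channel_match": self.channel == plant["channel"],
               "dt_ms": self.time_ms - plant["time_ms"]}
        if self.freq_hz is not None and "freq_hz" in plant:
            out["df_hz"] = self.freq_hz - plant["freq_hz"]
        return out


def first_selected_features(seed: int, n_subjects: int = 240,
                            effect_size: float = 1.2,
                            n_trials: int = 120) -> dict:
    """Run the full pipeline once and return the first SFFS-selected
    feature of the ERP and TF banks."""
    sim = recovery_sim(seed, n_subjects, effect_size, n_trials)
    behavior, erp_set, tfr_set = reduce_nogo(sim)
    labels, erp_bank, tf_bank = _group_banks(behavior, erp_set, tfr_set)
    cfg = SelectionConfig(seed=seed)
    out = {}
    for name, bank in (("erp", erp_bank), ("tf", tf_bank)):
        bank_z = zscore_features(bank)
        cand, pvals = ttest_filter(bank_z.values, labels, cfg.filter_alpha,
                                   cfg.equal_var)
        if len(cand) == 0:
            cand = np.asarray([int(np.argmin(pvals))])
        result = sffs(bank_z.values, labels, cand, pvals, cfg,
                      max_features=1)
        step = result.steps[0]
        desc = bank_z.descriptors.iloc[step.added]
        freq = None if pd.isna(desc["freq_hz"]) else float(desc["freq_hz"])
        out[name] = FirstFeature(str(desc["channel"]), float(desc["time_ms"]),
                                 freq, step.mean_accuracy)
    return out


def recovery_study(seeds, n_subjects: int = 240, effect_size: float = 1.2,
                   n_trials: int = 120) -> dict:
    """Strict and resolution-scaled recovery rates over the given seeds.

    Strict: selected channel equals the plant's and the time offset is
    within ±20 ms (TF additionally within ±1 Hz).  Resolution-scaled:
    channel match with offsets within the wavelet's own resolution
    (|dt| <= 2 sigma_t, |df| <= 2 sqrt(2) sigma_f at the plant frequency;
    for the ERP plant |dt| <= 50 ms).
    """
    p4 = morlet_params(TF_PLANT["freq_hz"])
    tf_dt = 2000.0 * p4.sigma_t                  # one wavelet duration, ms
    tf_df = 2.0 * np.sqrt(2.0) * p4.sigma_f      # effective spectral width
    rows = []
    for seed in seeds:
        feats = first_selected_features(int(seed), n_subjects, effect_size,
                                        n_trials)
        e, t = feats["erp"], feats["tf"]
        rows.append({
            "seed": int(seed),
            "erp_channel": e.channel, "erp_time_ms": e.time_ms,
            "erp_dt_ms": e.time_ms - ERP_PLANT["time_ms"],
            "tf_channel": t.channel, "tf_time_ms": t.time_ms,
            "tf_freq_hz": t.freq_hz,
            "tf_dt_ms": t.time_ms - TF_PLANT["time_ms"],
            "tf_df_hz": (t.freq_hz or np.nan) - TF_PLANT["freq_hz"],
            "erp_strict": (e.channel == ERP_PLANT["channel"]
                           and abs(e.time_ms - ERP_PLANT["time_ms"]) <= 20),
            "tf_strict": (t.channel == TF_PLANT["channel"]
                          and abs(t.time_ms - TF_PLANT["time_ms"]) <= 20
                          and t.freq_hz is not None
                          and abs(t.freq_hz - TF_PLANT["freq_hz"]) <= 1),
            "erp_resolution": (e.channel == ERP_PLANT["channel"]
                               and abs(e.time_ms - ERP_PLANT["time_ms"]) <= 50),
            "tf_resolution": (t.channel == TF_PLANT["channel"]
                              and abs(t.time_ms - TF_PLANT["time_ms"]) <= tf_dt
                              and t.freq_hz is not None
                              and abs(t.freq_hz - TF_PLANT["freq_hz"]) <= tf_df),
        })
    table = pd.DataFrame(rows)
    return {
        "runs": table,
        "erp_strict_pct": 100.0 * table["erp_strict"].mean(),
        "tf_strict_pct": 100.0 * table["tf_strict"].mean(),
        "erp_resolution_pct": 100.0 * table["erp_resolution"].mean(),
        "tf_resolution_pct": 100.0 * table["tf_resolution"].mean(),
        "erp_channel_pct": 100.0 * (table["erp_channel"]
                                    == ERP_PLANT["channel"]).mean(),
        "tf_channel_pct": 100.0 * (table["tf_channel"]
                                   == TF_PLANT["channel"]).mean(),
    }


def null_validation_accuracy(seed: int, n_subjects: int = 240,
                             n_trials: int = 120, n_perm: int = 0) -> float:
    """Validation-set accuracy of the first selected ERP feature on a
    cohort with no planted group effect (effect size 0)."""
    sim = recovery_sim(seed, n_subjects, effect_size=0.0, n_trials=n_trials)
    behavior, erp_set, tfr_set = reduce_nogo(sim)
    labels, erp_bank, _tf = _group_banks(behavior, erp_set, tfr_set)
    cfg = SelectionConfig(seed=seed)
    report, _sel = run_validation(zscore_features(erp_bank), labels, cfg,
                                  n_perm=n_perm, max_features=1,
                                  do_ablation=False)
    return report.validation_accuracy[0]


def planted_channel_columns(bank: FeatureBank, sim: SimConfig,
                            rel_threshold: float = 0.1) -> np.ndarray:
    """Columns on every channel where the planted components' CSD image
    exceeds ``rel_threshold`` of its maximum.

    A planted component is spatially extended: after the surface
    Laplacian its signal appears, with spline sidelobes, on neighboring
    electrodes too, so removing only the nominal channel's columns leaves
    redundant copies of the effect in the bank.
    """
    mat = csd_matrix(unit_sphere_positions(sim.channels))
    loadings = component_loadings(sim)
    channels = set()
    for comp, load in zip(sim.components, loadings):
        if not comp.group_modulation:
            continue
        image = np.abs(mat @ load)
        for name, rel in zip(sim.channels, image / image.max()):
            if rel >= rel_threshold:
                channels.add(name)
    mask = bank.descriptors["channel"].isin(sorted(channels)).to_numpy()
    return np.flatnonzero(mask)


def planted_ablation_accuracy(seed: int, n_subjects: int = 240,
                              effect_size: float = 1.2,
                              n_trials: int = 120) -> float:
    """Validation accuracy after removing every column the planted
    components load on (their CSD footprint), re-running the full
    filter + SFFS protocol on the remainder."""
    sim = recovery_sim(seed, n_subjects, effect_size, n_trials)
    behavior, erp_set, tfr_set = reduce_nogo(sim)
    labels, erp_bank, _tf = _group_banks(behavior, erp_set, tfr_set)
    bank_z = zscore_features(erp_bank)
    removed = planted_channel_columns(bank_z, sim)
    cfg = SelectionConfig(seed=seed)
    from .validation import split_train_validation

    train_idx, val_idx = split_train_validation(labels, 0.7, seed)
    acc, _sel = ablation(bank_z.values, labels, removed, train_idx, val_idx,
                         cfg)
    return acc


# --- oracle and calibration studies ----------------------------------------

def sffs_exhaustive_study(n_instances: int = 20, base_seed: int = 100,
                          n_candidates: int = 6) -> dict:
    """Compare SFFS against exhaustive subset search on small instances.

    Each instance: 40 subjects, 6 candidate features with three
    well-separated informative columns, 5-fold evaluation.  Size-1
    equality is exact by construction (both evaluate every singleton with
    the same folds); full best-subset-per-size agreement measures how
    often the greedy floating search attains the exhaustive optimum.
    """
    from .selection import draw_folds, exhaustive_best_subsets

    singleton_agree = 0
    subset_agree = 0
    sizes_checked = 0
    sizes_agree = 0
    for i in range(n_instances):
        rng = np.random.default_rng(base_seed + i)
        n = 40
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(size=(n, n_candidates))
        x[y == 1, 0] += 2.0
        x[y == 1, 1] += 1.6
        x[y == 1, 2] += 1.2
        cfg = SelectionConfig(k_folds=5, seed=base_seed + i)
        folds = draw_folds(y, cfg)
        _, pvals = ttest_filter(x, y, 1.0)
        res = sffs(x, y, np.arange(n_candidates), pvals, cfg, folds=folds,
                   max_features=n_candidates)
        ex = exhaustive_best_subsets(x, y, np.arange(n_candidates), cfg,
                                     folds=folds)
        ok = {s: abs(res.best_of_size(s).mean_accuracy - ex[s][1]) < 1e-12
              for s in ex}
        singleton_agree += ok[1]
        subset_agree += all(ok.values())
        sizes_checked += len(ok)
        sizes_agree += sum(ok.values())
    return {
        "n_instances": n_instances,
        "singleton_agreement_pct": 100.0 * singleton_agree / n_instances,
        "subset_agreement_pct": 100.0 * subset_agree / n_instances,
        "per_size_agreement_pct": 100.0 * sizes_agree / sizes_checked,
    }


def csd_eigenvalue_study(n_points: int = 300, max_degree: int = 4) -> dict:
    """Spherical-harmonic oracle: the surface Laplacian of a degree-l
    harmonic is l(l+1) times itself; measure the worst relative error of
    the spline CSD operator on a dense quasi-uniform montage."""
    from scipy.special import sph_harm_y

    from .montage import fibonacci_sphere

    pos = fibonacci_sphere(n_points)
    mat = csd_matrix(pos, CSDParams(smoothing_lambda=1e-9))
    theta = np.arccos(np.clip(pos[:, 2], -1, 1))
    phi = np.arctan2(pos[:, 1], pos[:, 0])
    worst = 0.0
    for ell in range(1, max_degree + 1):
        for m in range(0, ell + 1):
            y = sph_harm_y(ell, m, theta, phi).real
            if np.allclose(y, 0):
                continue
            out = mat @ y
            ratio = float(np.dot(out, y) / np.dot(y, y))
            worst = max(worst, abs(ratio - ell * (ell + 1))
                        / (ell * (ell + 1)))
    return {"n_points": n_points, "max_degree": max_degree,
            "max_rel_error": worst}


def cwt_oracle_study(fs: float = 64.0, seed: int = 0) -> dict:
    """Direct-convolution oracle on a 2-second test signal: the banked
    matrix evaluation must agree with numpy.convolve per frequency."""
    from .tfr import cwt_power, morlet_kernel

    rng = np.random.default_rng(seed)
    n = int(2 * fs) + 1
    x = rng.normal(size=n)
    freqs = np.arange(1.0, 19.0)
    power = cwt_power(x, fs, freqs)
    worst = 0.0
    for fi, f0 in enumerate(freqs):
        k = morlet_kernel(f0, fs)
        half = (len(k) - 1) // 2
        w = np.convolve(x, k, mode="full")[half:half + n]
        err = np.max(np.abs(power[fi] - np.abs(w) ** 2))
        worst = max(worst, err / np.max(np.abs(w) ** 2))
    return {"n_samples": n, "max_rel_error": worst}


def permutation_uniformity_study(n_seeds: int = 50, n_perm: int = 100,
                                 base_seed: int = 200,
                                 n_subjects: int = 240) -> dict:
    """Exceedance calibration under exchangeable labels.

    The 'real' labels are drawn by the same mechanism as the permutations
    (a label permutation drawn after the train/validation split is fixed),
    so the exceedance percentage must be distribution-uniform; features
    carry label-independent cluster structure so the classifier's
    predictions vary across relabelings (no degenerate tie atoms).
    """
    from scipy import stats as sps

    from .selection import make_svm
    from .validation import permutation_test, split_train_validation

    exceedance = []
    for s in range(n_seeds):
        seed = base_seed + s
        rng = np.random.default_rng(seed)
        y0 = np.repeat([0, 1], n_subjects // 2)
        clusters = rng.integers(0, 2, n_subjects)
        x = rng.normal(size=(n_subjects, 2)) + 2.0 * clusters[:, None]
        train_idx, val_idx = split_train_validation(y0, 0.7, seed)
        y_real = rng.permutation(y0)
        cfg = SelectionConfig(seed=seed)
        clf = make_svm(cfg).fit(x[train_idx], y_real[train_idx])
        real = float(np.mean(clf.predict(x[val_idx]) == y_real[val_idx]))
        exceedance.append(permutation_test(x, y0, train_idx, val_idx, [0, 1],
                                           real, n_perm=n_perm,
                                           seed=seed + 10_000, cfg=cfg))
    exceedance = np.asarray(exceedance)
    ks = sps.kstest(exceedance / 100.0, "uniform")
    return {"n_seeds": n_seeds, "n_perm": n_perm,
            "exceedance_pct": exceedance, "ks_pvalue": float(ks.pvalue)}


def cv_arithmetic(n_subjects: int = 240, k: int = 10) -> dict:
    """Fold size and per-fold accuracy granularity of the k-fold design."""
    from .selection import draw_folds

    labels = np.repeat([0, 1], n_subjects // 2)
    folds = draw_folds(labels, SelectionConfig(k_folds=k, seed=0))
    sizes = sorted({len(te) for _, te in folds})
    fold = sizes[0]
    return {"fold_sizes": sizes, "fold_size": fold,
            "accuracy_resolution_pct": round(100.0 / fold, 2)}
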