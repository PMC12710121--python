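"""End-to-end tremor classification pipeline: simulate/load -> preprocess ->
metrics -> features -> patient-grouped classification -> report.

The canonical run mirrors the clinical analysis design: per patient, the more
affected hand is chosen by the relative spectral-power side difference, the
rest recording of that hand is standardized (100 Hz, 15 s, 2-30 Hz), the two
model-based features (GARCH residual KS statistic and HMM state-comparison
log-likelihood) plus the six standard tremor characteristics are computed, and
a linear SVM is evaluated with 10-fold patient-grouped cross-validation.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify, features as ft, io_preprocess as iop, spectral, synth

__all__ = [
    "RunConfig",
    "RunRecord",
    "extract_cohort_features",
    "run",
    "permutation_null",
    "compare_standard_vs_features",
    "rest_vs_posture_classification",
    "length_ablation_study",
    "MODEL_FEATURES",
    "STANDARD_FEATURES",
]

MODEL_FEATURES = ("garch_ks", "hmm_nstates_ll")
STANDARD_FEATURES = ("auc", "tsi", "hwp", "peak_frequency", "fwhm", "peak_power")


@dataclass
class RunConfig:
    """Serializable pipeline configuration; defaults match the analysis constants
    (100 Hz, 15 s, 2-30 Hz band, 10 folds, 75% univariate screen)."""

    n_et: int = 60
    n_pd: int = 60
    duration: float = 15.0
    target_rate: float = 100.0
    band: tuple[float, float] = (2.0, 30.0)
    condition: str = "rest"
    model: str = "svm"
    k_folds: int = 10
    screen_threshold: float = 75.0
    hmm_state_range: tuple[int, ...] = (2, 3, 4)
    hmm_train_fraction: float = 0.6
    hmm_restarts: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.band = tuple(cfg.band)
        cfg.hmm_state_range = tuple(cfg.hmm_state_range)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class RunRecord:
    """Provenance of one pipeline run: config snapshot, timings, hashes."""

    config: dict
    version: str
    stage_seconds: dict[str, float] = field(default_factory=dict)
    warnings_: list[str] = field(default_factory=list)
    output_hashes: dict[str, str] = field(default_factory=dict)

    def add_hash(self, name: str, payload) -> None:
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        self.output_hashes[name] = hashlib.sha256(blob).hexdigest()


def _recording_seed(seed: int, patient_id: str) -> int:
    digest = hashlib.sha256(f"{seed}:{patient_id}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def extract_cohort_features(
    manifest: iop.CohortManifest,
    *,
    condition: str = "rest",
    duration: float = 15.0,
    seed: int = 0,
    include_standard: bool = True,
    hmm_state_range: Sequence[int] = (2, 3, 4),
    hmm_train_fraction: float = 0.6,
    hmm_restarts: int = 3,
    apply_loading_filter: bool = True,
    use_more_affected: bool = True,
) -> tuple[ft.FeatureMatrix, np.ndarray, np.ndarray, pd.DataFrame]:
    """Per-patient feature extraction on the more-affected-hand recording.

    Returns ``(features, labels, groups, metadata)`` with one row per patient.
    The GARCH-KS and HMM features are computed on the z-normalized canonical
    series; the standard characteristics come from the same series, except AUC
    and peak power which use the non-normalized series so amplitude information
    survives.
    """
    cond = iop.Condition(condition)
    rows, labels, groups, meta = {}, [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pid in manifest.patient_ids:
            recs = manifest.for_patient(pid)
            if apply_loading_filter:
                recs = [r for r in recs if iop.loading_test_filter(r)]
            if not recs:
                continue
            cond_recs = [r for r in recs if r.condition == cond]
            if not cond_recs:
                continue
            if use_more_affected:
                hand, _ = iop.select_more_affected_hand(recs)
            else:
                hand = cond_recs[0].hand
            rec = next((r for r in cond_recs if r.hand == hand), cond_recs[0])
            try:
                row = _recording_features(
                    rec, duration=duration, seed=seed,
                    include_standard=include_standard,
                    hmm_state_range=hmm_state_range,
                    hmm_train_fraction=hmm_train_fraction,
                    hmm_restarts=hmm_restarts,
                )
            except (ValueError, ft.FeatureInvalid) as exc:
                row = {}
            rows[pid] = row
            labels.append(rec.diagnosis.value)
            groups.append(pid)
            meta.append({"patient_id": pid, "center": rec.center,
                         "condition": cond.value, "hand": rec.hand.value})
    values = pd.DataFrame.from_dict(rows, orient="index")
    matrix = ft.FeatureMatrix(values)
    return matrix, np.asarray(labels), np.asarray(groups), pd.DataFrame(meta)


def _recording_features(
    rec: iop.RawRecording,
    *,
    duration: float,
    seed: int,
    include_standard: bool,
    hmm_state_range: Sequence[int],
    hmm_train_fraction: float,
    hmm_restarts: int,
) -> dict[str, float]:
    scalar = rec.scalar_series()
    allow_short = duration < iop.TARGET_DURATION
    norm = iop.standardize(scalar, rec.sampling_rate, duration=duration,
                           normalize=True, allow_short=allow_short)
    raw = iop.standardize(scalar, rec.sampling_rate, duration=duration,
                          normalize=False, allow_short=allow_short)
    rec_seed = _recording_seed(seed, rec.patient_id)
    row: dict[str, float] = {}
    try:
        row["garch_ks"] = ft.garch_ks_feature(norm.samples)
    except (ft.FeatureInvalid, ValueError):
        row["garch_ks"] = np.nan
    try:
        row["hmm_nstates_ll"] = ft.hmm_compare_nstates_feature(
            norm.samples, train_fraction=hmm_train_fraction,
            state_range=hmm_state_range, restarts=hmm_restarts, seed=rec_seed,
        )
    except (ft.FeatureInvalid, ValueError):
        row["hmm_nstates_ll"] = np.nan
    if include_standard:
        try:
            spec_norm = spectral.spectral_summary(norm.samples, norm.sampling_rate)
            spec_raw = spectral.welch_psd(raw.samples, raw.sampling_rate)
            pf, pp = spectral.peak_frequency_power(spec_raw)
            row.update({
                "tsi": spec_norm.tsi, "hwp": spec_norm.hwp,
                "peak_frequency": spec_norm.peak_frequency, "fwhm": spec_norm.fwhm,
                "auc": spectral.band_power_auc(spec_raw),
                "peak_power": pp,
            })
        except ValueError:
            for name in STANDARD_FEATURES:
                row.setdefault(name, np.nan)
    return row


def run(config: RunConfig) -> tuple[RunRecord, classify.ClassifierReport, dict]:
    """Execute the full pipeline on a synthetic default cohort.

    Returns the run record, the classifier report for the two model features,
    and a bundle with the feature matrix / labels / groups for further analysis.
    """
    record = RunRecord(config=asdict(config), version=_version())
    t0 = time.perf_counter()
    cohort_cfg = synth.SyntheticCohortConfig(
        n_et=config.n_et, n_pd=config.n_pd,
        duration=max(config.duration + 2.0, 16.0), seed=config.seed,
    )
    manifest, truth = synth.generate_cohort(cohort_cfg)
    record.stage_seconds["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    matrix, labels, groups, meta = extract_cohort_features(
        manifest, condition=config.condition, duration=config.duration,
        seed=config.seed, hmm_state_range=config.hmm_state_range,
        hmm_train_fraction=config.hmm_train_fraction,
        hmm_restarts=config.hmm_restarts,
    )
    record.stage_seconds["features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    folds = classify.grouped_kfold(groups, k=config.k_folds,
                                   seed=config.seed, labels=labels)
    report = classify.evaluate_classifier(
        matrix, labels, folds, config.model,
        feature_subset=list(MODEL_FEATURES), seed=config.seed,
    )
    record.stage_seconds["classify"] = time.perf_counter() - t0
    record.add_hash("report", report.pooled)
    record.add_hash("features", matrix.values.round(10).to_dict())
    bundle = {"matrix": matrix, "labels": labels, "groups": groups,
              "meta": meta, "folds": folds, "manifest": manifest, "truth": truth}
    return record, report, bundle


def permutation_null(
    matrix: ft.FeatureMatrix, labels: np.ndarray, groups: np.ndarray,
    *, n_permutations: int = 20, k: int = 10, model: str = "svm", seed: int = 0,
    feature_subset: Sequence[str] | None = None,
) -> float:
    """Mean balanced CV accuracy under patient-level label permutation (null ~50%)."""
    rng = np.random.default_rng(seed)
    patients = pd.unique(groups)
    patient_label = {p: labels[groups == p][0] for p in patients}
    accs = []
    for i in range(n_permutations):
        permuted = rng.permutation([patient_label[p] for p in patients])
        mapping = dict(zip(patients, permuted))
        y = np.asarray([mapping[g] for g in groups])
        folds = classify.grouped_kfold(groups, k=k, seed=seed + i, labels=y)
        rep = classify.evaluate_classifier(matrix, y, folds, model,
                                           feature_subset=feature_subset, seed=seed)
        accs.append(rep.pooled["balanced_accuracy"])
    return float(np.mean(accs))


def compare_standard_vs_features(
    matrix: ft.FeatureMatrix, labels: np.ndarray, groups: np.ndarray,
    *, k: int = 10, model: str = "svm", seed: int = 0,
) -> pd.DataFrame:
    """Side-by-side report: TSI alone, peak power alone, TSI + peak power, and
    the two-feature model, as rows of Accuracy / Sensitivity / Specificity /
    PPV / NPV (percent)."""
    if np.unique(labels).shape[0] < 2:
        raise ValueError("cohort contains a single class")
    folds = classify.grouped_kfold(groups, k=k, seed=seed, labels=labels)
    subsets = {
        "ML model": list(MODEL_FEATURES),
        "TSI": ["tsi"],
        "Peak power": ["peak_power"],
        "TSI + peak power": ["tsi", "peak_power"],
    }
    metric_rows = ["accuracy", "sensitivity", "specificity", "ppv", "npv"]
    table = {}
    for name, subset in subsets.items():
        rep = classify.evaluate_classifier(matrix, labels, folds, model,
                                           feature_subset=subset, seed=seed)
        table[name] = {m: rep.pooled[m] for m in metric_rows}
        table[name]["balanced_accuracy"] = rep.pooled["balanced_accuracy"]
    out = pd.DataFrame(table).reindex(metric_rows + ["balanced_accuracy"])
    out.index.name = "Parameter"
    return out


def rest_vs_posture_classification(
    manifest: iop.CohortManifest,
    *, duration: float = 15.0, k: int = 10, model: str = "svm", seed: int = 0,
) -> classify.ClassifierReport:
    """Classify recording position (rest vs posture) irrespective of diagnosis.

    Uses both condition recordings of each patient's more affected hand with
    condition as the label and patient-grouped folds; the feature set is the
    full (amplitude-dependent) pipeline output.
    """
    conds = {iop.Condition(r.condition) for r in manifest.recordings}
    if len(conds) < 2:
        raise ValueError("cohort contains a single recording condition")
    frames, labels, groups = [], [], []
    for condition in ("rest", "posture"):
        m, _, g, _ = extract_cohort_features(
            manifest, condition=condition, duration=duration, seed=seed,
        )
        m.values.index = [f"{i}/{condition}" for i in m.values.index]
        m.valid.index = m.values.index
        frames.append(m.values)
        labels.extend([condition] * len(g))
        groups.extend(g)
    values = pd.concat(frames, axis=0)
    matrix = ft.filter_invalid_features(ft.FeatureMatrix(values))
    labels, groups = np.asarray(labels), np.asarray(groups)
    folds = classify.grouped_kfold(groups, k=k, seed=seed, labels=labels)
    return classify.evaluate_classifier(matrix, labels, folds, model,
                                        positive_class="rest", seed=seed)


def length_ablation_study(
    manifest: iop.CohortManifest,
    lengths: Sequence[float] = (3.0, 5.0, 8.0, 10.0, 12.0, 15.0),
    *, condition: str = "rest", k: int = 10, model: str = "svm", seed: int = 0,
) -> dict[float, float | None]:
    """Balanced accuracy vs analysis segment length on truncations of the same series.

    Feature columns that become invalid at a given length (e.g. the GARCH stage
    below its minimum sample count) are dropped for that length; a length with
    no usable features yields None.
    """
    def feature_fn(length: float):
        matrix, labels, groups, _ = extract_cohort_features(
            manifest, condition=condition, duration=length, seed=seed,
        )
        filtered = ft.filter_invalid_features(matrix)
        if not filtered.feature_names:
            raise ValueError(f"no valid features at {length} s")
        return filtered, labels, groups

    return classify.length_ablation(lengths, feature_fn, k=k, model=model, seed=seed)


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("tremorlab")
    except Exception:  # noqa: BLE001
        return "unknown"
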