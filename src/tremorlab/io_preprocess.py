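"""Reading, reduction and standardization of raw tremor accelerometer recordings.

Raw recordings arrive as triaxial (x, y, z) or monoaxial acceleration traces at
center-specific sampling rates. Triaxial data are reduced to the vector
amplitude sum ``sqrt(x^2 + y^2 + z^2)``; every series is then brought to the
canonical analysis form: 100 Hz, 15 s, band-passed 2-30 Hz and (optionally)
z-normalized. Recording-selection rules implemented here: exclusion of
load-sensitive (enhanced physiological) tremor, and selection of the more
affected hand via the relative spectral-power side difference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "Diagnosis",
    "Condition",
    "Hand",
    "RawRecording",
    "PreprocessedSeries",
    "CohortManifest",
    "read_recordings",
    "vector_amplitude",
    "resample",
    "standardize",
    "relative_auc_side_difference",
    "select_more_affected_hand",
    "loading_test_filter",
    "screen_artifacts",
]

TARGET_RATE = 100.0          # Hz, canonical analysis rate
TARGET_DURATION = 15.0       # s, canonical segment length
BAND = (2.0, 30.0)           # Hz, tremor analysis band
TRANSIENT_SKIP = 1.0         # s discarded before segment extraction


class Diagnosis(str, Enum):
    ET = "ET"
    PD = "PD"
    UNKNOWN = "unknown"


class Condition(str, Enum):
    REST = "rest"
    POSTURE = "posture"


class Hand(str, Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass
class RawRecording:
    """One accelerometer capture (1 or 3 axes) with its clinical metadata."""

    patient_id: str
    center: str
    diagnosis: Diagnosis
    condition: Condition
    hand: Hand
    sampling_rate: float
    axes: list[np.ndarray]
    loading_peak_shift: float | None = None

    def __post_init__(self) -> None:
        self.diagnosis = Diagnosis(self.diagnosis)
        self.condition = Condition(self.condition)
        self.hand = Hand(self.hand)
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise ValueError(
                f"recording {self.key}: sampling_rate must be finite and > 0"
            )
        if len(self.axes) not in (1, 3):
            raise ValueError(f"recording {self.key}: axes count must be 1 or 3")
        self.axes = [np.asarray(a, dtype=float) for a in self.axes]
        lengths = {a.shape[0] for a in self.axes}
        if len(lengths) != 1 or min(lengths) < 1:
            raise ValueError(
                f"recording {self.key}: axis sequences must be equal length >= 1"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        cond = self.condition.value if isinstance(self.condition, Condition) else self.condition
        hand = self.hand.value if isinstance(self.hand, Hand) else self.hand
        return (self.patient_id, cond, hand)

    @property
    def n_samples(self) -> int:
        return self.axes[0].shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def scalar_series(self) -> np.ndarray:
        """Vector amplitude sum for triaxial data; the raw axis for monoaxial."""
        if len(self.axes) == 3:
            return vector_amplitude(*self.axes)
        return self.axes[0].copy()


@dataclass
class PreprocessedSeries:
    """Canonical analysis series: 100 Hz, 15 s, 2-30 Hz band-passed scalar."""

    samples: np.ndarray
    sampling_rate: float
    provenance: dict = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.normalized:
            if abs(self.samples.mean()) >= 1e-8:
                raise ValueError("normalized series must have |mean| < 1e-8")
            if abs(self.samples.std(ddof=1) - 1.0) >= 1e-6:
                raise ValueError("normalized series must have |sd - 1| < 1e-6")

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.sampling_rate


@dataclass
class CohortManifest:
    """The loaded cohort: recordings indexed by (patient, condition, hand)."""

    recordings: list[RawRecording]

    def __post_init__(self) -> None:
        keys = [r.key for r in self.recordings]
        if len(keys) != len(set(keys)):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise ValueError(f"duplicate (patient, condition, hand) keys: {sorted(dupes)}")

    @property
    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.recordings:
            seen.setdefault(r.patient_id, None)
        return list(seen)

    def for_patient(self, patient_id: str) -> list[RawRecording]:
        return [r for r in self.recordings if r.patient_id == patient_id]

    def get(self, patient_id: str, condition: Condition | str, hand: Hand | str) -> RawRecording:
        key = (patient_id, Condition(condition).value, Hand(hand).value)
        for r in self.recordings:
            if r.key == key:
                return r
        raise KeyError(f"no recording {key}")


def vector_amplitude(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of the three accelerometer axes."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError("vector_amplitude: axis lengths differ")
    return np.sqrt(x * x + y * y + z * z)


def read_recordings(path: str | Path) -> CohortManifest:
    """Load a cohort from a JSON manifest (or a directory containing ``manifest.json``).

    The manifest is a list of entries ``{file, patient_id, center, diagnosis,
    condition, hand, sampling_rate, loading_peak_shift}``; each ``file`` is a CSV
    with header ``t,x,y,z`` (triaxial) or ``t,a`` (monoaxial), time in seconds.
    """
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    entries = json.loads(path.read_text())
    base = path.parent
    recordings = []
    for i, entry in enumerate(entries):
        label = f"manifest entry {i} ({entry.get('file', '?')})"
        csv_path = base / entry["file"]
        if not csv_path.exists():
            raise FileNotFoundError(f"{label}: series file missing: {csv_path}")
        try:
            table = pd.read_csv(csv_path)
        except Exception as exc:  # noqa: BLE001 - surface file identity
            raise ValueError(f"{label}: unreadable CSV ({exc})") from exc
        cols = [c for c in ("x", "y", "z") if c in table.columns]
        if len(cols) == 3:
            axes = [table[c].to_numpy(dtype=float) for c in cols]
        elif "a" in table.columns:
            axes = [table["a"].to_numpy(dtype=float)]
        else:
            raise ValueError(f"{label}: expected columns t,x,y,z or t,a; got {list(table.columns)}")
        for arr in axes:
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{label}: non-numeric or non-finite samples")
        try:
            rec = RawRecording(
                patient_id=str(entry["patient_id"]),
                center=str(entry.get("center", "unknown")),
                diagnosis=Diagnosis(entry.get("diagnosis", "unknown")),
                condition=Condition(entry["condition"]),
                hand=Hand(entry["hand"]),
                sampling_rate=float(entry["sampling_rate"]),
                axes=axes,
                loading_peak_shift=(
                    None if entry.get("loading_peak_shift") is None
                    else float(entry["loading_peak_shift"])
                ),
            )
        except ValueError as exc:
            raise ValueError(f"{label}: {exc}") from exc
        recordings.append(rec)
    return CohortManifest(recordings)


def resample(series: np.ndarray, f_in: float, f_out: float) -> np.ndarray:
    """Anti-aliased decimation from ``f_in`` to ``f_out`` Hz.

    Polyphase resampling (scipy ``resample_poly``) applies the anti-alias
    low-pass before rate reduction. Upsampling is rejected: analysis never
    fabricates bandwidth.
    """
    series = np.asarray(series, dtype=float)
    if f_out > f_in:
        raise ValueError(f"upsampling requested ({f_in} Hz -> {f_out} Hz)")
    if f_in == f_out:
        return series.copy()
    from fractions import Fraction

    frac = Fraction(f_out / f_in).limit_denominator(10_000)
    return signal.resample_poly(series, frac.numerator, frac.denominator)


def _bandpass(series: np.ndarray, rate: float, band: tuple[float, float] = BAND) -> np.ndarray:
    # 4th-order Butterworth, forward-backward: zero phase so HMM state
    # structure in the waveform is not distorted.
    sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, series)


def standardize(
    series: np.ndarray,
    sampling_rate: float,
    *,
    duration: float = TARGET_DURATION,
    target_rate: float = TARGET_RATE,
    band: tuple[float, float] = BAND,
    normalize: bool = True,
    allow_short: bool = False,
) -> PreprocessedSeries:
    """Bring a scalar series to the canonical analysis form.

    Order of operations: resample to ``target_rate``, extract the analysis
    segment (first ``duration`` seconds after discarding 1 s of filter
    transient), band-pass 2-30 Hz (zero-phase Butterworth), then z-normalize.

    ``allow_short`` admits series shorter than ``duration`` (the length-ablation
    study truncates deliberately); otherwise a short series is an error.
    """
    series = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(series)):
        raise ValueError("standardize: non-finite samples")
    resampled = resample(series, sampling_rate, target_rate)
    n_target = int(round(duration * target_rate))
    skip = int(round(TRANSIENT_SKIP * target_rate))
    if resampled.shape[0] >= n_target + skip:
        offset = skip
    elif resampled.shape[0] >= n_target:
        offset = 0
    elif allow_short:
        offset = 0
        n_target = resampled.shape[0]
    else:
        raise ValueError(
            f"series too short: {resampled.shape[0] / target_rate:.2f} s < {duration} s "
            "(pass allow_short=True for ablation runs)"
        )
    segment = resampled[offset:offset + n_target]
    filtered = _bandpass(segment, target_rate, band)
    provenance = {
        "input_rate": sampling_rate,
        "target_rate": target_rate,
        "segment_offset_samples": offset,
        "segment_length": n_target,
        "band": list(band),
        "normalized": normalize,
    }
    if normalize:
        sd = filtered.std(ddof=1)
        if sd == 0:
            raise ValueError("standardize: zero-variance segment cannot be normalized")
        out = (filtered - filtered.mean()) / sd
        # one exact re-centering pass pins |mean| below the invariant bound
        out = (out - out.mean()) / out.std(ddof=1)
    else:
        out = filtered
    return PreprocessedSeries(out, target_rate, provenance, normalized=normalize)


def relative_auc_side_difference(auc_right: float, auc_left: float) -> float:
    """Relative side difference of spectral power: (R - L) / (R + L), in [-1, 1]."""
    if auc_right < 0 or auc_left < 0:
        raise ValueError("AUC values must be non-negative")
    total = auc_right + auc_left
    if total == 0:
        raise ValueError("relative AUC side difference undefined for two zero-power sides")
    return (auc_right - auc_left) / total


def _band_auc_raw(series: np.ndarray, rate: float, band: tuple[float, float] = BAND) -> float:
    # Spectral power proxy on the non-normalized amplitude-sum series;
    # normalization would erase the asymmetry this measures.
    from .spectral import welch_psd, band_power_auc

    ps = welch_psd(series, rate)
    return band_power_auc(ps, band)


def select_more_affected_hand(
    patient_recordings: Sequence[RawRecording],
    band: tuple[float, float] = BAND,
) -> tuple[Hand, Condition]:
    """Pick the clinically more affected hand from a patient's recordings.

    For each condition with bilateral coverage, compute the relative spectral
    power (AUC) side difference on the non-normalized amplitude-sum series; the
    condition with the largest absolute difference decides, and the hand on the
    stronger side is returned. Exact ties across conditions prefer rest.
    Returns ``(hand, condition_that_drove_selection)``.
    """
    by_cond: dict[Condition, dict[Hand, RawRecording]] = {}
    for rec in patient_recordings:
        by_cond.setdefault(Condition(rec.condition), {})[Hand(rec.hand)] = rec

    candidates: list[tuple[float, int, Hand, Condition]] = []
    # rest preferred on ties: sort key includes condition priority
    priority = {Condition.REST: 0, Condition.POSTURE: 1}
    for cond, hands in by_cond.items():
        if Hand.RIGHT in hands and Hand.LEFT in hands:
            auc_r = _band_auc_raw(hands[Hand.RIGHT].scalar_series(),
                                  hands[Hand.RIGHT].sampling_rate, band)
            auc_l = _band_auc_raw(hands[Hand.LEFT].scalar_series(),
                                  hands[Hand.LEFT].sampling_rate, band)
            rel = relative_auc_side_difference(auc_r, auc_l)
            hand = Hand.RIGHT if rel >= 0 else Hand.LEFT
            candidates.append((abs(rel), priority[cond], hand, cond))
    if not candidates:
        # no bilateral condition: fall back to the single recorded hand
        hands_present = {Hand(r.hand) for r in patient_recordings}
        if len(hands_present) == 1:
            only = next(iter(hands_present))
            cond = Condition(patient_recordings[0].condition)
            warnings.warn(
                f"patient {patient_recordings[0].patient_id}: no bilateral condition; "
                f"falling back to single recorded hand {only.value}",
                stacklevel=2,
            )
            return only, cond
        raise ValueError("no bilateral condition and recordings from both hands present")
    candidates.sort(key=lambda c: (-c[0], c[1]))
    _, _, hand, cond = candidates[0]
    return hand, cond


def loading_test_filter(recording: RawRecording, threshold: float = 1.0) -> bool:
    """Keep/drop decision for load-sensitive (enhanced physiological) tremor.

    Returns True (keep) unless the peak-frequency shift under 500 g/1000 g
    loading strictly exceeds ``threshold`` Hz. Recordings without a measured
    shift pass through with a warning.
    """
    shift = recording.loading_peak_shift
    if shift is None:
        warnings.warn(
            f"recording {recording.key}: no loading test available; keeping", stacklevel=2
        )
        return True
    return not (shift > threshold)


def screen_artifacts(
    series: np.ndarray,
    *,
    flat_run: int = 5,
    z_limit: float = 8.0,
) -> list[str]:
    """Automated clip/flat-line screen replacing manual visual inspection.

    Flags a recording when ``flat_run`` or more consecutive samples are
    identical (sensor clipping / flat line) or any sample exceeds ``z_limit``
    standard deviations after normalization. Returns the list of flags
    (empty list = clean).
    """
    series = np.asarray(series, dtype=float)
    flags: list[str] = []
    if series.size >= flat_run:
        same = np.diff(series) == 0
        run = 0
        for s in same:
            run = run + 1 if s else 0
            if run >= flat_run - 1:
                flags.append("flat-line")
                break
    sd = series.std(ddof=1) if series.size > 1 else 0.0
    if sd > 0:
        z = np.abs(series - series.mean()) / sd
        if np.any(z > z_limit):
            flags.append("clipping/outlier")
    return flags
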