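"""Synthetic tremor-cohort generator with ground truth.

Two mechanistic signal archetypes are emulated:

* **ET-like** — one stable oscillatory regime: a single hidden state, narrow
  cycle-to-cycle frequency jitter, a near-symmetric waveform (small second
  harmonic at zero phase), mild amplitude modulation, postural amplitude larger
  than rest amplitude, and mild left/right asymmetry.

* **PD-like** — two or three discrete Markov-switching regimes that differ in
  amplitude (waxing-waning) and frequency, a skewed waveform (strong second
  harmonic at quadrature phase gives an asymmetric acceleration distribution),
  broader frequency jitter, rest amplitude larger than postural amplitude, and
  marked hand asymmetry.

Recordings are emitted in the raw-accelerometer dialect the preprocessing
module reads (CSV series + JSON manifest), with per-center sampling-rate and
axis-count profiles and per-recording ground truth. All randomness derives
deterministically from a master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io_preprocess import (
    CohortManifest, Condition, Diagnosis, Hand, RawRecording,
)

__all__ = [
    "OscillatorParams",
    "StateSwitchingParams",
    "SyntheticCohortConfig",
    "simulate_series",
    "project_triaxial",
    "simulate_et_patient",
    "simulate_pd_patient",
    "generate_cohort",
    "simulate_cohort",
    "et_oscillator",
    "pd_oscillator",
    "et_switching",
    "pd_switching",
]


@dataclass
class OscillatorParams:
    """One tremor oscillator: fundamental + second harmonic with per-cycle jitter."""

    base_frequency: float = 5.0          # Hz, patient-level tremor frequency
    frequency_jitter_sd: float = 0.05    # Hz, per-cycle frequency wander
    amplitude_jitter_sd: float = 0.05    # relative per-cycle amplitude fluctuation
    phase_diffusion_sd: float = 0.0      # rad/sqrt(s), per-sample phase random walk
    amplitude: float = 1.0               # arbitrary acceleration units
    harmonic_ratio: float = 0.1          # 2nd harmonic relative amplitude
    harmonic_phase: float = 0.0          # rad; pi/2 skews the waveform
    am_depth: float = 0.1                # slow amplitude-modulation depth
    am_rate: float = 0.3                 # Hz
    # direction-specific acceleration bursts (one-sided pulses, the mechanism
    # behind an asymmetric/skewed acceleration distribution)
    burst_prob: float = 0.0              # probability of a burst per tremor cycle
    burst_amp: float = 0.0               # burst amplitude relative to state amplitude
    burst_width: float = 0.04            # s, half-sine pulse duration

    def __post_init__(self) -> None:
        if not (2.0 < self.base_frequency < 30.0):
            raise ValueError("base_frequency must lie in (2, 30) Hz")
        if self.frequency_jitter_sd < 0 or self.harmonic_ratio < 0:
            raise ValueError("jitter sd and harmonic ratio must be >= 0")


@dataclass
class StateSwitchingParams:
    """Hidden Markov regime structure modulating the oscillator."""

    n_states: int = 1
    amplitude_scales: tuple[float, ...] = (1.0,)
    frequency_offsets: tuple[float, ...] = (0.0,)
    mean_dwell: float = 3.0              # s per state sojourn
    transition_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if len(self.amplitude_scales) != self.n_states or len(self.frequency_offsets) != self.n_states:
            raise ValueError("per-state parameter lists must have n_states entries")
        if self.transition_matrix is not None:
            tm = np.asarray(self.transition_matrix, dtype=float)
            if tm.shape != (self.n_states, self.n_states):
                raise ValueError("transition matrix shape mismatch")
            if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-10):
                raise ValueError("transition matrix rows must sum to 1")
            self.transition_matrix = tm


def _state_path(
    switching: StateSwitchingParams, n: int, dt: float, rng: np.random.Generator,
    min_dwell: float,
) -> np.ndarray:
    """Sample a hidden state path with exponential sojourn times."""
    if switching.n_states == 1:
        return np.zeros(n, dtype=int)
    if switching.mean_dwell < min_dwell:
        raise ValueError(
            f"mean dwell {switching.mean_dwell} s shorter than one tremor cycle ({min_dwell:.3f} s)"
        )
    k = switching.n_states
    if switching.transition_matrix is None:
        jump = np.full((k, k), 1.0 / (k - 1))
        np.fill_diagonal(jump, 0.0)
    else:
        jump = switching.transition_matrix.copy()
        np.fill_diagonal(jump, 0.0)
        rows = jump.sum(axis=1)
        rows[rows == 0] = 1.0
        jump = jump / rows[:, None]
    path = np.empty(n, dtype=int)
    state = int(rng.integers(k))
    t = 0
    while t < n:
        dwell = max(rng.exponential(switching.mean_dwell), min_dwell)
        span = max(int(round(dwell / dt)), 1)
        path[t:t + span] = state
        t += span
        state = int(rng.choice(k, p=jump[state]))
    return path


def simulate_series(
    osc: OscillatorParams,
    switching: StateSwitchingParams,
    duration: float,
    rate: float,
    seed: int,
    noise_sd: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """One scalar tremor series plus its hidden state path.

    The oscillator is phase-continuous: per-sample frequency (state offset +
    per-cycle jitter) is integrated to a phase, the waveform is fundamental
    plus second harmonic, state-dependent amplitude scaling and slow amplitude
    modulation are applied, and Gaussian sensor noise is added. Deterministic
    per seed.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    dt = 1.0 / rate
    min_dwell = 1.0 / osc.base_frequency
    path = _state_path(switching, n, dt, rng, min_dwell)

    # per-cycle jitter as piecewise-constant blocks of one nominal cycle
    cycle_samples = max(int(round(rate / osc.base_frequency)), 1)
    n_cycles = n // cycle_samples + 2
    jitter = rng.normal(0.0, osc.frequency_jitter_sd, size=n_cycles)
    jitter_per_sample = np.repeat(jitter, cycle_samples)[:n]

    freq = osc.base_frequency + np.asarray(switching.frequency_offsets)[path] + jitter_per_sample
    freq = np.clip(freq, 0.5, rate / 2.5)
    phase = 2.0 * np.pi * np.cumsum(freq) * dt
    if osc.phase_diffusion_sd > 0:
        phase = phase + np.cumsum(rng.normal(0.0, osc.phase_diffusion_sd * np.sqrt(dt), n))
    wave = np.sin(phase) + osc.harmonic_ratio * np.sin(2.0 * phase + osc.harmonic_phase)

    amp_jitter = 1.0 + rng.normal(0.0, osc.amplitude_jitter_sd, size=n_cycles)
    amp = (osc.amplitude * np.asarray(switching.amplitude_scales)[path]
           * np.clip(np.repeat(amp_jitter, cycle_samples)[:n], 0.1, None))
    t = np.arange(n) * dt
    am = 1.0 + osc.am_depth * np.sin(2.0 * np.pi * osc.am_rate * t + rng.uniform(0, 2 * np.pi))
    series = amp * am * wave
    if osc.burst_prob > 0 and osc.burst_amp > 0:
        width = max(int(round(osc.burst_width * rate)), 2)
        pulse = np.sin(np.pi * np.arange(width) / (width - 1))  # one-sided half-sine
        bursts = np.zeros(n)
        for c in range(n_cycles):
            if rng.random() < osc.burst_prob:
                start = c * cycle_samples + int(rng.integers(max(cycle_samples - width, 1)))
                if start + width <= n:
                    # Burst strength follows the patient-level tremor amplitude,
                    # not the momentary regime amplitude: direction-specific
                    # acceleration persists through low-amplitude regimes, which
                    # is what keeps the residual distribution asymmetric after
                    # conditional-variance standardization.
                    bursts[start:start + width] += (
                        osc.burst_amp * osc.amplitude * float(rng.uniform(0.6, 1.4)) * pulse
                    )
        series = series + bursts
    series = series + rng.normal(0.0, noise_sd, size=n)
    return series, path


def project_triaxial(
    series: np.ndarray, rng: np.random.Generator, noise_sd: float = 0.05
) -> list[np.ndarray]:
    """Project a scalar oscillation onto three axes via a fixed random unit vector.

    Each axis receives independent sensor noise; the vector amplitude sum then
    recovers approximately the rectified envelope of the scalar signal.
    """
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    return [series * u[i] + rng.normal(0.0, noise_sd, size=series.shape[0]) for i in range(3)]


# ---------------------------------------------------------------------------
# Phenotype defaults
# ---------------------------------------------------------------------------

def et_oscillator(base_frequency: float, amplitude: float = 1.0) -> OscillatorParams:
    """ET archetype: symmetric waveform, narrow jitter, mild modulation."""
    return OscillatorParams(
        base_frequency=base_frequency, frequency_jitter_sd=0.05,
        amplitude_jitter_sd=0.05, amplitude=amplitude,
        harmonic_ratio=0.1, harmonic_phase=0.0,
        am_depth=0.35, am_rate=0.25,
    )


def pd_oscillator(base_frequency: float, amplitude: float = 1.0) -> OscillatorParams:
    """PD archetype: skewed waveform (quadrature 2nd harmonic), broad jitter."""
    return OscillatorParams(
        base_frequency=base_frequency, frequency_jitter_sd=0.30,
        amplitude_jitter_sd=0.15, amplitude=amplitude,
        harmonic_ratio=0.45, harmonic_phase=np.pi / 2,
        am_depth=0.15, am_rate=0.15,
        burst_prob=0.55, burst_amp=0.9,
    )


def et_switching() -> StateSwitchingParams:
    return StateSwitchingParams(n_states=1)


def pd_switching(n_states: int = 2, mean_dwell: float = 2.0) -> StateSwitchingParams:
    """PD regime structure: discrete amplitude/frequency states, waxing-waning."""
    scales = (1.0, 0.15, 0.50)[:n_states]
    offsets = (0.0, 0.5, -0.4)[:n_states]
    return StateSwitchingParams(
        n_states=n_states, amplitude_scales=scales,
        frequency_offsets=offsets, mean_dwell=mean_dwell,
    )


@dataclass
class CenterProfile:
    name: str
    sampling_rate: float
    n_axes: int


DEFAULT_CENTERS = (
    CenterProfile("graz", 500.0, 3),
    CenterProfile("budapest", 200.0, 3),
    CenterProfile("london", 1000.0, 3),
)
MONOAXIAL_CENTER = CenterProfile("kiel", 160.0, 1)


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort."""

    n_et: int = 60
    n_pd: int = 60
    duration: float = 20.0               # s (>= 16 s leaves room for the 1 s transient)
    noise_sd: float = 0.10               # scalar-signal sensor noise, unit-amplitude scale
    axis_noise_sd: float = 0.05          # per-axis noise after triaxial projection
    centers: tuple[CenterProfile, ...] = DEFAULT_CENTERS
    conditions: tuple[str, ...] = ("rest", "posture")
    affected_side_ratio_et: float = 1.3  # affected/unaffected amplitude
    affected_side_ratio_pd: float = 3.0
    # phenotype-conditioned position amplitudes (affected hand):
    et_rest_amp: float = 0.35
    et_posture_amp: float = 1.0
    pd_rest_amp: float = 1.0
    pd_posture_amp: float = 0.5
    # postural recordings carry extra broadband drive from holding against gravity
    posture_noise_factor: float = 2.0
    posture_physio_amp: float = 0.8      # ~9 Hz enhanced-physiological component
                                         # in posture; the diagnosis-independent
                                         # position marker
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_et < 0 or self.n_pd < 0:
            raise ValueError("cohort sizes must be >= 0")
        if self.duration < 15.0:
            raise ValueError("duration must be >= 15 s for the default pipeline")


def _patient_seed(master_seed: int, patient_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([master_seed, patient_index])


def _simulate_patient(
    config: SyntheticCohortConfig,
    diagnosis: Diagnosis,
    patient_index: int,
    seed_seq: np.random.SeedSequence | None = None,
) -> tuple[list[RawRecording], dict]:
    """All four recordings (2 hands x 2 conditions) for one synthetic patient."""
    ss = seed_seq if seed_seq is not None else _patient_seed(config.seed, patient_index)
    rng = np.random.default_rng(ss)
    center = config.centers[patient_index % len(config.centers)]
    base_freq = rng.uniform(4.0, 7.0) if diagnosis == Diagnosis.PD else rng.uniform(5.0, 8.0)
    amp_scale = float(np.exp(rng.normal(0.0, 0.25)))  # patient-level amplitude variation
    affected = Hand.RIGHT if rng.random() < 0.5 else Hand.LEFT
    if diagnosis == Diagnosis.ET:
        side_ratio = config.affected_side_ratio_et
        cond_amp = {Condition.REST: config.et_rest_amp, Condition.POSTURE: config.et_posture_amp}
        make_osc, switching = et_oscillator, et_switching()
    else:
        side_ratio = config.affected_side_ratio_pd
        cond_amp = {Condition.REST: config.pd_rest_amp, Condition.POSTURE: config.pd_posture_amp}
        make_osc = pd_oscillator
        switching = pd_switching(n_states=2 if rng.random() < 0.7 else 3)
    loading_shift = float(rng.uniform(0.0, 0.3))

    recordings: list[RawRecording] = []
    truth_recs = {}
    for condition in (Condition(c) for c in config.conditions):
        for hand in (Hand.RIGHT, Hand.LEFT):
            rec_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, patient_index,
                                        int(condition == Condition.POSTURE),
                                        int(hand == Hand.LEFT)])
            )
            amp = amp_scale * cond_amp[condition]
            if hand != affected:
                amp /= side_ratio
            osc = make_osc(base_freq, amplitude=amp)
            noise = config.noise_sd
            if condition == Condition.POSTURE:
                noise *= config.posture_noise_factor
            series, path = simulate_series(
                osc, switching, config.duration, center.sampling_rate,
                seed=int(rec_rng.integers(2**31)), noise_sd=noise,
            )
            if condition == Condition.POSTURE and config.posture_physio_amp > 0:
                t = np.arange(series.shape[0]) / center.sampling_rate
                f_physio = float(rec_rng.uniform(8.5, 10.5))
                series = series + config.posture_physio_amp * amp_scale * np.sin(
                    2 * np.pi * f_physio * t + rec_rng.uniform(0, 2 * np.pi)
                )
            if center.n_axes == 3:
                axes = project_triaxial(series, rec_rng, config.axis_noise_sd)
            else:
                u = rec_rng.normal(size=3)
                u /= np.linalg.norm(u)
                axes = [series * abs(u[2])
                        + rec_rng.normal(0.0, config.axis_noise_sd, size=series.shape[0])]
            pid = f"{diagnosis.value}{patient_index:03d}"
            recordings.append(RawRecording(
                patient_id=pid, center=center.name, diagnosis=diagnosis,
                condition=condition, hand=hand,
                sampling_rate=center.sampling_rate, axes=axes,
                loading_peak_shift=loading_shift,
            ))
            truth_recs[f"{condition.value}/{hand.value}"] = {
                "amplitude": amp,
                "n_states": switching.n_states,
                "n_states_visited": int(np.unique(path).shape[0]),
                "base_frequency": base_freq,
            }
    truth = {
        "diagnosis": diagnosis.value,
        "affected_side": affected.value,
        "base_frequency": base_freq,
        "n_states": switching.n_states,
        "recordings": truth_recs,
    }
    return recordings, truth


def simulate_et_patient(
    config: SyntheticCohortConfig, seed: int | np.random.SeedSequence
) -> tuple[list[RawRecording], dict]:
    """Recordings + ground truth for one ET-archetype patient."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return _simulate_patient(config, Diagnosis.ET, 0, seed_seq=ss)


def simulate_pd_patient(
    config: SyntheticCohortConfig, seed: int | np.random.SeedSequence
) -> tuple[list[RawRecording], dict]:
    """Recordings + ground truth for one PD-archetype patient."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return _simulate_patient(config, Diagnosis.PD, 0, seed_seq=ss)


def generate_cohort(config: SyntheticCohortConfig) -> tuple[CohortManifest, dict]:
    """In-memory cohort: manifest of recordings plus ground truth by patient id."""
    recordings: list[RawRecording] = []
    truth: dict[str, dict] = {}
    idx = 0
    for _ in range(config.n_et):
        recs, gt = _simulate_patient(config, Diagnosis.ET, idx)
        recordings.extend(recs)
        truth[recs[0].patient_id] = gt
        idx += 1
    for _ in range(config.n_pd):
        recs, gt = _simulate_patient(config, Diagnosis.PD, idx)
        recordings.extend(recs)
        truth[recs[0].patient_id] = gt
        idx += 1
    return CohortManifest(recordings), truth


def simulate_cohort(config: SyntheticCohortConfig, out_dir: str | Path) -> Path:
    """Write a cohort to disk in the raw-recording dialect; returns the manifest path.

    Emits one CSV per recording (``t,x,y,z`` or ``t,a``), ``manifest.json`` and
    ``ground_truth.json``. Byte-identical across runs with the same config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest, truth = generate_cohort(config)
    entries = []
    for rec in manifest.recordings:
        fname = f"{rec.patient_id}_{rec.condition.value}_{rec.hand.value}.csv"
        t = np.arange(rec.n_samples) / rec.sampling_rate
        cols = ["t", "x", "y", "z"] if len(rec.axes) == 3 else ["t", "a"]
        data = np.column_stack([t] + rec.axes)
        header = ",".join(cols)
        lines = [header] + [",".join(f"{v:.8g}" for v in row) for row in data]
        (out / fname).write_text("\n".join(lines) + "\n")
        entries.append({
            "file": fname,
            "patient_id": rec.patient_id,
            "center": rec.center,
            "diagnosis": rec.diagnosis.value,
            "condition": rec.condition.value,
            "hand": rec.hand.value,
            "sampling_rate": rec.sampling_rate,
            "loading_peak_shift": rec.loading_peak_shift,
        })
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(entries, indent=1, sort_keys=True))
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return manifest_path
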