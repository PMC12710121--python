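"""Unit tests for the synthetic tremor generator."""

import json

import numpy as np
import pytest

from tremorlab import io_preprocess as iop
from tremorlab import spectral as sp
from tremorlab import synth


class TestOscillatorParams:
    def test_base_frequency_bounds_enforced(self):
        with pytest.raises(ValueError):
            synth.OscillatorParams(base_frequency=1.0)
        with pytest.raises(ValueError):
            synth.OscillatorParams(base_frequency=35.0)


class TestStateSwitching:
    def test_transition_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            synth.StateSwitchingParams(
                n_states=2, amplitude_scales=(1.0, 0.5),
                frequency_offsets=(0.0, 0.0), mean_dwell=2.0,
                transition_matrix=((0.5, 0.2), (0.5, 0.5)))

    def test_dwell_below_one_cycle_rejected(self):
        params = synth.StateSwitchingParams(
            n_states=2, amplitude_scales=(1.0, 0.5),
            frequency_offsets=(0.0, 0.0), mean_dwell=0.05)
        with pytest.raises(ValueError):
            synth.simulate_series(synth.et_oscillator(6.0), params, 10.0, 100.0,
                                  seed=0)

    def test_sojourns_respect_minimum_dwell(self):
        params = synth.pd_switching(2)
        _, path = synth.simulate_series(synth.pd_oscillator(5.0), params,
                                        30.0, 100.0, seed=1)
        changes = np.flatnonzero(np.diff(path))
        if changes.size > 1:
            min_sojourn = np.diff(changes).min() / 100.0
            assert min_sojourn >= 1.0 / 5.0 - 1e-9


class TestSimulateSeries:
    def test_deterministic_given_seed(self):
        osc = synth.pd_oscillator(5.0)
        sw = synth.pd_switching(2)
        a, pa = synth.simulate_series(osc, sw, 15.0, 200.0, seed=3)
        b, pb = synth.simulate_series(osc, sw, 15.0, 200.0, seed=3)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(pa, pb)

    def test_spectral_peak_near_base_frequency(self):
        series, _ = synth.simulate_series(synth.et_oscillator(6.0),
                                          synth.et_switching(), 20.0, 100.0,
                                          seed=4, noise_sd=0.05)
        pre = iop.standardize(series, 100.0)
        spec = sp.welch_psd(pre.samples, 100.0)
        pf, _ = sp.peak_frequency_power(spec)
        assert pf == pytest.approx(6.0, abs=0.5)

    def test_pd_waveform_more_skewed_than_et(self):
        from scipy import stats
        et, _ = synth.simulate_series(synth.et_oscillator(6.0),
                                      synth.et_switching(), 20.0, 100.0, seed=5)
        pd_, _ = synth.simulate_series(synth.pd_oscillator(5.0),
                                       synth.et_switching(), 20.0, 100.0, seed=5)
        assert abs(stats.skew(pd_)) > abs(stats.skew(et))

    def test_bursts_are_one_sided(self):
        osc = synth.pd_oscillator(5.0)
        quiet = synth.OscillatorParams(
            base_frequency=5.0, amplitude=1.0, harmonic_ratio=0.0,
            frequency_jitter_sd=0.0, amplitude_jitter_sd=0.0,
            am_depth=0.0, burst_prob=1.0, burst_amp=2.0)
        with_bursts, _ = synth.simulate_series(quiet, synth.et_switching(),
                                               20.0, 100.0, seed=6, noise_sd=0.0)
        no_bursts_params = synth.OscillatorParams(
            base_frequency=5.0, amplitude=1.0, harmonic_ratio=0.0,
            frequency_jitter_sd=0.0, amplitude_jitter_sd=0.0, am_depth=0.0)
        without, _ = synth.simulate_series(no_bursts_params, synth.et_switching(),
                                           20.0, 100.0, seed=6, noise_sd=0.0)
        diff = with_bursts - without
        assert diff.max() > 1.0
        assert diff.min() > -1e-9  # strictly additive in one direction


class TestTriaxialProjection:
    def test_vector_amplitude_recovers_envelope(self):
        rng = np.random.default_rng(7)
        series, _ = synth.simulate_series(synth.et_oscillator(6.0),
                                          synth.et_switching(), 10.0, 100.0,
                                          seed=8, noise_sd=0.0)
        axes = synth.project_triaxial(series, rng, noise_sd=0.0)
        amp = iop.vector_amplitude(*axes)
        np.testing.assert_allclose(amp, np.abs(series), rtol=1e-9)


class TestCohortGeneration:
    def test_cohort_composition_and_ground_truth(self):
        cfg = synth.SyntheticCohortConfig(n_et=3, n_pd=2, duration=16.0, seed=5)
        manifest, truth = synth.generate_cohort(cfg)
        assert len(manifest.patient_ids) == 5
        diagnoses = [manifest.for_patient(p)[0].diagnosis.value
                     for p in manifest.patient_ids]
        assert diagnoses.count("ET") == 3 and diagnoses.count("PD") == 2
        for pid in manifest.patient_ids:
            assert truth[pid]["diagnosis"] in ("ET", "PD")
            # two hands x two conditions
            assert len(manifest.for_patient(pid)) == 4

    def test_rest_posture_amplitude_phenotype(self):
        # Total posture variance includes the diagnosis-independent
        # enhanced-physiological component, so the phenotype signature is the
        # rest/posture *ratio*: PD tremor is rest-dominant relative to ET.
        cfg = synth.SyntheticCohortConfig(n_et=4, n_pd=4, duration=16.0, seed=9)
        manifest, truth = synth.generate_cohort(cfg)
        ratios = {"ET": [], "PD": []}
        for pid in manifest.patient_ids:
            dx = truth[pid]["diagnosis"]
            hand = truth[pid]["affected_side"]
            rest = manifest.get(pid, "rest", hand).scalar_series()
            posture = manifest.get(pid, "posture", hand).scalar_series()
            ratios[dx].append(np.std(rest) / np.std(posture))
        assert min(ratios["PD"]) > max(ratios["ET"])
        # ET postural tremor dominates its own rest recording outright.
        assert max(ratios["ET"]) < 1.0

    def test_determinism_across_calls(self):
        cfg = synth.SyntheticCohortConfig(n_et=2, n_pd=2, duration=16.0, seed=3)
        m1, _ = synth.generate_cohort(cfg)
        m2, _ = synth.generate_cohort(cfg)
        for r1, r2 in zip(m1.recordings, m2.recordings):
            assert r1.key == r2.key
            np.testing.assert_array_equal(r1.scalar_series(), r2.scalar_series())

    def test_simulate_cohort_writes_readable_files(self, tmp_path):
        cfg = synth.SyntheticCohortConfig(n_et=1, n_pd=1, duration=16.0, seed=2)
        manifest_path = synth.simulate_cohort(cfg, tmp_path)
        assert manifest_path.exists()
        truth = json.loads((tmp_path / "ground_truth.json").read_text())
        assert len(truth) == 2
        cohort = iop.read_recordings(manifest_path)
        assert len(cohort.patient_ids) == 2
        in_memory, _ = synth.generate_cohort(cfg)
        rec_disk = cohort.recordings[0]
        rec_mem = in_memory.get(*rec_disk.key)
        np.testing.assert_allclose(rec_disk.scalar_series(),
                                   rec_mem.scalar_series(), atol=1e-6)
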