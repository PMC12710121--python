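"""From raw accelerometry to the six standard tremor characteristics.

This example simulates one essential-tremor (ET) and one Parkinson's-disease
(PD) patient, walks their recordings through the canonical preprocessing
(vector amplitude sum -> 100 Hz -> 15 s -> 2-30 Hz band-pass -> z-normalize),
selects the clinically more affected hand, and prints the six standard tremor
characteristics for the rest recording of that hand.
"""

import numpy as np

from tremorlab import io_preprocess as iop
from tremorlab import spectral as sp
from tremorlab import synth

config = synth.SyntheticCohortConfig(duration=20.0, seed=7)

patients = {
    "ET": synth.simulate_et_patient(config, seed=101),
    "PD": synth.simulate_pd_patient(config, seed=202),
}

print("Per-patient standard tremor characteristics (rest, more affected hand)")
print("=" * 72)
for diagnosis, (recordings, truth) in patients.items():
    # hand selection uses the relative spectral-power side difference
    hand, deciding_condition = iop.select_more_affected_hand(recordings)
    rec = next(r for r in recordings
               if r.hand == hand and r.condition == iop.Condition.REST)

    # triaxial recording -> scalar vector amplitude -> canonical form
    scalar = rec.scalar_series()
    pre = iop.standardize(scalar, rec.sampling_rate)

    summary = sp.spectral_summary(pre.samples, pre.sampling_rate)
    print(f"\n{diagnosis} patient  (true side: {truth['affected_side']}, "
          f"selected: {hand.value}, via {deciding_condition.value})")
    print(f"  base tremor frequency (ground truth): "
          f"{truth['base_frequency']:.2f} Hz")
    for name, value in summary.as_dict().items():
        print(f"  {name:>15}: {value:9.4f}")

print("\nTwo things to notice. First, the spectral peak sits at twice the")
print("oscillator frequency: the vector amplitude sum of a zero-mean")
print("oscillation is a rectified waveform, and rectification doubles the")
print("fundamental. Second, the direction of the ET/PD contrast: the PD")
print("patient's cycle-to-cycle frequency dispersion (TSI) and spectral")
print("width (FWHM) exceed the ET patient's, while the ET spectrum")
print("concentrates power near its peak (higher half-width power).")
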