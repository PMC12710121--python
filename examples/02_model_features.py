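"""The two disease-defining model features on paired synthetic patients.

Both features operate on the z-normalized canonical series and are therefore
amplitude-invariant:

- ``garch_ks``: fit an AR model (AIC order selection), rescale the residuals,
  fit GARCH(1,1) by Gaussian quasi-maximum likelihood, and report the
  Kolmogorov-Smirnov statistic of the standardized residuals against a
  standard normal. PD tremor carries one-sided (direction-specific)
  acceleration events that no conditional-variance model can whiten, so its
  residuals stay asymmetric and the KS statistic stays high.

- ``hmm_nstates_ll``: train Gaussian hidden Markov models with 2-4 states on
  the first 60% of the series (3 EM restarts each) and report the best
  per-sample train log-likelihood. PD tremor moves between distinct
  amplitude regimes that a few Gaussian states capture well; ET's smoothly
  modulated oscillation does not concentrate that way.

Ten paired seeds are enough to see the systematic PD > ET ordering of both
features (the acceptance run uses 100 pairs).
"""

import numpy as np

from tremorlab import features as ft
from tremorlab import io_preprocess as iop
from tremorlab import synth

config = synth.SyntheticCohortConfig(seed=5)
n_pairs = 10

print(f"{'pair':>4} | {'garch_ks ET':>11} {'garch_ks PD':>11} | "
      f"{'hmm_ll ET':>10} {'hmm_ll PD':>10}")
print("-" * 56)

garch_wins = hmm_wins = 0
for pair in range(n_pairs):
    row = {}
    for dx, simulate in (("ET", synth.simulate_et_patient),
                         ("PD", synth.simulate_pd_patient)):
        recordings, _ = simulate(config, np.random.SeedSequence([5, pair]))
        hand, _ = iop.select_more_affected_hand(recordings)
        rec = next(r for r in recordings
                   if r.hand == hand and r.condition == iop.Condition.REST)
        series = iop.standardize(rec.scalar_series(), rec.sampling_rate)
        row[dx] = (ft.garch_ks_feature(series.samples),
                   ft.hmm_compare_nstates_feature(series.samples, seed=pair))
    garch_wins += row["PD"][0] > row["ET"][0]
    hmm_wins += row["PD"][1] > row["ET"][1]
    print(f"{pair:>4} | {row['ET'][0]:>11.4f} {row['PD'][0]:>11.4f} | "
          f"{row['ET'][1]:>10.4f} {row['PD'][1]:>10.4f}")

print("-" * 56)
print(f"PD > ET: garch_ks {garch_wins}/{n_pairs} pairs, "
      f"hmm_nstates_ll {hmm_wins}/{n_pairs} pairs")
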