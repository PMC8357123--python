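"""Dwell-time survival analysis: Kaplan-Meier curve and dissociation rate.

Draws exponential binding dwell times at a known rate, censors the longest
ones as a finite trajectory would, and recovers the rate from the log-slope
of the survival curve.
"""

from hingeflex.analysis import fit_dissociation_rate, survival_curve
from hingeflex.synthetic import synth_dwell_times

TRUE_RATE = 1e-3          # per step
durations, observed = synth_dwell_times(TRUE_RATE, 1000, censor_at=5000.0,
                                        seed=11)
print(f"{len(durations)} dwell times, {int((~observed).sum())} censored "
      f"at 5000 steps")

curve = survival_curve((durations, observed))
for t in (500, 1000, 2000, 4000):
    print(f"  P(dwell >= {t:4d} steps) = {curve.at(t):.3f}")

fit = fit_dissociation_rate((durations, observed))
print(f"\nfitted dissociation rate: {fit.rate:.3e} per step "
      f"(bootstrap s.e. {fit.stderr:.1e}); truth {TRUE_RATE:.1e}")
print("The log-slope of the survival curve over P in [0.1, 1] estimates "
      "the rate; censored events stay in the risk set while observed.")
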