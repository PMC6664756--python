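"""Fit a single-motif occupancy model to synthetic ChIP signal.

Generates labeled 500-bp windows whose ChIP signal is analytic occupancy
under a known concentration (tau=2) and site-energy threshold (eT=3) plus
measurement noise, fits the model by correlation-maximizing grid search,
and reports the held-out Pearson correlation — the same quantity used to
benchmark binding predictors against real ChIP data.
"""

import numpy as np

from tfimpact.stap import fit_stap
from tfimpact.synthetic import gen_chip_windows, random_pwm

pwm = random_pwm(width=8, consensus_prob=0.85, seed=1, name="demo_motif")
train, truth = gen_chip_windows(pwm, n_pos=150, n_neg=150, noise_sd=0.05,
                                tau_true=2.0, eT_true=3.0, seed=2)
test, _ = gen_chip_windows(pwm, n_pos=50, n_neg=50, noise_sd=0.05,
                           tau_true=2.0, eT_true=3.0, seed=3)

model = fit_stap(train, pwm, seed=0)
pred = [model.occupancy(w.sequence) for w in test]
obs = [w.chip_signal for w in test]
cc = np.corrcoef(pred, obs)[0, 1]

print(f"motif consensus:      {pwm.consensus()}")
print(f"generating truth:     tau={truth['tau_true']}, eT={truth['eT_true']}")
print(f"fitted parameters:    tau={model.tau:.3g}, eT={model.eT:g}")
print(f"held-out Pearson CC:  {cc:.3f}")
print()
print("A held-out correlation near 1 means the fitted concentration and")
print("site threshold reproduce the planted occupancy signal; exact tau")
print("recovery is not required because occupancy curves at neighboring")
print("grid points are nearly affinely related.")
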