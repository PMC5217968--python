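"""Precision of the fraction estimate versus photon number (scaled down).

Subsamples a fixed-ratio mixture master curve at several photon counts,
fits each subsample, and fits a power law to the spread of the
estimates.  The central limit theorem predicts an exponent of -1/2;
this run uses 100 replicates over 8 photon counts to stay quick (the
full study uses 300 replicates over 10 counts).
"""

import numpy as np

import flim_bayes as fb

binning = fb.default_binning()
irf = fb.default_irf(binning)
master, theta = fb.low_photon_master(binning=binning, irf=irf)

counts = np.unique(np.round(np.logspace(np.log10(30), np.log10(3e4), 8)).astype(int))
res = fb.low_photon_study(
    master, counts, n_reps=100, tau_short=0.48, tau_long=4.03, period=12.5,
    irf=irf, seed=11, true_f_short=theta.f_short,
)

sd = res.condition_sd("mean")
print("photons   bias(mean)   sample s.d.")
for n, b, s in zip(counts, res.bias("mean"), sd):
    print(f"{n:7d}   {b:+.5f}     {s:.5f}")

law = fb.fit_power_law(counts, sd, exclude_lowest=3)
print(f"\npower law: s.d. = {law.amplitude:.3f} * n^({law.exponent:.3f} "
      f"+/- {law.exponent_ci95:.3f})")
print("An exponent near -0.5 means precision improves as the square root of the")
print("photon budget: 4x the photons halves the uncertainty.")
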