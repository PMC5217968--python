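"""Linearity of fraction recovery at rare short-lifetime fractions (scaled down).

Mixes photons from separate short-only and long-only master curves at
prescribed fractions 2^-1 .. 2^-8 of 5e6 total photons (the full study
uses 5e7), fits each mixture, and regresses the estimates on the
prescribed fractions.  Differences between adjacent fractions cancel
any additive bias.
"""

import numpy as np

import flim_bayes as fb

binning = fb.default_binning()
irf = fb.default_irf(binning)
short, long_ = fb.component_masters(binning=binning, irf=irf)

fractions = np.array([2.0**-k for k in range(1, 9)])
res = fb.low_fraction_study(
    short, long_, fractions, n_total=5_000_000, n_reps=5,
    tau_short=0.48, tau_long=4.03, period=12.5, irf=irf, seed=21,
)

print("prescribed   estimated (mean over reps)")
for f, est in zip(res.conditions, res.condition_mean("mean")):
    print(f"{f:9.5f}   {est:.5f}")

line = fb.fit_line(res.conditions, res.condition_mean("mean"))
delta = fb.delta_fraction_study(res)
print(f"\nestimated vs prescribed: slope = {line.slope:.4f} "
      f"+/- {line.slope_ci95:.4f}, offset = {line.offset:.2e}")
print(f"adjacent differences:    slope = {delta.fit_mean.slope:.4f}, "
      f"offset = {delta.fit_mean.offset:.2e}")
print("A slope near 1 (each master carries a 0.5% background, so ~0.995 is ideal)")
print("means rare FRET fractions are recovered proportionally; the difference fit")
print("shows that changes in fraction are measured essentially bias-free.")
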