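"""Pixel-wise amplitude-fraction maps with boxcar pooling, Bayes vs least squares.

Simulates a spatially uniform FLIM image at a low photon count per
pixel, pools photons over 3x3 and 7x7 pixel windows, and maps the
long-lifetime amplitude fraction with both the Bayesian estimator and a
weighted least-squares baseline.
"""

import flim_bayes as fb

binning = fb.default_binning()
irf = fb.default_irf(binning)
# ~69% long-lifetime amplitude fraction, as in a partially FRETting donor
theta = fb.DecayParameters(0.055, 0.925, 0.48, 4.03, 12.5)
print(f"true long-lifetime amplitude fraction: "
      f"{1 - fb.amplitude_fraction(theta, binning):.4f}")

img = fb.simulate_flim_image(theta, irf, binning, shape=(16, 16),
                             photons_per_pixel=120, seed=31)

model = dict(tau_short=0.48, tau_long=4.03, period=12.5)
for window in (3, 7):
    bayes = fb.boxcar_fit_image(img, window, irf, **model)
    ls = fb.boxcar_least_squares_image(img, window, irf, **model)
    print(f"\n{window}x{window} pooling "
          f"(~{int(bayes.photon_map.mean())} photons per fit):")
    print(f"  Bayesian:      mean = {bayes.mean:.4f}, s.d. = {bayes.sd:.4f}")
    print(f"  least squares: mean = {ls.mean:.4f}, s.d. = {ls.sd:.4f}")

print("\nWider pooling trades spatial resolution for precision; at low photon")
print("counts the Bayesian map is tighter and less biased than least squares.")
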