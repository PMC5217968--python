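# flim-bayes

Bayesian estimation of FRET photon fractions from binned time-correlated
single-photon-counting (TCSPC) fluorescence-lifetime histograms.

## The problem

In time-domain FLIM, a pulsed laser (period *T*, typically 12.5 ns at
80 MHz) excites donor fluorophores and each detected photon is tagged with
its arrival time relative to the pulse.  Donors undergoing FRET decay with
a short lifetime τ<sub>S</sub>; donors not undergoing FRET keep their long
lifetime τ<sub>L</sub>; detectors add a uniform background.  The recorded
histogram is therefore a mixture

&nbsp;&nbsp;&nbsp;&nbsp;p(t | θ) = f<sub>S</sub> · p<sub>S</sub>(t | τ<sub>S</sub>) + f<sub>L</sub> · p<sub>L</sub>(t | τ<sub>L</sub>) + f<sub>B</sub> · p<sub>B</sub>(t),&nbsp;&nbsp; f<sub>B</sub> = 1 − f<sub>S</sub> − f<sub>L</sub>,

where each decay component is a periodic exponential — the pulse train
wraps late emissions, giving a density ∝ e<sup>−t/τ</sup> / (1 − e<sup>−T/τ</sup>)
on [0, T) — convolved with the measured instrument response function (IRF)
and integrated over discrete time bins.  Counts per bin are multinomial, so
for bin counts P<sub>i</sub> and model bin probabilities p<sub>i</sub>(θ)
the log-likelihood is Σ<sub>i</sub> P<sub>i</sub> log p<sub>i</sub>(θ) up to
a constant.  With uniform priors over the fraction simplex, the posterior
is proportional to this likelihood; it is evaluated exhaustively on a
(refined) grid of parameter values, or sampled by random-walk Metropolis
MCMC, and marginalized before reporting posterior means, modes, standard
deviations and credible intervals.

The target audience is anyone quantifying FRET fractions (or any
biexponential mixture weight) from photon-starved FLIM data, where
least-squares histogram fitting becomes noisy and biased but the exact
multinomial posterior remains well behaved.

## Worked example

```python
import flim_bayes as fb

binning = fb.default_binning()              # 256 bins over 10 ns, T = 12.5 ns
irf = fb.default_irf(binning)               # Gaussian IRF, sigma 0.1 ns
theta = fb.DecayParameters(f_short=0.30, f_long=0.60,
                           tau_short=0.48, tau_long=4.03, period=12.5)

hist = fb.simulate_histogram(theta=theta, irf=irf, binning=binning,
                             n_photons=20_000, seed=1)
fitter = fb.FixedLifetimeGridFitter(binning, irf, tau_short=0.48,
                                    tau_long=4.03, period=12.5)
est = fitter.fit(hist)["f_short"]
print(est.mean[0], est.sd[0])
```

Running `python examples/01_fit_single_histogram.py` (which is exactly
this) prints:

```
simulated 20000 photons, true f_short = 0.3
f_short: posterior mean = 0.3021, mode = 0.3021, sd = 0.0054, 95% CI = [0.2913, 0.3129]
f_long: posterior mean = 0.6000, mode = 0.6000, sd = 0.0119, 95% CI = [0.5764, 0.6237]
```

The posterior mean lands within one posterior standard deviation of the
true fraction, and the standard deviation is the photon-limited precision
of the measurement.  The other scripts in `examples/` walk through the
remaining capabilities: MCMC/grid equivalence, precision-vs-photon-number
scaling, linear recovery of rare fractions, and pixel-wise amplitude-fraction
maps with boxcar pooling compared against weighted least squares.

## Command line

A thin CLI wraps the same workflows:

```bash
flim-bayes simulate          --config config.yaml --seed 1 --out-dir out/
flim-bayes fit               --config config.yaml --histogram out/histogram.tsv --out-dir out/
flim-bayes study-low-photon  --config config.yaml --seed 1 --out-dir out/
flim-bayes study-low-fraction --config config.yaml --seed 1 --out-dir out/
flim-bayes image-fit         --config config.yaml --seed 1 --out-dir out/
```

Histograms and IRFs are two-column delimited text; reports and study
summaries are JSON embedding a hash of the configuration.

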