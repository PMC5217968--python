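# Methods

## Model

A binned TCSPC histogram records counts P₁…P_N over half-open time bins
[(i−1)Δt + t₀, iΔt + t₀) inside one excitation period T.  The model for the
per-bin arrival probability is a three-component mixture:

* **Short-lifetime component** — exponential decay with lifetime τ_S,
  representing FRETting donors.
* **Long-lifetime component** — exponential decay with lifetime τ_L,
  representing non-FRETting donors.
* **Uniform background** — dark counts and stray light, uniform over the
  recorded (masked-in) window.

Because excitation is periodic, a fluorophore excited by one pulse can emit
after a later pulse.  Summing the geometric tail of previous pulses gives a
steady-state density ∝ e^(−t/τ)/(1 − e^(−T/τ)) on [0, T); each bin mass is
its exact closed-form integral τ(e^(−t_l/τ) − e^(−t_r/τ)) times the
prefactor, which cancels under normalization.  The component is then
convolved with the measured IRF — treated as a discrete distribution at bin
resolution — **circularly, modulo the period**: the decay is built on the
full period grid (T/Δt bins), convolved by FFT, windowed to the recorded
bins and renormalized.  Circularity is a modelling choice: the steady-state
arrival distribution under pulsed excitation is periodic, so IRF mass
pushed past the period boundary re-enters at the start.  An implementation
that truncates the IRF tail at the window edge would differ slightly in
the edge bins.

The recorded window may be shorter than the period (default: 10 ns window,
12.5 ns period) and bins can be masked out (TAC limits, bin removal).  Both
are handled by renormalizing probabilities over the masked-in bins, which
is the exact conditional multinomial given that a photon was recorded
there; out-of-window photons are never modelled explicitly.  The uniform
background lives on the masked-in window only, matching the observation
window that enters the likelihood.

Counts are multinomial given the total, so log L(θ) = Σ P_i log p_i(θ) up
to a θ-independent combinatorial constant that cancels in posteriors.

## Inference

Priors are uniform: over the fraction simplex {f_S, f_L ≥ 0, f_S + f_L ≤ 1}
with f_B = 1 − f_S − f_L derived, and, when lifetimes are free, uniform over
user-set bounds with τ_S ≤ τ_L enforced by ordering.  In the validation
studies the lifetimes are fixed at independently measured values (0.48 and
4.03 ns for the reference dyes) and only the fractions are inferred.

**Grid posterior.**  The likelihood is evaluated in the log domain over a
lattice, normalized by max-subtraction and log-sum (5×10⁷-photon histograms
underflow otherwise), marginalized by summation, and summarized by the
posterior mean, the lattice mode (ties break to the smallest value), the
posterior s.d., and a central credible interval read off the lattice CDF.
Bin probabilities are floored at 1e-300 before logs so zero-probability
bins cannot produce −∞ at valid parameters.

**Grid refinement.**  A fixed global lattice cannot serve both regimes: the
first pass uses 201 uniformly spaced points per fraction axis (0.005
resolution), but at 5×10⁷ photons the posterior s.d. of f_S is ~1e-4, far
below that spacing.  The fitter therefore re-centres a fresh uniform
201-point lattice on the current posterior — range mean ± max(6 s.d.,
2 spacings) per axis, clipped to [0, 1] — and repeats until the spacing is
at most a quarter of the smallest posterior s.d. (cap: 6 passes).  The
2-spacing guard keeps the next window wide enough when the posterior
concentrates inside a single coarse cell.  Batches of histograms sharing
the acquisition share each lattice, so a study of hundreds of fits is a
handful of matrix products.

**MCMC.**  Random-walk Metropolis with isotropic Gaussian proposals
reflected at the parameter bounds; points off the simplex have zero prior
mass.  Proposal scales start at 10% of each bound range and are tuned every
100 steps during the burn-in (first 20% of the chain, discarded) toward a
20–50% acceptance rate, then frozen so the post-burn-in chain is a proper
Markov chain.  Chains are fully determined by their seed.  A chain that
accepts nothing raises a diagnostics error with the acceptance rate.
Grid and MCMC posteriors agree to Kolmogorov–Smirnov distance well below
0.05 (tested), so MCMC is the practical choice when lifetimes are also
free and a dense grid would be 4-dimensional.

**Amplitude fractions.**  Photon fractions weight components by the photons
they deliver into the recorded window.  The pre-exponential amplitudes of
the wrapped biexponential divide that yield out: with
κ_j = τ_j (1 − e^(−T/τ_j)) w_j, where w_j is the share of component j's
(unconvolved) periodic density inside the masked window, the short
amplitude fraction is (f_S/κ_S)/(f_S/κ_S + f_L/κ_L).  For equal lifetimes
this reduces to the photon fraction; for a full window and T ≫ τ it gives
the familiar (f_S/τ_S)/(f_S/τ_S + f_L/τ_L).

## Synthetic data

The simulator draws bin counts multinomially from the model probabilities
(exactly the sampling distribution the likelihood assumes; this fast path
makes 5×10⁷-photon studies cheap) or photon by photon: component choice,
continuous exponential emission, an IRF delay drawn as a whole number of
bins (matching the bin-resolution convolution), wrap modulo T, and
rejection-with-redraw *within the component* for photons outside the
masked window — so fractions count recorded photons, exactly as the binned
model defines them.  The two paths agree distributionally (tested by
chi-square at 10⁶ photons).

Default acquisition: 256 bins over a 10 ns window, T = 12.5 ns (80 MHz),
τ_S = 0.48 ns, τ_L = 4.03 ns, Gaussian IRF with σ = 0.1 ns centred 0.5 ns
into the window, background fraction 0.02.  Master curves — stand-ins for
very-high-count dye measurements — are deterministic expected-count
histograms at 10⁹ effective photons.  The mixture master for the
low-photon study uses f_S = 0.5.  The pure-component masters for the
mixing studies carry a 0.5% background each, chosen as realistic for
bright reference-dye solutions at ~10⁶ counts/s; mixing at prescribed
fraction f then yields a true short-photon fraction of 0.995·f, so the
ideal estimated-vs-prescribed slope is 0.995, consistent with the ~0.99
slopes measured on real dye data at low intensity.

**What the synthetic studies do not show.**  Real data add detector
dead-time, afterpulsing and pile-up, IRF drift and mischaracterization,
non-monoexponential dye emission, and intensity-dependent systematics —
none are simulated.  Passing tests demonstrate the estimator's statistical
behaviour under its own model assumptions (calibration, scaling,
linearity), not robustness to instrument pathologies; the small positive
offsets seen in real dye experiments arise from exactly those unmodelled
effects and are reproduced here only insofar as boundary truncation skews
low-fraction posteriors.

## Validation studies

* **Low-photon study** — 300 multinomial subsamples of the mixture master
  at 10 log-spaced photon counts from 30 to 3×10⁴; per-condition bias and
  sample s.d. of the posterior-mean estimate (posterior-mode estimates are
  recorded alongside); power law fit by OLS on log10–log10 axes excluding
  the 4 lowest counts, where the asymptotic regime has not set in.
  Expected exponent −1/2 from the central limit theorem.
* **Low-fraction studies** — mixtures at prescribed fractions 2⁻¹…2⁻¹⁰ of
  5×10⁷ photons (20 replicates) for the linearity fit, and fraction 2⁻⁷ at
  totals 5×10⁵–5×10⁷ (50 replicates) for the s.d.-scaling fit.  Adjacent
  differences of the per-condition means cancel additive bias.
* **Image study** — spatially uniform synthetic images; per-pixel
  histograms pooled over centred odd boxcar windows truncated at the
  borders; pixels below a 100-photon floor are left unfit.  The weighted
  least-squares baseline minimizes Σ (P_i − n·p_i)²/max(P_i, 1) over the
  fractions (a bounded linear problem, with a simplex-boundary refit when
  needed) and is compared with the Bayesian map mean and s.d.

Replicate counts and photon lattices are the package defaults above;
condition-level seeds are spawned from one study seed so every run is
bit-reproducible.  Uncertainty on fitted power-law and line parameters is
reported as 95% Student-t intervals from the log-log / linear OLS.

## Numerical and design notes

* Probabilities are renormalized after every masking/convolution step;
  normalization holds to 1e-10 under randomized parameters (tested).
* The closed-form periodic density matches an explicit 50-pulse truncated
  sum to 1e-10 across τ ∈ [0.1, 10] ns (tested).
* Equal lifetimes τ_S = τ_L are accepted as a degenerate but well-defined
  mixture (needed for the amplitude-fraction limit); τ_S > τ_L is rejected
  to fix the component labelling.
* `convolve_with_irf` without an explicit period wraps on the recorded
  grid, the natural reading when the window spans the whole period; the
  mixture pipeline always wraps on the full period grid.
* IRFs supplied on a finer grid are rebinned by edge-aligned aggregation;
  an optional pre-pulse baseline subtraction (mean of a user-given bin
  range, clipped at zero) is off by default.
* Rounding of the prescribed short-photon count in mixing uses
  round-half-away-from-zero, deterministic and unbiased over the fraction
  lattice.
* All study randomness flows from explicit seeds through
  `numpy.random.SeedSequence` spawning; no global random state is used.

## Limitations

Vendor binary TCSPC formats, IRF time-shift/colour-shift fitting, model
selection (mono- vs bi- vs tri-exponential), spatially regularized priors,
and detector artefact modelling are out of scope.  Mode estimates are
lattice values without sub-grid interpolation.  The in-vivo-style numbers
quoted for real cells elsewhere depend on external data and are not
reproduced here; the image study checks the method-comparison *properties*
(dispersion ordering at low photons, agreement of means at high photons)
on synthetic images instead.
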