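"""Validation studies for the fraction estimator.

These drivers reproduce, on synthetic master curves, the resampling
protocols used to characterize the Bayesian fraction estimator on
reference-dye data:

* **low-photon study** — subsample a fixed-ratio mixture master at
  photon counts spanning orders of magnitude, fit each subsample with
  lifetimes fixed, and summarize bias and spread of the estimates; the
  sample standard deviation is expected to fall as ``n_photon**-1/2``
  (central limit theorem), and a power law is fit on log-log axes.
* **low-fraction study** — mix photons from separate short-lifetime
  and long-lifetime masters at prescribed fractions down to ~1e-3 of
  5e7 photons, and check that the estimated fraction tracks the
  prescribed fraction linearly; differences between adjacent
  prescribed fractions cancel any additive bias.
* **image boxcar fitting** — pool per-pixel histograms over square
  windows, estimate the long-lifetime amplitude fraction per pixel,
  and compare against a weighted least-squares baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.optimize import lsq_linear

from .decay_model import (
    DecayParameters,
    InstrumentResponse,
    InvalidParameterError,
    TimeBinning,
)
from .inference import (
    BinnedHistogram,
    FixedLifetimeGridFitter,
    amplitude_fraction,
    _model_components,
)
from .simulator import MasterCurve, mix_masters, subsample_master

__all__ = [
    "StudyResult",
    "PowerLawFit",
    "LinearFit",
    "DeltaFractionResult",
    "FlimImage",
    "ImageFitResult",
    "LeastSquaresFit",
    "low_photon_study",
    "low_fraction_study",
    "fraction_scaling_study",
    "delta_fraction_study",
    "fit_power_law",
    "fit_line",
    "simulate_flim_image",
    "boxcar_fit_image",
    "boxcar_least_squares_image",
    "least_squares_baseline",
]


@dataclass(frozen=True)
class StudyResult:
    """Replicated estimates of f_short across a condition axis.

    ``estimates_mean``/``estimates_mode`` are (n_conditions, n_reps)
    arrays of posterior-mean and posterior-mode estimates;
    ``true_values`` holds the known short-photon fraction per condition
    when the generating truth is available.
    """

    condition_name: str
    conditions: np.ndarray
    estimates_mean: np.ndarray
    estimates_mode: np.ndarray
    true_values: np.ndarray | None = None

    @property
    def n_reps(self) -> int:
        return self.estimates_mean.shape[1]

    def condition_mean(self, estimator: str = "mean") -> np.ndarray:
        return self._est(estimator).mean(axis=1)

    def condition_sd(self, estimator: str = "mean") -> np.ndarray:
        return self._est(estimator).std(axis=1, ddof=1)

    def condition_sem(self, estimator: str = "mean") -> np.ndarray:
        return self.condition_sd(estimator) / np.sqrt(self.n_reps)

    def bias(self, estimator: str = "mean") -> np.ndarray:
        if self.true_values is None:
            raise InvalidParameterError("study has no known true values")
        return self.condition_mean(estimator) - self.true_values

    def _est(self, estimator: str) -> np.ndarray:
        if estimator == "mean":
            return self.estimates_mean
        if estimator == "mode":
            return self.estimates_mode
        raise ValueError(f"unknown estimator {estimator!r}")


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of y = a * x**b on log10-log10 axes with 95% t-intervals."""

    amplitude: float
    exponent: float
    amplitude_ci95: float
    exponent_ci95: float
    n_points: int

    def predict(self, x: float) -> float:
        return self.amplitude * x**self.exponent


@dataclass(frozen=True)
class LinearFit:
    slope: float
    offset: float
    slope_ci95: float
    offset_ci95: float
    n_points: int


def fit_power_law(
    x: np.ndarray, y: np.ndarray, exclude_lowest: int = 0
) -> PowerLawFit:
    """Fit ``y = a * x**b`` by OLS on log10 axes.

    ``exclude_lowest`` drops the k smallest-x points before fitting
    (the scaling studies exclude the lowest photon counts, where the
    asymptotic n**-1/2 behaviour has not yet set in).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0) or np.any(y <= 0):
        raise InvalidParameterError("power-law fit requires positive x and y")
    order = np.argsort(x)
    x, y = x[order][exclude_lowest:], y[order][exclude_lowest:]
    if len(x) < 3:
        raise InvalidParameterError("power-law fit needs at least 3 points")
    lf = _ols_line(np.log10(x), np.log10(y))
    a = 10**lf.offset
    # delta-method half-width for the amplitude
    a_ci = a * np.log(10) * lf.offset_ci95
    return PowerLawFit(
        amplitude=float(a),
        exponent=lf.slope,
        amplitude_ci95=float(a_ci),
        exponent_ci95=lf.slope_ci95,
        n_points=len(x),
    )


def fit_line(x: np.ndarray, y: np.ndarray) -> LinearFit:
    """OLS straight line with 95% t-intervals on slope and offset."""
    return _ols_line(np.asarray(x, dtype=float), np.asarray(y, dtype=float))


def _ols_line(x: np.ndarray, y: np.ndarray) -> LinearFit:
    if len(x) < 2:
        raise InvalidParameterError("line fit needs at least 2 points")
    if len(x) == 2:
        slope = float((y[1] - y[0]) / (x[1] - x[0]))
        return LinearFit(slope, float(y[0] - slope * x[0]), np.nan, np.nan, 2)
    res = stats.linregress(x, y)
    dof = len(x) - 2
    tcrit = stats.t.ppf(0.975, dof)
    return LinearFit(
        slope=float(res.slope),
        offset=float(res.intercept),
        slope_ci95=float(tcrit * res.stderr),
        offset_ci95=float(tcrit * res.intercept_stderr),
        n_points=len(x),
    )


# ----------------------------------------------------------------------
# resampling studies

def _fitter_for(
    binning: TimeBinning,
    irf: InstrumentResponse | None,
    tau_short: float,
    tau_long: float,
    period: float,
    n_grid: int,
) -> FixedLifetimeGridFitter:
    return FixedLifetimeGridFitter(
        binning, irf, tau_short=tau_short, tau_long=tau_long, period=period, n_grid=n_grid
    )


def low_photon_study(
    master: MasterCurve,
    photon_counts: np.ndarray,
    n_reps: int,
    tau_short: float,
    tau_long: float,
    period: float,
    irf: InstrumentResponse | None,
    seed: int,
    true_f_short: float | None = None,
    n_grid: int = 201,
) -> StudyResult:
    """Subsample a mixture master at each photon count and fit every replicate.

    Per condition, ``n_reps`` multinomial subsamples of the master are
    fit with lifetimes fixed; posterior-mean and posterior-mode
    estimates of f_short are collected for bias and spread summaries.
    """
    photon_counts = np.asarray(photon_counts, dtype=int)
    if np.any(photon_counts < 1):
        raise InvalidParameterError("photon counts must be >= 1")
    if n_reps < 2:
        raise InvalidParameterError("need at least 2 replicates per condition")
    fitter = _fitter_for(master.binning, irf, tau_short, tau_long, period, n_grid)
    ss = np.random.SeedSequence(seed)
    means = np.empty((len(photon_counts), n_reps))
    modes = np.empty((len(photon_counts), n_reps))
    for i, (n, child) in enumerate(zip(photon_counts, ss.spawn(len(photon_counts)))):
        rng = np.random.default_rng(child)
        counts = np.stack(
            [subsample_master(master, int(n), rng).counts for _ in range(n_reps)]
        )
        est = fitter.fit_counts(counts)["f_short"]
        means[i], modes[i] = est.mean, est.mode
    truth = None
    if true_f_short is not None:
        truth = np.full(len(photon_counts), float(true_f_short))
    return StudyResult("n_photons", photon_counts, means, modes, truth)


def _mixing_study(
    short: MasterCurve,
    long: MasterCurve,
    fractions: np.ndarray,
    n_totals: np.ndarray,
    n_reps: int,
    tau_short: float,
    tau_long: float,
    period: float,
    irf: InstrumentResponse | None,
    seed: int,
    condition_name: str,
    conditions: np.ndarray,
    n_grid: int,
) -> StudyResult:
    fitter = _fitter_for(short.binning, irf, tau_short, tau_long, period, n_grid)
    ss = np.random.SeedSequence(seed)
    means = np.empty((len(conditions), n_reps))
    modes = np.empty((len(conditions), n_reps))
    for i, child in enumerate(ss.spawn(len(conditions))):
        rng = np.random.default_rng(child)
        counts = np.stack(
            [
                mix_masters(short, long, float(fractions[i]), int(n_totals[i]), rng).counts
                for _ in range(n_reps)
            ]
        )
        est = fitter.fit_counts(counts)["f_short"]
        means[i], modes[i] = est.mean, est.mode
    return StudyResult(condition_name, conditions, means, modes, None)


def low_fraction_study(
    short: MasterCurve,
    long: MasterCurve,
    fractions: np.ndarray,
    n_total: int,
    n_reps: int,
    tau_short: float,
    tau_long: float,
    period: float,
    irf: InstrumentResponse | None,
    seed: int,
    n_grid: int = 201,
) -> StudyResult:
    """Mix masters at each prescribed fraction (fixed total photons) and fit.

    The condition axis is the prescribed mixing fraction; linearity of
    estimated versus prescribed fraction is assessed with
    :func:`fit_line` on the per-condition means.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions <= 0) | (fractions >= 1)):
        raise InvalidParameterError("prescribed fractions must lie in (0, 1)")
    if n_reps < 2:
        raise InvalidParameterError("need at least 2 replicates per condition")
    order = np.argsort(fractions)
    fractions = fractions[order]
    n_totals = np.full(len(fractions), int(n_total))
    return _mixing_study(
        short, long, fractions, n_totals, n_reps, tau_short, tau_long, period,
        irf, seed, "f_short_prescribed", fractions, n_grid,
    )


def fraction_scaling_study(
    short: MasterCurve,
    long: MasterCurve,
    fraction: float,
    n_totals: np.ndarray,
    n_reps: int,
    tau_short: float,
    tau_long: float,
    period: float,
    irf: InstrumentResponse | None,
    seed: int,
    n_grid: int = 201,
) -> StudyResult:
    """Fixed prescribed fraction, varying total photon number (s.d. scaling)."""
    n_totals = np.asarray(n_totals, dtype=np.int64)
    fractions = np.full(len(n_totals), float(fraction))
    return _mixing_study(
        short, long, fractions, n_totals, n_reps, tau_short, tau_long, period,
        irf, seed, "n_photons", n_totals, n_grid,
    )


@dataclass(frozen=True)
class DeltaFractionResult:
    """Adjacent-condition differences of a fraction-linearity study."""

    prescribed_deltas: np.ndarray
    estimated_deltas_mean: np.ndarray
    estimated_deltas_mode: np.ndarray
    fit_mean: LinearFit
    fit_mode: LinearFit


def delta_fraction_study(result: StudyResult) -> DeltaFractionResult:
    """Differences between adjacent prescribed fractions; additive bias cancels.

    Any offset common to all conditions drops out of the differences,
    so the delta fit isolates the estimator's proportional response.
    """
    if len(result.conditions) < 2:
        raise InvalidParameterError("need at least two fraction conditions")
    order = np.argsort(result.conditions)
    cond = np.asarray(result.conditions, dtype=float)[order]
    d_pre = np.diff(cond)
    d_mean = np.diff(result.condition_mean("mean")[order])
    d_mode = np.diff(result.condition_mean("mode")[order])
    if len(d_pre) >= 3:
        fit_mean = fit_line(d_pre, d_mean)
        fit_mode = fit_line(d_pre, d_mode)
    else:
        # two conditions give a single difference: slope through it, no CI
        slope_mean = float(d_mean[0] / d_pre[0])
        slope_mode = float(d_mode[0] / d_pre[0])
        fit_mean = LinearFit(slope_mean, 0.0, np.nan, np.nan, 1)
        fit_mode = LinearFit(slope_mode, 0.0, np.nan, np.nan, 1)
    return DeltaFractionResult(d_pre, d_mean, d_mode, fit_mean, fit_mode)


# ----------------------------------------------------------------------
# image-mode fitting

@dataclass(frozen=True)
class FlimImage:
    """2-D grid of per-pixel arrival-time histograms sharing one binning."""

    counts: np.ndarray  # (height, width, n_bins)
    binning: TimeBinning

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3 or c.shape[2] != self.binning.n_bins:
            raise InvalidParameterError(
                "image counts must be (height, width, n_bins) on the shared binning"
            )
        if np.any(c < 0):
            raise InvalidParameterError("image counts must be non-negative")
        c = np.ascontiguousarray(np.round(c).astype(np.int64))
        c.setflags(write=False)
        object.__setattr__(self, "counts", c)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]


@dataclass(frozen=True)
class ImageFitResult:
    """Per-pixel long-lifetime amplitude-fraction map with a summary."""

    fraction_map: np.ndarray  # NaN where the pixel was not fit
    photon_map: np.ndarray  # pooled photons per pixel
    mean: float
    sd: float
    n_fit: int


def simulate_flim_image(
    theta: DecayParameters,
    irf: InstrumentResponse | None,
    binning: TimeBinning,
    shape: tuple[int, int],
    photons_per_pixel: float,
    seed: int,
    poisson: bool = True,
) -> FlimImage:
    """Spatially uniform synthetic image; per-pixel totals are Poisson by default."""
    rng = np.random.default_rng(seed)
    h, w = shape
    if poisson:
        totals = rng.poisson(photons_per_pixel, size=h * w)
    else:
        totals = np.full(h * w, int(round(photons_per_pixel)))
    from .decay_model import mixture_bin_probabilities

    p = mixture_bin_probabilities(theta, irf, binning).p
    counts = np.stack([rng.multinomial(int(n), p) for n in totals])
    return FlimImage(counts.reshape(h, w, binning.n_bins), binning)


def _pool_boxcar(counts: np.ndarray, window: int) -> np.ndarray:
    """Sum counts over centred window x window neighbourhoods, truncated at borders."""
    summed = ndimage.uniform_filter(
        counts.astype(float), size=(window, window, 1), mode="constant", cval=0.0
    ) * (window * window)
    return np.round(summed).astype(np.int64)


def _check_window(window: int, shape: tuple[int, int]) -> None:
    if window % 2 != 1 or window < 1:
        raise InvalidParameterError("boxcar window must be an odd positive integer")
    if window > min(shape):
        raise InvalidParameterError("boxcar window exceeds the image")


def boxcar_fit_image(
    img: FlimImage,
    window: int,
    irf: InstrumentResponse | None,
    tau_short: float,
    tau_long: float,
    period: float,
    min_photons: int = 100,
    n_grid: int = 201,
) -> ImageFitResult:
    """Bayesian long-lifetime amplitude-fraction map from boxcar-pooled pixels.

    Each pixel's histogram is the sum over its centred window
    (truncated at the borders); the posterior-mean photon fractions are
    converted to the long-lifetime amplitude fraction.  Pixels whose
    pooled photon count falls below ``min_photons`` are left unfit
    (NaN) and excluded from the mean/s.d. summary.
    """
    _check_window(window, img.shape)
    pooled = _pool_boxcar(img.counts, window)
    h, w, nb = pooled.shape
    flat = pooled.reshape(h * w, nb)
    photons = flat[:, img.binning.mask].sum(axis=1)
    ok = photons >= min_photons
    frac_map = np.full(h * w, np.nan)
    if ok.any():
        fitter = _fitter_for(img.binning, irf, tau_short, tau_long, period, n_grid)
        est = fitter.fit_counts(flat[ok])
        f_s, f_l = est["f_short"].mean, est["f_long"].mean
        a_long = np.array(
            [
                1.0
                - amplitude_fraction(
                    DecayParameters(fs, fl, tau_short, tau_long, period), img.binning
                )
                if fs + fl > 0
                else np.nan
                for fs, fl in zip(f_s, f_l)
            ]
        )
        frac_map[ok] = a_long
    return _summarize_map(frac_map, photons, (h, w))


def boxcar_least_squares_image(
    img: FlimImage,
    window: int,
    irf: InstrumentResponse | None,
    tau_short: float,
    tau_long: float,
    period: float,
    min_photons: int = 100,
) -> ImageFitResult:
    """Least-squares counterpart of :func:`boxcar_fit_image`."""
    _check_window(window, img.shape)
    pooled = _pool_boxcar(img.counts, window)
    h, w, nb = pooled.shape
    flat = pooled.reshape(h * w, nb)
    photons = flat[:, img.binning.mask].sum(axis=1)
    frac_map = np.full(h * w, np.nan)
    for i in range(h * w):
        if photons[i] < min_photons:
            continue
        hist = BinnedHistogram(flat[i], img.binning)
        fit = least_squares_baseline(hist, irf, tau_short, tau_long, period)
        frac_map[i] = fit.amplitude_fraction_long
    return _summarize_map(frac_map, photons, (h, w))


def _summarize_map(
    frac_flat: np.ndarray, photons: np.ndarray, shape: tuple[int, int]
) -> ImageFitResult:
    ok = np.isfinite(frac_flat)
    mean = float(np.mean(frac_flat[ok])) if ok.any() else np.nan
    sd = float(np.std(frac_flat[ok], ddof=1)) if ok.sum() > 1 else np.nan
    return ImageFitResult(
        fraction_map=frac_flat.reshape(shape),
        photon_map=photons.reshape(shape),
        mean=mean,
        sd=sd,
        n_fit=int(ok.sum()),
    )


@dataclass(frozen=True)
class LeastSquaresFit:
    f_short: float
    f_long: float
    f_background: float
    amplitude_fraction_short: float
    amplitude_fraction_long: float


def least_squares_baseline(
    hist: BinnedHistogram,
    irf: InstrumentResponse | None,
    tau_short: float,
    tau_long: float,
    period: float,
) -> LeastSquaresFit:
    """Weighted least-squares fraction fit, the conventional baseline method.

    Minimizes ``sum_i (P_i - n p_i(theta))^2 / max(P_i, 1)`` over the
    free fractions with lifetimes fixed.  The model counts are linear
    in (f_short, f_long), so this is a bounded linear least-squares
    problem; the photon fractions are converted to amplitude fractions
    for comparison with the Bayesian maps.
    """
    p_s, p_l, u = _model_components(
        hist.binning, irf, tau_short, tau_long, period
    )
    counts = hist.masked_counts.astype(float)
    n = counts.sum()
    if n <= 0:
        raise InvalidParameterError("histogram holds no photons")
    w = 1.0 / np.sqrt(np.maximum(counts, 1.0))
    design = np.column_stack([n * (p_s - u), n * (p_l - u)]) * w[:, None]
    rhs = (counts - n * u) * w
    sol = lsq_linear(design, rhs, bounds=(0.0, 1.0))
    if not sol.success:
        raise RuntimeError(f"least-squares fit did not converge: {sol.message}")
    f_s, f_l = float(sol.x[0]), float(sol.x[1])
    if f_s + f_l > 1.0:
        # background pinned at zero: refit on the 1-D boundary f_long = 1 - f_short
        d = n * (p_s - p_l) * w
        r = (counts - n * p_l) * w
        f_s = float(np.clip((d @ r) / (d @ d), 0.0, 1.0))
        f_l = 1.0 - f_s
    theta = DecayParameters(f_s, f_l, tau_short, tau_long, period)
    a_s = amplitude_fraction(theta, hist.binning) if f_s + f_l > 0 else np.nan
    return LeastSquaresFit(
        f_short=f_s,
        f_long=f_l,
        f_background=max(1.0 - f_s - f_l, 0.0),
        amplitude_fraction_short=float(a_s),
        amplitude_fraction_long=float(1.0 - a_s),
    )
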