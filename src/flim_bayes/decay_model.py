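"""Forward model for binned TCSPC photon-arrival probabilities.

In time-domain FLIM the sample is excited by a periodic pulse train
(period ``T``, typically 12.5 ns for an 80 MHz laser) and each detected
photon is tagged with its arrival time relative to the pulse.  A donor
population in which only a fraction of fluorophores undergo FRET emits
with a biexponential decay: a short lifetime ``tau_short`` (FRETting
donors), a long lifetime ``tau_long`` (non-FRETting donors), plus a
uniform background of dark counts and stray light.  The detected times
are additionally smeared by the instrument response function (IRF) and
recorded on a discrete time axis whose window may cover only part of
the excitation period.

This module builds the per-bin arrival probabilities implied by a
parameter vector: the exact bin integrals of the periodic exponential
decay, circular (mod-T) convolution with a discrete IRF, uniform
background, mixture weighting, and renormalization over the recorded
(masked-in) bins.  Everything downstream — the multinomial likelihood,
posteriors, simulators — consumes these probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

__all__ = [
    "InvalidParameterError",
    "DegenerateBinningError",
    "BinningMismatchError",
    "TimeBinning",
    "DecayParameters",
    "InstrumentResponse",
    "BinProbabilities",
    "periodic_decay_density",
    "convolve_with_irf",
    "component_bin_probabilities",
    "mixture_bin_probabilities",
    "apply_bin_mask",
]

#: Floor applied to bin probabilities before logarithms; finite masks can
#: underflow genuine probabilities for extreme lifetimes.
PROBABILITY_FLOOR = 1e-300


class InvalidParameterError(ValueError):
    """A model parameter violates its domain (negative lifetime, fraction outside [0, 1], ...)."""


class DegenerateBinningError(ValueError):
    """A binning operation left no recorded (masked-in) bins."""


class BinningMismatchError(ValueError):
    """Two objects that must share a time axis do not."""


@dataclass(frozen=True)
class TimeBinning:
    """Uniform time axis of a TCSPC recording.

    Bins are half-open ``[t0 + (i-1)*dt, t0 + i*dt)`` for 1-based bin
    index ``i``; ``mask`` marks bins inside the recorded TAC window
    (the TAC limit settings of the counting electronics can exclude
    part of the axis).  ``t0`` is the offset of the first bin edge
    within the excitation period.
    """

    n_bins: int
    dt: float
    t0: float = 0.0
    mask: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise InvalidParameterError("n_bins must be >= 1")
        if not self.dt > 0:
            raise InvalidParameterError("bin width dt must be positive")
        mask = self.mask
        if mask is None:
            mask = np.ones(self.n_bins, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (self.n_bins,):
                raise BinningMismatchError(
                    f"mask has shape {mask.shape}, expected ({self.n_bins},)"
                )
        if not mask.any():
            raise DegenerateBinningError("at least one bin must be masked in")
        mask = mask.copy()
        mask.setflags(write=False)
        object.__setattr__(self, "mask", mask)

    # -- constructors -------------------------------------------------
    @classmethod
    def uniform(
        cls,
        n_bins: int,
        window: float | None = None,
        dt: float | None = None,
        t0: float = 0.0,
        mask: np.ndarray | None = None,
    ) -> "TimeBinning":
        """Build a binning from either the total window length or the bin width (ns)."""
        if (window is None) == (dt is None):
            raise InvalidParameterError("give exactly one of window or dt")
        if dt is None:
            dt = window / n_bins
        return cls(n_bins=n_bins, dt=dt, t0=t0, mask=mask)

    def with_mask(self, mask: np.ndarray) -> "TimeBinning":
        return replace(self, mask=np.asarray(mask, dtype=bool))

    def mask_bin_range(self, low_bin: int, high_bin: int) -> "TimeBinning":
        """Mask in the 1-based inclusive bin range [low_bin, high_bin] only."""
        if not (1 <= low_bin <= high_bin <= self.n_bins):
            raise InvalidParameterError(
                f"bin range [{low_bin}, {high_bin}] outside 1..{self.n_bins}"
            )
        mask = np.zeros(self.n_bins, dtype=bool)
        mask[low_bin - 1 : high_bin] = True
        return self.with_mask(mask)

    # -- derived quantities -------------------------------------------
    @property
    def window(self) -> float:
        """Total length of the binned axis in ns."""
        return self.n_bins * self.dt

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    @property
    def left_edges(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_bins)

    @property
    def right_edges(self) -> np.ndarray:
        return self.t0 + self.dt * (np.arange(self.n_bins) + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.t0 + self.dt * (np.arange(self.n_bins) + 0.5)

    def matches(self, other: "TimeBinning") -> bool:
        return (
            self.n_bins == other.n_bins
            and np.isclose(self.dt, other.dt, rtol=1e-12, atol=0.0)
            and np.isclose(self.t0, other.t0, rtol=0.0, atol=1e-12)
        )

    def require_matches(self, other: "TimeBinning") -> None:
        if not self.matches(other):
            raise BinningMismatchError("time binnings differ (n_bins, dt or t0)")

    def offset_bins(self) -> int:
        """Position of bin 1 within the period grid, in whole bins."""
        k = int(round(self.t0 / self.dt))
        if abs(k * self.dt - self.t0) > 1e-9 * max(self.dt, 1.0):
            raise InvalidParameterError("t0 must be an integer multiple of dt")
        return k

    def period_bins(self, period: float) -> int:
        """Number of bins in one full excitation period at this resolution."""
        if not period > 0:
            raise InvalidParameterError("period must be positive")
        n_p = int(round(period / self.dt))
        if n_p < self.offset_bins() + self.n_bins:
            raise InvalidParameterError(
                "recorded window cannot exceed one excitation period"
            )
        return n_p


@dataclass(frozen=True)
class DecayParameters:
    """Mixture parameter vector theta.

    ``f_short``/``f_long`` are the fractions of detected photons coming
    from the short- and long-lifetime exponential components;
    ``f_background = 1 - f_short - f_long`` is the uniform background
    fraction and is always derived, never stored.  Lifetimes are in ns
    and ordered ``tau_short <= tau_long``; ``period`` is the excitation
    pulse period in ns.
    """

    f_short: float
    f_long: float
    tau_short: float
    tau_long: float
    period: float

    def __post_init__(self) -> None:
        for name in ("f_short", "f_long"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise InvalidParameterError(f"{name}={v} outside [0, 1]")
        if self.f_background < -1e-12:
            raise InvalidParameterError(
                f"f_short + f_long = {self.f_short + self.f_long} exceeds 1"
            )
        if not (self.tau_short > 0 and self.tau_long > 0):
            raise InvalidParameterError("lifetimes must be positive")
        if self.tau_short > self.tau_long:
            raise InvalidParameterError(
                "ordering convention requires tau_short <= tau_long"
            )
        if not self.period > 0:
            raise InvalidParameterError("excitation period must be positive")

    @property
    def f_background(self) -> float:
        return 1.0 - self.f_short - self.f_long


@dataclass(frozen=True)
class InstrumentResponse:
    """Measured IRF as a discrete probability distribution on a TimeBinning grid."""

    weights: np.ndarray
    binning: TimeBinning

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.binning.n_bins,):
            raise BinningMismatchError(
                f"IRF weights shape {w.shape} does not match binning ({self.binning.n_bins},)"
            )
        if np.any(w < 0):
            raise InvalidParameterError("IRF weights must be non-negative")
        total = w.sum()
        if not total > 0:
            raise InvalidParameterError("IRF weights sum to zero")
        if abs(total - 1.0) > 1e-12:
            w = w / total
        w = w.copy()
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @classmethod
    def delta(cls, binning: TimeBinning, bin_index: int = 1) -> "InstrumentResponse":
        """Idealized instantaneous response: all weight in one 1-based bin."""
        if not (1 <= bin_index <= binning.n_bins):
            raise InvalidParameterError("delta bin index outside the grid")
        w = np.zeros(binning.n_bins)
        w[bin_index - 1] = 1.0
        return cls(w, binning)

    @classmethod
    def gaussian(
        cls, binning: TimeBinning, center: float, sigma: float
    ) -> "InstrumentResponse":
        """Bin-integrated Gaussian response centred ``center`` ns into the axis."""
        if not sigma > 0:
            raise InvalidParameterError("IRF sigma must be positive")
        z_r = (binning.right_edges - binning.t0 - center) / (np.sqrt(2.0) * sigma)
        z_l = (binning.left_edges - binning.t0 - center) / (np.sqrt(2.0) * sigma)
        w = 0.5 * (erf(z_r) - erf(z_l))
        return cls(w, binning)


@dataclass(frozen=True)
class BinProbabilities:
    """Per-bin arrival probabilities, normalized to 1 over masked-in bins.

    ``p`` covers the full grid; masked-out bins carry zero probability.
    """

    p: np.ndarray
    binning: TimeBinning

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (self.binning.n_bins,):
            raise BinningMismatchError("probability vector does not match binning")
        if np.any(p < 0):
            raise InvalidParameterError("bin probabilities must be non-negative")
        total = p[self.binning.mask].sum()
        if abs(total - 1.0) > 1e-10:
            raise InvalidParameterError(
                f"bin probabilities sum to {total!r} over masked-in bins, expected 1"
            )
        p = p.copy()
        p.setflags(write=False)
        object.__setattr__(self, "p", p)

    @property
    def masked(self) -> np.ndarray:
        """Probabilities of the masked-in bins only."""
        return self.p[self.binning.mask]


# ----------------------------------------------------------------------
# internal helpers

def _normalize_over_mask(raw: np.ndarray, binning: TimeBinning) -> BinProbabilities:
    p = np.where(binning.mask, np.clip(raw, 0.0, None), 0.0)
    total = p.sum()
    if not total > 0:
        raise DegenerateBinningError("model places zero probability on the recorded window")
    return BinProbabilities(p / total, binning)


def _periodic_bin_integrals(tau: float, period: float, edges: np.ndarray) -> np.ndarray:
    """Unnormalized bin masses of the steady-state periodic exponential decay.

    Under pulsed excitation with period T, fluorophores excited by
    earlier pulses contribute a geometric tail; summing it yields a
    density proportional to exp(-t/tau) / (1 - exp(-T/tau)) on [0, T).
    The bin mass is the exact integral of that density, computed in
    closed form; the constant prefactor is retained here but cancels in
    any later normalization.
    """
    if not tau > 0:
        raise InvalidParameterError("lifetime must be positive")
    if not period > 0:
        raise InvalidParameterError("period must be positive")
    prefactor = 1.0 / -np.expm1(-period / tau)
    left, right = edges[:-1], edges[1:]
    # tau * (e^{-l/tau} - e^{-r/tau}); written via expm1 for tau >> window.
    mass = tau * np.exp(-left / tau) * -np.expm1(-(right - left) / tau)
    return prefactor * mass


def _circular_convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n = len(a)
    out = np.fft.irfft(np.fft.rfft(a) * np.fft.rfft(b), n=n)
    return np.clip(out, 0.0, None)


def _embed_in_period(values: np.ndarray, binning: TimeBinning, n_period: int) -> np.ndarray:
    buf = np.zeros(n_period)
    k = binning.offset_bins()
    buf[k : k + binning.n_bins] = values
    return buf


# ----------------------------------------------------------------------
# operations

def periodic_decay_density(
    tau: float, period: float, binning: TimeBinning
) -> BinProbabilities:
    """Bin probabilities of a single exponential decay under periodic excitation.

    Uses the closed-form geometric-series density; each bin mass is the
    exact integral ``tau * (e^(-t_left/tau) - e^(-t_right/tau))`` times
    the period prefactor, renormalized over the masked-in bins.
    """
    binning.period_bins(period)  # validates window <= period
    edges = np.concatenate([binning.left_edges, binning.right_edges[-1:]])
    raw = _periodic_bin_integrals(tau, period, edges)
    return _normalize_over_mask(raw, binning)


def convolve_with_irf(
    decay: BinProbabilities,
    irf: InstrumentResponse,
    period: float | None = None,
) -> BinProbabilities:
    """Circular convolution of a decay bin distribution with the IRF.

    The convolution wraps modulo the excitation period at bin
    resolution; when ``period`` is omitted it wraps on the recorded
    grid itself (window == period).  The result is renormalized over
    the masked-in bins of the decay's binning.
    """
    binning = decay.binning
    binning.require_matches(irf.binning)
    if period is None:
        n_period = binning.offset_bins() + binning.n_bins
    else:
        n_period = binning.period_bins(period)
    d = _embed_in_period(decay.p, binning, n_period)
    h = _embed_in_period(irf.weights, binning, n_period)
    conv = _circular_convolve(d, h)
    k = binning.offset_bins()
    return _normalize_over_mask(conv[k : k + binning.n_bins], binning)


def component_bin_probabilities(
    tau: float,
    period: float,
    binning: TimeBinning,
    irf: InstrumentResponse | None = None,
) -> BinProbabilities:
    """IRF-convolved periodic decay probabilities on the recorded window.

    The decay is built on the full period grid (so probability mass in
    the unrecorded part of the period is represented before wrapping),
    convolved circularly with the IRF, windowed, and renormalized over
    masked-in bins.  With ``irf=None`` this reduces to
    :func:`periodic_decay_density`.
    """
    if irf is None:
        return periodic_decay_density(tau, period, binning)
    binning.require_matches(irf.binning)
    n_period = binning.period_bins(period)
    edges = binning.dt * np.arange(n_period + 1)
    d = _periodic_bin_integrals(tau, period, edges)
    h = _embed_in_period(irf.weights, binning, n_period)
    conv = _circular_convolve(d, h)
    k = binning.offset_bins()
    return _normalize_over_mask(conv[k : k + binning.n_bins], binning)


def background_bin_probabilities(binning: TimeBinning) -> BinProbabilities:
    """Uniform background over the recorded (masked-in) window."""
    raw = np.ones(binning.n_bins)
    return _normalize_over_mask(raw, binning)


def mixture_bin_probabilities(
    theta: DecayParameters,
    irf: InstrumentResponse | None,
    binning: TimeBinning,
) -> BinProbabilities:
    """Per-bin probability of the full model: f_S p_S + f_L p_L + f_B uniform."""
    p_s = component_bin_probabilities(theta.tau_short, theta.period, binning, irf)
    p_l = component_bin_probabilities(theta.tau_long, theta.period, binning, irf)
    u = background_bin_probabilities(binning)
    p = (
        theta.f_short * p_s.p
        + theta.f_long * p_l.p
        + max(theta.f_background, 0.0) * u.p
    )
    return _normalize_over_mask(p, binning)


def apply_bin_mask(probs: BinProbabilities, mask: np.ndarray) -> BinProbabilities:
    """Drop bins by mask and renormalize the retained ones.

    The combined mask is the intersection of the existing mask and the
    one supplied; dropping bins holding probability ``q`` rescales each
    retained bin by ``1/(1-q)``, which is the exact conditional
    distribution given arrival inside the retained set.
    """
    mask = np.asarray(mask, dtype=bool)
    new_binning = probs.binning.with_mask(probs.binning.mask & mask)
    return _normalize_over_mask(probs.p, new_binning)
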