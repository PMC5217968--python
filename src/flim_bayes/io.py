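"""Readers, writers and configuration for histograms, IRFs and reports.

All time units are nanoseconds.  Histograms and IRFs travel as
two-column delimited text (bin index or time, counts) so fixtures and
outputs stay plain text; fit reports and study summaries are JSON with
an embedded hash of the configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decay_model import (
    InstrumentResponse,
    InvalidParameterError,
    TimeBinning,
)
from .inference import BinnedHistogram

__all__ = [
    "AcquisitionConfig",
    "ParseError",
    "read_histogram",
    "write_histogram",
    "read_irf",
    "write_irf",
    "load_config",
    "acquisition_from_config",
    "config_hash",
    "write_json",
    "write_study_table",
]


class ParseError(ValueError):
    """A data file could not be parsed; the message names the offending line."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry: time axis, period and recorded-window mask."""

    n_bins: int
    dt_ns: float
    period_ns: float
    t0_ns: float = 0.0
    mask_low_bin: int | None = None
    mask_high_bin: int | None = None

    def binning(self) -> TimeBinning:
        b = TimeBinning(self.n_bins, self.dt_ns, self.t0_ns)
        if self.mask_low_bin is not None or self.mask_high_bin is not None:
            lo = self.mask_low_bin or 1
            hi = self.mask_high_bin or self.n_bins
            b = b.mask_bin_range(lo, hi)
        return b


def _read_two_columns(path: str | Path) -> np.ndarray:
    """Parse (index_or_time, counts) rows; tolerate one header line."""
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.replace(",", " ").split()
            if len(parts) < 2:
                raise ParseError(f"{path.name}:{lineno}: expected two columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ParseError(
                    f"{path.name}:{lineno}: could not parse {text!r}"
                ) from None
    if not rows:
        raise ParseError(f"{path.name}: no data rows")
    return np.asarray(rows, dtype=float)


def read_histogram(path: str | Path, binning: TimeBinning) -> BinnedHistogram:
    """Load a photon histogram; validates non-negative integer counts."""
    data = _read_two_columns(path)
    if len(data) != binning.n_bins:
        raise ParseError(
            f"{Path(path).name}: {len(data)} rows but binning has {binning.n_bins} bins"
        )
    counts = data[:, 1]
    neg = np.nonzero(counts < 0)[0]
    if len(neg):
        raise ParseError(
            f"{Path(path).name}: negative count in data row {neg[0] + 1}"
        )
    if not np.allclose(counts, np.round(counts)):
        bad = int(np.nonzero(~np.isclose(counts, np.round(counts)))[0][0])
        raise ParseError(
            f"{Path(path).name}: non-integer count in data row {bad + 1}"
        )
    return BinnedHistogram(np.round(counts).astype(np.int64), binning)


def write_histogram(path: str | Path, hist: BinnedHistogram) -> None:
    with open(path, "w") as fh:
        fh.write("bin\tcounts\n")
        for i, c in enumerate(hist.counts, start=1):
            fh.write(f"{i}\t{int(c)}\n")


def read_irf(
    path: str | Path,
    binning: TimeBinning,
    baseline_bins: tuple[int, int] | None = None,
) -> InstrumentResponse:
    """Load a measured IRF and normalize it to a discrete distribution.

    If the file holds an integer multiple of the target bin count, it
    is rebinned by edge-aligned aggregation.  ``baseline_bins`` (1-based
    inclusive range) optionally subtracts the mean of a pre-pulse
    region (dark counts), clipping negatives to zero.
    """
    data = _read_two_columns(path)
    w = data[:, 1]
    if np.any(w < 0):
        raise ParseError(f"{Path(path).name}: negative IRF counts")
    if baseline_bins is not None:
        lo, hi = baseline_bins
        if not (1 <= lo <= hi <= len(w)):
            raise InvalidParameterError("baseline bin range outside the IRF")
        w = np.clip(w - w[lo - 1 : hi].mean(), 0.0, None)
    if len(w) != binning.n_bins:
        if len(w) % binning.n_bins != 0:
            raise ParseError(
                f"{Path(path).name}: {len(w)} IRF bins cannot be aggregated to "
                f"{binning.n_bins}"
            )
        w = w.reshape(binning.n_bins, -1).sum(axis=1)
    if not w.sum() > 0:
        raise ParseError(f"{Path(path).name}: IRF is all zero")
    return InstrumentResponse(w / w.sum(), binning)


def write_irf(path: str | Path, irf: InstrumentResponse) -> None:
    with open(path, "w") as fh:
        fh.write("bin\tweight\n")
        for i, w in enumerate(irf.weights, start=1):
            fh.write(f"{i}\t{w:.12e}\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{Path(path).name}: configuration must be a mapping")
    return cfg


def acquisition_from_config(cfg: dict) -> AcquisitionConfig:
    acq = cfg.get("acquisition", cfg)
    n_bins = int(acq.get("n_bins", 256))
    if "dt_ns" in acq:
        dt = float(acq["dt_ns"])
    else:
        dt = float(acq.get("window_ns", 10.0)) / n_bins
    return AcquisitionConfig(
        n_bins=n_bins,
        dt_ns=dt,
        period_ns=float(acq.get("period_ns", 12.5)),
        t0_ns=float(acq.get("t0_ns", 0.0)),
        mask_low_bin=acq.get("mask_low_bin"),
        mask_high_bin=acq.get("mask_high_bin"),
    )


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration dict, for output provenance."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_json(path: str | Path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
        fh.write("\n")


def write_study_table(path: str | Path, result) -> None:
    """Long-format table: condition, replicate, estimate_mean, estimate_mode."""
    n_cond, n_reps = result.estimates_mean.shape
    rows = {
        result.condition_name: np.repeat(result.conditions, n_reps),
        "replicate": np.tile(np.arange(1, n_reps + 1), n_cond),
        "estimate_mean": result.estimates_mean.ravel(),
        "estimate_mode": result.estimates_mode.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
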