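"""Statistical summaries of per-frame time series.

The same summary vector is applied to every shape scalar (area,
eccentricity, perimeter, solidity) and every kinematic series (speed,
curvature, turning angle, angular velocity): mean, standard deviation,
skewness, kurtosis and Shannon entropy, plus — for shape series — a
spectral "signal entropy".

Conventions (fixed so tests are exact):

* standard deviation: population (ddof=0);
* skewness: adjusted Fisher-Pearson sample skewness;
* kurtosis: Pearson convention (non-excess; a Gaussian scores 3);
* Shannon entropy: histogram with 16 equal-width bins spanning the
  series' own range, probabilities = bin occupancy fractions, log base 2;
* signal entropy: Shannon entropy of the normalized periodogram
  (DC bin excluded), divided by log2 of the number of frequency bins so
  the value lies in [0, 1].

A constant series is degenerate: skewness and kurtosis are reported as 0
with ``degenerate=True``, and both entropies are 0 (single occupied bin,
zero-power spectrum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

N_HISTOGRAM_BINS = 16

__all__ = ["SummaryVector", "summarize_series", "shannon_entropy", "signal_entropy",
           "SHAPE_STATISTICS", "MOTILITY_STATISTICS"]

#: statistic names, in output order, for shape (6) and motility (5) summaries
SHAPE_STATISTICS = ("mean", "std", "skewness", "kurtosis", "shannon_entropy", "signal_entropy")
MOTILITY_STATISTICS = ("mean", "std", "skewness", "kurtosis", "shannon_entropy")


@dataclass(frozen=True)
class SummaryVector:
    """Summary statistics of one time series."""

    mean: float
    standard_deviation: float
    skewness: float
    kurtosis: float
    shannon_entropy: float
    signal_entropy: float | None = None
    degenerate: bool = False

    def as_dict(self, include_signal_entropy: bool = True) -> dict[str, float]:
        out = {
            "mean": self.mean,
            "std": self.standard_deviation,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "shannon_entropy": self.shannon_entropy,
        }
        if include_signal_entropy:
            out["signal_entropy"] = self.signal_entropy if self.signal_entropy is not None else 0.0
        return out


def shannon_entropy(series: np.ndarray, n_bins: int = N_HISTOGRAM_BINS) -> float:
    """Histogram Shannon entropy in bits over ``n_bins`` equal-width bins.

    Bins span the series' own range; a constant series occupies one bin
    and has zero entropy.  Bounded above by log2(n_bins).
    """
    x = np.asarray(series, dtype=float)
    lo, hi = x.min(), x.max()
    # a span below float resolution cannot be split into bins
    if hi - lo <= n_bins * np.finfo(float).eps * max(abs(lo), abs(hi), 1.0):
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def signal_entropy(series: np.ndarray) -> float:
    """Normalized spectral entropy of the periodogram, in [0, 1].

    Power at zero frequency (the mean) is excluded; a constant series has
    zero spectral power and entropy 0.  A flat (white) spectrum scores 1.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        return 0.0
    lo, hi = x.min(), x.max()
    if hi - lo <= np.finfo(float).eps * max(abs(lo), abs(hi), 1.0) * x.size:
        return 0.0
    _, pxx = _signal.periodogram(x, detrend=False)
    pxx = pxx[1:]  # drop DC
    total = pxx.sum()
    if total <= 0 or pxx.size < 2:
        return 0.0
    p = pxx[pxx > 0] / total
    h = -(p * np.log2(p)).sum()
    return float(h / np.log2(pxx.size))


def summarize_series(series, include_signal_entropy: bool = True) -> SummaryVector:
    """Summarize one real-valued series.

    Parameters
    ----------
    series : sequence of float
        At least 2 finite values.  NaNs are not accepted here; callers
        drop missing entries first (see motility_features missing-value
        policy).
    include_signal_entropy : bool
        True for the 6-statistic shape summary, False for the
        5-statistic motility summary.

    Raises
    ------
    ValueError
        If the series is shorter than 2 or contains non-finite values.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be one-dimensional with length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")

    mean = float(x.mean())
    std = float(x.std(ddof=0))
    # numerically constant series: higher moments are catastrophic cancellation
    degenerate = std <= 1e-12 * max(abs(mean), 1.0)
    if degenerate:
        skew = 0.0
        kurt = 0.0
    else:
        # adjusted (bias-corrected) moments need n >= 4; fall back to the
        # biased estimator for very short series rather than emitting NaN
        unbiased = x.size >= 4
        skew = float(_stats.skew(x, bias=not unbiased))
        kurt = float(_stats.kurtosis(x, fisher=False, bias=not unbiased))
    h = shannon_entropy(x)
    se = signal_entropy(x) if include_signal_entropy else None
    return SummaryVector(
        mean=mean,
        standard_deviation=std,
        skewness=skew,
        kurtosis=kurt,
        shannon_entropy=h,
        signal_entropy=se,
        degenerate=degenerate,
    )
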