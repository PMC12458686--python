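"""Uniformly-strided scalar observable time series and their statistics.

Simulation observables (volume, energies, instantaneous temperature) are
logged at a fixed stride; estimating ensemble averages from them must respect
the serial correlation of the samples.  The standard error reported here uses
the statistical inefficiency g = 1 + 2 Σ_τ c(τ) (sum truncated at the first
non-positive normalized autocorrelation), so n_eff = n/g independent samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

_STRIDE_RTOL = 1e-9


@dataclass
class ScalarSeries:
    """A named scalar observable sampled at a uniform time stride.

    times : fs, strictly increasing and uniform within 1e-9 relative
    values : observable units
    units : free-text unit label carried through I/O
    """

    name: str
    times: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.max(dt) - np.min(dt) > _STRIDE_RTOL * max(abs(dt[0]), 1.0):
                raise ValueError("times must have a uniform stride")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def stride(self) -> float:
        if len(self.times) < 2:
            raise ValueError("stride undefined for series of length < 2")
        return float(self.times[1] - self.times[0])

    def mean(self) -> float:
        return float(np.mean(self.values))

    def slice_time(self, t_lo: float, t_hi: float = np.inf) -> "ScalarSeries":
        """Sub-series with t_lo <= t <= t_hi (inclusive)."""
        m = (self.times >= t_lo) & (self.times <= t_hi)
        return ScalarSeries(self.name, self.times[m], self.values[m], self.units)


class SeriesStats(NamedTuple):
    mean: float
    variance: float          # population variance <X²> − <X>²
    std_error: float         # autocorrelation-corrected
    std_error_naive: float   # sqrt(var / n), no correlation correction
    n_eff: float             # effective number of independent samples


def statistical_inefficiency(values: np.ndarray) -> float:
    """g = 1 + 2 Σ_τ c(τ), truncated at the first non-positive c(τ).

    c(τ) is the normalized autocorrelation of the series.  Returns 1.0 for
    an uncorrelated or constant series; g ≥ 1 always.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        return 1.0
    dx = x - x.mean()
    var = float(np.dot(dx, dx)) / n
    if var == 0.0:
        return 1.0
    # full autocorrelation via FFT
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(dx, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[:n].real
    acf /= acf[0]
    # acf[τ] here is the raw lag-sum ratio, i.e. c(τ)·(n−τ)/n for the
    # unbiased autocorrelation c(τ); summing it directly applies the
    # (1 − τ/n) triangular weight of the finite-series formula.
    g = 1.0
    for tau in range(1, n):
        if acf[tau] <= 0.0:
            break
        g += 2.0 * acf[tau]
    return max(g, 1.0)


def series_stats(s: ScalarSeries | np.ndarray) -> SeriesStats:
    """Mean, population variance and standard errors of a logged observable.

    The variance is the population (biased) variance <X²> − <X>², matching
    the fluctuation-formula convention; the corrected standard error divides
    by the effective sample size n/g.
    """
    values = s.values if isinstance(s, ScalarSeries) else np.asarray(s, float)
    n = len(values)
    if n < 2:
        raise ValueError("series_stats requires at least 2 samples")
    mean = float(np.mean(values))
    var = float(np.mean((values - mean) ** 2))
    if var == 0.0:
        return SeriesStats(mean, 0.0, 0.0, 0.0, float(n))
    g = statistical_inefficiency(values)
    n_eff = n / g
    se_naive = np.sqrt(var / n)
    se = np.sqrt(var / n_eff)
    return SeriesStats(mean, var, float(se), float(se_naive), float(n_eff))


def check_aligned(*series: ScalarSeries) -> None:
    """Raise if the series do not share identical time grids."""
    t0 = series[0].times
    for s in series[1:]:
        if len(s.times) != len(t0) or not np.allclose(s.times, t0, rtol=0, atol=1e-9):
            raise ValueError(
                f"series '{series[0].name}' and '{s.name}' are not time-aligned")
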