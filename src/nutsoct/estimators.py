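"""Autocorrelation and motility-amplitude estimators for single-pixel series.

The motility amplitude of a pixel's magnitude time series S(t) is

    M = sqrt( (Gamma(ts) - Sbar^2) / Sbar^2 ),

where Gamma(ts) is the unbiased discrete autocorrelation at one sampling
interval and Sbar is the time-averaged signal.  White noise decorrelates
within one sample, so it drops out of Gamma(ts); perfectly stationary
scatterers contribute Sbar^2 at all lags.  The difference therefore isolates
"motile" scatterers — those decorrelating between ts and the total span —
and the Sbar^2 normalization makes M unitless and depth-invariant under
signal roll-off.

Three Gamma(ts) estimators correspond to the three sampling schemes:

* full sampling: the mean of all N-1 adjacent products;
* UTS: the same adjacent-product mean applied to the decimated series,
  which actually estimates the correlation at lag r*ts (the scheme's
  characteristic bias, reproduced deliberately);
* NUTS: the mean of the N' retained pair products, an unbiased estimate of
  the lag-ts correlation at any compression ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .schedules import Method, SamplingSchedule


@dataclass(frozen=True)
class PixelSeries:
    """Magnitude samples of one pixel plus the frame slots they occupy."""

    values: np.ndarray
    slots: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        slots = np.asarray(self.slots, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "slots", slots)
        if values.shape != slots.shape or values.ndim != 1:
            raise ValueError("values and slots must be equal-length 1-D arrays")
        if len(slots) > 1 and np.any(np.diff(slots) <= 0):
            raise ValueError("slots must be strictly increasing")


@dataclass(frozen=True)
class AutocorrTrace:
    """Autocorrelation Gamma(j*ts) on integer lag multiples j."""

    lags: np.ndarray
    gamma: np.ndarray


@dataclass(frozen=True)
class MotilityResult:
    """Lag-ts autocorrelation, mean signal and derived motility amplitude.

    ``radicand_clamped`` is True when sampling noise drove the estimate
    Gamma(ts) below Sbar^2 and the negative radicand was clipped to zero.
    ``m`` is NaN for a zero-mean-signal pixel (no motility information).
    """

    gamma_ts: float
    mean_s: float
    m: float
    radicand_clamped: bool


def _values(series) -> np.ndarray:
    v = series.values if isinstance(series, PixelSeries) else np.asarray(series, dtype=float)
    return np.asarray(v, dtype=float)


def autocorr_unbiased(series, max_lag: int) -> AutocorrTrace:
    """Unbiased discrete autocorrelation of a uniformly sampled series.

    Gamma(j*ts) = (1/(N-j)) * sum_{i=0}^{N-j-1} S((i+j) ts) S(i ts), for
    j = 0..max_lag.  Gamma(0) is the mean of the squared samples.
    """
    v = _values(series)
    n = len(v)
    if not 0 <= max_lag <= n - 1:
        raise ValueError(f"max_lag must be in [0, {n - 1}], got {max_lag}")
    lags = np.arange(max_lag + 1)
    gamma = np.array([float(v[j:] @ v[: n - j]) / (n - j) for j in lags])
    return AutocorrTrace(lags=lags, gamma=gamma)


def gamma_ts_full(series) -> float:
    """Lag-1 autocorrelation of a fully sampled series: mean adjacent product."""
    v = _values(series)
    if len(v) < 2:
        raise ValueError("need at least 2 samples for an adjacent product")
    return float(v[1:] @ v[:-1]) / (len(v) - 1)


def gamma_ts_uts(series, r: int = 1) -> float:
    """Adjacent-product mean of a decimated series.

    The decimated series is spaced ``r * ts`` apart, so this estimates the
    correlation at lag ``r * ts`` while being *used* as the lag-ts estimate —
    exactly the bias that degrades motility amplitudes under uniform
    sub-sampling.  ``r`` is bookkeeping only; it does not enter the sum.
    """
    if r < 1:
        raise ValueError(f"compression ratio must be >= 1, got {r}")
    return gamma_ts_full(series)


def gamma_ts_nuts(series, schedule: SamplingSchedule) -> float:
    """Pair-product estimate of the lag-ts autocorrelation on a NUTS schedule.

    Gamma(ts) = (1/N') * sum over pair starts i of S((i+1) ts) S(i ts).
    ``series`` holds only the retained samples, ordered by frame slot, so
    pair k occupies positions (2k, 2k+1).
    """
    if schedule.method is not Method.NUTS:
        raise ValueError(f"schedule method is {schedule.method}, expected NUTS")
    v = _values(series)
    if isinstance(series, PixelSeries):
        if not np.array_equal(series.slots, np.asarray(schedule.indices)):
            raise ValueError("series slots do not match the schedule's retained indices")
    elif len(v) != schedule.n_samples:
        raise ValueError(
            f"series length {len(v)} does not match schedule n_samples {schedule.n_samples}"
        )
    return float(np.mean(v[0::2] * v[1::2]))


def mean_signal(series) -> float:
    """Time-averaged signal Sbar: arithmetic mean of every retained sample."""
    v = _values(series)
    if len(v) == 0:
        raise ValueError("empty series has no mean signal")
    return float(np.mean(v))


def motility_amplitude(gamma_ts: float, mean_s: float) -> MotilityResult:
    """Motility amplitude M = sqrt(max(0, (Gamma(ts) - Sbar^2) / Sbar^2)).

    The radicand can go negative through sampling noise alone (Gamma(ts)
    estimated below Sbar^2); it is clamped to zero and flagged, which leaves
    a positive background floor of M over purely stationary pixels because
    only positive excursions survive.  A zero mean signal carries no motility
    information: the result is flagged NaN, never a division by zero.
    """
    if mean_s == 0:
        return MotilityResult(gamma_ts=gamma_ts, mean_s=0.0, m=math.nan, radicand_clamped=False)
    radicand = (gamma_ts - mean_s**2) / mean_s**2
    clamped = radicand < 0
    return MotilityResult(
        gamma_ts=gamma_ts,
        mean_s=mean_s,
        m=math.sqrt(max(0.0, radicand)),
        radicand_clamped=bool(clamped),
    )


def gamma_lag1(series, schedule: SamplingSchedule) -> float:
    """Dispatch the lag-ts estimator appropriate to a schedule.

    At r = 1 either scheme retains every slot, so the uncompressed estimator
    (all adjacent products) is used; the NUTS pair-product form would discard
    half of the available products for no compression gain.
    """
    if schedule.method is Method.FULL or schedule.r == 1:
        return gamma_ts_full(series)
    if schedule.method is Method.UTS:
        return gamma_ts_uts(series, schedule.r)
    return gamma_ts_nuts(series, schedule)


def motility_from_series(series, schedule: SamplingSchedule) -> MotilityResult:
    """Full estimation path for one pixel: Gamma(ts), Sbar, then M."""
    return motility_amplitude(gamma_lag1(series, schedule), mean_signal(series))
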