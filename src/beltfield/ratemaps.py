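"""Occupancy-normalized firing-rate vectors on the circular belt.

The belt is divided into ``n_pixels`` (default 100) half-open pixels
``[i*delta, (i+1)*delta)`` with circular adjacency between the last pixel and
pixel 0. Unsmoothed rate is spike count over occupancy time per pixel; the
smoothed vector is the circular convolution with a unit-sum Gaussian kernel
of 15 cm full width at half maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d

__all__ = [
    "RateMap",
    "TrialRateMatrix",
    "gaussian_kernel",
    "smooth_circular",
    "compute_occupancy",
    "spike_pixels",
    "compute_rate_map",
    "compute_trial_rate_matrix",
]

DEFAULT_N_PIXELS = 100
DEFAULT_FWHM_CM = 15.0
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_kernel(fwhm_cm, pixel_size_cm, truncate_sigmas=4.0):
    """Unit-sum Gaussian kernel with the given FWHM, truncated at ±4σ."""
    sigma_px = fwhm_cm * FWHM_TO_SIGMA / pixel_size_cm
    radius = max(1, int(np.ceil(truncate_sigmas * sigma_px)))
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma_px) ** 2)
    return k / k.sum()


def smooth_circular(rates, fwhm_cm, pixel_size_cm):
    """Circular (wrap-around) Gaussian smoothing along the last axis."""
    kernel = gaussian_kernel(fwhm_cm, pixel_size_cm)
    return convolve1d(np.asarray(rates, dtype=float), kernel, axis=-1, mode="wrap")


@dataclass(frozen=True)
class RateMap:
    """Whole-session firing-rate vector of one unit."""

    rates_hz: np.ndarray  # smoothed
    rates_raw_hz: np.ndarray
    counts: np.ndarray
    occupancy_s: np.ndarray
    pixel_size_cm: float
    smoothing_fwhm_cm: float
    smoothed: bool = True

    @property
    def n_pixels(self) -> int:
        return self.rates_hz.size

    @property
    def belt_length_cm(self) -> float:
        return self.pixel_size_cm * self.n_pixels

    @property
    def pixel_centers_cm(self) -> np.ndarray:
        return (np.arange(self.n_pixels) + 0.5) * self.pixel_size_cm

    @property
    def zero_occupancy(self) -> np.ndarray:
        return self.occupancy_s <= 0

    @property
    def spike_count(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TrialRateMatrix:
    """Per-trial rate maps stacked into a (n_trials, n_pixels) matrix."""

    rates_hz: np.ndarray  # smoothed, (n_trials, n_pixels)
    rates_raw_hz: np.ndarray
    counts: np.ndarray
    occupancy_s: np.ndarray
    pixel_size_cm: float
    smoothing_fwhm_cm: float

    @property
    def n_trials(self) -> int:
        return self.rates_hz.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.rates_hz.shape[1]

    @property
    def belt_length_cm(self) -> float:
        return self.pixel_size_cm * self.n_pixels


def _sample_pixels(trajectory, n_pixels):
    pixel_size = trajectory.belt_length_cm / n_pixels
    px = (trajectory.position_cm // pixel_size).astype(int)
    return np.clip(px, 0, n_pixels - 1)


def compute_occupancy(trajectory, n_pixels=DEFAULT_N_PIXELS, per_trial=False):
    """Time spent in each pixel, in seconds.

    Each inter-sample interval is credited to the pixel (and trial) of its
    left sample, so the occupancy sums to the session duration exactly.
    With ``per_trial=True`` returns a (n_trials, n_pixels) matrix whose rows
    sum to the trial durations.
    """
    if trajectory.time_s.size < 2:
        raise ValueError("trajectory too short for occupancy")
    dts = np.diff(trajectory.time_s)
    px = _sample_pixels(trajectory, n_pixels)[:-1]
    if not per_trial:
        return np.bincount(px, weights=dts, minlength=n_pixels)
    trials = trajectory.trial_index[:-1]
    n_trials = trajectory.n_trials
    flat = np.bincount(
        trials * n_pixels + px, weights=dts, minlength=n_trials * n_pixels
    )
    return flat.reshape(n_trials, n_pixels)


def spike_pixels(spike_times, trajectory, n_pixels=DEFAULT_N_PIXELS):
    """Pixel (and trial) index of each spike.

    Spike positions are obtained by linear interpolation of the unwrapped
    trajectory at the spike time; spikes outside the trajectory span are a
    hard error (with the offending count).
    """
    spike_times = np.asarray(spike_times, dtype=float)
    dist = trajectory.distance_at(spike_times)
    L = trajectory.belt_length_cm
    pixel_size = L / n_pixels
    px = ((dist % L) // pixel_size).astype(int)
    px = np.clip(px, 0, n_pixels - 1)
    trials = np.minimum((dist // L).astype(int), max(trajectory.n_trials - 1, 0))
    return px, trials


def compute_rate_map(
    spike_times,
    trajectory,
    belt=None,
    smoothing_fwhm_cm=DEFAULT_FWHM_CM,
    n_pixels=DEFAULT_N_PIXELS,
    occupancy=None,
):
    """Build the whole-session :class:`RateMap` of one unit.

    Zero-occupancy pixels get rate 0 (flagged via ``RateMap.zero_occupancy``).
    ``occupancy`` may be passed in to avoid recomputation across units.
    """
    if occupancy is None:
        occupancy = compute_occupancy(trajectory, n_pixels)
    px, _ = spike_pixels(spike_times, trajectory, n_pixels)
    counts = np.bincount(px, minlength=n_pixels).astype(float)
    raw = np.divide(
        counts, occupancy, out=np.zeros(n_pixels), where=occupancy > 0
    )
    pixel_size = trajectory.belt_length_cm / n_pixels
    smoothed = smooth_circular(raw, smoothing_fwhm_cm, pixel_size)
    return RateMap(
        rates_hz=smoothed,
        rates_raw_hz=raw,
        counts=counts,
        occupancy_s=occupancy,
        pixel_size_cm=pixel_size,
        smoothing_fwhm_cm=smoothing_fwhm_cm,
    )


def compute_trial_rate_matrix(
    spike_times,
    trajectory,
    belt=None,
    smoothing_fwhm_cm=DEFAULT_FWHM_CM,
    n_pixels=DEFAULT_N_PIXELS,
):
    """Per-trial rate maps; occupancy-weighted row mean equals the session
    unsmoothed map exactly (same pixel/trial assignment rules)."""
    if trajectory.n_trials < 1:
        raise ValueError("need at least one complete trial")
    occupancy = compute_occupancy(trajectory, n_pixels, per_trial=True)
    durations = occupancy.sum(axis=1)
    if np.any(durations <= 0):
        bad = np.flatnonzero(durations <= 0)
        raise ValueError(f"trial(s) with zero duration: {bad.tolist()}")
    px, trials = spike_pixels(spike_times, trajectory, n_pixels)
    n_trials = trajectory.n_trials
    counts = np.bincount(
        trials * n_pixels + px, minlength=n_trials * n_pixels
    ).reshape(n_trials, n_pixels).astype(float)
    raw = np.divide(counts, occupancy, out=np.zeros_like(counts), where=occupancy > 0)
    pixel_size = trajectory.belt_length_cm / n_pixels
    smoothed = smooth_circular(raw, smoothing_fwhm_cm, pixel_size)
    return TrialRateMatrix(
        rates_hz=smoothed,
        rates_raw_hz=raw,
        counts=counts,
        occupancy_s=occupancy,
        pixel_size_cm=pixel_size,
        smoothing_fwhm_cm=smoothing_fwhm_cm,
    )
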