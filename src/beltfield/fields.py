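"""Shuffle-based place-field significance and field descriptive properties.

The null preserves the temporal structure of the spike train: the whole train
is rotated circularly in time by a random shift t, decoupling spikes from
behaviour. 1,000 shuffled rate maps give per-pixel p-values (fraction of
shuffles strictly above the observed rate); place fields are maximal circular
runs of at least 5 pixels with p < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .ratemaps import (
    DEFAULT_FWHM_CM,
    DEFAULT_N_PIXELS,
    RateMap,
    smooth_circular,
    spike_pixels,
)

__all__ = [
    "PlaceField",
    "NullMapEnsemble",
    "circular_shift_shuffle",
    "build_null_ensemble",
    "pixel_pvalues",
    "circular_runs",
    "detect_fields",
    "field_properties",
]

DEFAULT_N_SHUFFLES = 1000
SHIFT_RANGE = (0.05, 0.95)  # random shifts drawn on [0.05 T, 0.95 T)
WIDTH_EDGE_FRACTION = 0.10


@dataclass(frozen=True)
class PlaceField:
    """A circular run of significant pixels and its descriptive properties."""

    start_px: int
    n_px: int
    peak_hz: float
    peak_position_cm: float
    com_cm: float
    width10_cm: float
    min_p: float = np.nan

    def pixels(self, n_pixels=DEFAULT_N_PIXELS):
        return (self.start_px + np.arange(self.n_px)) % n_pixels

    def contains_pixel(self, px, n_pixels=DEFAULT_N_PIXELS):
        return (px - self.start_px) % n_pixels < self.n_px

    def contains_cm(self, position_cm, belt_length_cm, n_pixels=DEFAULT_N_PIXELS):
        px = int(position_cm % belt_length_cm // (belt_length_cm / n_pixels))
        return self.contains_pixel(px, n_pixels)


@dataclass(frozen=True)
class NullMapEnsemble:
    """Smoothed rate maps of circularly time-shifted copies of one unit."""

    maps_hz: np.ndarray  # (n_shuffles, n_pixels)
    shifts_s: np.ndarray
    seed_key: tuple

    @property
    def n_shuffles(self) -> int:
        return self.maps_hz.shape[0]


def circular_shift_shuffle(spike_times, session_span, t):
    """Rotate the spike train by ``t`` seconds circularly within the session.

    Every spike s maps to ``t_start + ((s - t_start + t) mod T)``; the spike
    count and all inter-spike intervals (except at the single wrap point) are
    preserved.
    """
    t_start, t_end = session_span
    T = t_end - t_start
    if not 0 <= t < T:
        raise ValueError(f"shift t={t} outside [0, {T})")
    s = np.asarray(spike_times, dtype=float)
    return t_start + ((s - t_start + t) % T)


def build_null_ensemble(
    spike_times,
    trajectory,
    n_shuffles=DEFAULT_N_SHUFFLES,
    seed=0,
    unit_key="unit",
    smoothing_fwhm_cm=DEFAULT_FWHM_CM,
    n_pixels=DEFAULT_N_PIXELS,
    occupancy=None,
):
    """Rate maps of ``n_shuffles`` circular time rotations of the spike train.

    Shifts are uniform on [0.05 T, 0.95 T) to exclude near-identity
    rotations. All shuffles are binned in one vectorized pass.
    """
    if n_shuffles < 100:
        warnings.warn(f"n_shuffles={n_shuffles} gives coarse p-value resolution")
    rng = substream(seed, unit_key, "shuffle")
    t0, t1 = trajectory.span
    T = t1 - t0
    shifts = rng.uniform(SHIFT_RANGE[0] * T, SHIFT_RANGE[1] * T, size=n_shuffles)

    if occupancy is None:
        from .ratemaps import compute_occupancy

        occupancy = compute_occupancy(trajectory, n_pixels)

    s = np.asarray(spike_times, dtype=float)
    if s.size == 0:
        maps = np.zeros((n_shuffles, n_pixels))
        return NullMapEnsemble(maps, shifts, (seed, unit_key))

    shifted = t0 + ((s[None, :] - t0 + shifts[:, None]) % T)
    px, _ = spike_pixels(shifted.ravel(), trajectory, n_pixels)
    rows = np.repeat(np.arange(n_shuffles), s.size)
    counts = np.bincount(
        rows * n_pixels + px, minlength=n_shuffles * n_pixels
    ).reshape(n_shuffles, n_pixels)
    raw = np.divide(
        counts, occupancy[None, :], out=np.zeros_like(counts, dtype=float),
        where=occupancy[None, :] > 0,
    )
    pixel_size = trajectory.belt_length_cm / n_pixels
    maps = smooth_circular(raw, smoothing_fwhm_cm, pixel_size)
    return NullMapEnsemble(maps, shifts, (seed, unit_key))


def pixel_pvalues(rate_map, null_ensemble):
    """Per-pixel p = fraction of shuffles with a strictly higher rate.

    Ties count as "not higher" (no +1 correction). Zero-occupancy pixels get
    p = 1 so they can never seed a field.
    """
    obs = rate_map.rates_hz if isinstance(rate_map, RateMap) else np.asarray(rate_map)
    p = (null_ensemble.maps_hz > obs[None, :]).mean(axis=0)
    if isinstance(rate_map, RateMap):
        p = np.where(rate_map.zero_occupancy, 1.0, p)
    return p


def circular_runs(mask):
    """Maximal runs of True in a circular boolean vector.

    Returns a list of (start, length); a run crossing the wrap is reported
    once with its true circular start. An all-True vector is one run covering
    the whole circle.
    """
    mask = np.asarray(mask, dtype=bool)
    n = mask.size
    if mask.all():
        return [(0, n)]
    if not mask.any():
        return []
    starts = np.flatnonzero(mask & ~np.roll(mask, 1))
    doubled = np.concatenate([mask, mask])
    runs = []
    for s in starts:
        length = 0
        while doubled[s + length]:
            length += 1
        runs.append((int(s), int(length)))
    return runs


def detect_fields(
    rate_map: RateMap,
    null_ensemble: NullMapEnsemble,
    alpha=0.01,
    min_run=5,
    background_hz=None,
):
    """Place fields: maximal circular runs of >= ``min_run`` sub-alpha pixels.

    ``background_hz`` defaults to the mean smoothed rate over all pixels not
    in any sub-alpha run (the out-of-field baseline used for the field
    centre-of-mass and width).
    """
    p = pixel_pvalues(rate_map, null_ensemble)
    sub = p < alpha
    runs = [(s, ln) for s, ln in circular_runs(sub) if ln >= min_run]
    if not runs:
        return []

    if background_hz is None:
        out_of_field = ~sub
        if out_of_field.any():
            background_hz = float(rate_map.rates_hz[out_of_field].mean())
        else:
            background_hz = float(rate_map.rates_hz.min())

    fields = []
    for start, length in runs:
        span_px = (start + np.arange(length)) % rate_map.n_pixels
        try:
            props = field_properties((start, length), rate_map, background_hz)
        except ValueError:
            continue  # degenerate (peak <= background)
        fields.append(
            PlaceField(
                start_px=start,
                n_px=length,
                min_p=float(p[span_px].min()),
                **props,
            )
        )
    return fields


def field_properties(field_span, rate_map: RateMap, background_hz):
    """Peak, circular centre of mass and 10%-edges width of one field.

    The COM and width are computed on the background-subtracted smoothed rate
    in a window extended circularly from the peak out to where the rate falls
    below 10% of (peak - background); the 10% crossings are interpolated
    linearly between pixels.
    """
    start, length = field_span
    n = rate_map.n_pixels
    delta = rate_map.pixel_size_cm
    rates = rate_map.rates_hz
    span_px = (start + np.arange(length)) % n

    peak_rel = int(np.argmax(rates[span_px]))
    peak_px = int(span_px[peak_rel])
    peak_hz = float(rates[peak_px])
    if peak_hz <= background_hz:
        raise ValueError(
            f"degenerate field: peak {peak_hz:.3g} Hz <= background "
            f"{background_hz:.3g} Hz"
        )
    peak_cm = (peak_px + 0.5) * delta
    excess = rates - background_hz
    thresh = WIDTH_EDGE_FRACTION * (peak_hz - background_hz)

    def edge(direction):
        """Signed offset (cm, from the peak centre) of the 10% crossing."""
        for step in range(1, n // 2 + 1):
            j = (peak_px + direction * step) % n
            if excess[j] < thresh:
                prev = (peak_px + direction * (step - 1)) % n
                drop = excess[prev] - excess[j]
                frac = (excess[prev] - thresh) / drop if drop > 0 else 0.0
                return direction * ((step - 1) + frac) * delta
        return direction * (n // 2) * delta  # never crosses: half belt

    left = edge(-1)
    right = edge(+1)
    width10 = right - left

    # COM over the extended window, positions unwrapped around the peak
    n_left = int(np.ceil(-left / delta))
    n_right = int(np.ceil(right / delta))
    offsets = np.arange(-n_left, n_right + 1)
    win_px = (peak_px + offsets) % n
    w = np.clip(excess[win_px], 0.0, None)
    com_cm = (peak_cm + float((w * (offsets * delta)).sum() / w.sum())) % (n * delta)

    return {
        "peak_hz": peak_hz,
        "peak_position_cm": peak_cm,
        "com_cm": com_cm,
        "width10_cm": float(width10),
    }
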