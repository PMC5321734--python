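"""Animal trajectory on the belt and its simulation.

A trajectory is a time-ordered sequence of (time, belt position, trial index)
samples. Internally the unwrapped cumulative distance is kept so that wraps
never have to be reconstructed from the wrapped coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Trajectory", "simulate_trajectory"]


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped belt positions with trial indices.

    ``distance_cm`` is the unwrapped cumulative distance run since the first
    sample; ``position_cm = distance_cm % belt_length`` and
    ``trial_index = distance_cm // belt_length``.
    """

    time_s: np.ndarray
    distance_cm: np.ndarray
    belt_length_cm: float

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        d = np.asarray(self.distance_cm, dtype=float)
        if t.ndim != 1 or t.shape != d.shape:
            raise ValueError("time_s and distance_cm must be equal-length 1-D arrays")
        if t.size < 2:
            raise ValueError("trajectory needs at least two samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if np.any(np.diff(d) < -1e-6 * self.belt_length_cm):
            raise ValueError("distance must be non-decreasing (no backward running)")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "distance_cm", d)

    @property
    def position_cm(self) -> np.ndarray:
        return self.distance_cm % self.belt_length_cm

    @property
    def trial_index(self) -> np.ndarray:
        return (self.distance_cm // self.belt_length_cm).astype(int)

    @property
    def n_trials(self) -> int:
        """Number of complete belt rotations covered by the samples.

        A lap whose wrap point is within float precision of the final sample
        counts as complete (the simulator ends a hair before the last wrap so
        that ``trial_index`` stays in ``[0, n_trials)``).
        """
        L = self.belt_length_cm
        return int(np.floor(self.distance_cm[-1] / L + 1e-9))

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    @property
    def span(self) -> tuple[float, float]:
        return float(self.time_s[0]), float(self.time_s[-1])

    def distance_at(self, times_s) -> np.ndarray:
        """Unwrapped distance at arbitrary times, by linear interpolation."""
        times_s = np.asarray(times_s, dtype=float)
        lo, hi = self.span
        if times_s.size and (times_s.min() < lo or times_s.max() > hi):
            n_bad = int(np.sum((times_s < lo) | (times_s > hi)))
            raise ValueError(f"{n_bad} time(s) outside trajectory span [{lo}, {hi}]")
        return np.interp(times_s, self.time_s, self.distance_cm)

    def position_at(self, times_s) -> np.ndarray:
        return self.distance_at(times_s) % self.belt_length_cm

    def trial_at(self, times_s) -> np.ndarray:
        return (self.distance_at(times_s) // self.belt_length_cm).astype(int)

    def trial_bounds_s(self) -> np.ndarray:
        """(n_trials, 2) array of wall-clock [start, end) times per trial."""
        n = self.n_trials
        L = self.belt_length_cm
        # time at which each multiple of the belt length is crossed
        crossings = np.interp(np.arange(n + 1) * L, self.distance_cm, self.time_s)
        return np.column_stack([crossings[:-1], crossings[1:]])

    def restrict(self, t0_s, t1_s) -> "Trajectory":
        """Sub-trajectory covering [t0, t1] (interpolated end knots included).

        Distance stays on the session's absolute scale, so trial indices of
        the restricted trajectory remain those of the full session.
        """
        lo, hi = self.span
        t0 = max(t0_s, lo)
        t1 = min(t1_s, hi)
        inside = (self.time_s > t0) & (self.time_s < t1)
        t = np.concatenate([[t0], self.time_s[inside], [t1]])
        d = np.concatenate(
            [self.distance_at([t0]), self.distance_cm[inside], self.distance_at([t1])]
        )
        return Trajectory(t, d, self.belt_length_cm)

    @classmethod
    def from_samples(cls, time_s, position_cm, trial_index, belt_length_cm):
        """Rebuild a trajectory from wrapped (position, trial) samples."""
        position_cm = np.asarray(position_cm, dtype=float)
        trial_index = np.asarray(trial_index, dtype=float)
        return cls(
            np.asarray(time_s, dtype=float),
            trial_index * belt_length_cm + position_cm,
            belt_length_cm,
        )


def simulate_trajectory(
    belt, n_trials, mean_speed_cmps=15.0, speed_cv=0.3, dt_s=0.02, seed=0, ar_coef=0.98
):
    """Simulate a forward-running trajectory covering exactly ``n_trials`` laps.

    Per-sample speed follows a stationary log-normal multiplicative AR(1)
    process with the requested mean and coefficient of variation, so speed is
    positive and autocorrelated (time constant ``-dt/ln(ar_coef)``). With
    ``speed_cv=0`` the speed is constant.

    The last sample lands exactly at ``n_trials`` belt lengths of cumulative
    distance (the final step is shortened to hit the wrap point).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if mean_speed_cmps <= 0:
        raise ValueError("mean speed must be positive")
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    if speed_cv < 0:
        raise ValueError("speed_cv must be non-negative")

    rng = np.random.default_rng(seed)
    total = n_trials * belt.length_cm
    # generate in chunks until the target distance is covered
    n_guess = int(np.ceil(total / (mean_speed_cmps * dt_s) * 1.2)) + 10

    if speed_cv == 0:
        speeds = np.full(n_guess, mean_speed_cmps)
    else:
        # log-speed AR(1): x_k = a x_{k-1} + e_k, stationary sd chosen so that
        # exp(x) has the requested cv; mean corrected so E[speed] is exact
        sigma2 = np.log1p(speed_cv**2)
        mu = np.log(mean_speed_cmps) - sigma2 / 2
        innov_sd = np.sqrt(sigma2 * (1 - ar_coef**2))
        x = np.empty(n_guess)
        x[0] = rng.normal(0.0, np.sqrt(sigma2))
        eps = rng.normal(0.0, innov_sd, size=n_guess - 1)
        for k in range(1, n_guess):
            x[k] = ar_coef * x[k - 1] + eps[k - 1]
        speeds = np.exp(mu + x)

    steps = speeds * dt_s
    dist = np.concatenate([[0.0], np.cumsum(steps)])
    while dist[-1] < total:  # pragma: no cover - n_guess nearly always suffices
        extra = np.full(n_guess // 2, mean_speed_cmps * dt_s)
        dist = np.concatenate([dist, dist[-1] + np.cumsum(extra)])

    k_end = int(np.searchsorted(dist, total))  # first index with dist >= total
    dist = dist[: k_end + 1].copy()
    time = np.arange(dist.size) * dt_s
    # shorten the final step to land exactly on the wrap point
    if dist[k_end] > total:
        frac = (total - dist[k_end - 1]) / (dist[k_end] - dist[k_end - 1])
        time[k_end] = time[k_end - 1] + frac * dt_s
        dist[k_end] = total
    # nudge the endpoint below the wrap so trial_index stays in [0, n_trials)
    dist[k_end] = np.nextafter(total, 0.0)
    return Trajectory(time, dist, belt.length_cm)
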