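"""Trial-resolved remapping dynamics and cross-belt comparison.

Window timecourses measure, per trial, the mean rate in a 30 cm window
centred on a manipulated landmark minus the background estimated in two
15 cm flanking windows — this exactly cancels any spatially uniform rate
component. Drift is tracked as the per-trial field centre of mass with a
robust (Theil-Sen) slope; switching onset is the first post-event trial
sustainedly exceeding half the post-event asymptote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .belt import signed_circular_displacement

__all__ = [
    "WindowTimecourse",
    "DriftTrack",
    "rate_overlap",
    "cross_belt_compare",
    "landmark_window_pixels",
    "manipulation_window_timecourse",
    "population_vector_timecourse",
    "track_field_drift",
    "detect_switching",
]

DRIFT_THRESHOLD_CM_PER_TRIAL = 0.1


def rate_overlap(peak_a_hz, peak_b_hz):
    """min/max ratio of two peak rates; symmetric, in [0, 1]."""
    if peak_a_hz < 0 or peak_b_hz < 0:
        raise ValueError("peak rates must be non-negative")
    if peak_a_hz == 0 and peak_b_hz == 0:
        raise ValueError("rate overlap undefined for two zero peaks")
    return min(peak_a_hz, peak_b_hz) / max(peak_a_hz, peak_b_hz)


def cross_belt_compare(sessions, matched_units=None):
    """Paired per-unit metric table across sessions (chronic design).

    ``sessions``: dict session_label -> {unit_id -> {metric -> value}}.
    Units missing from any session are excluded with a warning. Returns a
    dict ``unit_id -> {f"{metric}_{label}": value}``.
    """
    labels = list(sessions)
    common = set(sessions[labels[0]])
    for lab in labels[1:]:
        common &= set(sessions[lab])
    if matched_units is not None:
        common &= set(matched_units)
    dropped = set().union(*(set(sessions[lab]) for lab in labels)) - common
    if dropped:
        warnings.warn(f"excluding {len(dropped)} unmatched unit(s): {sorted(dropped)}")
    table = {}
    for uid in sorted(common):
        row = {}
        for lab in labels:
            for metric, value in sessions[lab][uid].items():
                row[f"{metric}_{lab}"] = value
        table[uid] = row
    return table


@dataclass(frozen=True)
class WindowTimecourse:
    rates_hz: np.ndarray  # (n_cells, n_trials) background-subtracted
    p_values: np.ndarray  # per-trial group test, right-tailed
    significant: np.ndarray  # p < alpha
    window_px: np.ndarray
    flank_px: np.ndarray
    used_sign_test: bool = False

    @property
    def mean_hz(self):
        return self.rates_hz.mean(axis=0)

    @property
    def sem_hz(self):
        n = self.rates_hz.shape[0]
        return self.rates_hz.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(
            self.rates_hz.shape[1]
        )


def landmark_window_pixels(belt_length_cm, n_pixels, landmark, window_cm=30.0, flank_cm=15.0):
    """Pixel indices of the window centred on a landmark and of its flanks."""
    if window_cm + 2 * flank_cm > belt_length_cm / 2:
        raise ValueError(
            f"window + flanks ({window_cm + 2 * flank_cm} cm) exceed half the belt"
        )
    delta = belt_length_cm / n_pixels
    center = (landmark.start_cm + landmark.length_cm / 2) % belt_length_cm
    centers = (np.arange(n_pixels) + 0.5) * delta

    def span(lo, width):
        # pixels whose centre falls in the half-open circular interval
        return np.flatnonzero((centers - lo) % belt_length_cm < width)

    window = span(center - window_cm / 2, window_cm)
    flanks = np.concatenate(
        [
            span(center - window_cm / 2 - flank_cm, flank_cm),
            span(center + window_cm / 2, flank_cm),
        ]
    )
    return window, np.unique(flanks)


def manipulation_window_timecourse(
    trial_rate_matrices,
    belt,
    event,
    alpha=0.05,
    window_cm=30.0,
    flank_cm=15.0,
    min_cells_t_test=5,
):
    """Per-trial background-subtracted rate around a manipulated landmark.

    ``trial_rate_matrices``: (n_cells, n_trials, n_pixels) array or list of
    per-cell matrices. Background is the mean rate over the two 15 cm flanks,
    so a spatially uniform component cancels exactly. Per trial, the cell
    group is tested against 0 with a right-tailed one-sample t-test (a sign
    test below ``min_cells_t_test`` cells, flagged).
    """
    mats = np.stack(
        [m.rates_hz if hasattr(m, "rates_hz") else np.asarray(m) for m in trial_rate_matrices]
    )
    n_cells, n_trials, n_pixels = mats.shape
    if n_cells < 2:
        raise ValueError("need >= 2 cells for the per-trial group test")
    window, flanks = landmark_window_pixels(
        belt.length_cm, n_pixels, event.landmark, window_cm, flank_cm
    )
    sub = mats[:, :, window].mean(axis=2) - mats[:, :, flanks].mean(axis=2)

    use_sign = n_cells < min_cells_t_test
    pvals = np.empty(n_trials)
    for t in range(n_trials):
        x = sub[:, t]
        if use_sign:
            pvals[t] = stats.binomtest(
                int((x > 0).sum()), n=n_cells, p=0.5, alternative="greater"
            ).pvalue
        elif np.allclose(x, x[0]):
            pvals[t] = 0.0 if x[0] > 0 else 1.0
        else:
            pvals[t] = stats.ttest_1samp(x, 0.0, alternative="greater").pvalue
    return WindowTimecourse(
        rates_hz=sub,
        p_values=pvals,
        significant=pvals < alpha,
        window_px=window,
        flank_px=flanks,
        used_sign_test=use_sign,
    )


def population_vector_timecourse(
    trial_rate_matrices, window_px, event_trial=0, ref_trials=(40, 80)
):
    """Per-trial Pearson correlation with a late-session reference PV.

    The PV of a trial is the concatenation over cells of the window-pixel
    rates; the reference is the mean PV over trials ``event_trial +
    ref_trials[0] .. event_trial + ref_trials[1]`` (inclusive). Trials whose
    PV has zero variance yield NaN.
    """
    mats = np.stack(
        [m.rates_hz if hasattr(m, "rates_hz") else np.asarray(m) for m in trial_rate_matrices]
    )
    n_cells, n_trials, _ = mats.shape
    if n_cells < 2:
        raise ValueError("need >= 2 cells for a population vector")
    pv = mats[:, :, window_px].reshape(n_cells, n_trials, -1)
    pv = np.concatenate([pv[c] for c in range(n_cells)], axis=1)  # (n_trials, dim)
    lo = event_trial + ref_trials[0]
    hi = event_trial + ref_trials[1]
    if hi >= n_trials:
        raise ValueError(
            f"reference trials {lo}..{hi} exceed the session ({n_trials} trials)"
        )
    ref = pv[lo : hi + 1].mean(axis=0)
    if ref.std() == 0:
        raise ValueError("reference population vector has zero variance")
    corr = np.full(n_trials, np.nan)
    for t in range(n_trials):
        if pv[t].std() > 0:
            corr[t] = np.corrcoef(pv[t], ref)[0, 1]
    return corr


@dataclass(frozen=True)
class DriftTrack:
    com_cm: np.ndarray  # per-trial COM, unwrapped (can leave [0, L))
    drift_rate_cm_per_trial: float
    is_drifting: bool
    direction: str  # "backward" | "forward" | "stationary"
    carried_forward: np.ndarray  # trials where the COM was carried over
    span_cm: float
    duration_trials: int


def track_field_drift(
    trial_rate_matrix,
    initial_field,
    trials=None,
    drift_threshold=DRIFT_THRESHOLD_CM_PER_TRIAL,
):
    """Track a field's centre of mass trial by trial and fit a robust slope.

    The COM of each trial is computed over an adaptive circular window of
    half-width ``width10/2`` centred on the previous trial's COM, on the
    smoothed per-trial rates; trials with no in-window rate mass carry the
    previous COM forward (flagged). The drift rate is the Theil-Sen slope of
    the unwrapped COM against trial number; backward = negative = opposite to
    the running direction.
    """
    mat = (
        trial_rate_matrix.rates_hz
        if hasattr(trial_rate_matrix, "rates_hz")
        else np.asarray(trial_rate_matrix, dtype=float)
    )
    n_trials, n_pixels = mat.shape
    if hasattr(trial_rate_matrix, "pixel_size_cm"):
        delta = trial_rate_matrix.pixel_size_cm
    else:
        raise ValueError("pass a TrialRateMatrix (pixel size needed)")
    L = n_pixels * delta
    if trials is None:
        trials = np.arange(n_trials)
    half_w = max(initial_field.width10_cm / 2.0, 2 * delta)
    centers_px = np.arange(n_pixels) + 0.5

    com = np.empty(len(trials))
    carried = np.zeros(len(trials), dtype=bool)
    current = initial_field.com_cm % L
    for k, t in enumerate(trials):
        offsets = signed_circular_displacement(current, centers_px * delta, L)
        in_win = np.abs(offsets) <= half_w
        w = np.clip(mat[t, in_win], 0.0, None)
        if w.sum() <= 0:
            carried[k] = True
        else:
            current = (current + float((w * offsets[in_win]).sum() / w.sum())) % L
        com[k] = current

    # unwrap the circular COM sequence so slopes through 0 are continuous
    steps = signed_circular_displacement(com[:-1], com[1:], L)
    unwrapped = com[0] + np.concatenate([[0.0], np.cumsum(steps)])

    ok = ~carried
    if ok.sum() >= 2:
        slope, *_ = stats.theilslopes(unwrapped[ok], np.asarray(trials)[ok])
    else:
        slope = 0.0
    is_drifting = abs(slope) > drift_threshold
    direction = (
        "stationary" if not is_drifting else ("backward" if slope < 0 else "forward")
    )
    return DriftTrack(
        com_cm=unwrapped,
        drift_rate_cm_per_trial=float(slope),
        is_drifting=bool(is_drifting),
        direction=direction,
        carried_forward=carried,
        span_cm=float(unwrapped.max() - unwrapped.min()),
        duration_trials=len(trials),
    )


def detect_switching(
    trial_rate_matrix,
    event,
    fields_post,
    fields_pre=(),
    asymptote_trials=20,
    onset_fraction=0.5,
):
    """Onset trial (1-based, counted after the event) of a switching cell.

    A cell is switching iff a field is detected in the post-event map and no
    pre-event field overlaps its location. The onset is the first post-event
    trial whose in-field mean rate exceeds ``onset_fraction`` of the
    post-event asymptote (mean over the last ``asymptote_trials`` trials, or
    all post trials when fewer, flagged via a warning) with at least 3 of the
    following 5 trials also above. Returns ``None`` when not switching.
    """
    if not fields_post:
        return None
    mat = (
        trial_rate_matrix.rates_hz
        if hasattr(trial_rate_matrix, "rates_hz")
        else np.asarray(trial_rate_matrix, dtype=float)
    )
    n_trials, n_pixels = mat.shape
    at = int(event.at_trial)
    if not 0 < at < n_trials:
        raise ValueError("manipulation trial outside the session")

    new_field = max(fields_post, key=lambda f: f.peak_hz)
    post_px = new_field.pixels(n_pixels)
    for f in fields_pre:
        if np.any(f.contains_pixel(post_px, n_pixels)):
            return None  # location already had a field: not switching

    in_field = mat[:, post_px].mean(axis=1)
    post = in_field[at:]
    if post.size < asymptote_trials:
        warnings.warn(
            f"only {post.size} post-event trials; asymptote uses all of them"
        )
        asym = post.mean()
    else:
        asym = post[-asymptote_trials:].mean()
    if asym <= 0:
        return None
    thresh = onset_fraction * asym
    above = post > thresh
    for k in range(post.size):
        if above[k]:
            nxt = above[k + 1 : k + 6]
            if nxt.size == 0 or (nxt.sum() >= min(3, nxt.size)):
                return k + 1  # 1-based: first post-event trial is 1
    return None
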