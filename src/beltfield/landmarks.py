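"""LV / CM classification, landmark geometry and identity statistics.

The landmark score of a cell is the maximum over all circular lags of the
Pearson correlation between its firing-rate vector and the belt template
(1 inside landmark intervals, 0 outside), floored at 0 so it ranges from 0 to
1 and is invariant to affine rescaling of the rate vector. A cell with more
than one detected place field whose score exceeds the 95th percentile of
scores recomputed on its circular-shift shuffles is a landmark-vector (LV)
cell; single-field place cells are context-modulated (CM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .belt import signed_circular_displacement
from .ratemaps import DEFAULT_N_PIXELS

__all__ = [
    "CellClassification",
    "IdentityResult",
    "belt_template",
    "landmark_score",
    "classify_cell",
    "field_to_landmark_distance",
    "identity_index",
    "identity_index_test",
    "saliency_counts",
]


@dataclass(frozen=True)
class CellClassification:
    label: str  # LV | CM | multi_field_unclassified | non_place
    landmark_score: float
    score_threshold_95: float
    n_fields: int


@dataclass(frozen=True)
class IdentityResult:
    index: float
    dominant_type: str
    secondary_type: str | None
    significant: bool
    shuffle_threshold: float
    single_type: bool = False  # all fields at one type (secondary max = 0)


def belt_template(belt, n_pixels=DEFAULT_N_PIXELS, type_label=None):
    """0/1 vector marking pixels whose centre lies inside a landmark."""
    centers = (np.arange(n_pixels) + 0.5) * belt.length_cm / n_pixels
    template = np.zeros(n_pixels)
    for lm in belt.landmarks:
        if type_label is not None and lm.type_label != type_label:
            continue
        template[lm.contains(centers, belt.length_cm)] = 1.0
    return template


def _zscore_rows(x):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    z = np.zeros_like(x)
    z[ok] = (x[ok] - mu[ok]) / sd[ok]
    return z, ok


def landmark_score(rate_map, template):
    """Max over circular lags of Pearson(rate vector, lagged template) in
    [0, 1]; a constant rate vector scores 0 by convention."""
    return float(landmark_scores(np.atleast_2d(rate_map), template)[0])


def landmark_scores(rate_maps, template):
    """Vectorized :func:`landmark_score` over rows of ``rate_maps``."""
    template = np.asarray(template, dtype=float)
    if template.std() == 0:
        raise ValueError("constant belt template: landmark score undefined")
    n = template.size
    lagged = np.stack([np.roll(template, k) for k in range(n)])
    tz, _ = _zscore_rows(lagged)
    rz, ok = _zscore_rows(rate_maps)
    corr = rz @ tz.T / n  # (n_maps, n_lags)
    scores = np.clip(corr.max(axis=1), 0.0, 1.0)
    scores[~ok] = 0.0
    return scores


def classify_cell(fields, rate_map, template, null_scores):
    """LV / CM / multi_field_unclassified / non_place for one unit.

    ``null_scores`` are landmark scores of the unit's circular-shift shuffled
    rate maps (>= 1000 recommended).
    """
    null_scores = np.asarray(null_scores, dtype=float)
    if null_scores.size == 0:
        raise ValueError("null landmark scores required for classification")
    rates = rate_map.rates_hz if hasattr(rate_map, "rates_hz") else rate_map
    score = landmark_score(rates, template)
    thr = float(np.percentile(null_scores, 95))
    n_fields = len(fields)
    if n_fields == 0:
        label = "non_place"
    elif n_fields == 1:
        label = "CM"
    elif score > thr:
        label = "LV"
    else:
        label = "multi_field_unclassified"
    return CellClassification(
        label=label, landmark_score=score, score_threshold_95=thr, n_fields=n_fields
    )


def field_to_landmark_distance(field, belt):
    """Signed circular distance from the nearest landmark onset to the peak.

    Negative = peak before the landmark's entry edge (anticipatory);
    0..landmark length = inside; beyond = after. Nearest means smallest
    absolute signed displacement, ties broken toward the anticipatory side.
    Returns ``(signed_distance_cm, landmark)``.
    """
    if not belt.landmarks:
        raise ValueError("belt has no landmarks")
    peak = field.peak_position_cm if hasattr(field, "peak_position_cm") else float(field)
    best = None
    for lm in belt.landmarks:
        d = float(signed_circular_displacement(lm.start_cm, peak, belt.length_cm))
        if best is None:
            best = (d, lm)
            continue
        if abs(d) < abs(best[0]) - 1e-12:
            best = (d, lm)
        elif abs(abs(d) - abs(best[0])) <= 1e-12 and d < best[0]:
            best = (d, lm)  # tie -> anticipatory (negative) side
    return best


def identity_index(peaks_by_type):
    """Identity index of one cell from its per-type field peak rates.

    Peaks are normalized so the largest field is 1; the dominant type is the
    type holding that field. index = min(normalized dominant peaks) -
    max(normalized secondary peaks); with all fields at one type the
    secondary max is 0 (exclusive coding).

    Returns ``(index, dominant_type, secondary_type, single_type)``.
    """
    types = [t for t, ps in peaks_by_type.items() if len(ps) > 0]
    if not types:
        raise ValueError("cell has no fields")
    if len(types) > 2:
        raise ValueError("identity index defined for at most two landmark types")
    all_peaks = np.concatenate([np.asarray(peaks_by_type[t], float) for t in types])
    norm = all_peaks.max()
    if norm <= 0:
        raise ValueError("all field peaks are zero")
    dominant = max(types, key=lambda t: max(peaks_by_type[t]))
    if len(types) == 1:
        return float(min(peaks_by_type[dominant]) / norm), dominant, None, True
    secondary = next(t for t in types if t != dominant)
    idx = min(peaks_by_type[dominant]) / norm - max(peaks_by_type[secondary]) / norm
    return float(idx), dominant, secondary, False


def _shuffled_indexes(peaks, labels, n_shuffles, rng):
    """Indexes after permuting type labels across the cell's fields.

    Vectorized over shuffles (uniform random permutations via argsort of
    iid uniforms); exactly two label values are assumed.
    """
    peaks = np.asarray(peaks, dtype=float)
    norm = peaks.max()
    labs = np.asarray(labels)
    uniq = np.unique(labs)
    is_a = labs == uniq[0]
    order = np.argsort(rng.random((n_shuffles, labs.size)), axis=1)
    perm_a = is_a[order]  # (n_shuffles, n_fields) membership of type a
    p = np.broadcast_to(peaks, perm_a.shape)
    min_a = np.where(perm_a, p, np.inf).min(axis=1)
    max_a = np.where(perm_a, p, -np.inf).max(axis=1)
    min_b = np.where(~perm_a, p, np.inf).min(axis=1)
    max_b = np.where(~perm_a, p, -np.inf).max(axis=1)
    a_dominant = max_a >= max_b
    return np.where(a_dominant, min_a - max_b, min_b - max_a) / norm


def identity_index_test(cells_fields_by_type, n_shuffles=10_000, seed=0):
    """Population identity-index test with a pooled permutation null.

    ``cells_fields_by_type``: list of per-cell dicts ``type -> peak rates``.
    For each cell the type labels are permuted across its fields
    ``n_shuffles`` times, the index recomputed with the dominant type
    re-derived, and all shuffled indexes pooled; a cell is significant iff
    its observed index exceeds the pooled 95th percentile.

    Returns ``(results, pooled_threshold)``.
    """
    observed = []
    pooled = []
    for i, peaks_by_type in enumerate(cells_fields_by_type):
        idx, dom, sec, single = identity_index(peaks_by_type)
        observed.append((idx, dom, sec, single))
        types = [t for t, ps in peaks_by_type.items() if len(ps) > 0]
        peaks = np.concatenate([np.asarray(peaks_by_type[t], float) for t in types])
        labels = np.concatenate([[t] * len(peaks_by_type[t]) for t in types])
        if len(types) < 2:
            continue  # label permutation is degenerate; nothing to pool
        rng = substream(seed, i, "identity")
        pooled.append(_shuffled_indexes(peaks, labels, n_shuffles, rng))
    if pooled:
        threshold = float(np.percentile(np.concatenate(pooled), 95))
    else:
        threshold = np.inf
    results = [
        IdentityResult(
            index=idx,
            dominant_type=dom,
            secondary_type=sec,
            significant=bool(idx > threshold),
            shuffle_threshold=threshold,
            single_type=single,
        )
        for idx, dom, sec, single in observed
    ]
    return results, threshold


def saliency_counts(lv_dominant_types_by_session, type_labels):
    """Per-session fraction of LV cells dominated by each landmark type.

    ``lv_dominant_types_by_session``: dict session_id -> list of dominant
    type labels (one per LV cell). Sessions with zero LV cells are excluded
    with a warning. Returns ``{session_id: {type: fraction}}``; fractions sum
    to 1 within each session.
    """
    out = {}
    for session, doms in lv_dominant_types_by_session.items():
        if len(doms) == 0:
            warnings.warn(f"session {session!r} has no LV cells; excluded")
            continue
        doms = list(doms)
        out[session] = {t: doms.count(t) / len(doms) for t in type_labels}
    return out
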