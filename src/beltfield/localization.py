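"""Soma localization from per-site spike amplitudes.

Spike amplitude is assumed to attenuate with distance d from the soma as
1/d^2 (dipole; 1/d monopole exposed as an option), so for the true source
``A_i * d_i^2`` is the same constant at every site. The soma estimate is the
grid argmin of the sum of squared pairwise residuals

    S(x) = sum_{i<j} (A_i d_i(x)^p - A_j d_j(x)^p)^2 ,

searched coarse-to-fine down to 1 um over a half-space on one side of the
shank plane (the mirror image gives an identical S). Depths are expressed
relative to the site of maximum ripple-band power on the unit's shank; the
depth axis is the third coordinate, increasing toward stratum oriens, so
positive relative depth means above the ripple peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ProbeGeometry",
    "UnitPosition",
    "pairwise_residual_objective",
    "localize_unit",
    "ripple_reference_depth",
    "pairwise_depth_contrast",
    "ripple_band_power",
]

DEPTH_AXIS = 2  # coordinate index running along the shank, + toward oriens


@dataclass(frozen=True)
class ProbeGeometry:
    """Shank -> site -> 3-D coordinates (um)."""

    shanks: dict  # shank_id -> {site_id -> (x, y, z) um}

    def __post_init__(self):
        for shank_id, sites in self.shanks.items():
            coords = np.array(list(sites.values()), dtype=float)
            if coords.shape[0] >= 3:
                centered = coords - coords.mean(axis=0)
                if np.linalg.matrix_rank(centered, tol=1e-6) < 2:
                    raise ValueError(f"sites of shank {shank_id!r} are collinear")
            if len({tuple(c) for c in coords.tolist()}) != coords.shape[0]:
                raise ValueError(f"duplicate site coordinates on shank {shank_id!r}")

    def site_array(self, shank_id):
        sites = self.shanks[shank_id]
        ids = list(sites.keys())
        return ids, np.array([sites[s] for s in ids], dtype=float)

    def to_dict(self):
        return {
            str(shank): {str(site): list(map(float, xyz)) for site, xyz in sites.items()}
            for shank, sites in self.shanks.items()
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            {
                shank: {site: np.asarray(xyz, dtype=float) for site, xyz in sites.items()}
                for shank, sites in d.items()
            }
        )


@dataclass
class UnitPosition:
    position_um: np.ndarray
    objective_S: float
    shank_id: object = None
    depth_rel_ripple_um: float | None = None

    @property
    def depth_um(self) -> float:
        return float(self.position_um[DEPTH_AXIS])


def pairwise_residual_objective(points, site_positions, amplitudes, exponent=2):
    """Evaluate S at each query point (vectorized over points).

    Uses the identity sum_{i<j}(v_i - v_j)^2 = n*sum v^2 - (sum v)^2 with
    v_i = A_i * d_i^p.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    sites = np.asarray(site_positions, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    d2 = ((points[:, None, :] - sites[None, :, :]) ** 2).sum(axis=2)
    dp = d2 if exponent == 2 else d2 ** (exponent / 2.0)
    v = amps[None, :] * dp
    n = sites.shape[0]
    return n * (v**2).sum(axis=1) - v.sum(axis=1) ** 2


def _grid(extent, step):
    axes = [np.arange(lo, hi + step / 2, step) for lo, hi in extent]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def localize_unit(
    site_positions,
    amplitudes,
    search_extent_um=None,
    resolution_um=1.0,
    exponent=2,
    coarse_um=10.0,
    shank_id=None,
):
    """Grid-search soma estimate for one unit.

    Parameters
    ----------
    site_positions : (n, 3) array
        Site coordinates in um. Sites are assumed to lie in (or near) the
        plane ``x = const``; the search covers only the half-space on the
        +x side of that plane to break the mirror symmetry.
    amplitudes : (n,) array
        Mean spike amplitude at each site. Sites with zero amplitude are
        excluded (with a warning); at least 3 positive sites are required.
    search_extent_um : 3 pairs, optional
        ((xmin, xmax), (ymin, ymax), (zmin, zmax)). Default: 0-100 um off
        the shank plane, site bounding box +/- 50 um in the other axes.
    """
    sites = np.asarray(site_positions, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if np.any(amps < 0):
        raise ValueError("amplitudes must be non-negative")
    keep = amps > 0
    if not np.all(keep):
        warnings.warn(f"excluding {int((~keep).sum())} zero-amplitude site(s)")
        sites, amps = sites[keep], amps[keep]
    if sites.shape[0] < 3:
        raise ValueError("need >= 3 sites with positive amplitudes")

    if search_extent_um is None:
        x0 = sites[:, 0].mean()
        lo = sites.min(axis=0) - 50.0
        hi = sites.max(axis=0) + 50.0
        search_extent_um = ((x0, x0 + 100.0), (lo[1], hi[1]), (lo[2], hi[2]))

    coarse = _grid(search_extent_um, coarse_um)
    s_coarse = pairwise_residual_objective(coarse, sites, amps, exponent)
    best = coarse[int(np.argmin(s_coarse))]

    fine_extent = tuple(
        (max(lo, b - coarse_um), min(hi, b + coarse_um))
        for b, (lo, hi) in zip(best, search_extent_um)
    )
    fine = _grid(fine_extent, resolution_um)
    s_fine = pairwise_residual_objective(fine, sites, amps, exponent)
    k = int(np.argmin(s_fine))
    return UnitPosition(
        position_um=fine[k], objective_S=float(s_fine[k]), shank_id=shank_id
    )


def ripple_reference_depth(site_depths, powers):
    """Depth of the maximum ripple-power site; ties -> midpoint, flagged."""
    site_depths = np.asarray(site_depths, dtype=float)
    powers = np.asarray(powers, dtype=float)
    top = powers == powers.max()
    if top.sum() > 1:
        warnings.warn("tie in max ripple power; using midpoint of tied sites")
        return float(site_depths[top].mean())
    return float(site_depths[np.argmax(powers)])


def assign_relative_depths(unit_positions, probe, ripple_power_by_shank):
    """Fill ``depth_rel_ripple_um`` for each unit from its shank's profile.

    ``ripple_power_by_shank``: shank_id -> {site_id -> power}.
    Positive relative depth is toward stratum oriens (above the ripple peak).
    """
    for up in unit_positions:
        powers = ripple_power_by_shank[up.shank_id]
        ids, coords = probe.site_array(up.shank_id)
        p = np.array([powers[s] for s in ids], dtype=float)
        ref = ripple_reference_depth(coords[:, DEPTH_AXIS], p)
        up.depth_rel_ripple_um = up.depth_um - ref
    return unit_positions


@dataclass(frozen=True)
class DepthContrast:
    differences_um: np.ndarray
    mean_um: float
    t_stat: float
    p_value: float
    n_pairs: int
    n_shanks: int


def pairwise_depth_contrast(group_a_depths, group_b_depths, alternative="greater"):
    """All A x B within-shank depth differences and a one-tailed t-test.

    Both arguments map shank_id -> sequence of depths; only shanks holding
    cells of both groups qualify. Differences are depth_a - depth_b with the
    positive-toward-oriens convention.
    """
    diffs = []
    n_shanks = 0
    for shank, a in group_a_depths.items():
        b = group_b_depths.get(shank, [])
        if len(a) == 0 or len(b) == 0:
            continue
        n_shanks += 1
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        diffs.append((a[:, None] - b[None, :]).ravel())
    if n_shanks == 0:
        raise ValueError("no shank contains cells of both groups")
    diffs = np.concatenate(diffs)
    t, p = stats.ttest_1samp(diffs, 0.0, alternative=alternative)
    return DepthContrast(
        differences_um=diffs,
        mean_um=float(diffs.mean()),
        t_stat=float(t),
        p_value=float(p),
        n_pairs=diffs.size,
        n_shanks=n_shanks,
    )


def ripple_band_power(lfp, sampling_hz, band=(130.0, 200.0)):
    """Mean squared ripple-band amplitude per channel of a (n_samples,) or
    (n_samples, n_channels) LFP array (4th-order Butterworth, zero-phase)."""
    from scipy.signal import butter, filtfilt

    lfp = np.asarray(lfp, dtype=float)
    nyq = sampling_hz / 2.0
    b, a = butter(4, [band[0] / nyq, band[1] / nyq], btype="band")
    filtered = filtfilt(b, a, lfp, axis=0)
    return np.mean(filtered**2, axis=0)
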