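"""Ground-truthed synthetic treadmill sessions.

Units carry a generating rate function

    r(x, trial) = background + sum_fields peak * weight * gauss(x - center(trial))

with Gaussian field shapes on the circle. Landmark-vector (LV) units place one
field at every instance of each anchored landmark type, all sharing a single
field-to-landmark offset, with per-type identity weights scaling the peaks.
Context-modulated (CM) units have exactly one field at an absolute position;
drifting units translate their center by a fixed amount per trial; switching
units' fields are gated on from an onset trial. Spikes are drawn from the
inhomogeneous Poisson process r(x(t), trial(t)) by thinning, which is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import substream
from .belt import BeltLayout, Landmark, ManipulationEvent
from .localization import DEPTH_AXIS, ProbeGeometry
from .ratemaps import FWHM_TO_SIGMA
from .trajectory import Trajectory, simulate_trajectory

__all__ = [
    "GroundTruthUnit",
    "ResolvedField",
    "resolve_fields",
    "apply_landmark_manipulation",
    "unit_rate",
    "simulate_spike_trains",
    "simulate_probe_observations",
]

UNIT_KINDS = ("LV", "CM", "drifting", "switching", "untuned")


@dataclass(frozen=True)
class GroundTruthUnit:
    """Generating parameters of one simulated unit."""

    unit_id: str
    kind: str
    background_hz: float = 0.5
    peak_hz: float = 5.5
    fwhm_cm: float = 18.7  # gives ~34 cm 10%-edges width
    # LV parameters
    offset_cm: float = 0.0  # common signed field-to-landmark offset
    anchor_types: tuple = ()  # landmark types carrying fields
    identity_weights: dict = field(default_factory=dict)  # type -> [0, 1]
    # CM / drifting / switching parameters
    field_center_cm: float | None = None
    drift_cm_per_trial: float = 0.0
    onset_trial: int | None = None  # switching latency (trials after event)
    true_position_um: tuple | None = None
    shank_id: object = None

    def __post_init__(self):
        if self.kind not in UNIT_KINDS:
            raise ValueError(f"unknown unit kind {self.kind!r}")
        if self.background_hz < 0:
            raise ValueError("background rate must be non-negative")
        if self.kind != "drifting" and self.drift_cm_per_trial != 0.0:
            raise ValueError("drift_cm_per_trial must be 0 unless kind='drifting'")
        if self.kind == "LV" and not self.anchor_types:
            raise ValueError("LV unit needs at least one anchored landmark type")
        if self.kind in ("CM", "drifting", "switching") and self.field_center_cm is None:
            raise ValueError(f"{self.kind} unit needs field_center_cm")

    def to_dict(self):
        d = {
            "unit_id": self.unit_id,
            "kind": self.kind,
            "background_hz": self.background_hz,
            "peak_hz": self.peak_hz,
            "fwhm_cm": self.fwhm_cm,
            "offset_cm": self.offset_cm,
            "anchor_types": list(self.anchor_types),
            "identity_weights": dict(self.identity_weights),
            "field_center_cm": self.field_center_cm,
            "drift_cm_per_trial": self.drift_cm_per_trial,
            "onset_trial": self.onset_trial,
            "true_position_um": (
                None if self.true_position_um is None else list(self.true_position_um)
            ),
            "shank_id": self.shank_id,
        }
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["anchor_types"] = tuple(d.get("anchor_types", ()))
        if d.get("true_position_um") is not None:
            d["true_position_um"] = tuple(d["true_position_um"])
        return cls(**d)


@dataclass(frozen=True)
class ResolvedField:
    """A concrete field of the rate function, possibly gated in trial time."""

    center_cm: float  # center at trial `ref_trial`
    peak_hz: float  # already identity-weighted
    fwhm_cm: float
    drift_cm_per_trial: float = 0.0
    active_from: int = 0  # first trial the field is on
    active_until: float = np.inf  # first trial it is off again
    ref_trial: int = 0  # trial at which center_cm is anchored
    anchor_start_cm: float | None = None  # landmark start, for bookkeeping

    def center_at(self, trial, belt_length):
        c = self.center_cm + self.drift_cm_per_trial * (
            np.asarray(trial, dtype=float) - self.ref_trial
        )
        return c % belt_length


def resolve_fields(unit: GroundTruthUnit, belt: BeltLayout) -> tuple:
    """Concrete field list of a unit on a given belt.

    LV units get one field per instance of each anchored type; a type absent
    from the belt is a hard error.
    """
    if unit.kind == "untuned":
        return ()
    L = belt.length_cm
    if unit.kind == "LV":
        fields = []
        for type_label in unit.anchor_types:
            instances = belt.landmarks_of_type(type_label)
            if not instances:
                raise ValueError(
                    f"unit {unit.unit_id!r} anchored to landmark type "
                    f"{type_label!r} absent from the belt"
                )
            w = unit.identity_weights.get(type_label, 1.0)
            for lm in instances:
                fields.append(
                    ResolvedField(
                        center_cm=(lm.start_cm + unit.offset_cm) % L,
                        peak_hz=unit.peak_hz * w,
                        fwhm_cm=unit.fwhm_cm,
                        anchor_start_cm=lm.start_cm,
                    )
                )
        return tuple(fields)
    onset = unit.onset_trial if unit.kind == "switching" else None
    return (
        ResolvedField(
            center_cm=unit.field_center_cm % L,
            peak_hz=unit.peak_hz,
            fwhm_cm=unit.fwhm_cm,
            drift_cm_per_trial=unit.drift_cm_per_trial,
            active_from=0 if onset is None else int(onset),
            ref_trial=0 if onset is None else int(onset),
        ),
    )


def apply_landmark_manipulation(belt, units, event, fields_by_unit=None):
    """Apply an add/remove landmark event to the belt and rate functions.

    Returns ``(belt_after, fields_by_unit_after)`` where fields carry
    activation windows: LV units gain (lose) the field at the manipulated
    landmark instantly at ``event.at_trial`` with the same offset and
    identity-weighted peak; switching units' onset latency is counted from
    ``event.at_trial``; CM and drifting units are untouched.
    """
    if fields_by_unit is None:
        fields_by_unit = {u.unit_id: resolve_fields(u, belt) for u in units}
    lm = event.landmark
    if event.action == "remove":
        belt_after = belt.without_landmark(lm.type_label, lm.start_cm)
    else:
        belt_after = belt.with_landmark(lm)

    out = {}
    for unit in units:
        fields = fields_by_unit[unit.unit_id]
        if unit.kind == "LV" and lm.type_label in unit.anchor_types:
            L = belt.length_cm
            if event.action == "add":
                w = unit.identity_weights.get(lm.type_label, 1.0)
                fields = fields + (
                    ResolvedField(
                        center_cm=(lm.start_cm % L + unit.offset_cm) % L,
                        peak_hz=unit.peak_hz * w,
                        fwhm_cm=unit.fwhm_cm,
                        active_from=event.at_trial,
                        anchor_start_cm=lm.start_cm % L,
                    ),
                )
            else:
                fields = tuple(
                    replace(f, active_until=float(event.at_trial))
                    if f.anchor_start_cm is not None
                    and np.isclose(f.anchor_start_cm, lm.start_cm % L)
                    else f
                    for f in fields
                )
        elif unit.kind == "switching" and event.action == "add":
            latency = unit.onset_trial or 0
            fields = tuple(
                replace(
                    f,
                    active_from=event.at_trial + latency,
                    ref_trial=event.at_trial + latency,
                )
                for f in fields
            )
        out[unit.unit_id] = fields
    return belt_after, out


def _gauss_circ(x, center, fwhm, length):
    d = np.abs(x - center) % length
    d = np.minimum(d, length - d)
    sigma = fwhm * FWHM_TO_SIGMA
    return np.exp(-0.5 * (d / sigma) ** 2)


def unit_rate(fields, background_hz, position_cm, trial, belt_length):
    """Evaluate the generating rate function at (position, trial) arrays."""
    position_cm = np.asarray(position_cm, dtype=float)
    trial = np.asarray(trial)
    rate = np.full(position_cm.shape, float(background_hz))
    for f in fields:
        active = (trial >= f.active_from) & (trial < f.active_until)
        if not np.any(active):
            continue
        center = f.center_at(trial, belt_length)
        rate += np.where(
            active, f.peak_hz * _gauss_circ(position_cm, center, f.fwhm_cm, belt_length), 0.0
        )
    return rate


def _simulate_one(fields, background_hz, trajectory, rng):
    """Inhomogeneous Poisson spikes by thinning against the peak-sum bound."""
    rate_max = background_hz + sum(f.peak_hz for f in fields)
    if rate_max <= 0:
        return np.empty(0)
    t0, t1 = trajectory.span
    duration = t1 - t0
    n_cand = rng.poisson(rate_max * duration)
    cand = np.sort(rng.uniform(t0, t1, size=n_cand))
    if n_cand == 0:
        return np.empty(0)
    dist = trajectory.distance_at(cand)
    L = trajectory.belt_length_cm
    pos = dist % L
    trial = np.minimum((dist // L).astype(int), trajectory.n_trials - 1)
    r = unit_rate(fields, background_hz, pos, trial, L)
    accept = rng.uniform(0.0, rate_max, size=n_cand) < r
    return cand[accept]


def simulate_spike_trains(belt, trajectory, units, seed, events=()):
    """Per-unit spike-time arrays for a session, with optional manipulations.

    Each unit uses an independent substream keyed by ``(seed, unit_id)`` so
    results do not depend on unit order. Returns ``(spikes, belt_after,
    fields_by_unit)`` where the fields include any event gating.
    """
    fields_by_unit = {u.unit_id: resolve_fields(u, belt) for u in units}
    belt_after = belt
    for event in sorted(events, key=lambda e: e.at_trial):
        belt_after, fields_by_unit = apply_landmark_manipulation(
            belt_after, units, event, fields_by_unit
        )
    spikes = {}
    for unit in units:
        rng = substream(seed, unit.unit_id, "spikes")
        spikes[unit.unit_id] = _simulate_one(
            fields_by_unit[unit.unit_id], unit.background_hz, trajectory, rng
        )
    return spikes, belt_after, fields_by_unit


def simulate_probe_observations(
    units,
    probe: ProbeGeometry,
    amp_at_source=5e6,
    noise_frac=0.1,
    ripple_peak_depth_um=0.0,
    ripple_profile_sd_um=40.0,
    seed=0,
):
    """Per-site spike amplitudes (1/d^2 with multiplicative Gaussian noise,
    truncated at -90%) and a unimodal per-site ripple-band power profile
    peaking at ``ripple_peak_depth_um``.

    Returns ``(amplitudes, ripple_power)`` with
    ``amplitudes[unit_id][site_id]`` and ``ripple_power[shank_id][site_id]``.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be non-negative")
    amplitudes = {}
    for unit in units:
        if unit.true_position_um is None:
            continue
        if unit.shank_id is None or unit.shank_id not in probe.shanks:
            raise ValueError(f"unit {unit.unit_id!r} has no valid shank_id")
        rng = substream(seed, unit.unit_id, "amplitudes")
        ids, coords = probe.site_array(unit.shank_id)
        d = np.linalg.norm(coords - np.asarray(unit.true_position_um, float), axis=1)
        if np.any(d == 0):
            raise ValueError(
                f"unit {unit.unit_id!r} soma coincides with a recording site"
            )
        amps = amp_at_source / d**2
        if noise_frac > 0:
            eps = np.maximum(rng.normal(0.0, noise_frac, size=d.size), -0.9)
            amps = amps * (1.0 + eps)
        amplitudes[unit.unit_id] = dict(zip(ids, amps.tolist()))

    ripple_power = {}
    for shank_id in probe.shanks:
        ids, coords = probe.site_array(shank_id)
        depths = coords[:, DEPTH_AXIS]
        power = np.exp(
            -0.5 * ((depths - ripple_peak_depth_um) / ripple_profile_sd_um) ** 2
        )
        ripple_power[shank_id] = dict(zip(ids, power.tolist()))
    return amplitudes, ripple_power
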