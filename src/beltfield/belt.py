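"""Circular belt layout: typed landmark intervals on a loop.

All coordinates are in cm and interpreted modulo the belt length. Coordinate 0
is the trial-wrap point; the running direction is the direction of increasing
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Landmark",
    "BeltLayout",
    "ManipulationEvent",
    "build_belt",
    "circular_distance",
    "signed_circular_displacement",
]


def circular_distance(a, b, length):
    """Shortest unsigned distance between positions ``a`` and ``b`` on a loop."""
    d = np.abs(np.asarray(a) - np.asarray(b)) % length
    return np.minimum(d, length - d)


def signed_circular_displacement(frm, to, length):
    """Signed displacement from ``frm`` to ``to``, in (-length/2, length/2].

    Positive means ``to`` lies ahead of ``frm`` in the running direction.
    """
    d = (np.asarray(to) - np.asarray(frm)) % length
    return np.where(d > length / 2, d - length, d)


@dataclass(frozen=True)
class Landmark:
    type_label: str
    start_cm: float
    length_cm: float

    def __post_init__(self):
        if self.length_cm <= 0:
            raise ValueError(f"landmark length must be positive, got {self.length_cm}")

    def contains(self, position_cm, belt_length):
        """True if ``position_cm`` falls inside this interval on the circle."""
        rel = (np.asarray(position_cm) - self.start_cm) % belt_length
        return rel < self.length_cm


@dataclass(frozen=True)
class BeltLayout:
    """A circular treadmill belt with typed landmark intervals."""

    length_cm: float
    landmarks: tuple[Landmark, ...] = ()
    reward_cm: float = 0.0

    def __post_init__(self):
        if self.length_cm <= 0:
            raise ValueError("belt length must be positive")
        lms = tuple(
            replace(lm, start_cm=lm.start_cm % self.length_cm) for lm in self.landmarks
        )
        object.__setattr__(self, "landmarks", lms)
        self._check_overlap()

    def _check_overlap(self):
        L = self.length_cm
        for i, a in enumerate(self.landmarks):
            for b in self.landmarks[i + 1 :]:
                # overlap on the circle iff either start lies in the other interval
                if a.contains(b.start_cm, L) or b.contains(a.start_cm, L):
                    raise ValueError(
                        "landmarks overlap on the circle: "
                        f"({a.type_label} @ {a.start_cm} cm, len {a.length_cm}) and "
                        f"({b.type_label} @ {b.start_cm} cm, len {b.length_cm})"
                    )

    @property
    def type_labels(self):
        """Distinct landmark types, in order of first appearance."""
        seen = []
        for lm in self.landmarks:
            if lm.type_label not in seen:
                seen.append(lm.type_label)
        return tuple(seen)

    def landmarks_of_type(self, type_label):
        return tuple(lm for lm in self.landmarks if lm.type_label == type_label)

    def with_landmark(self, landmark: Landmark) -> "BeltLayout":
        return BeltLayout(self.length_cm, self.landmarks + (landmark,), self.reward_cm)

    def without_landmark(self, type_label, start_cm) -> "BeltLayout":
        start_cm = start_cm % self.length_cm
        keep = tuple(
            lm
            for lm in self.landmarks
            if not (lm.type_label == type_label and np.isclose(lm.start_cm, start_cm))
        )
        if len(keep) == len(self.landmarks):
            raise ValueError(
                f"no landmark of type {type_label!r} at {start_cm} cm to remove"
            )
        return BeltLayout(self.length_cm, keep, self.reward_cm)

    def to_dict(self):
        return {
            "length_cm": self.length_cm,
            "reward_cm": self.reward_cm,
            "landmarks": [
                {
                    "type_label": lm.type_label,
                    "start_cm": lm.start_cm,
                    "length_cm": lm.length_cm,
                }
                for lm in self.landmarks
            ],
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            length_cm=d["length_cm"],
            landmarks=tuple(Landmark(**lm) for lm in d["landmarks"]),
            reward_cm=d.get("reward_cm", 0.0),
        )


@dataclass(frozen=True)
class ManipulationEvent:
    """Addition or removal of a landmark at a given trial."""

    action: str  # "add" | "remove"
    landmark: Landmark
    at_trial: int

    def __post_init__(self):
        if self.action not in ("add", "remove"):
            raise ValueError(f"action must be 'add' or 'remove', got {self.action!r}")
        if self.at_trial < 0:
            raise ValueError("at_trial must be non-negative")

    def to_dict(self):
        return {
            "action": self.action,
            "landmark": {
                "type_label": self.landmark.type_label,
                "start_cm": self.landmark.start_cm,
                "length_cm": self.landmark.length_cm,
            },
            "at_trial": self.at_trial,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            action=d["action"],
            landmark=Landmark(**d["landmark"]),
            at_trial=int(d["at_trial"]),
        )


def build_belt(length_cm, landmark_spec, seed=None, reward_cm=0.0):
    """Construct a validated :class:`BeltLayout`.

    Parameters
    ----------
    length_cm : float
        Belt circumference.
    landmark_spec : sequence
        Entries are either ``(type_label, start_cm, length_cm)`` tuples /
        ``Landmark`` instances with explicit positions, or
        ``(type_label, "random", length_cm)`` requesting a random
        non-overlapping placement (requires ``seed``).
    seed : int, optional
        Used only when random placements are requested.

    Raises
    ------
    ValueError
        If any two intervals overlap on the circle (offending pair named).
    """
    fixed, random_reqs = [], []
    for entry in landmark_spec:
        if isinstance(entry, Landmark):
            fixed.append(entry)
            continue
        type_label, start, lm_len = entry
        if isinstance(start, str) and start == "random":
            random_reqs.append((type_label, float(lm_len)))
        else:
            fixed.append(Landmark(type_label, float(start), float(lm_len)))

    landmarks = list(fixed)
    if random_reqs:
        if seed is None:
            raise ValueError("seed required for random landmark placement")
        rng = np.random.default_rng(seed)
        for type_label, lm_len in random_reqs:
            for _ in range(10_000):
                start = float(rng.uniform(0, length_cm))
                cand = Landmark(type_label, start, lm_len)
                try:
                    BeltLayout(length_cm, tuple(landmarks) + (cand,))
                except ValueError:
                    continue
                landmarks.append(cand)
                break
            else:
                raise ValueError(
                    f"could not place landmark {type_label!r} without overlap"
                )
    return BeltLayout(length_cm, tuple(landmarks), reward_cm)
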