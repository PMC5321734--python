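"""Session bundles, on-disk formats, configuration and the analysis pipeline.

A session directory holds plain-text files only:

- ``belt.json``       landmark list as typed intervals
- ``trajectory.csv``  time_s, position_cm, trial_index
- ``spikes.csv``      unit_id, time_s
- ``events.json``     landmark manipulations (optional)
- ``probe.json``      shank -> site coordinates in um (optional)
- ``amplitudes.csv``  unit_id, site_id, amplitude_uv (optional)
- ``ripple_power.csv`` shank_id, site_id, power (optional)
- ``ground_truth.json`` generating parameters (simulation only)
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics, fields, landmarks, localization, ratemaps, synth
from .belt import BeltLayout, Landmark, ManipulationEvent, build_belt
from .localization import ProbeGeometry
from .trajectory import Trajectory, simulate_trajectory

logger = logging.getLogger("beltfield")

__all__ = [
    "SessionBundle",
    "AnalysisConfig",
    "simulate_session",
    "save_session",
    "load_session",
    "run_pipeline",
]

PIPELINE_STAGES = (
    "ratemaps",
    "fields",
    "classify",
    "identity",
    "dynamics",
    "localize",
    "report",
)


@dataclass
class AnalysisConfig:
    """All analysis constants, serialized into every run manifest."""

    n_pixels: int = 100
    smoothing_fwhm_cm: float = 15.0
    n_shuffles_fields: int = 1000
    n_shuffles_identity: int = 10_000
    alpha_pixel: float = 0.01
    min_run_pixels: int = 5
    alpha_trial: float = 0.05
    window_cm: float = 30.0
    flank_cm: float = 15.0
    drift_threshold: float = 0.1
    ref_trials: tuple = (40, 80)
    resolution_um: float = 1.0
    exponent: int = 2
    master_seed: int = 0

    def to_dict(self):
        d = asdict(self)
        d["ref_trials"] = list(self.ref_trials)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "ref_trials" in d:
            d["ref_trials"] = tuple(d["ref_trials"])
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class SessionBundle:
    belt: BeltLayout
    trajectory: Trajectory
    spikes: dict  # unit_id -> spike-time array
    events: tuple = ()
    probe: ProbeGeometry | None = None
    amplitudes: dict | None = None  # unit_id -> {site_id -> uV}
    ripple_power: dict | None = None  # shank_id -> {site_id -> power}
    ground_truth: list | None = None  # list of GroundTruthUnit
    belt_post: BeltLayout | None = None  # layout after the last event

    def validate(self):
        """Collect (not just the first of) all invariant violations."""
        problems = []
        lo, hi = self.trajectory.span
        for uid, st in self.spikes.items():
            st = np.asarray(st, dtype=float)
            n_bad = int(np.sum((st < lo) | (st > hi)))
            if n_bad:
                problems.append(
                    f"unit {uid!r}: {n_bad} spike(s) outside trajectory span"
                )
            if st.size > 1 and np.any(np.diff(st) < 0):
                problems.append(f"unit {uid!r}: spike times not sorted")
        for ev in self.events:
            if not 0 <= ev.at_trial < self.trajectory.n_trials:
                problems.append(f"event at trial {ev.at_trial} outside session")
        if self.amplitudes is not None and self.probe is None:
            problems.append("amplitudes present but probe.json missing")
        if problems:
            raise ValueError("invalid session bundle:\n  " + "\n  ".join(problems))
        return self

    @property
    def unit_ids(self):
        return sorted(self.spikes)


def simulate_session(config: dict, seed: int) -> SessionBundle:
    """Build a full ground-truthed session from a config dictionary.

    Config keys: ``belt`` (length_cm, landmarks), ``trajectory`` (n_trials,
    mean_speed_cmps, speed_cv, dt_s), ``units`` (list of GroundTruthUnit
    dicts), optional ``events`` and ``probe`` (geometry + amp_at_source,
    noise_frac, ripple_peak_depth_um).
    """
    belt = build_belt(
        config["belt"]["length_cm"],
        [
            (lm["type_label"], lm.get("start_cm", "random"), lm["length_cm"])
            for lm in config["belt"]["landmarks"]
        ],
        seed=seed,
        reward_cm=config["belt"].get("reward_cm", 0.0),
    )
    tcfg = config.get("trajectory", {})
    trajectory = simulate_trajectory(
        belt,
        n_trials=tcfg.get("n_trials", 100),
        mean_speed_cmps=tcfg.get("mean_speed_cmps", 15.0),
        speed_cv=tcfg.get("speed_cv", 0.3),
        dt_s=tcfg.get("dt_s", 0.02),
        seed=seed,
    )
    units = [synth.GroundTruthUnit.from_dict(u) for u in config.get("units", [])]
    events = tuple(
        ManipulationEvent.from_dict(e) for e in config.get("events", [])
    )
    spikes, belt_post, _ = synth.simulate_spike_trains(
        belt, trajectory, units, seed=seed, events=events
    )

    probe = amplitudes = ripple_power = None
    if "probe" in config:
        pcfg = config["probe"]
        probe = ProbeGeometry.from_dict(pcfg["geometry"])
        amplitudes, ripple_power = synth.simulate_probe_observations(
            units,
            probe,
            amp_at_source=pcfg.get("amp_at_source", 5e6),
            noise_frac=pcfg.get("noise_frac", 0.1),
            ripple_peak_depth_um=pcfg.get("ripple_peak_depth_um", 0.0),
            seed=seed,
        )
    return SessionBundle(
        belt=belt,
        trajectory=trajectory,
        spikes=spikes,
        events=events,
        probe=probe,
        amplitudes=amplitudes,
        ripple_power=ripple_power,
        ground_truth=units,
        belt_post=belt_post,
    ).validate()


def save_session(bundle: SessionBundle, directory):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "belt.json").write_text(json.dumps(bundle.belt.to_dict(), indent=1))
    pd.DataFrame(
        {
            "time_s": bundle.trajectory.time_s,
            "position_cm": bundle.trajectory.position_cm,
            "trial_index": bundle.trajectory.trial_index,
        }
    ).to_csv(directory / "trajectory.csv", index=False)
    rows = [
        {"unit_id": uid, "time_s": t}
        for uid in sorted(bundle.spikes)
        for t in np.asarray(bundle.spikes[uid], dtype=float)
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
        directory / "spikes.csv", index=False
    )
    if bundle.events:
        (directory / "events.json").write_text(
            json.dumps([e.to_dict() for e in bundle.events], indent=1)
        )
    if bundle.probe is not None:
        (directory / "probe.json").write_text(
            json.dumps(bundle.probe.to_dict(), indent=1)
        )
    if bundle.amplitudes is not None:
        pd.DataFrame(
            [
                {"unit_id": uid, "site_id": site, "amplitude_uv": amp}
                for uid, sites in sorted(bundle.amplitudes.items())
                for site, amp in sites.items()
            ]
        ).to_csv(directory / "amplitudes.csv", index=False)
    if bundle.ripple_power is not None:
        pd.DataFrame(
            [
                {"shank_id": shank, "site_id": site, "power": p}
                for shank, sites in sorted(bundle.ripple_power.items())
                for site, p in sites.items()
            ]
        ).to_csv(directory / "ripple_power.csv", index=False)
    if bundle.ground_truth is not None:
        (directory / "ground_truth.json").write_text(
            json.dumps([u.to_dict() for u in bundle.ground_truth], indent=1)
        )
    return directory


def _read_csv(path, required_columns):
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"{path.name}: cannot parse ({exc})") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    bad = df[required_columns].isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.values)[0]) + 2  # header + 1-based
        raise ValueError(f"{path.name}: malformed row at line {line} (missing value)")
    return df


def load_session(directory) -> SessionBundle:
    """Load and validate a session directory (see module docstring)."""
    directory = Path(directory)
    for name in ("belt.json", "trajectory.csv", "spikes.csv"):
        if not (directory / name).exists():
            raise ValueError(f"required file missing: {name}")
    belt = BeltLayout.from_dict(json.loads((directory / "belt.json").read_text()))
    tdf = _read_csv(directory / "trajectory.csv", ["time_s", "position_cm", "trial_index"])
    trajectory = Trajectory.from_samples(
        tdf["time_s"].to_numpy(),
        tdf["position_cm"].to_numpy(),
        tdf["trial_index"].to_numpy(),
        belt.length_cm,
    )
    sdf = _read_csv(directory / "spikes.csv", ["unit_id", "time_s"])
    spikes = {
        str(uid): np.sort(grp["time_s"].to_numpy(dtype=float))
        for uid, grp in sdf.groupby("unit_id")
    }

    events = ()
    if (directory / "events.json").exists():
        events = tuple(
            ManipulationEvent.from_dict(e)
            for e in json.loads((directory / "events.json").read_text())
        )
    probe = None
    if (directory / "probe.json").exists():
        probe = ProbeGeometry.from_dict(
            json.loads((directory / "probe.json").read_text())
        )
    else:
        logger.warning("probe.json missing: localization disabled")
    amplitudes = None
    if (directory / "amplitudes.csv").exists():
        adf = _read_csv(directory / "amplitudes.csv", ["unit_id", "site_id", "amplitude_uv"])
        amplitudes = {
            str(uid): dict(zip(grp["site_id"].astype(str), grp["amplitude_uv"]))
            for uid, grp in adf.groupby("unit_id")
        }
    ripple_power = None
    if (directory / "ripple_power.csv").exists():
        rdf = _read_csv(directory / "ripple_power.csv", ["shank_id", "site_id", "power"])
        ripple_power = {
            str(shank): dict(zip(grp["site_id"].astype(str), grp["power"]))
            for shank, grp in rdf.groupby("shank_id")
        }
    ground_truth = None
    if (directory / "ground_truth.json").exists():
        ground_truth = [
            synth.GroundTruthUnit.from_dict(u)
            for u in json.loads((directory / "ground_truth.json").read_text())
        ]
    return SessionBundle(
        belt=belt,
        trajectory=trajectory,
        spikes=spikes,
        events=events,
        probe=probe,
        amplitudes=amplitudes,
        ripple_power=ripple_power,
        ground_truth=ground_truth,
    ).validate()


def run_pipeline(bundle: SessionBundle, config: AnalysisConfig, outdir, stages=None):
    """Run ratemaps -> fields -> classify -> identity -> dynamics ->
    localize -> report, writing one CSV per stage plus ``manifest.json``.

    Stages may be restricted (each stage's in-memory prerequisites are
    computed regardless; only the outputs are restricted). Identical
    (bundle, config) inputs give byte-identical CSV bodies.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = set(PIPELINE_STAGES if stages is None else stages)
    unknown = stages - set(PIPELINE_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    cfg = config
    results = {}

    unit_ids = bundle.unit_ids
    occupancy = ratemaps.compute_occupancy(bundle.trajectory, cfg.n_pixels)
    maps = {
        uid: ratemaps.compute_rate_map(
            bundle.spikes[uid],
            bundle.trajectory,
            bundle.belt,
            smoothing_fwhm_cm=cfg.smoothing_fwhm_cm,
            n_pixels=cfg.n_pixels,
            occupancy=occupancy,
        )
        for uid in unit_ids
    }
    results["ratemaps"] = maps
    if "ratemaps" in stages:
        rows = []
        for uid in unit_ids:
            m = maps[uid]
            for px in range(cfg.n_pixels):
                rows.append(
                    (uid, px, m.rates_hz[px], m.rates_raw_hz[px], m.occupancy_s[px])
                )
        pd.DataFrame(
            rows,
            columns=["unit_id", "pixel", "rate_hz_smoothed", "rate_hz_raw", "occupancy_s"],
        ).to_csv(outdir / "ratemaps.csv", index=False, float_format="%.6g")

    needs_fields = stages & {"fields", "classify", "identity", "dynamics", "report"}
    ensembles, unit_fields = {}, {}
    if needs_fields:
        for uid in unit_ids:
            ensembles[uid] = fields.build_null_ensemble(
                bundle.spikes[uid],
                bundle.trajectory,
                n_shuffles=cfg.n_shuffles_fields,
                seed=cfg.master_seed,
                unit_key=uid,
                smoothing_fwhm_cm=cfg.smoothing_fwhm_cm,
                n_pixels=cfg.n_pixels,
                occupancy=occupancy,
            )
            unit_fields[uid] = fields.detect_fields(
                maps[uid], ensembles[uid], alpha=cfg.alpha_pixel, min_run=cfg.min_run_pixels
            )
        results["fields"] = unit_fields
    if "fields" in stages:
        rows = []
        for uid in unit_ids:
            for k, f in enumerate(unit_fields[uid]):
                rows.append(
                    (uid, k, f.start_px, (f.start_px + f.n_px - 1) % cfg.n_pixels,
                     f.peak_hz, f.peak_position_cm, f.com_cm, f.width10_cm, f.min_p)
                )
        pd.DataFrame(
            rows,
            columns=["unit_id", "field_id", "start_px", "end_px", "peak_hz",
                     "peak_cm", "com_cm", "width10_cm", "min_p"],
        ).to_csv(outdir / "fields.csv", index=False, float_format="%.6g")

    classifications = {}
    if stages & {"classify", "identity", "report"}:
        template = landmarks.belt_template(bundle.belt, cfg.n_pixels)
        has_landmarks = template.std() > 0
        for uid in unit_ids:
            if has_landmarks:
                null_scores = landmarks.landmark_scores(
                    ensembles[uid].maps_hz, template
                )
                classifications[uid] = landmarks.classify_cell(
                    unit_fields[uid], maps[uid], template, null_scores
                )
            else:
                n_f = len(unit_fields[uid])
                classifications[uid] = landmarks.CellClassification(
                    label="non_place" if n_f == 0 else ("CM" if n_f == 1 else
                                                        "multi_field_unclassified"),
                    landmark_score=0.0,
                    score_threshold_95=np.nan,
                    n_fields=n_f,
                )
        results["classify"] = classifications
    if "classify" in stages:
        pd.DataFrame(
            [
                (uid, c.label, c.n_fields, c.landmark_score, c.score_threshold_95)
                for uid, c in sorted(classifications.items())
            ],
            columns=["unit_id", "label", "n_fields", "landmark_score", "threshold95"],
        ).to_csv(outdir / "classification.csv", index=False, float_format="%.6g")
        # field-to-landmark distances for place fields
        rows = []
        if bundle.belt.landmarks:
            for uid in unit_ids:
                for k, f in enumerate(unit_fields[uid]):
                    d, lm = landmarks.field_to_landmark_distance(f, bundle.belt)
                    rows.append((uid, k, d, lm.type_label))
        pd.DataFrame(
            rows, columns=["unit_id", "field_id", "distance_cm", "landmark_type"]
        ).to_csv(outdir / "distances.csv", index=False, float_format="%.6g")

    if "identity" in stages and len(bundle.belt.type_labels) == 2:
        lv_units = [
            uid for uid in unit_ids if classifications[uid].label == "LV"
        ]
        cells = []
        for uid in lv_units:
            by_type = {t: [] for t in bundle.belt.type_labels}
            for f in unit_fields[uid]:
                _, lm = landmarks.field_to_landmark_distance(f, bundle.belt)
                by_type[lm.type_label].append(f.peak_hz)
            cells.append(by_type)
        if cells:
            id_results, _thr = landmarks.identity_index_test(
                cells, n_shuffles=cfg.n_shuffles_identity, seed=cfg.master_seed
            )
            pd.DataFrame(
                [
                    (uid, r.index, r.dominant_type, r.secondary_type, r.significant)
                    for uid, r in zip(lv_units, id_results)
                ],
                columns=["unit_id", "index", "dominant_type", "secondary_type",
                         "significant"],
            ).to_csv(outdir / "identity.csv", index=False, float_format="%.6g")
            results["identity"] = dict(zip(lv_units, id_results))

    if "dynamics" in stages and bundle.events:
        event = bundle.events[0]
        matrices = {
            uid: ratemaps.compute_trial_rate_matrix(
                bundle.spikes[uid],
                bundle.trajectory,
                bundle.belt,
                smoothing_fwhm_cm=cfg.smoothing_fwhm_cm,
                n_pixels=cfg.n_pixels,
            )
            for uid in unit_ids
        }
        tc = dynamics.manipulation_window_timecourse(
            [matrices[uid] for uid in unit_ids],
            bundle.belt_post
            if bundle.belt_post is not None and event.action == "add"
            else bundle.belt,
            event,
            alpha=cfg.alpha_trial,
            window_cm=cfg.window_cm,
            flank_cm=cfg.flank_cm,
        )
        rows = []
        for i, uid in enumerate(unit_ids):
            for t in range(tc.rates_hz.shape[1]):
                rows.append((uid, t, tc.rates_hz[i, t], bool(tc.significant[t])))
        pd.DataFrame(
            rows, columns=["unit_id", "trial", "window_rate_hz", "significant"]
        ).to_csv(outdir / "dynamics.csv", index=False, float_format="%.6g")
        n_trials = next(iter(matrices.values())).n_trials
        if event.at_trial + cfg.ref_trials[1] < n_trials:
            pv = dynamics.population_vector_timecourse(
                [matrices[uid] for uid in unit_ids],
                tc.window_px,
                event_trial=event.at_trial,
                ref_trials=cfg.ref_trials,
            )
            pd.DataFrame({"trial": np.arange(pv.size), "correlation": pv}).to_csv(
                outdir / "pv.csv", index=False, float_format="%.6g"
            )
        results["dynamics"] = tc

    if "localize" in stages and bundle.probe is not None and bundle.amplitudes:
        site_of_unit = {}
        positions = []
        for uid in sorted(bundle.amplitudes):
            amps = bundle.amplitudes[uid]
            shank_id = _shank_of_sites(bundle.probe, amps)
            ids, coords = bundle.probe.site_array(shank_id)
            a = np.array([amps[str(s)] if str(s) in amps else amps[s] for s in ids])
            up = localization.localize_unit(
                coords,
                a,
                resolution_um=cfg.resolution_um,
                exponent=cfg.exponent,
                shank_id=shank_id,
            )
            site_of_unit[uid] = up
            positions.append(up)
        if bundle.ripple_power:
            localization.assign_relative_depths(
                positions, bundle.probe, bundle.ripple_power
            )
        pd.DataFrame(
            [
                (uid, *site_of_unit[uid].position_um, site_of_unit[uid].objective_S,
                 site_of_unit[uid].depth_rel_ripple_um)
                for uid in sorted(site_of_unit)
            ],
            columns=["unit_id", "x_um", "y_um", "z_um", "S", "depth_rel_um"],
        ).to_csv(outdir / "positions.csv", index=False, float_format="%.8g")
        results["localize"] = site_of_unit

    if "report" in stages:
        report = {"n_units": len(unit_ids)}
        if classifications:
            counts = {}
            for c in classifications.values():
                counts[c.label] = counts.get(c.label, 0) + 1
            report["label_counts"] = counts
        if bundle.ground_truth is not None and classifications:
            truth = {u.unit_id: u.kind for u in bundle.ground_truth}
            confusion = {}
            for uid, c in classifications.items():
                key = f"{truth.get(uid, '?')}|{c.label}"
                confusion[key] = confusion.get(key, 0) + 1
            report["confusion_true_vs_label"] = confusion
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        results["report"] = report

    manifest = {
        "config": cfg.to_dict(),
        "stages": sorted(stages),
        "n_units": len(unit_ids),
        "n_trials": bundle.trajectory.n_trials,
        "belt_length_cm": bundle.belt.length_cm,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return results


def _shank_of_sites(probe, amps):
    """Shank whose site ids cover the amplitude keys."""
    keys = {str(k) for k in amps}
    for shank_id, sites in probe.shanks.items():
        if keys <= {str(s) for s in sites}:
            return shank_id
    raise ValueError(f"no shank matches amplitude site ids {sorted(keys)[:5]}...")
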