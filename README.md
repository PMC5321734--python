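# beltfield

Analysis toolkit for hippocampal place-cell recordings from head-fixed mice
running on a circular treadmill belt, together with a ground-truthed session
simulator for validating every stage of the analysis.

The pipeline covers:

- **Rate maps** — 100-pixel occupancy-normalized firing-rate vectors,
  whole-session and per-trial, circularly smoothed with a 15 cm-FWHM
  Gaussian (`beltfield.ratemaps`).
- **Place-field detection** — per-pixel significance against 1,000 circular
  spike-time rotations; fields are maximal circular runs of ≥ 5 pixels with
  p < 0.01, with peak, circular centre of mass and 10%-edges width
  (`beltfield.fields`).
- **Landmark analysis** — landmark score (max circular-lag correlation with
  the belt template), LV / CM classification against a shuffle threshold,
  field-to-landmark distances, identity-index permutation test and saliency
  repartition (`beltfield.landmarks`).
- **Remapping dynamics** — background-subtracted window timecourses around
  manipulated landmarks, population-vector correlation, switching-onset
  estimation and robust field-drift tracking (`beltfield.dynamics`).
- **Unit localization** — inverse-square soma estimation from per-site spike
  amplitudes on a 1 µm grid, depths relative to the ripple-power peak, and
  pairwise depth contrasts (`beltfield.localization`).
- **Simulation** — belts, log-normal AR(1) trajectories, inhomogeneous
  Poisson spike trains (by thinning) for LV / CM / drifting / switching /
  untuned units, landmark add/remove manipulations, and probe observations
  with 1/d² amplitude attenuation (`beltfield.synth`).

## CLI

Simulate a ground-truthed session, analyze it, and inspect the report:

```bash
beltfield simulate --config cfg.json --out session/ --seed 1
beltfield analyze --session session/ --out results/ --seed 1 \
    --stages ratemaps,fields,classify,identity,dynamics,localize,report
beltfield report --out results/
```

`cfg.json` describes the belt (landmark types/positions), trajectory
(trials, speed statistics), units (kind and generating parameters), optional
manipulation events and probe geometry; see
`tests/test_io_cli.py::demo_config` for a complete example. Session
directories and results are plain text (CSV/JSON) throughout.

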