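import numpy as np
import pytest

from beltfield import build_belt, simulate_trajectory
from beltfield.belt import Landmark, ManipulationEvent
from beltfield.localization import ProbeGeometry
from beltfield.ratemaps import compute_rate_map
from beltfield.synth import (
    GroundTruthUnit,
    apply_landmark_manipulation,
    resolve_fields,
    simulate_probe_observations,
    simulate_spike_trains,
    unit_rate,
)


class TestGroundTruthUnit:
    def test_drift_only_for_drifting(self):
        with pytest.raises(ValueError, match="drift"):
            GroundTruthUnit("u", "CM", field_center_cm=50, drift_cm_per_trial=0.1)

    def test_lv_needs_anchor(self):
        with pytest.raises(ValueError, match="anchored"):
            GroundTruthUnit("u", "LV")

    def test_cm_needs_center(self):
        with pytest.raises(ValueError, match="field_center_cm"):
            GroundTruthUnit("u", "CM")

    def test_round_trip(self):
        u = GroundTruthUnit(
            "u", "LV", offset_cm=-8, anchor_types=("spine", "tube"),
            identity_weights={"tube": 0.5},
        )
        assert GroundTruthUnit.from_dict(u.to_dict()) == u


class TestResolveFields:
    def test_lv_one_field_per_instance(self, mixed_belt):
        u = GroundTruthUnit(
            "u", "LV", offset_cm=-5, anchor_types=("spine", "tube"),
            identity_weights={"spine": 1.0, "tube": 0.5}, peak_hz=6.0,
        )
        fields = resolve_fields(u, mixed_belt)
        assert len(fields) == 4
        centers = sorted(f.center_cm for f in fields)
        assert np.allclose(centers, [15, 65, 115, 165])
        peaks = sorted(f.peak_hz for f in fields)
        assert np.allclose(peaks, [3, 3, 6, 6])

    def test_missing_anchor_type_rejected(self, two_spine_belt):
        u = GroundTruthUnit("u", "LV", anchor_types=("velcro",))
        with pytest.raises(ValueError, match="velcro"):
            resolve_fields(u, two_spine_belt)

    def test_untuned_has_no_fields(self, two_spine_belt):
        u = GroundTruthUnit("u", "untuned")
        assert resolve_fields(u, two_spine_belt) == ()

    def test_switching_gated(self, two_spine_belt):
        u = GroundTruthUnit("u", "switching", field_center_cm=100, onset_trial=30)
        (f,) = resolve_fields(u, two_spine_belt)
        assert f.active_from == 30


class TestSpikeSimulation:
    def test_untuned_poisson_count(self, two_spine_belt):
        traj = simulate_trajectory(
            two_spine_belt, 45, mean_speed_cmps=15, speed_cv=0.0, seed=2
        )
        assert traj.duration_s == pytest.approx(600, rel=0.01)
        u = GroundTruthUnit("u", "untuned", background_hz=2.0)
        spikes, _, _ = simulate_spike_trains(two_spine_belt, traj, [u], seed=4)
        mean = 2.0 * traj.duration_s
        band = 2.58 * np.sqrt(mean)  # 99% Poisson band
        assert abs(spikes["u"].size - mean) < band

    def test_lv_peaks_at_offset_positions(self, two_spine_belt, lv_session):
        # long simulation: empirical peaks within 1 pixel of start - 5 cm
        traj = simulate_trajectory(two_spine_belt, 100, seed=12345)
        m = compute_rate_map(lv_session, traj)
        for start in (40, 140):
            expect_px = int(((start - 5) % 200) // 2)
            local = [(m.rates_hz[(expect_px + k) % 100], (expect_px + k) % 100)
                     for k in range(-10, 11)]
            best_px = max(local)[1]
            assert abs(best_px - expect_px) <= 1

    def test_switching_silent_before_onset(self, two_spine_belt):
        traj = simulate_trajectory(two_spine_belt, 60, seed=4)
        u = GroundTruthUnit(
            "u", "switching", background_hz=0.5, peak_hz=6, field_center_cm=100,
            onset_trial=30,
        )
        spikes, _, _ = simulate_spike_trains(two_spine_belt, traj, [u], seed=5)
        t_onset = traj.trial_bounds_s()[30, 0]
        pre = spikes["u"][spikes["u"] < t_onset]
        # pre-onset activity is pure background
        expected = 0.5 * (t_onset - traj.time_s[0])
        assert abs(pre.size - expected) < 4 * np.sqrt(expected)

    def test_determinism_and_order_independence(self, two_spine_belt, trajectory):
        u1 = GroundTruthUnit("a", "CM", field_center_cm=30)
        u2 = GroundTruthUnit("b", "CM", field_center_cm=90)
        s12, _, _ = simulate_spike_trains(two_spine_belt, trajectory, [u1, u2], seed=9)
        s21, _, _ = simulate_spike_trains(two_spine_belt, trajectory, [u2, u1], seed=9)
        assert np.array_equal(s12["a"], s21["a"])
        assert np.array_equal(s12["b"], s21["b"])

    def test_rate_map_converges_to_generator(self, two_spine_belt):
        # empirical map from a long session approaches the planted rate
        traj = simulate_trajectory(two_spine_belt, 200, speed_cv=0.0, seed=6)
        u = GroundTruthUnit("u", "CM", background_hz=1.0, peak_hz=6.0,
                            field_center_cm=100, fwhm_cm=30)
        spikes, _, fields = simulate_spike_trains(two_spine_belt, traj, [u], seed=7)
        m = compute_rate_map(spikes["u"], traj, smoothing_fwhm_cm=4.0)
        truth = unit_rate(fields["u"], 1.0, m.pixel_centers_cm, 0, 200.0)
        assert np.max(np.abs(m.rates_hz - truth)) < 0.1 * (6.0 + 1.0)


class TestManipulation:
    def make(self, belt):
        lv = GroundTruthUnit("lv", "LV", offset_cm=-5, anchor_types=("spine",),
                             peak_hz=6.0)
        untuned = GroundTruthUnit("bg", "untuned", background_hz=2.0)
        return [lv, untuned]

    def test_add_creates_field_at_event_trial(self, two_spine_belt):
        units = self.make(two_spine_belt)
        ev = ManipulationEvent("add", Landmark("spine", 90, 10), at_trial=20)
        belt2, fields = apply_landmark_manipulation(two_spine_belt, units, ev)
        assert len(belt2.landmarks) == 3
        new = [f for f in fields["lv"] if f.active_from == 20]
        assert len(new) == 1
        assert new[0].center_cm == pytest.approx(85)
        assert new[0].peak_hz == 6.0  # same peak as pre-existing fields
        # rate at the new center switches on exactly at trial 20
        r19 = unit_rate(fields["lv"], 0.5, np.array([85.0]), 19, 200.0)
        r20 = unit_rate(fields["lv"], 0.5, np.array([85.0]), 20, 200.0)
        assert r19[0] == pytest.approx(0.5 + 6.0 * np.exp(-0.5 * (50 / (18.7 / 2.355)) ** 2), abs=0.01)
        assert r20[0] == pytest.approx(0.5 + 6.0, rel=0.05)

    def test_remove_zeroes_that_instance_only(self, two_spine_belt):
        units = self.make(two_spine_belt)
        ev = ManipulationEvent("remove", Landmark("spine", 140, 10), at_trial=15)
        belt2, fields = apply_landmark_manipulation(two_spine_belt, units, ev)
        assert len(belt2.landmarks) == 1
        r_removed_pre = unit_rate(fields["lv"], 0.0, np.array([135.0]), 14, 200.0)
        r_removed_post = unit_rate(fields["lv"], 0.0, np.array([135.0]), 15, 200.0)
        r_kept_post = unit_rate(fields["lv"], 0.0, np.array([35.0]), 15, 200.0)
        assert r_removed_pre[0] == pytest.approx(6.0)
        assert r_removed_post[0] < 0.1
        assert r_kept_post[0] == pytest.approx(6.0)  # other instance unchanged

    def test_remove_nonexistent_rejected(self, two_spine_belt):
        units = self.make(two_spine_belt)
        ev = ManipulationEvent("remove", Landmark("spine", 77, 10), at_trial=5)
        with pytest.raises(ValueError, match="no landmark"):
            apply_landmark_manipulation(two_spine_belt, units, ev)

    def test_untuned_unaffected(self, two_spine_belt):
        units = self.make(two_spine_belt)
        ev = ManipulationEvent("add", Landmark("spine", 90, 10), at_trial=20)
        _, fields = apply_landmark_manipulation(two_spine_belt, units, ev)
        assert fields["bg"] == ()


class TestProbeObservations:
    @pytest.fixture()
    def probe(self):
        sites = {f"s{i}": np.array([0.0, (i % 2) * 20.0, i * 20.0]) for i in range(8)}
        return ProbeGeometry({"shank0": sites})

    def test_equidistant_sites_equal_amplitudes(self, probe):
        u = GroundTruthUnit("u", "untuned", true_position_um=(20, 10, 70),
                            shank_id="shank0")
        amps, _ = simulate_probe_observations([u], probe, noise_frac=0.0, seed=0)
        a = amps["u"]
        # sites s3 (0,20,60) and s4 (0,0,80) are equidistant from (20,10,70)
        assert a["s3"] == pytest.approx(a["s4"])

    def test_inverse_square_law(self, probe):
        near = GroundTruthUnit("n", "untuned", true_position_um=(10, 10, 70),
                               shank_id="shank0")
        far = GroundTruthUnit("f", "untuned", true_position_um=(20, 20, 140),
                              shank_id="shank0")
        amps, _ = simulate_probe_observations([near, far], probe, noise_frac=0.0, seed=0)
        # doubling every distance divides amplitudes by 4: compare explicitly
        ids, coords = probe.site_array("shank0")
        d_near = np.linalg.norm(coords - np.array([10, 10, 70.0]), axis=1)
        for sid, d in zip(ids, d_near):
            assert amps["n"][sid] == pytest.approx(5e6 / d**2)

    def test_ripple_profile_peaks_at_requested_depth(self, probe):
        _, power = simulate_probe_observations(
            [], probe, ripple_peak_depth_um=100.0, seed=0
        )
        sites = power["shank0"]
        assert max(sites, key=sites.get) == "s5"  # depth 100

    def test_soma_on_site_rejected(self, probe):
        u = GroundTruthUnit("u", "untuned", true_position_um=(0, 0, 0),
                            shank_id="shank0")
        with pytest.raises(ValueError, match="coincides"):
            simulate_probe_observations([u], probe, seed=0)

    def test_noise_truncation_keeps_amplitudes_positive(self, probe):
        u = GroundTruthUnit("u", "untuned", true_position_um=(20, 10, 70),
                            shank_id="shank0")
        amps, _ = simulate_probe_observations([u], probe, noise_frac=2.0, seed=1)
        assert all(v > 0 for v in amps["u"].values())
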