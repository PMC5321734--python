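import numpy as np
import pytest

from beltfield import build_belt
from beltfield.belt import Landmark, ManipulationEvent
from beltfield.dynamics import (
    cross_belt_compare,
    detect_switching,
    landmark_window_pixels,
    manipulation_window_timecourse,
    population_vector_timecourse,
    rate_overlap,
    track_field_drift,
)
from beltfield.fields import PlaceField
from beltfield.ratemaps import TrialRateMatrix


def make_matrix(rates):
    rates = np.asarray(rates, dtype=float)
    return TrialRateMatrix(
        rates_hz=rates, rates_raw_hz=rates, counts=rates,
        occupancy_s=np.ones_like(rates), pixel_size_cm=2.0, smoothing_fwhm_cm=15.0,
    )


def gaussian_rows(centers_cm, peak=6.0, fwhm=20.0, n_px=100, delta=2.0):
    x = (np.arange(n_px) + 0.5) * delta
    L = n_px * delta
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    rows = []
    for c in centers_cm:
        d = np.abs(x - c) % L
        d = np.minimum(d, L - d)
        rows.append(peak * np.exp(-0.5 * (d / sigma) ** 2))
    return np.array(rows)


class TestRateOverlap:
    @pytest.mark.parametrize("a,b,expected", [(4, 8, 0.5), (5, 5, 1.0), (0, 5, 0.0)])
    def test_values(self, a, b, expected):
        assert rate_overlap(a, b) == pytest.approx(expected)

    def test_symmetric(self):
        assert rate_overlap(3, 7) == rate_overlap(7, 3)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            rate_overlap(0, 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            rate_overlap(-1, 3)


class TestCrossBeltCompare:
    def test_identical_sessions_correlate_perfectly(self):
        a = {f"u{i}": {"peak_hz": float(i + 1)} for i in range(10)}
        table = cross_belt_compare({"A": a, "A2": dict(a)})
        pa = [table[u]["peak_hz_A"] for u in sorted(table)]
        pb = [table[u]["peak_hz_A2"] for u in sorted(table)]
        assert np.corrcoef(pa, pb)[0, 1] == pytest.approx(1.0)

    def test_unmatched_units_excluded_with_warning(self):
        a = {"u1": {"x": 1.0}, "u2": {"x": 2.0}}
        b = {"u1": {"x": 3.0}}
        with pytest.warns(UserWarning, match="u2"):
            table = cross_belt_compare({"A": a, "B": b})
        assert list(table) == ["u1"]


class TestWindowTimecourse:
    def setup_method(self):
        self.belt = build_belt(200, [("spine", 95, 10)])
        self.event = ManipulationEvent("add", Landmark("spine", 95, 10), at_trial=5)

    def test_window_and_flank_geometry(self):
        window, flanks = landmark_window_pixels(200.0, 100, Landmark("spine", 95, 10))
        assert window.size == 15  # 30 cm on 2 cm pixels
        assert flanks.size == 15  # 2 x 15 cm, 7.5 px each
        assert set(window) & set(flanks) == set()

    def test_uniform_rate_cancels_exactly(self):
        mats = [make_matrix(np.full((20, 100), c)) for c in (1.0, 3.5, 7.0)]
        tc = manipulation_window_timecourse(mats, self.belt, self.event)
        assert np.allclose(tc.rates_hz, 0.0, atol=1e-12)

    def test_field_at_landmark_positive(self):
        rows = gaussian_rows([100.0] * 20)
        mats = [make_matrix(rows)] * 5
        tc = manipulation_window_timecourse(mats, self.belt, self.event)
        assert np.all(tc.rates_hz > 0)
        assert tc.significant.all()

    def test_window_too_wide_rejected(self):
        belt = build_belt(100, [("spine", 45, 10)])
        ev = ManipulationEvent("add", Landmark("spine", 45, 10), 2)
        mats = [make_matrix(np.ones((5, 100)))] * 2
        with pytest.raises(ValueError, match="half the belt"):
            manipulation_window_timecourse(mats, belt, ev)

    def test_sign_test_below_five_cells(self):
        rng = np.random.default_rng(0)
        mats = [make_matrix(rng.uniform(0, 1, (10, 100))) for _ in range(3)]
        tc = manipulation_window_timecourse(mats, self.belt, self.event)
        assert tc.used_sign_test

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError, match=">= 2 cells"):
            manipulation_window_timecourse(
                [make_matrix(np.ones((5, 100)))], self.belt, self.event
            )


class TestPopulationVector:
    def test_identical_trials_correlate_one(self):
        rng = np.random.default_rng(1)
        row = rng.uniform(0, 5, 100)
        mats = [make_matrix(np.tile(row * (c + 1), (90, 1))) for c in range(3)]
        pv = population_vector_timecourse(mats, np.arange(40, 55), 0, (40, 80))
        assert np.allclose(pv, 1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(2)
        mats = [make_matrix(rng.uniform(0, 5, (100, 100))) for _ in range(4)]
        pv = population_vector_timecourse(mats, np.arange(40, 55), 0, (40, 80))
        outside_ref = np.concatenate([pv[:40], pv[81:]])
        assert abs(np.nanmean(outside_ref)) < 0.15

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 5, (90, 100))
        pv1 = population_vector_timecourse(
            [make_matrix(base), make_matrix(base[::-1])], np.arange(30, 45), 0, (40, 80)
        )
        pv2 = population_vector_timecourse(
            [make_matrix(base + 7.0), make_matrix(base[::-1] + 7.0)],
            np.arange(30, 45), 0, (40, 80),
        )
        assert np.allclose(pv1, pv2, atol=1e-9)

    def test_reference_beyond_session_rejected(self):
        mats = [make_matrix(np.ones((50, 100)))] * 2
        with pytest.raises(ValueError, match="reference"):
            population_vector_timecourse(mats, np.arange(10), 0, (40, 80))


class TestDriftTracking:
    def _field(self, com_cm):
        return PlaceField(int(com_cm // 2) - 5, 11, 6.0, com_cm, com_cm, 40.0)

    def test_planted_negative_drift_recovered(self):
        centers = 100.0 - 0.2 * np.arange(100)
        track = track_field_drift(make_matrix(gaussian_rows(centers)), self._field(100))
        assert track.is_drifting
        assert track.direction == "backward"
        assert track.drift_rate_cm_per_trial == pytest.approx(-0.2, abs=0.02)

    def test_positive_drift_forward_label(self):
        centers = (50.0 + 0.2 * np.arange(100)) % 200
        track = track_field_drift(make_matrix(gaussian_rows(centers)), self._field(50))
        assert track.direction == "forward"

    def test_stationary_not_drifting(self):
        track = track_field_drift(
            make_matrix(gaussian_rows([80.0] * 60)), self._field(80)
        )
        assert not track.is_drifting and track.direction == "stationary"

    def test_drift_through_wrap_unwrapped(self):
        centers = (10.0 - 0.5 * np.arange(100)) % 200
        track = track_field_drift(make_matrix(gaussian_rows(centers)), self._field(10))
        assert track.drift_rate_cm_per_trial == pytest.approx(-0.5, abs=0.05)
        assert track.span_cm == pytest.approx(0.5 * 99, rel=0.1)

    def test_empty_trials_carried_forward(self):
        rows = gaussian_rows([100.0] * 30)
        rows[10:13] = 0.0
        track = track_field_drift(make_matrix(rows), self._field(100))
        assert track.carried_forward[10:13].all()
        assert not track.is_drifting


class TestDetectSwitching:
    def setup_method(self):
        self.event = ManipulationEvent("add", Landmark("spine", 95, 10), at_trial=20)

    def _post_field(self):
        return PlaceField(45, 10, 6.0, 100.0, 100.0, 30.0)

    def test_step_at_event_gives_onset_one(self):
        rows = np.vstack(
            [np.zeros((20, 100)), gaussian_rows([100.0] * 60)]
        )
        onset = detect_switching(make_matrix(rows), self.event, [self._post_field()])
        assert onset == 1

    def test_delayed_step_onset(self):
        rows = np.vstack(
            [np.zeros((30, 100)), gaussian_rows([100.0] * 50)]
        )
        onset = detect_switching(make_matrix(rows), self.event, [self._post_field()])
        assert onset == 11  # field turns on 10 trials after the event

    def test_pre_existing_field_not_switching(self):
        rows = gaussian_rows([100.0] * 80)
        pre = [self._post_field()]
        onset = detect_switching(
            make_matrix(rows), self.event, [self._post_field()], fields_pre=pre
        )
        assert onset is None

    def test_no_post_field_returns_none(self):
        rows = np.zeros((80, 100))
        assert detect_switching(make_matrix(rows), self.event, []) is None

    def test_short_post_session_warns(self):
        rows = np.vstack([np.zeros((20, 100)), gaussian_rows([100.0] * 10)])
        with pytest.warns(UserWarning, match="post-event"):
            onset = detect_switching(make_matrix(rows), self.event, [self._post_field()])
        assert onset == 1
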