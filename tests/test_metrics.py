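"""Rate smoothing, bump decoding and the categorical trial criteria."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cxring import lif, metrics
from cxring.metrics import (UndefinedHeadingError, classify_transition,
                            decode_heading, decode_heading_wta, heading_error,
                            profile_fwhm, shortest_angular_distance,
                            smooth_rates, transition_time, trial_stability)


def _raster(spikes, dt=1e-4):
    return lif.SpikeRaster(spikes=np.asarray(spikes, bool), dt=dt)


class TestSmoothing:
    def test_empty_raster_zero_rates(self):
        trace = smooth_rates(_raster(np.zeros((3, 5000))))
        assert np.all(trace.rates == 0)

    def test_single_spike_integrates_to_one(self):
        spk = np.zeros((1, 10000), bool)
        spk[0, 5000] = True
        trace = smooth_rates(_raster(spk))
        assert trace.rates[0].sum() * trace.dt == pytest.approx(1.0, rel=1e-3)

    def test_regular_train_plateau(self):
        spk = np.zeros((1, 20000), bool)
        spk[0, ::100] = True   # 100 Hz at dt = 0.1 ms
        trace = smooth_rates(_raster(spk))
        mid = trace.rates[0, 5000:15000]
        assert np.median(mid) == pytest.approx(100.0, rel=0.02)

    def test_point_estimate_matches_full_convolution(self):
        rng = np.random.default_rng(3)
        spk = rng.random((4, 20000)) < 0.01
        raster = _raster(spk)
        trace = smooth_rates(raster)
        t = 1.2345
        point = metrics.rates_at(raster, t)
        full = trace.rates[:, trace.index_at(t)]
        assert np.allclose(point, full, rtol=1e-4, atol=1e-3)


class TestDecoding:
    def test_uniform_profile_undefined(self):
        with pytest.raises(UndefinedHeadingError):
            decode_heading(np.full(8, 7.0))

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedHeadingError):
            decode_heading(np.zeros(8))

    def test_single_active_octant(self):
        p = np.zeros(8)
        p[3] = 50.0
        assert decode_heading(p) == pytest.approx(135.0)
        fwhm, n_arcs = profile_fwhm(p)
        assert fwhm <= 45.0
        assert n_arcs == 1

    def test_wta_cross_check(self):
        p = np.array([0, 1, 5, 40, 40.5, 6, 1, 0.0])
        pv = decode_heading(p)
        wta = decode_heading_wta(p)
        assert shortest_angular_distance(abs(pv - wta) % 360) < 45.0

    @given(shift=st.integers(0, 7))
    @settings(max_examples=8, deadline=None)
    def test_equivariance_under_rotation(self, shift):
        p = np.array([0.0, 2.0, 10.0, 42.0, 30.0, 8.0, 1.0, 0.0])
        base = decode_heading(p)
        rotated = decode_heading(np.roll(p, shift))
        assert ((rotated - base) % 360.0) == pytest.approx(
            (45.0 * shift) % 360.0, abs=1e-9)

    def test_fwhm_matches_von_mises_closed_form(self):
        kappa = 0.75 * np.pi
        theta = np.deg2rad(metrics.octant_centres(8))
        # octant-centred bump: interpolation error < 3 deg; mid-octant
        # placement is the worst case for an 8-point grid (< 7 deg)
        for mu_deg, tol in ((90.0, 3.0), (112.5, 7.0)):
            p = np.exp(kappa * np.cos(theta - np.deg2rad(mu_deg)))
            level = (p.max() + p.min()) / 2.0
            d = np.arccos(np.log(level) / kappa)
            expected = np.degrees(2 * d)
            fwhm, _ = profile_fwhm(p)
            assert fwhm == pytest.approx(expected, abs=tol)

    def test_flat_profile_fwhm_nan(self):
        fwhm, n_arcs = profile_fwhm(np.full(8, 3.0))
        assert np.isnan(fwhm)


class TestAngularDistance:
    @pytest.mark.parametrize("angle,expected", [(120.0, 120.0), (200.0, 160.0),
                                                (180.0, 180.0), (0.0, 0.0),
                                                (360.0, 0.0)])
    def test_examples(self, angle, expected):
        assert shortest_angular_distance(angle) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            shortest_angular_distance(-5.0)

    @given(st.floats(0.0, 360.0))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_bounded(self, angle):
        d = shortest_angular_distance(angle)
        assert 0.0 <= d <= 180.0
        assert shortest_angular_distance(d) == d


class TestTransitionTime:
    def test_already_at_target(self):
        t = np.arange(0, 5, 0.01)
        h = np.full_like(t, 90.0)
        assert transition_time(t, h, 1.0, 90.0) == 0.0

    def test_step_response(self):
        t = np.arange(0, 6, 0.01)
        h = np.where(t < 2.5, 0.0, 90.0)
        assert transition_time(t, h, 1.0, 90.0) == pytest.approx(1.5, abs=0.02)

    def test_never_settles(self):
        t = np.arange(0, 5, 0.01)
        h = np.zeros_like(t)
        assert transition_time(t, h, 1.0, 180.0) == np.inf

    def test_onset_outside_series(self):
        with pytest.raises(ValueError):
            transition_time(np.arange(0, 1, 0.1), np.zeros(10), 5.0, 0.0)


class TestClassifyTransition:
    def _profiles(self, kind):
        # octant rate matrix over a transition from octant 1 to octant 4
        n, T = 8, 1000
        prof = np.zeros((n, T))
        ramp = np.linspace(1, 0, T)
        prof[1] = 100 * ramp
        prof[4] = 100 * (1 - ramp)
        if kind == "gradual":
            prof[2, 300:500] = 98.0
            prof[3, 500:700] = 97.0
        elif kind == "weak_path":
            prof[2, 300:500] = 30.0
            prof[3, 500:700] = 25.0
        return prof

    def test_travelling_bump_is_gradual(self):
        assert classify_transition(self._profiles("gradual"), 1, 4) == "gradual"

    def test_silent_path_is_jump(self):
        assert classify_transition(self._profiles("jump"), 1, 4) == "jump"

    def test_weak_path_is_jump(self):
        assert classify_transition(self._profiles("weak_path"), 1, 4) == "jump"

    def test_adjacent_move_gradual_by_convention(self):
        prof = np.zeros((8, 100))
        prof[1] = 50.0
        prof[2] = 50.0
        assert classify_transition(prof, 1, 2) == "gradual"

    def test_same_octant_rejected(self):
        with pytest.raises(ValueError):
            classify_transition(np.zeros((8, 10)), 3, 3)


class TestTrialStability:
    def test_perfect_hold(self):
        t = np.arange(0, 4, 0.01)
        assert trial_stability(t, np.full_like(t, 10.0), 10.0)

    def test_final_error_too_large(self):
        t = np.arange(0, 4, 0.01)
        assert not trial_stability(t, np.full_like(t, 60.0), 10.0)

    def test_bump_lost_during_hold(self):
        t = np.arange(0, 5, 0.01)
        h = np.full_like(t, 10.0)
        h[300:320] = np.nan
        assert not trial_stability(t, h, 10.0, hold_duration=3.0)

    def test_short_hold_insufficient(self):
        t = np.arange(0, 2, 0.01)
        assert not trial_stability(t, np.full_like(t, 0.0), 0.0,
                                   hold_duration=3.0)


class TestHeadingError:
    def test_wraps_circularly(self):
        assert heading_error(350.0, 10.0) == pytest.approx(20.0)
        assert np.isnan(heading_error(np.nan, 10.0))
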