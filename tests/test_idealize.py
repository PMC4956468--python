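import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatecycle import (
    AnalysisWindow,
    EventTable,
    GatingScheme,
    SimProtocol,
    count_channels,
    estimate_baseline,
    idealize_half_amplitude,
    impose_dead_time,
    refilter,
    select_window,
    simulate_path,
    superpose,
    synthesize_trace,
)
from gatecycle.simulate import CurrentTrace


def _trace(samples, fs=10000.0):
    return CurrentTrace(np.asarray(samples, float), dt=1.0 / fs)


class TestRefilter:
    def test_constant_trace_unchanged(self):
        tr = _trace(np.full(5000, -1.3))
        out = refilter(tr, 50.0)
        np.testing.assert_allclose(out.samples, -1.3, rtol=1e-9)

    def test_impulse_response_is_unit_sum_kernel(self):
        x = np.zeros(4001)
        x[2000] = 1.0
        out = refilter(_trace(x), 100.0)
        assert out.samples.sum() == pytest.approx(1.0, abs=1e-9)
        assert out.samples.max() < 1.0  # spread, not preserved

    def test_corner_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            refilter(_trace(np.zeros(100)), 6000.0)


class TestBaseline:
    def test_offset_recovered_from_shifted_trace(self):
        rng = np.random.default_rng(0)
        tr = _trace(1.0 + rng.normal(0, 0.1, 20000))
        off = estimate_baseline(tr, [(0.0, 1.0)])
        assert off == pytest.approx(1.0, abs=3 * 0.1 / np.sqrt(10000))

    def test_pooled_mean_of_two_windows(self):
        samples = np.concatenate([np.full(1000, 2.0), np.full(3000, 0.0)])
        tr = _trace(samples)
        # windows of 1000 samples each at means 2.0 and 0.0 -> pooled 1.0
        off = estimate_baseline(tr, [(0.0, 0.1), (0.1, 0.2)])
        assert off == pytest.approx(1.0)

    def test_empty_windows_rejected(self):
        with pytest.raises(ValueError):
            estimate_baseline(_trace(np.zeros(10)), [])


class TestHalfAmplitude:
    def test_noiseless_rectangular_pulse(self):
        i_unit = -0.64
        fs = 10000.0
        lv = np.concatenate([np.zeros(1000), np.ones(500), np.zeros(1000)])
        ev = idealize_half_amplitude(_trace(lv * i_unit, fs), i_unit, max_level=3)
        np.testing.assert_array_equal(ev.levels, [0, 1, 0])
        np.testing.assert_allclose(ev.dwells, [0.1, 0.05, 0.1])

    def test_two_channel_staircase(self):
        i_unit = -0.5
        lv = np.concatenate(
            [np.zeros(100), np.ones(100), np.full(100, 2), np.ones(100), np.zeros(100)]
        )
        ev = idealize_half_amplitude(_trace(lv * i_unit), i_unit, max_level=2)
        np.testing.assert_array_equal(ev.levels, [0, 1, 2, 1, 0])

    def test_event_durations_match_ground_truth_within_one_sample(self, no_flicker_scheme):
        proto = SimProtocol(
            n_channels=2,
            seg_durations=(("s", 20.0),),
            fs=10000.0,
            f_acq=3500.0,
            noise_sd=0.0,
            seed=9,
        )
        paths = [simulate_path(no_flicker_scheme, 20.0, seed=s) for s in (7, 8)]
        lp = superpose(paths)
        trace = synthesize_trace(lp, no_flicker_scheme, proto)
        ev = idealize_half_amplitude(trace, no_flicker_scheme.i_unit, max_level=2)
        np.testing.assert_array_equal(ev.levels, lp.levels)
        # each transition time may shift by at most one sampling interval
        true_edges = np.cumsum(lp.dwells)[:-1]
        est_edges = np.cumsum(ev.dwells)[:-1]
        assert np.max(np.abs(true_edges - est_edges)) <= 1.0 / proto.fs + 1e-9

    def test_idealization_idempotent_on_own_output(self):
        i_unit = -0.64
        rng = np.random.default_rng(5)
        levels = rng.integers(0, 5, 30)
        dwells = rng.uniform(0.01, 0.1, 30)
        ev = EventTable(levels, dwells)
        fs = 10000.0
        # once dwell durations are integer multiples of dt, a further
        # render->idealize cycle must be the identity
        rendered = ev.to_level_path().sample(fs) * i_unit
        ev2 = idealize_half_amplitude(_trace(rendered, fs), i_unit, max_level=4)
        rerendered = ev2.to_level_path().sample(fs) * i_unit
        ev3 = idealize_half_amplitude(_trace(rerendered, fs), i_unit, max_level=4)
        np.testing.assert_array_equal(ev2.levels, ev3.levels)
        # float jitter in cumulative start times may shift an edge by one sample
        np.testing.assert_allclose(
            np.cumsum(ev2.dwells), np.cumsum(ev3.dwells), atol=1.01 / fs
        )


class TestCountChannels:
    def test_max_simultaneous_level(self):
        ev = EventTable(np.array([0, 2, 3, 1]), np.array([1.0, 0.5, 0.2, 1.0]))
        assert count_channels(ev) == 3

    def test_silent_bracket_flagged(self):
        ev = EventTable(np.array([0]), np.array([10.0]))
        with pytest.warns(UserWarning, match="no active channels"):
            assert count_channels(ev) == 0

    def test_four_channels_at_high_po_all_detected(self):
        bracket = GatingScheme(1.0, 0.25, 1.0, 100.0)
        paths = [simulate_path(bracket, 30.0, seed=s) for s in range(4)]
        lp = superpose(paths)
        ev = EventTable(lp.levels, lp.dwells)
        assert count_channels(ev) == 4


class TestDeadTime:
    def test_no_short_events_unchanged(self):
        ev = EventTable(np.array([0, 1, 0]), np.array([0.1, 0.05, 0.2]))
        out = impose_dead_time(ev, 0.006)
        np.testing.assert_array_equal(out.levels, ev.levels)
        np.testing.assert_allclose(out.dwells, ev.dwells)
        assert out.dead_time == 0.006

    def test_short_gap_absorbed_and_neighbours_merged(self):
        ev = EventTable(np.array([0, 1, 0]), np.array([0.1, 0.003, 0.1]))
        out = impose_dead_time(ev, 0.006)
        np.testing.assert_array_equal(out.levels, [0])
        np.testing.assert_allclose(out.dwells, [0.203])

    def test_leading_short_event_absorbed_forward(self):
        ev = EventTable(np.array([1, 0, 1]), np.array([0.002, 0.1, 0.1]))
        out = impose_dead_time(ev, 0.006)
        assert out.total_duration == pytest.approx(0.202)
        assert np.all(out.dwells >= 0.006)

    @given(
        levels=st.lists(st.integers(0, 3), min_size=2, max_size=40),
        dwells=st.lists(
            st.floats(min_value=5e-4, max_value=0.5), min_size=2, max_size=40
        ),
    )
    @settings(derandomize=True, max_examples=100)
    def test_conserves_total_time_and_enforces_minimum(self, levels, dwells):
        n = min(len(levels), len(dwells))
        lv, dw = np.array(levels[:n]), np.array(dwells[:n])
        ev = EventTable(lv, dw)
        out = impose_dead_time(ev, 0.006)
        assert out.total_duration == pytest.approx(ev.total_duration, rel=1e-12)
        if sum(dw) >= 0.006:
            assert np.all(out.dwells >= 0.006 - 1e-12)
        # consecutive surviving events always differ in level
        assert np.all(np.diff(out.levels) != 0)

    def test_subsample_dead_time_is_noop(self):
        ev = EventTable(np.array([0, 1]), np.array([0.1, 0.2]), dt=1e-4)
        with pytest.warns(UserWarning):
            out = impose_dead_time(ev, 5e-5)
        np.testing.assert_allclose(out.dwells, ev.dwells)


class TestSelectWindow:
    SEGS = [("bracket", 0.0, 30.0), ("spontaneous", 30.0, 150.0), ("bracket", 150.0, 180.0)]

    def test_default_drops_leading_fifth(self):
        w = select_window(self.SEGS)
        assert (w.t_start, w.t_end) == (54.0, 150.0)
        assert w.duration == pytest.approx(96.0)

    def test_explicit_window_verbatim(self):
        w = select_window(self.SEGS, policy=(40.0, 90.0))
        assert (w.t_start, w.t_end) == (40.0, 90.0)

    def test_recording_scale_five_minute_segment(self):
        segs = [("bracket", 0, 150.0), ("spontaneous", 150.0, 450.0), ("bracket", 450.0, 600.0)]
        w = select_window(segs)
        # last ~4 min of the 5 min ATP-free segment
        assert (w.t_start, w.t_end) == (210.0, 450.0)

    def test_collapsed_window_rejected(self):
        with pytest.raises(ValueError):
            select_window(self.SEGS, policy=(100.0, 100.5), min_length=1.0)
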