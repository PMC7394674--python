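"""Waveform engine: beat synthesis, ring buffer, and the streaming pipeline."""

import threading

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abpsim import (
    EngineConfig,
    EngineError,
    RingBuffer,
    make_synthetic_scenario,
    resample_beat,
    run_pipeline,
    scale_beat,
    synthesize_beat,
)
from abpsim.engine import FLATLINE_BEAT
from abpsim.vitals import Scenario, VitalsSample


class TestResampleBeat:
    @pytest.mark.parametrize("hr,expected_len", [(60.0, 250), (120.0, 125), (350.0, 43)])
    def test_sample_count_follows_heart_rate(self, template, hr, expected_len):
        beat = resample_beat(template, hr, fs_out=250.0)
        assert len(beat) == expected_len

    def test_identity_at_reference_rate(self, template):
        beat = resample_beat(template, template.hr_ref, fs_out=template.fs)
        assert len(beat) == len(template)
        np.testing.assert_allclose(beat, template.samples, atol=1e-12)

    @given(hr=st.floats(20.0, 350.0))
    @settings(max_examples=60, deadline=None)
    def test_output_repinned_to_unit_range(self, hr):
        from abpsim import default_template

        beat = resample_beat(default_template(), hr, fs_out=250.0)
        assert beat.min() == 0.0 and beat.max() == 1.0

    @pytest.mark.parametrize("hr", [0.0, -10.0])
    def test_nonpositive_hr_rejected(self, template, hr):
        with pytest.raises(EngineError):
            resample_beat(template, hr, 250.0)


class TestScaleBeat:
    def test_affine_map(self):
        np.testing.assert_array_equal(
            scale_beat(np.array([0.0, 1.0, 0.25]), 120.0, 80.0),
            np.array([80.0, 120.0, 90.0]),
        )

    def test_unit_pressures_give_identity(self):
        n = np.array([0.0, 0.3, 1.0, 0.5])
        np.testing.assert_array_equal(scale_beat(n, 1.0, 0.0), n)

    def test_midpoint(self):
        assert scale_beat(np.array([0.5]), 120.0, 80.0)[0] == 100.0

    def test_extrema_exact(self, template):
        p = scale_beat(template.samples, 137.3, 91.8)
        assert p.max() == 137.3 and p.min() == 91.8

    def test_inverted_pressures_rejected(self):
        with pytest.raises(EngineError, match="sbp > dbp"):
            scale_beat(np.array([0.0, 1.0]), 80.0, 120.0)


class TestSynthesizeBeat:
    def test_standard_beat(self, template):
        beat = synthesize_beat(template, 60.0, 120.0, 80.0, 250.0)
        assert len(beat) == 250
        assert beat.max() == 120.0 and beat.min() == 80.0

    def test_double_identity_returns_template(self, template):
        beat = synthesize_beat(template, template.hr_ref, 1.0, 0.0, template.fs)
        np.testing.assert_allclose(beat, template.samples, atol=1e-12)

    def test_ceiling_heart_rate(self, template):
        beat = synthesize_beat(template, 350.0, 90.0, 60.0, 250.0)
        assert len(beat) == 43
        assert beat.max() == 90.0 and beat.min() == 60.0


class TestRingBuffer:
    def test_fifo_order(self):
        buf = RingBuffer(8)
        buf.write([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(buf.read(2), [1.0, 2.0])
        buf.write([4.0])
        np.testing.assert_array_equal(buf.read(2), [3.0, 4.0])

    def test_read_never_returns_unwritten_slots(self):
        buf = RingBuffer(8)
        buf.write([1.0])
        got = []
        reader = threading.Thread(target=lambda: got.extend(buf.read(3)))
        reader.start()
        buf.write([2.0, 3.0])
        reader.join(timeout=5.0)
        assert got == [1.0, 2.0, 3.0]

    def test_blocking_producer_is_lossless(self):
        buf = RingBuffer(4, policy="block")
        consumed = []

        def consumer():
            for _ in range(5):
                consumed.extend(buf.read(2))

        thread = threading.Thread(target=consumer)
        thread.start()
        buf.write(np.arange(10.0))  # must block-and-drain, never drop
        thread.join(timeout=5.0)
        assert consumed == list(np.arange(10.0))
        assert buf.dropped == 0

    def test_overwrite_policy_drops_oldest(self):
        buf = RingBuffer(3, policy="overwrite")
        buf.write([1.0, 2.0, 3.0, 4.0, 5.0])
        assert buf.dropped == 2
        np.testing.assert_array_equal(buf.read(3), [3.0, 4.0, 5.0])

    def test_close_wakes_blocked_reader(self):
        buf = RingBuffer(4)
        errors = []

        def reader():
            try:
                buf.read(2)
            except EngineError as exc:
                errors.append(exc)

        t = threading.Thread(target=reader)
        t.start()
        buf.close()
        t.join(timeout=5.0)
        assert errors and "closed" in str(errors[0])


class TestPipeline:
    def test_steady_run_counts(self, template):
        scenario = Scenario((VitalsSample(0.0, 60.0, 120.0, 80.0),), 10.0)
        report = run_pipeline(scenario, template)
        assert report.beats == 10
        assert report.samples == 2500

    def test_sample_timing_grid(self, template, steady_scenario):
        report = run_pipeline(steady_scenario, template)
        t = report.sink.times()
        assert t[0] == 0.0
        np.testing.assert_allclose(np.diff(t), 1.0 / 250.0, atol=1e-12)
        assert np.all(np.diff(t) > 0)

    def test_zero_duration_scenario_is_empty_run(self, template):
        scenario = Scenario((VitalsSample(0.0, 70.0, 120.0, 80.0),), 0.0)
        report = run_pipeline(scenario, template)
        assert (report.beats, report.samples) == (0, 0)

    def test_poll_cadence_is_one_second(self, template, steady_scenario):
        report = run_pipeline(steady_scenario, template)
        times = [t for t, _ in report.poll_log]
        assert times[0] == 0.0
        assert all(b - a == 1.0 for a, b in zip(times, times[1:]))

    def test_per_beat_extrema_match_command(self, template, steady_scenario):
        report = run_pipeline(steady_scenario, template)
        p = report.sink.pressures()
        beats = report.sink.beat_indices()
        for b in range(report.beats):
            seg = p[beats == b]
            assert seg.max() == 120.0
            assert seg.min() == 80.0

    def test_junction_continuity(self, template, steady_scenario):
        report = run_pipeline(steady_scenario, template)
        p = report.sink.pressures()
        beats = report.sink.beat_indices()
        starts = np.flatnonzero(np.diff(beats)) + 1
        jumps = np.abs(p[starts] - p[starts - 1])
        assert np.all(jumps <= 0.05 * (120.0 - 80.0))

    @pytest.mark.parametrize("hr", [45.0, 70.0, 133.0, 350.0])
    def test_beat_conservation(self, template, hr):
        duration = 12.0
        scenario = Scenario((VitalsSample(0.0, hr, 120.0, 80.0),), duration)
        report = run_pipeline(scenario, template)
        assert abs(report.beats - round(hr * duration / 60.0)) <= 1

    def test_beat_atomic_updates_never_straddle(self, template):
        scenario = Scenario(
            (VitalsSample(0.0, 60.0, 120.0, 80.0), VitalsSample(5.0, 120.0, 100.0, 70.0)),
            10.0,
        )
        report = run_pipeline(scenario, template)
        # every beat is tagged with exactly one vitals sample, and beat length
        # flips from 250 to 125 samples when the new command takes effect
        beats = report.sink.beat_indices()
        lengths = {b: int(np.sum(beats == b)) for b, _, _ in report.beat_log}
        for idx, t_start, vit in report.beat_log:
            assert lengths[idx] == (250 if vit.hr == 60.0 else 125)
            seg = report.sink.pressures()[beats == idx]
            assert seg.max() == vit.sbp and seg.min() == vit.dbp

    def test_immediate_policy_rescales_mid_beat(self, template):
        # at 70 bpm the beat starting t = 0.856 straddles the t = 1 s poll
        scenario = Scenario(
            (VitalsSample(0.0, 70.0, 120.0, 80.0), VitalsSample(1.0, 70.0, 200.0, 100.0)),
            4.0,
        )
        atomic = run_pipeline(scenario, template, EngineConfig(update_policy="beat-atomic"))
        immediate = run_pipeline(scenario, template, EngineConfig(update_policy="immediate"))
        assert not np.array_equal(atomic.sink.pressures(), immediate.sink.pressures())
        assert immediate.sink.pressures().max() == 200.0

    def test_hr_zero_flatlines_at_dbp(self, template):
        scenario = Scenario(
            (VitalsSample(0.0, 70.0, 120.0, 80.0), VitalsSample(3.0, 0.0, 120.0, 80.0)),
            6.0,
        )
        report = run_pipeline(scenario, template)
        p = report.sink.pressures()
        beats = report.sink.beat_indices()
        flat = p[beats == FLATLINE_BEAT]
        assert len(flat) > 0
        assert np.all(flat == 80.0)
        assert any("flatline" in w for w in report.warnings)

    def test_sink_failure_yields_partial_report(self, template, steady_scenario):
        class FailingSink:
            def __init__(self):
                self.calls = 0

            def write(self, t, p, beat_index):
                self.calls += 1
                if self.calls > 3:
                    raise IOError("disk full")

        sink = FailingSink()
        report = run_pipeline(steady_scenario, template, sink=sink)
        assert report.beats == 3
        assert any("sink failure" in w for w in report.warnings)

    def test_buffer_capacity_must_hold_one_beat(self, template, steady_scenario):
        with pytest.raises(EngineError, match="capacity"):
            run_pipeline(
                steady_scenario, template, EngineConfig(buffer_capacity=10)
            )


class TestThreadedEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_threaded_equals_deterministic(self, template, seed):
        kinds = ["steady", "hemorrhage-ramp", "hypotension-step"]
        scenario = make_synthetic_scenario(
            kinds[seed % 3], duration=6.0, noise_sd=8.0, seed=seed
        )
        det = run_pipeline(scenario, template, mode="deterministic")
        thr = run_pipeline(scenario, template, mode="threaded")
        np.testing.assert_array_equal(det.sink.pressures(), thr.sink.pressures())
        np.testing.assert_array_equal(det.sink.times(), thr.sink.times())
        np.testing.assert_array_equal(det.sink.beat_indices(), thr.sink.beat_indices())
        assert det.beats == thr.beats
        assert [t for t, _ in det.poll_log] == [t for t, _ in thr.poll_log]

    def test_realtime_pacing_smoke(self, template):
        scenario = Scenario((VitalsSample(0.0, 120.0, 120.0, 80.0),), 0.5)
        report = run_pipeline(scenario, template, mode="threaded", pace=True)
        assert report.samples > 0


def test_engine_config_validation():
    with pytest.raises(EngineError):
        EngineConfig(fs_out=0.0)
    with pytest.raises(EngineError):
        EngineConfig(update_policy="sometimes")
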