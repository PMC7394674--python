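"""Waveform synthesis pipeline.

Turns a vitals scenario plus a pulse template into a continuous arterial
pressure waveform, following a three-role streaming contract:

1. a **coordinator** initializes the ring buffer and keeps it fed with the
   normalized template cycle;
2. a **vitals producer** polls the scenario every ``poll_period`` seconds
   (1 s by default — the cadence at which the patient simulator publishes
   HR/SBP/DBP) and validates each sample;
3. a **waveform consumer** drains one template beat from the buffer per
   heartbeat, resamples it to the commanded HR, rescales it to the
   commanded SBP/DBP and pushes the pressure samples to a sink at
   ``fs_out``.

Per beat: the template is interpolated onto ``round(fs_out * 60 / hr)``
uniformly spaced phase points, re-pinned to [0, 1] exactly, then mapped
affinely so the beat maximum equals SBP and the minimum equals DBP.

Two execution modes produce the identical sample stream: ``deterministic``
runs all three roles in one thread on a virtual clock (the test surface),
``threaded`` runs real producer/consumer threads synchronized on the same
virtual clock (optionally paced against the wall clock for live demos).

Under the default ``beat-atomic`` update policy a vitals change takes
effect at the next beat boundary, never mid-beat; the ``immediate`` policy
rescales the remainder of a beat as soon as a new poll lands (beat length,
i.e. HR, is still fixed at beat start).  ``hr = 0`` segments produce a
flatline at the current DBP until the next poll.
"""

from __future__ import annotations

import math
import threading
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .buffer import RingBuffer
from .errors import EngineError
from .template import PulseTemplate, _round_half_away
from .vitals import Scenario, VitalsSample, sample_vitals

__all__ = [
    "PressureSample",
    "EngineConfig",
    "RunReport",
    "MemorySink",
    "resample_beat",
    "scale_beat",
    "synthesize_beat",
    "run_pipeline",
]

UPDATE_POLICIES = ("beat-atomic", "immediate")
EXECUTION_MODES = ("deterministic", "threaded")

#: beat_index assigned to flatline (hr = 0) samples, which belong to no beat.
FLATLINE_BEAT = -1

_EPS = 1e-12


@dataclass(frozen=True)
class PressureSample:
    """One output waveform sample: time (s), pressure (mmHg), owning beat."""

    t: float
    p: float
    beat_index: int


@dataclass(frozen=True)
class EngineConfig:
    """Pipeline configuration.

    ``buffer_capacity`` defaults to four template beats (lossless headroom);
    it must hold at least one full beat.  ``update_policy`` is
    ``"beat-atomic"`` or ``"immediate"``; ``buffer_policy`` is ``"block"``
    (lossless) or ``"overwrite"`` (real-time dropout emulation).
    """

    fs_out: float = 250.0
    poll_period: float = 1.0
    buffer_capacity: Optional[int] = None
    update_policy: str = "beat-atomic"
    buffer_policy: str = "block"
    hr_zero: str = "flatline-at-dbp"

    def __post_init__(self) -> None:
        if not self.fs_out > 0:
            raise EngineError(f"fs_out must be positive, got {self.fs_out}")
        if not self.poll_period > 0:
            raise EngineError(f"poll_period must be positive, got {self.poll_period}")
        if self.update_policy not in UPDATE_POLICIES:
            raise EngineError(
                f"unknown update policy {self.update_policy!r}; choose from {UPDATE_POLICIES}"
            )
        if self.hr_zero != "flatline-at-dbp":
            raise EngineError(f"unknown hr-zero behavior {self.hr_zero!r}")


@dataclass
class RunReport:
    """What a pipeline run did: counts, logs and any warnings raised."""

    beats: int = 0
    samples: int = 0
    warnings: list[str] = field(default_factory=list)
    #: (virtual time, validated sample) for every vitals poll, in order.
    poll_log: list[tuple[float, VitalsSample]] = field(default_factory=list)
    #: (beat index, beat start time, vitals the beat was synthesized from).
    beat_log: list[tuple[int, float, VitalsSample]] = field(default_factory=list)
    sink: object = None


class MemorySink:
    """Collects the emitted stream in memory (the default sink)."""

    def __init__(self) -> None:
        self._t: list[np.ndarray] = []
        self._p: list[np.ndarray] = []
        self._beats: list[np.ndarray] = []

    def write(self, t: np.ndarray, p: np.ndarray, beat_index: int) -> None:
        self._t.append(np.asarray(t, dtype=float))
        self._p.append(np.asarray(p, dtype=float))
        self._beats.append(np.full(len(t), beat_index, dtype=int))

    def times(self) -> np.ndarray:
        return np.concatenate(self._t) if self._t else np.empty(0)

    def pressures(self) -> np.ndarray:
        return np.concatenate(self._p) if self._p else np.empty(0)

    def beat_indices(self) -> np.ndarray:
        return np.concatenate(self._beats) if self._beats else np.empty(0, dtype=int)

    def samples(self) -> list[PressureSample]:
        return [
            PressureSample(float(t), float(p), int(b))
            for t, p, b in zip(self.times(), self.pressures(), self.beat_indices())
        ]


# --- beat-level operations -------------------------------------------------


def _resample_array(samples: np.ndarray, n_out: int) -> np.ndarray:
    """Interpolate one normalized beat onto n_out uniform phase points.

    The beat is treated as one period of a cyclic signal (the phase grid
    wraps back to the first sample), then re-pinned so min = 0 and
    max = 1 exactly.
    """
    n_in = len(samples)
    xp = np.arange(n_in + 1) / n_in
    fp = np.concatenate([samples, samples[:1]])
    x = np.arange(n_out) / n_out
    y = np.interp(x, xp, fp)
    y = y - y.min()
    return y / y.max()


def resample_beat(template: PulseTemplate, hr: float, fs_out: float) -> np.ndarray:
    """Resample the template to one beat at heart rate ``hr``, sampled at ``fs_out``.

    Returns ``round(fs_out * 60 / hr)`` normalized samples (round half away
    from zero).  At ``hr == hr_ref`` and ``fs_out == template.fs`` this is
    the template verbatim.
    """
    if not hr > 0:
        raise EngineError(f"resample_beat requires hr > 0, got {hr} (hr = 0 is a pipeline state)")
    if hr > 350:
        raise EngineError(f"hr {hr} exceeds the 350 bpm ceiling")
    if not fs_out > 0:
        raise EngineError(f"fs_out must be positive, got {fs_out}")
    n_out = _round_half_away(fs_out * 60.0 / hr)
    if n_out < 2:
        raise EngineError(
            f"fs_out {fs_out} Hz cannot represent a beat at {hr} bpm ({n_out} samples)"
        )
    return _resample_array(template.samples, n_out)


def scale_beat(normalized: np.ndarray, sbp: float, dbp: float) -> np.ndarray:
    """Affinely map a normalized beat so its max is SBP and its min is DBP.

    ``p_i = n_i * sbp + (1 - n_i) * dbp`` — exact at both extrema.
    """
    if not sbp > dbp:
        raise EngineError(f"scale_beat requires sbp > dbp, got {sbp}/{dbp}")
    if dbp < 0:
        raise EngineError(f"scale_beat requires dbp >= 0, got {dbp}")
    n = np.asarray(normalized, dtype=float)
    return n * sbp + (1.0 - n) * dbp


def synthesize_beat(
    template: PulseTemplate, hr: float, sbp: float, dbp: float, fs_out: float
) -> np.ndarray:
    """Resample then rescale: one pressure beat in mmHg at the commanded vitals."""
    return scale_beat(resample_beat(template, hr, fs_out), sbp, dbp)


# --- pipeline --------------------------------------------------------------


def _poll_count(duration: float, poll_period: float) -> int:
    if duration <= 0:
        return 0
    return int(math.ceil(duration / poll_period - _EPS))


def _consume(
    duration: float,
    fs: float,
    poll: float,
    n_polls: int,
    template_samples: np.ndarray,
    policy: str,
    get_vitals: Callable[[int], VitalsSample],
    read_block: Callable[[int], np.ndarray],
    sink,
    report: RunReport,
    consume_warnings: list[str],
    pace_clock: Optional[Callable[[float], None]] = None,
) -> None:
    """Shared waveform-consumer loop (both execution modes run this verbatim)."""
    n_t = len(template_samples)
    counter = 0  # samples emitted so far; virtual time = counter / fs
    beat_idx = 0
    in_flatline = False

    def emit(t_arr: np.ndarray, p_arr: np.ndarray, tag: int) -> bool:
        try:
            sink.write(t_arr, p_arr, tag)
        except Exception as exc:  # sink failure stops the run, partial report
            consume_warnings.append(f"sink failure at t={t_arr[0]:.6g}: {exc}")
            return False
        report.samples += len(t_arr)
        return True

    while counter / fs < duration - _EPS:
        t = counter / fs
        if pace_clock is not None:
            pace_clock(t)
        k = min(int(t / poll + 1e-9), n_polls - 1)
        vit = get_vitals(k)
        if vit.hr <= 0:
            if not in_flatline:
                consume_warnings.append(
                    f"hr = 0 at t={t:.6g}: emitting flatline at dbp = {vit.dbp:g} mmHg"
                )
                in_flatline = True
            end_t = min((k + 1) * poll, duration)
            end_counter = int(math.ceil(end_t * fs - 1e-9))
            n = max(end_counter - counter, 1)
            t_arr = (counter + np.arange(n)) / fs
            if not emit(t_arr, np.full(n, float(vit.dbp)), FLATLINE_BEAT):
                return
            counter += n
            continue
        in_flatline = False

        block = read_block(n_t)
        n_out = _round_half_away(fs * 60.0 / vit.hr)
        y = _resample_array(block, n_out)
        t_arr = (counter + np.arange(n_out)) / fs

        if policy == "beat-atomic":
            p = y * vit.sbp + (1.0 - y) * vit.dbp
            if not emit(t_arr, p, beat_idx):
                return
        else:  # immediate: pressures follow polls mid-beat, HR fixed at beat start
            ks = np.minimum((t_arr / poll + 1e-9).astype(int), n_polls - 1)
            start = 0
            for kk in range(ks[0], ks[-1] + 1):
                span = int(np.searchsorted(ks, kk, side="right"))
                if span == start:
                    continue
                v = get_vitals(kk)
                if v.hr <= 0:  # mid-beat collapse: hold dbp for the remainder
                    v = VitalsSample(v.t, vit.hr, max(v.dbp, 1.0), v.dbp)
                chunk = y[start:span]
                p = chunk * v.sbp + (1.0 - chunk) * v.dbp
                if not emit(t_arr[start:span], p, beat_idx):
                    return
                start = span
        report.beat_log.append((beat_idx, t, vit))
        beat_idx += 1
        report.beats += 1
        counter += n_out


def _resolve_capacity(config: EngineConfig, n_t: int) -> int:
    cap = config.buffer_capacity if config.buffer_capacity is not None else 4 * n_t
    if cap < n_t:
        raise EngineError(
            f"buffer capacity {cap} is smaller than one template beat ({n_t} samples)"
        )
    return cap


def run_pipeline(
    scenario: Scenario,
    template: PulseTemplate,
    config: Optional[EngineConfig] = None,
    sink=None,
    mode: str = "deterministic",
    pace: bool = False,
) -> RunReport:
    """Run the full scenario → waveform pipeline and return a :class:`RunReport`.

    ``mode="deterministic"`` executes the three roles in one thread on a
    virtual clock; ``mode="threaded"`` uses real producer/consumer threads
    synchronized to the same virtual clock and yields the identical sample
    stream.  ``pace=True`` (threaded only) additionally paces emission
    against the wall clock for live demonstration.
    """
    if mode not in EXECUTION_MODES:
        raise EngineError(f"unknown mode {mode!r}; choose from {EXECUTION_MODES}")
    config = config or EngineConfig()
    if sink is None:
        sink = MemorySink()
    report = RunReport(sink=sink)
    fs, poll = config.fs_out, config.poll_period
    duration = scenario.duration
    n_polls = _poll_count(duration, poll)
    if n_polls == 0:
        return report
    n_t = len(template)
    cap = _resolve_capacity(config, n_t)
    tpl = template.samples
    poll_warnings: list[str] = []
    consume_warnings: list[str] = []

    if mode == "deterministic":
        polled: list[VitalsSample] = []
        for k in range(n_polls):
            t_poll = k * poll
            vit = sample_vitals(scenario, t_poll, on_warning=poll_warnings.append)
            polled.append(vit)
            report.poll_log.append((t_poll, vit))

        buf = RingBuffer(cap, policy=config.buffer_policy)
        pos = 0

        def read_block(n: int) -> np.ndarray:
            nonlocal pos
            while len(buf) < n:
                free = cap - len(buf)
                take = min(free, n_t - pos)
                buf.write(tpl[pos : pos + take])
                pos = (pos + take) % n_t
            return buf.read(n)

        _consume(
            duration, fs, poll, n_polls, tpl, config.update_policy,
            lambda k: polled[k], read_block, sink, report, consume_warnings,
        )
    else:
        _run_threaded(
            scenario, tpl, config, sink, report,
            n_polls, cap, poll_warnings, consume_warnings, pace,
        )

    report.warnings = poll_warnings + consume_warnings
    return report


class _VitalsBoard:
    """Publish/subscribe slot for polled vitals, ordered by poll index."""

    def __init__(self, timeout: float = 10.0):
        self._polls: list[VitalsSample] = []
        self._cond = threading.Condition()
        self._failed = False
        self._timeout = timeout

    def publish(self, sample: VitalsSample) -> None:
        with self._cond:
            self._polls.append(sample)
            self._cond.notify_all()

    def fail(self) -> None:
        with self._cond:
            self._failed = True
            self._cond.notify_all()

    def get(self, k: int) -> VitalsSample:
        with self._cond:
            while len(self._polls) <= k and not self._failed:
                if not self._cond.wait(self._timeout):
                    raise EngineError(f"timed out waiting for vitals poll {k}")
            if len(self._polls) <= k:
                raise EngineError("vitals producer failed before publishing required poll")
            return self._polls[k]


def _run_threaded(
    scenario, tpl, config, sink, report, n_polls, cap, poll_warnings,
    consume_warnings, pace,
) -> None:
    import time

    fs, poll = config.fs_out, config.poll_period
    duration = scenario.duration
    n_t = len(tpl)
    board = _VitalsBoard()
    buf = RingBuffer(cap, policy=config.buffer_policy)
    consumer_done = threading.Event()
    errors: list[BaseException] = []
    wall_start = time.monotonic()

    def producer() -> None:
        try:
            for k in range(n_polls):
                t_poll = k * poll
                if pace:
                    time.sleep(max(0.0, wall_start + t_poll - time.monotonic()))
                vit = sample_vitals(scenario, t_poll, on_warning=poll_warnings.append)
                report.poll_log.append((t_poll, vit))
                board.publish(vit)
        except BaseException as exc:
            errors.append(exc)
            board.fail()

    def pace_clock(t: float) -> None:
        time.sleep(max(0.0, wall_start + t - time.monotonic()))

    def consumer() -> None:
        try:
            _consume(
                duration, fs, poll, n_polls, tpl, config.update_policy,
                board.get, buf.read, sink, report, consume_warnings,
                pace_clock if pace else None,
            )
        except BaseException as exc:
            errors.append(exc)
        finally:
            consumer_done.set()
            buf.close()

    prod_t = threading.Thread(target=producer, name="abpsim-vitals-producer", daemon=True)
    cons_t = threading.Thread(target=consumer, name="abpsim-waveform-consumer", daemon=True)
    prod_t.start()
    cons_t.start()

    # Coordinator role: keep the ring buffer fed with the template cycle.
    pos = 0
    while not consumer_done.is_set():
        take = min(n_t - pos, max(1, cap // 4))
        if not buf.write(tpl[pos : pos + take]):
            break
        pos = (pos + take) % n_t

    cons_t.join(timeout=60.0)
    prod_t.join(timeout=60.0)
    if cons_t.is_alive() or prod_t.is_alive():
        raise EngineError("pipeline threads failed to terminate")
    if errors:
        raise errors[0]
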