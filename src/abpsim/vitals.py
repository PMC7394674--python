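"""Scripted vital-sign sources.

A patient simulator publishes heart rate (HR), systolic (SBP) and diastolic
(DBP) blood pressure once per second.  This module replaces that live feed
with a :class:`Scenario`: an ordered script of (time, HR, SBP, DBP) segments
that can be sampled at any instant, either step-held or linearly ramped
between segments.  Sampling always passes through :func:`validate_vitals`,
which enforces the transmissible value ranges (HR 0-350 bpm; pressures
0-500 mmHg, the span representable on the 0-5 V analog output) and rejects
non-physiological SBP <= DBP pairs.
"""

from __future__ import annotations

import csv
import math
import warnings
from bisect import bisect_right
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, IO, Optional, Union

import numpy as np

from .errors import ScenarioError, VitalsError

__all__ = [
    "HR_MAX",
    "PRESSURE_MAX",
    "SCENARIO_COLUMNS",
    "ClampWarning",
    "VitalsSample",
    "Scenario",
    "validate_vitals",
    "load_scenario",
    "save_scenario",
    "sample_vitals",
    "make_synthetic_scenario",
    "SCENARIO_PRESETS",
]

#: Superior transmissible heart rate, bpm.
HR_MAX = 350.0
#: Largest pressure representable on the 0-5 V analog output, mmHg.
PRESSURE_MAX = 500.0

SCENARIO_COLUMNS = ("t_s", "hr_bpm", "sbp_mmhg", "dbp_mmhg")

INTERPOLATION_MODES = ("hold", "linear-ramp")


class ClampWarning(UserWarning):
    """A vitals value was clamped into its transmissible range."""


@dataclass(frozen=True)
class VitalsSample:
    """One (HR, SBP, DBP) reading at ``t`` seconds after run start."""

    t: float
    hr: float
    sbp: float
    dbp: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.t, self.hr, self.sbp, self.dbp)


@dataclass(frozen=True)
class Scenario:
    """An ordered script of vitals segments over a finite run.

    Parameters
    ----------
    segments
        Segments in effect from their start time onward.  Start times must
        be strictly increasing with the first at t = 0.
    duration
        Run length in seconds; must cover the last segment start.
    mode
        ``"hold"`` (step function, a segment takes effect at exactly its
        start time) or ``"linear-ramp"`` (component-wise linear
        interpolation between segment starts).
    """

    segments: tuple[VitalsSample, ...]
    duration: float
    mode: str = "hold"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ScenarioError("empty scenario: no segments")
        starts = [s.t for s in self.segments]
        if starts[0] != 0.0:
            raise ScenarioError(
                f"unordered scenario: first segment starts at t={starts[0]}, expected 0"
            )
        for a, b in zip(starts, starts[1:]):
            if not b > a:
                raise ScenarioError(
                    f"unordered scenario: segment times must strictly increase "
                    f"(got {a} then {b})"
                )
        if not (math.isfinite(self.duration) and self.duration >= starts[-1]):
            raise ScenarioError(
                f"duration {self.duration} does not cover last segment start {starts[-1]}"
            )
        if self.mode not in INTERPOLATION_MODES:
            raise ScenarioError(
                f"unknown interpolation mode {self.mode!r}; choose from {INTERPOLATION_MODES}"
            )


def _emit_warning(on_warning: Optional[Callable[[str], None]], message: str) -> None:
    if on_warning is None:
        warnings.warn(message, ClampWarning, stacklevel=3)
    else:
        on_warning(message)


def validate_vitals(
    raw: VitalsSample, on_warning: Optional[Callable[[str], None]] = None
) -> VitalsSample:
    """Clamp a vitals sample into transmissible ranges and reject bad pairs.

    HR is clamped into [0, 350] bpm and each pressure into [0, 500] mmHg;
    any clamp is reported through ``on_warning`` (default: a
    :class:`ClampWarning`).  SBP <= DBP while HR > 0 is a
    :class:`VitalsError` — such a pair has no arterial pulse to synthesize.
    Validation is a projection: applying it twice changes nothing further.
    """
    for name, value in (("t", raw.t), ("hr", raw.hr), ("sbp", raw.sbp), ("dbp", raw.dbp)):
        if not math.isfinite(value):
            raise VitalsError(f"non-finite {name} in vitals sample: {value!r}")
    if raw.t < 0:
        raise VitalsError(f"negative timestamp in vitals sample: {raw.t}")

    hr, sbp, dbp = raw.hr, raw.sbp, raw.dbp
    if not 0.0 <= hr <= HR_MAX:
        clamped = min(max(hr, 0.0), HR_MAX)
        _emit_warning(
            on_warning, f"t={raw.t}: hr {hr} bpm clamped to {clamped} (range 0-{HR_MAX:g})"
        )
        hr = clamped
    for name, value in (("sbp", sbp), ("dbp", dbp)):
        if not 0.0 <= value <= PRESSURE_MAX:
            clamped = min(max(value, 0.0), PRESSURE_MAX)
            _emit_warning(
                on_warning,
                f"t={raw.t}: {name} {value} mmHg clamped to {clamped} "
                f"(range 0-{PRESSURE_MAX:g})",
            )
            if name == "sbp":
                sbp = clamped
            else:
                dbp = clamped
    if hr > 0 and sbp <= dbp:
        raise VitalsError(
            f"non-physiological pressure pair at t={raw.t}: sbp {sbp} <= dbp {dbp} with hr {hr}"
        )
    if (hr, sbp, dbp) == (raw.hr, raw.sbp, raw.dbp):
        return raw
    return replace(raw, hr=hr, sbp=sbp, dbp=dbp)


def load_scenario(
    source: Union[str, Path, IO[str]],
    duration: Optional[float] = None,
    mode: str = "hold",
) -> Scenario:
    """Read a scenario from its CSV form.

    The dialect is a header ``t_s,hr_bpm,sbp_mmhg,dbp_mmhg`` followed by one
    row per segment.  ``duration`` defaults to the last segment time + 1 s
    (one further polling interval).  Malformed rows are reported with their
    line number.  Values outside the transmissible ranges parse fine here;
    they are clamped later at sampling time.
    """
    if hasattr(source, "read"):
        return _parse_scenario(source, duration, mode)  # type: ignore[arg-type]
    with open(source, "r", encoding="utf-8", newline="") as fh:
        return _parse_scenario(fh, duration, mode)


def _parse_scenario(fh: IO[str], duration: Optional[float], mode: str) -> Scenario:
    reader = csv.DictReader(fh)
    if reader.fieldnames is None:
        raise ScenarioError("empty scenario: file has no header")
    missing = [c for c in SCENARIO_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise ScenarioError(f"scenario file missing column(s): {', '.join(missing)}")
    segments: list[VitalsSample] = []
    for row in reader:
        line = reader.line_num
        values = []
        for col in SCENARIO_COLUMNS:
            cell = row.get(col)
            if cell is None or cell.strip() == "":
                raise ScenarioError(f"line {line}: missing value for column {col!r}")
            try:
                values.append(float(cell))
            except ValueError:
                raise ScenarioError(
                    f"line {line}: cannot parse {col!r} value {cell!r} as a number"
                ) from None
        segments.append(VitalsSample(*values))
    if not segments:
        raise ScenarioError("empty scenario: no segment rows")
    if duration is None:
        duration = segments[-1].t + 1.0
    return Scenario(tuple(segments), duration, mode)


def save_scenario(scenario: Scenario, path: Union[str, Path]) -> int:
    """Write a scenario in the CSV dialect; returns segment rows written."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCENARIO_COLUMNS)
        for seg in scenario.segments:
            writer.writerow([f"{v:.10g}" for v in seg.as_tuple()])
    return len(scenario.segments)


def sample_vitals(
    scenario: Scenario,
    t: float,
    on_warning: Optional[Callable[[str], None]] = None,
) -> VitalsSample:
    """Evaluate the scenario at time ``t`` (seconds) and validate the result.

    Hold mode returns the last segment whose start is <= t (a segment takes
    effect at exactly its start time); linear-ramp mode interpolates each
    vital between the bracketing segments and holds the last segment's
    values beyond it.
    """
    if not (0.0 <= t <= scenario.duration):
        raise ScenarioError(
            f"sample time {t} outside scenario range [0, {scenario.duration}]"
        )
    starts = [s.t for s in scenario.segments]
    if scenario.mode == "hold":
        idx = bisect_right(starts, t) - 1
        seg = scenario.segments[idx]
        raw = VitalsSample(t, seg.hr, seg.sbp, seg.dbp)
    else:  # linear-ramp
        hrs = [s.hr for s in scenario.segments]
        sbps = [s.sbp for s in scenario.segments]
        dbps = [s.dbp for s in scenario.segments]
        raw = VitalsSample(
            t,
            float(np.interp(t, starts, hrs)),
            float(np.interp(t, starts, sbps)),
            float(np.interp(t, starts, dbps)),
        )
    return validate_vitals(raw, on_warning=on_warning)


# --- synthetic scenario presets -------------------------------------------

#: Baseline adult vitals for the presets: 70 bpm, 120/80 mmHg.
_BASELINE = (70.0, 120.0, 80.0)


def _steady(u: float) -> tuple[float, float, float]:
    return _BASELINE


def _hemorrhage_ramp(u: float) -> tuple[float, float, float]:
    # Progressive blood loss: HR compensates upward while pressures fall.
    return (70.0 + 60.0 * u, 120.0 - 60.0 * u, 80.0 - 40.0 * u)


def _hypotension_step(u: float) -> tuple[float, float, float]:
    # Abrupt hypotensive event (e.g. induction) at mid-run.
    return (70.0, 120.0, 80.0) if u < 0.5 else (90.0, 80.0, 50.0)


SCENARIO_PRESETS = {
    "steady": _steady,
    "hemorrhage-ramp": _hemorrhage_ramp,
    "hypotension-step": _hypotension_step,
}


def make_synthetic_scenario(
    kind: str,
    duration: float = 60.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    mode: str = "hold",
) -> Scenario:
    """Generate a scripted scenario from a named clinical preset.

    ``steady`` is a constant 70 bpm, 120/80 mmHg; ``hemorrhage-ramp``
    ramps HR 70→130 bpm against SBP 120→60 / DBP 80→40 mmHg;
    ``hypotension-step`` drops to 90 bpm, 80/50 mmHg at mid-run.  With
    ``noise_sd`` > 0 a new segment is emitted every second with additive
    Gaussian jitter (same SD on each vital, seeded and reproducible); raw
    values may stray beyond the transmissible ranges and are clamped at
    sampling time, but DBP is kept at least 5 mmHg below the clamped SBP so
    every emitted sample passes validation.
    """
    if kind not in SCENARIO_PRESETS:
        raise ScenarioError(
            f"unknown scenario preset {kind!r}; choose from {sorted(SCENARIO_PRESETS)}"
        )
    if not duration > 0:
        raise ScenarioError(f"duration must be positive, got {duration}")
    if noise_sd < 0:
        raise ScenarioError(f"noise_sd must be non-negative, got {noise_sd}")
    profile = SCENARIO_PRESETS[kind]

    if noise_sd > 0:
        times = [float(k) for k in range(int(math.ceil(duration)))]
    elif kind == "steady":
        times = [0.0]
    elif kind == "hypotension-step":
        times = [0.0, duration / 2.0]
    else:  # hemorrhage-ramp: piecewise every 5 s
        times = [float(t) for t in np.arange(0.0, duration, min(5.0, duration))]

    rng = np.random.default_rng(seed)
    segments = []
    for t in times:
        hr, sbp, dbp = profile(t / duration)
        if noise_sd > 0:
            jitter = rng.normal(0.0, noise_sd, size=3)
            hr, sbp, dbp = hr + jitter[0], sbp + jitter[1], dbp + jitter[2]
        hr = max(hr, 0.0)
        sbp = max(sbp, 6.0)
        dbp = min(max(dbp, 1.0), min(sbp, PRESSURE_MAX) - 5.0)
        segments.append(VitalsSample(t, hr, sbp, dbp))
    return Scenario(tuple(segments), float(duration), mode)
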