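"""Pulse-contour verification of the synthesized waveform.

A desk-scale stand-in for the monitor side of the chain: segment the
pressure stream into beats at diastolic troughs, read off per-beat SBP
(beat maximum), DBP (beat minimum), pulse pressure and mean arterial
pressure, estimate HR from beat periods, and compute pulse pressure
variation (PPV) over an averaging window.  These are the openly defined
textbook statistics — explicitly *not* a re-implementation of the
proprietary PulseCO pulse-contour algorithm (cardiac output, stroke volume
and vascular resistance are out of scope).

Conventions: MAP uses the clinical approximation DBP + PP/3; PPV is
100 * (PPmax - PPmin) / mean(PPmax, PPmin) over the window; beat
segmentation uses a refractory period of 60/350 s, one beat at the 350 bpm
transmissible HR ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .engine import EngineConfig, MemorySink, RunReport, run_pipeline
from .errors import AnalysisError
from .output import DEFAULT_MAPPING, MappingConfig, code_to_mmhg, mmhg_to_volts, quantize_to_code
from .template import PulseTemplate, default_template
from .vitals import Scenario, VitalsSample, validate_vitals

__all__ = [
    "BeatFeatures",
    "AnalyzerReport",
    "detect_beats",
    "extract_features",
    "compute_ppv",
    "analyze",
    "roundtrip_report",
    "run_roundtrip",
    "max_abs_errors",
]

#: Minimum trough-to-trough spacing, seconds (one beat at the 350 bpm ceiling).
REFRACTORY_S = 60.0 / 350.0

#: Default PPV/HR averaging window, seconds (typical monitor setting).
DEFAULT_WINDOW_S = 10.0

_FLAT_EPS = 1e-9


@dataclass(frozen=True)
class BeatFeatures:
    """Pressures and timing of one detected beat."""

    t: float        # beat start (diastolic trough), seconds
    period: float   # trough-to-trough interval, seconds
    sbp: float      # beat maximum, mmHg
    dbp: float      # beat minimum, mmHg
    pp: float       # pulse pressure = sbp - dbp, mmHg
    map: float      # mean arterial pressure ~ dbp + pp/3, mmHg


@dataclass(frozen=True)
class AnalyzerReport:
    """Windowed summary of a beat sequence."""

    beats: tuple[BeatFeatures, ...]
    hr_est: float   # bpm over the window (0 if no beats)
    ppv: float      # percent over the window (0 if < 2 beats)
    window: float   # seconds


def detect_beats(p: Sequence[float], fs: float) -> np.ndarray:
    """Locate beat boundaries (diastolic troughs) in a pressure series.

    Troughs are local minima at least 60/350 s apart with prominence of a
    quarter of the signal range; the series endpoints are included as
    boundaries when they sit near local diastole, so a stream that starts
    and ends at a trough yields one boundary per beat plus one.  A flatline
    has no beats and returns an empty array.
    """
    if not fs > 0:
        raise AnalysisError(f"fs must be positive, got {fs}")
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise AnalysisError(f"pressure series must be 1-D, got shape {arr.shape}")
    span = float(np.ptp(arr)) if arr.size else 0.0
    if arr.size == 0 or span < _FLAT_EPS:
        return np.empty(0, dtype=int)
    min_len = int(2 * fs * REFRACTORY_S)
    if arr.size < min_len:
        raise AnalysisError(
            f"series too short for beat detection: {arr.size} samples "
            f"(need >= {min_len} at the 350 bpm ceiling)"
        )
    distance = max(1, int(fs * REFRACTORY_S))
    troughs, _ = find_peaks(-arr, distance=distance, prominence=0.25 * span)
    boundaries = list(troughs)

    w = max(2, int(0.5 * fs))
    head, tail = arr[: min(w, arr.size)], arr[-min(w, arr.size):]
    if (not boundaries or boundaries[0] > 0) and _near_diastole(arr[0], head):
        boundaries.insert(0, 0)
    if (not boundaries or boundaries[-1] < arr.size - 1) and _near_diastole(arr[-1], tail):
        boundaries.append(arr.size - 1)
    return np.asarray(sorted(set(boundaries)), dtype=int)


def _near_diastole(value: float, window: np.ndarray) -> bool:
    span = float(np.ptp(window))
    return span > 0 and value <= window.min() + 0.15 * span


def extract_features(
    p: Sequence[float], boundaries: Sequence[int], fs: float
) -> list[BeatFeatures]:
    """Per-beat extrema and timing between consecutive boundaries.

    Fewer than two boundaries (no complete beat) yields an empty list.
    """
    if not fs > 0:
        raise AnalysisError(f"fs must be positive, got {fs}")
    arr = np.asarray(p, dtype=float)
    b = np.asarray(boundaries, dtype=int)
    features = []
    for i0, i1 in zip(b, b[1:]):
        if not 0 <= i0 < i1 < arr.size:
            raise AnalysisError(f"invalid beat boundaries ({i0}, {i1}) for series of {arr.size}")
        # half-open [i0, i1): the closing trough is the next beat's first sample
        seg = arr[i0:i1]
        sbp, dbp = float(seg.max()), float(seg.min())
        pp = sbp - dbp
        features.append(
            BeatFeatures(
                t=i0 / fs,
                period=(i1 - i0) / fs,
                sbp=sbp,
                dbp=dbp,
                pp=pp,
                map=dbp + pp / 3.0,
            )
        )
    return features


def compute_ppv(features: Sequence[BeatFeatures]) -> float:
    """Pulse pressure variation over a beat window, percent.

    ``100 * (pp_max - pp_min) / ((pp_max + pp_min) / 2)``; identical pulse
    pressures give exactly 0.
    """
    if len(features) < 2:
        raise AnalysisError(f"insufficient beats for PPV: {len(features)} (need >= 2)")
    pps = np.array([f.pp for f in features], dtype=float)
    hi, lo = float(pps.max()), float(pps.min())
    if hi + lo == 0:
        return 0.0
    return 100.0 * (hi - lo) / ((hi + lo) / 2.0)


def analyze(
    p: Sequence[float], fs: float, window: float = DEFAULT_WINDOW_S
) -> AnalyzerReport:
    """Full analyzer pass: detect beats, then window the trailing statistics.

    HR is estimated as 60 / mean(beat period) over beats starting within
    the trailing ``window`` seconds; PPV likewise.  A flatline reports
    zero beats, HR 0 and PPV 0.
    """
    if not window > 0:
        raise AnalysisError(f"window must be positive, got {window}")
    arr = np.asarray(p, dtype=float)
    boundaries = detect_beats(arr, fs)
    features = extract_features(arr, boundaries, fs)
    t_end = arr.size / fs
    recent = [f for f in features if f.t >= t_end - window]
    hr_est = 60.0 / float(np.mean([f.period for f in recent])) if recent else 0.0
    ppv = compute_ppv(recent) if len(recent) >= 2 else 0.0
    return AnalyzerReport(tuple(features), hr_est, ppv, window)


# --- round-trip verification ------------------------------------------------


def roundtrip_report(
    scenario: Scenario,
    features: Sequence[BeatFeatures],
    min_beats: int = 5,
) -> pd.DataFrame:
    """Compare recovered beat statistics against the commanded vitals.

    For every steady (hold) segment with HR > 0, beats starting within the
    segment are compared with the segment's validated command values; the
    first beat after each segment change is excluded as a transition beat.
    Segments retaining fewer than ``min_beats`` beats are skipped; if no
    segment qualifies the scenario is too short to verify.

    Returns a tidy frame with columns ``segment_t, metric, commanded,
    recovered, abs_error`` where ``abs_error`` is the worst per-beat
    deviation for pressures and the windowed deviation for HR.
    """
    if scenario.mode != "hold":
        raise AnalysisError("roundtrip verification requires a hold-mode scenario")
    rows = []
    segs = scenario.segments
    ends = [s.t for s in segs[1:]] + [scenario.duration]
    for i, (seg, end) in enumerate(zip(segs, ends)):
        cmd = validate_vitals(
            VitalsSample(seg.t, seg.hr, seg.sbp, seg.dbp), on_warning=lambda m: None
        )
        if cmd.hr <= 0:
            continue
        in_seg = [f for f in features if seg.t <= f.t < end]
        if i > 0 and in_seg:  # drop the transition beat after the change
            in_seg = in_seg[1:]
        if len(in_seg) < min_beats:
            continue
        sbps = np.array([f.sbp for f in in_seg])
        dbps = np.array([f.dbp for f in in_seg])
        periods = np.array([f.period for f in in_seg])
        hr_rec = 60.0 / float(periods.mean())
        rows.extend(
            [
                (seg.t, "sbp", cmd.sbp, float(sbps.mean()),
                 float(np.abs(sbps - cmd.sbp).max())),
                (seg.t, "dbp", cmd.dbp, float(dbps.mean()),
                 float(np.abs(dbps - cmd.dbp).max())),
                (seg.t, "hr", cmd.hr, hr_rec, abs(hr_rec - cmd.hr)),
            ]
        )
    if not rows:
        raise AnalysisError(
            f"scenario too short: no steady segment retained >= {min_beats} beats"
        )
    return pd.DataFrame(
        rows, columns=["segment_t", "metric", "commanded", "recovered", "abs_error"]
    )


def max_abs_errors(report: pd.DataFrame) -> dict[str, float]:
    """Worst absolute error per metric across all verified segments."""
    return report.groupby("metric")["abs_error"].max().to_dict()


def run_roundtrip(
    scenario: Scenario,
    template: Optional[PulseTemplate] = None,
    config: Optional[EngineConfig] = None,
    quantize: bool = True,
    mapping: MappingConfig = DEFAULT_MAPPING,
    min_beats: int = 5,
) -> tuple[pd.DataFrame, RunReport]:
    """End-to-end verification: synthesize, (optionally) quantize, analyze.

    Runs the deterministic pipeline, passes the stream through the
    voltage/DAC round trip when ``quantize`` is set (as the monitor would
    see it), extracts beats and compares against the commanded vitals.
    """
    template = template or default_template()
    config = config or EngineConfig()
    sink = MemorySink()
    engine_report = run_pipeline(scenario, template, config, sink, mode="deterministic")
    p = sink.pressures()
    if quantize:
        p = code_to_mmhg(
            quantize_to_code(mmhg_to_volts(p, mapping, warn=False), mapping, warn=False),
            mapping,
        )
    boundaries = detect_beats(p, config.fs_out)
    features = extract_features(p, boundaries, config.fs_out)
    return roundtrip_report(scenario, features, min_beats=min_beats), engine_report
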