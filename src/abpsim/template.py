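"""Single-beat pulse templates.

The waveform engine replays one reference arterial beat over and over,
resampled to the commanded heart rate and rescaled to the commanded
pressures.  A :class:`PulseTemplate` holds that reference beat as a
min-max normalized amplitude series (exactly 0 at the diastolic trough,
exactly 1 at the systolic peak) together with the sampling rate and heart
rate of the source recording.  Because real arterial recordings cannot be
redistributed, a parametric synthetic beat — fast systolic upstroke,
exponential diastolic decay, Gaussian dicrotic bump — ships as the default,
carrying the reference metadata of a resting recording (250 Hz, 47 bpm).

Template endpoints must sit near diastole (<= 0.05 normalized) so that
concatenated beats join without a pressure discontinuity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import TemplateError

__all__ = [
    "MIN_SAMPLES",
    "ENDPOINT_MAX",
    "PulseTemplate",
    "normalize_template",
    "make_synthetic_template",
    "default_template",
    "load_template",
    "save_template",
]

#: Shortest template considered a waveform rather than a blip.
MIN_SAMPLES = 8
#: Largest normalized amplitude allowed at either endpoint (diastole proximity).
ENDPOINT_MAX = 0.05

_HR_MAX = 350.0


def _round_half_away(x: float) -> int:
    """Round half away from zero (for non-negative x: floor(x + 0.5))."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class PulseTemplate:
    """A normalized single-beat amplitude series with recording metadata.

    Attributes
    ----------
    samples
        Dimensionless amplitudes in [0, 1] with min exactly 0 and max
        exactly 1; read-only after construction.
    fs
        Sampling rate of the source recording, Hz.
    hr_ref
        Heart rate of the source recording, bpm.
    """

    samples: np.ndarray
    fs: float
    hr_ref: float

    def __post_init__(self) -> None:
        samples = np.ascontiguousarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise TemplateError(f"template samples must be 1-D, got shape {samples.shape}")
        if samples.size < MIN_SAMPLES:
            raise TemplateError(
                f"template too short: {samples.size} samples (need >= {MIN_SAMPLES})"
            )
        if not np.all(np.isfinite(samples)):
            raise TemplateError("template contains non-finite samples")
        if samples.min() != 0.0 or samples.max() != 1.0:
            raise TemplateError(
                f"template not normalized: min {samples.min()!r}, max {samples.max()!r} "
                "(expected exactly 0 and 1)"
            )
        if samples[0] > ENDPOINT_MAX or samples[-1] > ENDPOINT_MAX:
            raise TemplateError(
                f"template endpoints must lie near diastole (<= {ENDPOINT_MAX}); "
                f"got first {samples[0]:.4g}, last {samples[-1]:.4g}"
            )
        if not (math.isfinite(self.fs) and self.fs > 0):
            raise TemplateError(f"sampling rate must be positive, got {self.fs}")
        if not (0 < self.hr_ref <= _HR_MAX):
            raise TemplateError(
                f"reference heart rate must be in (0, {_HR_MAX:g}], got {self.hr_ref}"
            )
        samples.flags.writeable = False
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(self, "hr_ref", float(self.hr_ref))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def beat_duration(self) -> float:
        """Duration of the recorded beat in seconds (n / fs)."""
        return self.samples.size / self.fs


def normalize_template(
    raw: np.ndarray, fs: float, hr_ref: float
) -> PulseTemplate:
    """Min-max normalize a recorded pressure beat into a template.

    ``samples_i = (raw_i - min) / (max - min)`` — idempotent, and invariant
    to positive affine rescaling of the input (gain and offset of the
    acquisition chain drop out).  Metadata is carried through unchanged.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.size < MIN_SAMPLES:
        raise TemplateError(
            f"template too short: {arr.size} samples (need >= {MIN_SAMPLES})"
        )
    if not np.all(np.isfinite(arr)):
        raise TemplateError("template contains non-finite samples")
    lo = arr.min()
    span = arr.max() - lo
    if span == 0:
        raise TemplateError("zero amplitude template: max(raw) == min(raw)")
    return PulseTemplate((arr - lo) / span, fs, hr_ref)


def make_synthetic_template(
    fs: float = 250.0,
    hr_ref: float = 47.0,
    systolic_fraction: float = 0.3,
    dicrotic_amplitude: float = 0.15,
    seed: Optional[int] = None,
) -> PulseTemplate:
    """Build a parametric arterial beat of ``round(fs * 60 / hr_ref)`` samples.

    The beat is a half-cosine systolic upstroke peaking at half the systolic
    fraction of the cycle, an exponential diastolic decay, and a Gaussian
    dicrotic bump shortly after end-systole.  ``dicrotic_amplitude = 0``
    yields a strictly unimodal beat.  A ``seed`` jitters the decay constant
    and dicrotic timing by a few percent (morphology variation between
    "patients"); the call is deterministic for a fixed seed or ``None``.
    """
    if not fs > 0:
        raise TemplateError(f"fs must be positive, got {fs}")
    if not 0 < hr_ref <= _HR_MAX:
        raise TemplateError(f"hr_ref must be in (0, {_HR_MAX:g}], got {hr_ref}")
    if not 0 < systolic_fraction < 1:
        raise TemplateError(
            f"systolic_fraction must be in (0, 1), got {systolic_fraction}"
        )
    if not 0 <= dicrotic_amplitude < 1:
        raise TemplateError(
            f"dicrotic_amplitude must be in [0, 1), got {dicrotic_amplitude}"
        )

    n = _round_half_away(fs * 60.0 / hr_ref)
    if n < MIN_SAMPLES:
        raise TemplateError(
            f"fs/hr_ref combination yields only {n} samples per beat (need >= {MIN_SAMPLES})"
        )

    t_peak = 0.5 * systolic_fraction
    tau = (1.0 - t_peak) / math.log(1.0 / 0.02)  # decay reaches ~2% by cycle end
    t_dicrotic = systolic_fraction + 0.15
    sigma = 0.05
    if seed is not None:
        rng = np.random.default_rng(seed)
        tau *= 1.0 + 0.05 * rng.uniform(-1.0, 1.0)
        t_dicrotic += 0.02 * rng.uniform(-1.0, 1.0)
        sigma *= 1.0 + 0.10 * rng.uniform(-1.0, 1.0)

    t = np.arange(n) / n
    wave = np.where(
        t <= t_peak,
        0.5 * (1.0 - np.cos(np.pi * np.minimum(t, t_peak) / t_peak)),
        np.exp(-(t - t_peak) / tau),
    )
    if dicrotic_amplitude > 0:
        wave = wave + dicrotic_amplitude * np.exp(
            -0.5 * ((t - t_dicrotic) / sigma) ** 2
        )
    wave = (wave - wave.min()) / (wave.max() - wave.min())
    return PulseTemplate(wave, fs, hr_ref)


@lru_cache(maxsize=1)
def default_template() -> PulseTemplate:
    """The packaged default beat: synthetic morphology at 250 Hz, 47 bpm."""
    return make_synthetic_template(fs=250.0, hr_ref=47.0)


def save_template(template: PulseTemplate, path: Union[str, Path]) -> None:
    """Write a template file: ``# key=value`` metadata then one amplitude per line.

    Floats are written with 17 significant digits so save → load round-trips
    bit-identically.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs_hz={template.fs:.17g}\n")
        fh.write(f"# hr_ref_bpm={template.hr_ref:.17g}\n")
        for value in template.samples:
            fh.write(f"{value:.17g}\n")


def load_template(path: Union[str, Path]) -> PulseTemplate:
    """Read a template file written by :func:`save_template`; validates on load."""
    meta: dict[str, float] = {}
    samples: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise TemplateError(f"line {lineno}: malformed metadata line {line!r}")
                key, _, value = body.partition("=")
                try:
                    meta[key.strip()] = float(value)
                except ValueError:
                    raise TemplateError(
                        f"line {lineno}: cannot parse metadata value {value!r}"
                    ) from None
            else:
                try:
                    samples.append(float(line))
                except ValueError:
                    raise TemplateError(
                        f"line {lineno}: cannot parse sample {line!r}"
                    ) from None
    missing = [k for k in ("fs_hz", "hr_ref_bpm") if k not in meta]
    if missing:
        raise TemplateError(f"template file missing metadata: {', '.join(missing)}")
    return PulseTemplate(np.asarray(samples, dtype=float), meta["fs_hz"], meta["hr_ref_bpm"])
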