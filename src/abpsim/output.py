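"""Pressure → voltage → DAC-code output stage.

The monitor's analog input reads 0–5 V as 0–500 mmHg, one volt per
100 mmHg.  This module implements that linear map, the 12-bit quantizer of
the MCP4725-class DAC driving the line, waveform-file I/O, and pluggable
sinks for the waveform engine (CSV file, in-memory, mock DAC).

Quantizer convention (fixed and tested here, since hardware conventions
vary): full scale maps to code 2**bits - 1 and codes are rounded half away
from zero, so 0 V → 0 and 5 V → 4095.  The worst-case pressure error of
the map + quantizer round trip is half an LSB, 0.5 * 500 / 4095 ≈
0.061 mmHg.  Out-of-range pressures are clamped, never raised: the output
stage must not crash a running stream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .errors import HardwareUnavailableError, SinkError

__all__ = [
    "MappingConfig",
    "DEFAULT_MAPPING",
    "VoltageSample",
    "mmhg_to_volts",
    "volts_to_mmhg",
    "quantize_to_code",
    "code_to_volts",
    "code_to_mmhg",
    "write_waveform",
    "read_waveform",
    "WAVEFORM_COLUMNS",
    "FileSink",
    "MockDAC",
    "DacSink",
    "dac_sink",
]

WAVEFORM_COLUMNS = ("t_s", "p_mmhg", "volts", "dac_code")


class RangeClampWarning(UserWarning):
    """An out-of-range value was clamped at the output stage."""


@dataclass(frozen=True)
class MappingConfig:
    """Analog output convention: ``p_max`` mmHg ↔ ``v_max`` V, ``bits``-deep codes."""

    p_max: float = 500.0
    v_max: float = 5.0
    bits: int = 12

    def __post_init__(self) -> None:
        if not self.p_max > 0:
            raise ValueError(f"p_max must be positive, got {self.p_max}")
        if not self.v_max > 0:
            raise ValueError(f"v_max must be positive, got {self.v_max}")
        if self.bits < 1:
            raise ValueError(f"bits must be >= 1, got {self.bits}")

    @property
    def full_scale_code(self) -> int:
        return 2 ** self.bits - 1


DEFAULT_MAPPING = MappingConfig()


@dataclass(frozen=True)
class VoltageSample:
    """One output sample on the analog side: time, volts and DAC code."""

    t: float
    volts: float
    code: int


def _clamp(values: np.ndarray, lo: float, hi: float, what: str, warn: bool) -> np.ndarray:
    clipped = np.clip(values, lo, hi)
    if warn and np.any(clipped != values):
        warnings.warn(
            f"{what} outside [{lo:g}, {hi:g}] clamped at output stage",
            RangeClampWarning,
            stacklevel=3,
        )
    return clipped


def mmhg_to_volts(p, cfg: MappingConfig = DEFAULT_MAPPING, warn: bool = True):
    """Linear pressure → voltage map: v = clamp(p, 0, p_max) * v_max / p_max."""
    arr = np.asarray(p, dtype=float)
    v = _clamp(arr, 0.0, cfg.p_max, "pressure", warn) * (cfg.v_max / cfg.p_max)
    return float(v) if np.isscalar(p) or arr.ndim == 0 else v


def volts_to_mmhg(v, cfg: MappingConfig = DEFAULT_MAPPING):
    """Inverse of :func:`mmhg_to_volts` on [0, v_max]."""
    arr = np.asarray(v, dtype=float)
    p = arr * (cfg.p_max / cfg.v_max)
    return float(p) if np.isscalar(v) or arr.ndim == 0 else p


def quantize_to_code(v, cfg: MappingConfig = DEFAULT_MAPPING, warn: bool = True):
    """Quantize volts to integer DAC codes.

    ``code = round(v * (2**bits - 1) / v_max)`` with round-half-away-from-
    zero, clamped to [0, 2**bits - 1].
    """
    arr = np.asarray(v, dtype=float)
    clipped = _clamp(arr, 0.0, cfg.v_max, "voltage", warn)
    fsc = cfg.full_scale_code
    codes = np.floor(clipped * (fsc / cfg.v_max) + 0.5)
    codes = np.clip(codes, 0, fsc).astype(np.int64)
    return int(codes) if np.isscalar(v) or arr.ndim == 0 else codes


def code_to_volts(code, cfg: MappingConfig = DEFAULT_MAPPING):
    """Volts a DAC code reconstructs to: code * v_max / (2**bits - 1)."""
    arr = np.asarray(code, dtype=float)
    v = arr * (cfg.v_max / cfg.full_scale_code)
    return float(v) if np.isscalar(code) or arr.ndim == 0 else v


def code_to_mmhg(code, cfg: MappingConfig = DEFAULT_MAPPING):
    """Pressure a DAC code reconstructs to (map + quantizer round trip)."""
    return volts_to_mmhg(code_to_volts(code, cfg), cfg)


# --- waveform files --------------------------------------------------------


def write_waveform(
    t: Sequence[float],
    p: Sequence[float],
    path: Union[str, Path],
    cfg: MappingConfig = DEFAULT_MAPPING,
) -> int:
    """Write a pressure stream as CSV ``t_s,p_mmhg,volts,dac_code``.

    Voltages and codes are derived from the pressures through the mapping.
    Floats are written with 6 significant digits (codes exactly); returns
    the number of data rows written.
    """
    t_arr = np.asarray(t, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if t_arr.shape != p_arr.shape:
        raise SinkError(f"t and p length mismatch: {t_arr.shape} vs {p_arr.shape}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(WAVEFORM_COLUMNS) + "\n")
        count = _write_rows(fh, t_arr, p_arr, cfg)
    return count


def _write_rows(fh, t_arr, p_arr, cfg) -> int:
    volts = mmhg_to_volts(p_arr, cfg, warn=False)
    codes = quantize_to_code(volts, cfg, warn=False)
    if np.ndim(volts) == 0:
        volts, codes = np.atleast_1d(volts), np.atleast_1d(codes)
    for ti, pi, vi, ci in zip(np.atleast_1d(t_arr), np.atleast_1d(p_arr), volts, codes):
        fh.write(f"{ti:.6g},{pi:.6g},{vi:.6g},{ci:d}\n")
    return len(np.atleast_1d(t_arr))


def read_waveform(path: Union[str, Path]) -> pd.DataFrame:
    """Read a waveform CSV back into a DataFrame with the standard columns."""
    df = pd.read_csv(path)
    missing = [c for c in WAVEFORM_COLUMNS if c not in df.columns]
    if missing:
        raise SinkError(f"waveform file missing column(s): {', '.join(missing)}")
    return df


class FileSink:
    """Engine sink streaming rows to a waveform CSV file."""

    def __init__(self, path: Union[str, Path], cfg: MappingConfig = DEFAULT_MAPPING):
        self._cfg = cfg
        try:
            self._fh = open(path, "w", encoding="utf-8", newline="")
        except OSError as exc:
            raise SinkError(f"cannot open waveform file {path}: {exc}") from exc
        self._fh.write(",".join(WAVEFORM_COLUMNS) + "\n")
        self.count = 0

    def write(self, t: np.ndarray, p: np.ndarray, beat_index: int) -> None:
        self.count += _write_rows(self._fh, np.asarray(t), np.asarray(p), self._cfg)

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "FileSink":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


# --- DAC sink ---------------------------------------------------------------


class MockDAC:
    """Recording stand-in for the I²C DAC driver: logs every code written."""

    def __init__(self) -> None:
        self.codes: list[int] = []

    def write(self, codes) -> None:
        self.codes.extend(int(c) for c in np.atleast_1d(codes))


class DacSink:
    """Engine sink forwarding quantized codes to a pluggable DAC driver.

    The packaged driver is :class:`MockDAC`; driving real hardware needs an
    external I²C driver object with a ``write(codes)`` method.  Building a
    sink with no driver raises :class:`HardwareUnavailableError` — never a
    silent no-op.
    """

    def __init__(self, driver=None, cfg: MappingConfig = DEFAULT_MAPPING):
        if driver is None:
            raise HardwareUnavailableError(
                "hardware unavailable: no DAC driver installed "
                "(pass MockDAC() for a recording stub)"
            )
        self._driver = driver
        self._cfg = cfg
        self.count = 0

    def write(self, t: np.ndarray, p: np.ndarray, beat_index: int) -> None:
        codes = quantize_to_code(
            mmhg_to_volts(np.asarray(p, dtype=float), self._cfg, warn=False),
            self._cfg,
            warn=False,
        )
        self._driver.write(codes)
        self.count += len(np.atleast_1d(codes))


def dac_sink(driver=None, cfg: MappingConfig = DEFAULT_MAPPING) -> DacSink:
    """Factory for :class:`DacSink` (interface named after the hardware stage)."""
    return DacSink(driver, cfg)
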