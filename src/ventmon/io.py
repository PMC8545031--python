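"""Trace file I/O, sensor calibration, and config serialization.

Traces travel as plain CSV — either a single ``pressure`` column with an
explicitly stated sample rate, or ``time,pressure`` pairs from which the
sample rate is inferred.  This mirrors the raw data path of the target
hardware (an ADC stream at a fixed rate) while keeping fixtures
human-readable and diffable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PressureTrace",
    "SensorCalibration",
    "TraceFormatError",
    "read_pressure_csv",
    "write_pressure_csv",
    "counts_to_pressure",
    "load_config",
    "dump_config",
]

#: Maximum relative jitter tolerated in the time column of a two-column
#: trace before sampling is declared irregular.
MAX_TIME_JITTER = 0.01


class TraceFormatError(ValueError):
    """A trace file could not be interpreted as a uniform pressure series."""


@dataclass
class PressureTrace:
    """A uniformly sampled airway-pressure series in cm H2O."""

    fs: float
    samples: np.ndarray
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError("pressure trace is empty")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class SensorCalibration:
    """Affine map from raw ADC counts to pressure in cm H2O.

    The default spans a 10-bit converter over a 0-100 cm H2O sensor.
    """

    offset: float = 0.0  # cm H2O at zero counts
    gain: float = 100.0 / 1023.0  # cm H2O per count
    count_min: int = 0
    count_max: int = 1023

    def __post_init__(self) -> None:
        if self.gain == 0:
            raise ValueError("gain must be nonzero")
        if self.count_min >= self.count_max:
            raise ValueError(
                f"count range must be nondegenerate, got [{self.count_min}, {self.count_max}]"
            )


def counts_to_pressure(counts: Sequence[int], cal: SensorCalibration) -> np.ndarray:
    """Convert raw sensor counts to pressure via the linear calibration."""
    arr = np.asarray(counts)
    bad = (arr < cal.count_min) | (arr > cal.count_max)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"count {arr[i]} at index {i} outside range [{cal.count_min}, {cal.count_max}]"
        )
    return cal.offset + cal.gain * arr.astype(float)


def _looks_numeric(row: Sequence[str]) -> bool:
    try:
        [float(x) for x in row]
        return True
    except (TypeError, ValueError):
        return False


def read_pressure_csv(path: str | Path, fs_override: Optional[float] = None) -> PressureTrace:
    """Read a one- or two-column pressure trace.

    Two-column files are interpreted as ``time_s,pressure``; the sample
    rate is inferred from the median time step, and more than 1%
    relative jitter in the steps is rejected as irregular sampling.
    One-column files require ``fs_override``.  A header row is optional.
    """
    path = Path(path)
    first = pd.read_csv(path, nrows=1, header=None, dtype=str)
    has_header = not _looks_numeric(first.iloc[0].tolist())
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] not in (1, 2):
        raise TraceFormatError(
            f"{path}: expected 1 or 2 columns, found {df.shape[1]}"
        )
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values).all(axis=1))
    if bad.size:
        row = int(bad[0]) + (2 if has_header else 1)  # 1-based file line
        raise TraceFormatError(f"{path}: non-numeric or missing value at line {row}")

    if values.shape[1] == 2:
        t, p = values[:, 0], values[:, 1]
        dt = np.diff(t)
        if dt.size == 0:
            raise TraceFormatError(f"{path}: need at least 2 rows to infer fs")
        med = float(np.median(dt))
        if med <= 0:
            raise TraceFormatError(f"{path}: time column is not increasing")
        if np.max(np.abs(dt - med)) > MAX_TIME_JITTER * med:
            raise TraceFormatError(
                f"{path}: irregular sampling (time-step jitter exceeds "
                f"{MAX_TIME_JITTER:.0%} of the median step {med:.6g} s)"
            )
        fs = 1.0 / med
        if fs_override is not None and not math_isclose(fs_override, fs):
            raise TraceFormatError(
                f"{path}: fs override {fs_override} conflicts with inferred {fs:.6g}"
            )
        return PressureTrace(fs=fs, samples=p, source={"path": str(path)})

    if fs_override is None:
        raise TraceFormatError(
            f"{path}: single-column trace requires an explicit sample rate"
        )
    return PressureTrace(fs=fs_override, samples=values[:, 0], source={"path": str(path)})


def math_isclose(a: float, b: float, rel: float = 1e-6) -> bool:
    return abs(a - b) <= rel * max(abs(a), abs(b))


def write_pressure_csv(
    path: str | Path, trace: PressureTrace, include_time: bool = True
) -> None:
    """Write a trace as CSV (full float precision, round-trip safe)."""
    path = Path(path)
    if include_time:
        t = np.arange(trace.samples.size) / trace.fs
        df = pd.DataFrame({"time_s": t, "pressure": trace.samples})
    else:
        df = pd.DataFrame({"pressure": trace.samples})
    df.to_csv(path, index=False, float_format="%.12g")


def load_config(path: str | Path) -> dict:
    """Load a YAML config; an empty file is a valid (all-defaults) config."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise TraceFormatError(f"{path}: config must be a mapping")
    return data


def dump_config(path: str | Path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
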