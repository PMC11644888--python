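"""Timestamped frequency series and its CSV representation.

``FrequencySeries`` is the container that flows through the whole pipeline:
raw (possibly jittered) samples from the front end, the uniformly resampled
signal, the band-passed signal and the detector-unit derivative all live in
it. On disk it is a two-column CSV with header ``time_s,frequency_hz``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FrequencySeries", "SeriesFormatError", "read_series", "write_series"]

CSV_COLUMNS = ("time_s", "frequency_hz")


class SeriesFormatError(ValueError):
    """Raised when a series file violates the CSV contract."""


@dataclass(frozen=True)
class FrequencySeries:
    """Resonance-frequency samples at strictly increasing times.

    Attributes
    ----------
    times:
        Sample times in seconds, strictly increasing.
    values:
        Resonance frequency in Hz at each time.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if times.shape != values.shape:
            raise ValueError(
                f"length mismatch: {times.shape[0]} times vs {values.shape[0]} values"
            )
        if times.size == 0:
            raise ValueError("series must be non-empty")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        """Recording length in seconds, counting one trailing sample period."""
        if len(self) == 1:
            return 0.0
        return float(self.times[-1] - self.times[0] + self.median_dt)

    @property
    def median_dt(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(np.median(np.diff(self.times)))

    @property
    def sample_rate(self) -> float:
        """Nominal sample rate in Hz (reciprocal median spacing)."""
        dt = self.median_dt
        return 1.0 / dt if dt > 0 else float("nan")

    def is_uniform(self, rtol: float = 1e-6) -> bool:
        """True when sample spacing is constant to relative tolerance ``rtol``."""
        if len(self) < 3:
            return True
        dt = np.diff(self.times)
        return bool(np.all(np.abs(dt - dt[0]) <= rtol * abs(dt[0])))

    def crop(self, start: float, stop: float) -> "FrequencySeries":
        """Samples with ``start <= t < stop``."""
        mask = (self.times >= start) & (self.times < stop)
        return FrequencySeries(self.times[mask], self.values[mask])


def read_series(path: str | Path) -> FrequencySeries:
    """Read a ``time_s,frequency_hz`` CSV, enforcing strictly increasing time.

    Raises :class:`SeriesFormatError` with the offending 1-based data line
    number on a non-monotone or duplicated timestamp.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SeriesFormatError(f"{path}: empty file") from exc
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SeriesFormatError(f"{path}: missing columns {missing}; expected {list(CSV_COLUMNS)}")
    if len(frame) == 0:
        raise SeriesFormatError(f"{path}: no data rows")
    times = frame["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        # +2: one for the header line, one for 0- vs 1-based row numbering.
        line = int(bad[0]) + 3
        raise SeriesFormatError(
            f"{path}: time_s not strictly increasing at line {line} "
            f"(t={times[bad[0] + 1]!r} follows t={times[bad[0]]!r})"
        )
    return FrequencySeries(times, frame["frequency_hz"].to_numpy(dtype=float))


def write_series(series: FrequencySeries, path: str | Path) -> None:
    """Write a series as ``time_s,frequency_hz`` CSV (round-trips to 1e-9)."""
    frame = pd.DataFrame({"time_s": series.times, "frequency_hz": series.values})
    frame.to_csv(path, index=False, float_format="%.17g")
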