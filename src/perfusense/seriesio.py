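"""Timestamped concentration series and their on-disk CSV dialect.

A series file is plain CSV with a small comment header::

    # series: blood_creatinine
    # units: mg/dL
    # t_unit: min
    time,value
    0.0,8.0
    1.0,7.98

Parsing is strict: non-numeric rows and non-increasing timestamps are
rejected with the offending line number. Round trips are lossless at
float repr precision; CRLF and LF files parse identically.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import FormatError, ValidationError


@dataclass
class TimeSeries:
    """A strictly time-ordered scalar series."""

    times: np.ndarray
    values: np.ndarray
    name: str = ""
    units: str = ""
    t_unit: str = "min"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValidationError("times and values must be 1-D arrays of equal length")
        if len(self.times) == 0:
            raise ValidationError("series must be nonempty")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("series timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def shifted(self, delta: float) -> "TimeSeries":
        """Pure time shift: identical values at times + delta."""
        return replace(self, times=self.times + delta)

    def scaled(self, factor: float) -> "TimeSeries":
        return replace(self, values=self.values * factor)

    def window(self, t0: float, t1: float) -> "TimeSeries":
        """Restrict to samples with t0 <= t <= t1."""
        m = (self.times >= t0) & (self.times <= t1)
        if not m.any():
            raise ValidationError(f"no samples in window [{t0}, {t1}]")
        return replace(self, times=self.times[m], values=self.values[m])


def write_series(path: str | Path, series: TimeSeries) -> None:
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write(f"# series: {series.name}\n")
        fh.write(f"# units: {series.units}\n")
        fh.write(f"# t_unit: {series.t_unit}\n")
        fh.write("time,value\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{float(t)!r},{float(v)!r}\n")


def read_series(path: str | Path) -> TimeSeries:
    path = Path(path)
    meta = {"series": "", "units": "", "t_unit": "min"}
    times: list[float] = []
    values: list[float] = []
    with path.open("r", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if line.lower() == "time,value":
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 'time,value', got {line!r}")
            try:
                t, v = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
            if times and t <= times[-1]:
                raise FormatError(
                    f"{path}:{lineno}: time {t} not strictly increasing "
                    f"(previous {times[-1]})"
                )
            times.append(t)
            values.append(v)
    if not times:
        raise FormatError(f"{path}: no data rows")
    return TimeSeries(
        np.array(times), np.array(values),
        name=meta["series"], units=meta["units"], t_unit=meta["t_unit"],
    )


def write_spectrum_csv(fh: io.TextIOBase, spec) -> None:
    """Append one detector frame in the spectrum CSV dialect."""
    fh.write(f"# led_id: {spec.led_id}\n")
    fh.write(f"# is_dark: {int(spec.is_dark)}\n")
    fh.write(f"# integration_time_s: {spec.integration_time_s!r}\n")
    fh.write(f"# timestamp_s: {spec.timestamp_s!r}\n")
    fh.write("wavelength_nm,counts\n")
    for wl, c in zip(spec.grid.wavelengths, spec.counts):
        fh.write(f"{float(wl)!r},{float(c)!r}\n")
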