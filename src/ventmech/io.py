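"""Reading and writing three-column ventilator time-series files.

The on-disk dialect is plain UTF-8 text, one sample per line, three
tab-separated numeric columns in fixed order: airway pressure (mbar),
flow (L/s), volume (L).  There is no header row; the sampling interval is
not stored in the file and is supplied by the reader (default 10 ms).
Blank lines and trailing whitespace are tolerated; anything else is a
hard parse error — these files are machine-generated and silent repair
would hide acquisition faults.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Union

import numpy as np

__all__ = [
    "WaveformRecord",
    "WaveformParseError",
    "read_waveform",
    "write_waveform",
    "slice_record",
]

Source = Union[str, Path, IO[str]]


class WaveformParseError(ValueError):
    """Raised when a waveform file violates the three-column dialect."""


@dataclass(frozen=True)
class WaveformRecord:
    """Uniformly sampled pressure/flow/volume triplet.

    Attributes
    ----------
    pressure : ndarray
        Airway pressure P(t) in mbar.
    flow : ndarray
        Flow V'(t) in L/s.
    volume : ndarray
        Volume V(t) in L.
    h : float
        Sampling interval in seconds (default 0.01, i.e. 10 ms).
    t0 : float
        Time of the first sample in seconds.
    """

    pressure: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    h: float = 0.01
    t0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pressure", "flow", "volume"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        n = self.pressure.shape[0]
        if self.pressure.ndim != 1 or self.flow.shape != (n,) or self.volume.shape != (n,):
            raise ValueError("pressure, flow and volume must be 1-D series of equal length")
        if n < 1:
            raise ValueError("a waveform record needs at least one sample")
        if not (self.h > 0):
            raise ValueError(f"sampling interval must be positive, got h={self.h}")
        for name in ("pressure", "flow", "volume"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name} series")
        if not np.isfinite(self.t0):
            raise ValueError("t0 must be finite")

    @property
    def n(self) -> int:
        return self.pressure.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times t0 + i*h, seconds."""
        return self.t0 + self.h * np.arange(self.n)

    @property
    def duration(self) -> float:
        return self.n * self.h

    def with_channels(self, **channels: np.ndarray) -> "WaveformRecord":
        """Copy of the record with one or more series replaced."""
        return replace(self, **channels)


def read_waveform(source: Source, h: float = 0.01, t0: float = 0.0) -> WaveformRecord:
    """Parse a three-column tab-separated waveform file.

    Parameters
    ----------
    source : path or open text stream
    h : float
        Sampling interval in seconds.  The study's ventilator samples
        every 10 ms, hence the default.

    Raises
    ------
    WaveformParseError
        On a malformed line (wrong field count, non-numeric field),
        naming the 1-based line number, or on an empty file.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text(encoding="utf-8").splitlines()

    pressure, flow, volume = [], [], []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 3:
            raise WaveformParseError(
                f"line {lineno}: expected 3 tab-separated fields, got {len(fields)}"
            )
        try:
            p, f, v = (float(x) for x in fields)
        except ValueError as exc:
            raise WaveformParseError(f"line {lineno}: non-numeric field ({exc})") from None
        pressure.append(p)
        flow.append(f)
        volume.append(v)

    if not pressure:
        raise WaveformParseError("empty waveform file")
    return WaveformRecord(
        pressure=np.array(pressure),
        flow=np.array(flow),
        volume=np.array(volume),
        h=h,
        t0=t0,
    )


def write_waveform(record: WaveformRecord, sink: Source, decimals: int = 6) -> None:
    """Write a record in the three-column tab-separated dialect.

    One row per sample, column order pressure, flow, volume, fixed-point
    with ``decimals`` digits after the decimal point.
    """
    fmt = f"%.{int(decimals)}f"
    data = np.column_stack([record.pressure, record.flow, record.volume])
    if hasattr(sink, "write"):
        np.savetxt(sink, data, fmt=fmt, delimiter="\t")
    else:
        with open(sink, "w", encoding="utf-8", newline="\n") as fh:
            np.savetxt(fh, data, fmt=fmt, delimiter="\t")


def waveform_to_string(record: WaveformRecord, decimals: int = 6) -> str:
    buf = _stdio.StringIO()
    write_waveform(record, buf, decimals=decimals)
    return buf.getvalue()


def slice_record(record: WaveformRecord, start: int, end: int) -> WaveformRecord:
    """Sub-record of rows ``start:end`` with t0 shifted by ``start*h``.

    Supports the cross-validation workflow of fitting on one time period
    and validating on another cut from the same recording.
    """
    if not (0 <= start < end <= record.n):
        raise IndexError(
            f"slice [{start}, {end}) out of range for record of length {record.n}"
        )
    return WaveformRecord(
        pressure=record.pressure[start:end].copy(),
        flow=record.flow[start:end].copy(),
        volume=record.volume[start:end].copy(),
        h=record.h,
        t0=record.t0 + start * record.h,
    )
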