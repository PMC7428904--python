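"""RR-interval (inter-beat-interval) containers and plain-text I/O.

The RR series is the universal currency of the package: an ordered sequence
of strictly positive inter-beat intervals in milliseconds.  Beat times are
derived, never stored: ``beat_times[i]`` is the time (in seconds, origin at
the first detected beat) of the beat that *terminates* interval ``i``, i.e.
the cumulative sum of the intervals.

Two on-disk formats are supported, both plain text:

* ``lines_ms`` — one interval (ms) per line, UTF-8, ``#`` comment lines and
  blank lines ignored.
* ``csv_time_interval`` — two comma-separated columns ``beat_time_s, rr_ms``
  with an optional header row (auto-detected).  The time column is validated
  against the cumulative sum of the intervals but never trusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np

__all__ = [
    "BeatFlag",
    "RRSeries",
    "Recording",
    "read_rr",
    "write_rr",
    "from_beat_times",
]

log = logging.getLogger(__name__)


class BeatFlag(IntEnum):
    """Per-interval provenance flag."""

    NORMAL = 0
    CORRECTED = 1


@dataclass
class RRSeries:
    """An ordered series of inter-beat intervals.

    Parameters
    ----------
    intervals
        Strictly positive inter-beat intervals in milliseconds.
    flags
        Per-interval :class:`BeatFlag` values; defaults to all ``NORMAL``.
    """

    intervals: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if self.intervals.size and not np.all(np.isfinite(self.intervals)):
            raise ValueError("intervals must be finite")
        if np.any(self.intervals <= 0):
            bad = int(np.argmax(self.intervals <= 0))
            raise ValueError(f"non-positive interval at index {bad}")
        if self.flags is None:
            self.flags = np.zeros(self.intervals.size, dtype=np.int8)
        else:
            self.flags = np.asarray(self.flags, dtype=np.int8)
        if self.flags.shape != self.intervals.shape:
            raise ValueError("flags must align with intervals")

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def beat_times(self) -> np.ndarray:
        """Seconds since the first beat, one entry per interval."""
        return np.cumsum(self.intervals) / 1000.0

    @property
    def duration(self) -> float:
        """Total span of the series in seconds."""
        return float(self.beat_times[-1]) if len(self) else 0.0

    @property
    def n_corrected(self) -> int:
        return int(np.sum(self.flags == BeatFlag.CORRECTED))

    def copy(self) -> "RRSeries":
        return RRSeries(self.intervals.copy(), self.flags.copy())


@dataclass
class Recording:
    """One device's RR recording for one subject.

    ``device`` names the arm of the comparison: ``"reference"`` for the
    ECG-derived series, ``"test"`` for the chest-strap/app-derived series.
    """

    subject_id: str
    device: str
    rr: RRSeries
    meta: dict = field(default_factory=dict)

    DEVICES = ("reference", "test")

    def __post_init__(self) -> None:
        if self.device not in self.DEVICES:
            raise ValueError(
                f"device must be one of {self.DEVICES}, got {self.device!r}"
            )


def from_beat_times(times) -> RRSeries:
    """Build an :class:`RRSeries` from strictly increasing beat times (s)."""
    times = np.asarray(times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two beat times")
    dt = np.diff(times)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0))
        raise ValueError(f"beat times not strictly increasing at index {bad + 1}")
    return RRSeries(dt * 1000.0)


def _parse_float(token: str, lineno: int, path) -> float:
    try:
        return float(token)
    except ValueError as exc:
        raise ValueError(f"{path}: line {lineno}: not a number: {token!r}") from exc


def read_rr(path, format: str = "lines_ms") -> RRSeries:
    """Read an RR series from a plain-text file.

    Raises ``ValueError`` naming the offending line on non-numeric or
    non-positive intervals, and on an empty file.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    intervals: list[float] = []
    if format == "lines_ms":
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            value = _parse_float(line, lineno, path)
            if value <= 0:
                raise ValueError(f"{path}: line {lineno}: non-positive interval {value}")
            intervals.append(value)
    elif format == "csv_time_interval":
        times: list[float] = []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns")
            if lineno == 1 or (not intervals and not times):
                # header auto-detection: a non-numeric first data row is a header
                try:
                    float(parts[0])
                except ValueError:
                    continue
            t = _parse_float(parts[0], lineno, path)
            value = _parse_float(parts[1], lineno, path)
            if value <= 0:
                raise ValueError(f"{path}: line {lineno}: non-positive interval {value}")
            times.append(t)
            intervals.append(value)
        if intervals:
            stated = np.asarray(times)
            recomputed = np.cumsum(intervals) / 1000.0
            worst = float(np.max(np.abs(stated - recomputed))) * 1000.0
            if worst > 1.0:
                log.warning(
                    "%s: stated beat times deviate from cumulative intervals "
                    "by up to %.3f ms; times recomputed from intervals",
                    path,
                    worst,
                )
    else:
        raise ValueError(f"unknown format {format!r}")
    if not intervals:
        raise ValueError(f"{path}: no RR intervals found")
    return RRSeries(np.asarray(intervals))


def write_rr(rr: RRSeries, path, format: str = "lines_ms") -> None:
    """Write an RR series; refuses empty series.

    Fixed ``%.3f`` formatting makes output byte-stable and guarantees a
    read→write round trip exact to 1e-3 ms.
    """
    if len(rr) == 0:
        raise ValueError("refusing to write an empty RR series")
    path = Path(path)
    if format == "lines_ms":
        body = "\n".join(f"{v:.3f}" for v in rr.intervals) + "\n"
    elif format == "csv_time_interval":
        lines = ["beat_time_s,rr_ms"]
        for t, v in zip(rr.beat_times, rr.intervals):
            lines.append(f"{t:.6f},{v:.3f}")
        body = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unknown format {format!r}")
    path.write_text(body, encoding="utf-8")
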