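"""The 9-window analysis scheme for a 5-minute recording.

Five consecutive 1-minute windows (0-1, 1-2, 2-3, 3-4, 4-5 min; class
``ultra_short``), three cumulative windows (0-2, 0-3, 0-4 min; class
``short``) and the 5-minute ``standard`` window (0-5 min).  An interval
belongs to a window iff its *terminating* beat time t satisfies
``start < t <= end``, which makes the five ultra-short windows an exact
partition of the standard window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .rr import RRSeries

__all__ = ["SegmentSpec", "default_scheme", "parse_segments", "extract", "STANDARD_LABEL"]

log = logging.getLogger(__name__)

STANDARD_LABEL = "0-5"

#: tolerance (s) before a recording is considered too short for a window
SPAN_TOLERANCE_S = 2.0


@dataclass(frozen=True)
class SegmentSpec:
    """A labelled half-open (start, end] analysis window, in seconds."""

    label: str
    start: float
    end: float
    window_class: str  # ultra_short | short | standard

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("need 0 <= start < end")


def default_scheme() -> list[SegmentSpec]:
    """The nine windows of the ultra-short-term validation design."""
    segs = [
        SegmentSpec(f"{m}-{m + 1}", 60.0 * m, 60.0 * (m + 1), "ultra_short")
        for m in range(5)
    ]
    segs += [SegmentSpec(f"0-{m}", 0.0, 60.0 * m, "short") for m in (2, 3, 4)]
    segs.append(SegmentSpec(STANDARD_LABEL, 0.0, 300.0, "standard"))
    return segs


def parse_segments(text: str) -> list[SegmentSpec]:
    """Parse ``"a-b,a-b,..."`` (minutes) into custom segments."""
    segs = []
    for chunk in text.split(","):
        a, b = chunk.strip().split("-")
        start, end = 60.0 * float(a), 60.0 * float(b)
        segs.append(SegmentSpec(chunk.strip(), start, end, "custom"))
    return segs


def extract(rr: RRSeries, seg: SegmentSpec) -> RRSeries:
    """Sub-series of intervals whose terminating beat falls in (start, end]."""
    bt = rr.beat_times
    if bt[-1] < seg.end - SPAN_TOLERANCE_S:
        log.warning(
            "recording spans %.1f s, short of window %s (ends %.0f s)",
            bt[-1],
            seg.label,
            seg.end,
        )
    mask = (bt > seg.start) & (bt <= seg.end)
    if not mask.any():
        raise ValueError(f"no intervals in window {seg.label}")
    return RRSeries(rr.intervals[mask], rr.flags[mask])
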