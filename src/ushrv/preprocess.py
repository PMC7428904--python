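"""Artefact handling and smoothness-priors detrending for RR series.

The preprocessing chain mirrors the common research workflow for chest-strap
and ECG-derived RR data: (1) flag ectopic/aberrant intervals by their
deviation from a local median, (2) replace flagged intervals by cubic-spline
interpolation over their unflagged neighbours in beat-index space, and
(3) remove slow trends with the smoothness-priors method — a ridge-type fit
penalising the second difference of the series, with regularisation
parameter lambda (default 500).

Artefact sensitivity levels follow the documented threshold ladder used by
standard HRV software: the absolute deviation (in seconds) from the local
median above which an interval is flagged is

    very_low 0.45, low 0.35, medium 0.25, strong 0.15, very_strong 0.05

and ``none`` disables detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.interpolate import CubicSpline
from scipy.linalg import solveh_banded

from .rr import BeatFlag, RRSeries

__all__ = [
    "ARTEFACT_THRESHOLDS_S",
    "PreprocessConfig",
    "detect_artefacts",
    "correct_artefacts",
    "detrend_smoothness_priors",
    "preprocess",
]

log = logging.getLogger(__name__)

ARTEFACT_THRESHOLDS_S: dict[str, float | None] = {
    "none": None,
    "very_low": 0.45,
    "low": 0.35,
    "medium": 0.25,
    "strong": 0.15,
    "very_strong": 0.05,
}


@dataclass
class PreprocessConfig:
    """Settings for the artefact/detrending chain.

    artefact_level
        One of the keys of :data:`ARTEFACT_THRESHOLDS_S`.
    detrend_lambda
        Smoothness-priors regularisation parameter (dimensionless, >= 0);
        0 disables nothing but reduces the trend to the series itself,
        i.e. the output collapses to its mean.  Set to ``None`` to skip
        detrending entirely.
    median_window
        Odd number of neighbouring intervals (excluding the candidate)
        over which the local median is taken.
    """

    artefact_level: str = "strong"
    detrend_lambda: float | None = 500.0
    median_window: int = 11

    def __post_init__(self) -> None:
        if self.artefact_level not in ARTEFACT_THRESHOLDS_S:
            raise ValueError(f"unknown artefact level {self.artefact_level!r}")
        if self.detrend_lambda is not None and self.detrend_lambda < 0:
            raise ValueError("detrend_lambda must be >= 0")
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 3")


def detect_artefacts(rr: RRSeries, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Flag intervals deviating from their local median.

    Interval ``i`` is flagged iff ``|RR_i - median(nearest median_window
    intervals, excluding i)|`` exceeds the level's threshold.  Returns a
    boolean array aligned with ``rr.intervals``.
    """
    cfg = cfg or PreprocessConfig()
    z = rr.intervals
    n = z.size
    thr = ARTEFACT_THRESHOLDS_S[cfg.artefact_level]
    if thr is None:
        return np.zeros(n, dtype=bool)
    if n < cfg.median_window:
        log.warning(
            "series of %d intervals shorter than median window %d; no artefact scan",
            n,
            cfg.median_window,
        )
        return np.zeros(n, dtype=bool)
    w = min(cfg.median_window, n - 1)  # neighbours used, excluding self
    width = w + 1
    starts = np.clip(np.arange(n) - width // 2, 0, n - width)
    windows = sliding_window_view(z, width)[starts].astype(float).copy()
    windows[np.arange(n), np.arange(n) - starts] = np.nan
    local_median = np.nanmedian(windows, axis=1)
    return np.abs(z - local_median) > thr * 1000.0


def correct_artefacts(rr: RRSeries, flags: np.ndarray) -> RRSeries:
    """Replace flagged intervals by cubic-spline interpolation.

    The spline runs over unflagged intervals in beat-index space, so the
    beat count is preserved.  Flagged intervals before the first (or after
    the last) unflagged interval take the nearest unflagged value rather
    than a polynomial extrapolation, which can be wildly non-physiological
    at the series edges.
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != rr.intervals.shape:
        raise ValueError("flags must align with intervals")
    if not flags.any():
        return rr.copy()
    if flags.all():
        raise ValueError("all intervals flagged; series is uncorrectable")
    z = rr.intervals.copy()
    idx = np.arange(z.size)
    good = ~flags
    if good.sum() >= 4:
        spline = CubicSpline(idx[good], z[good], extrapolate=False)
        repl = spline(idx[flags])
        # outside the hull of good beats: nearest good value
        repl = np.where(np.isnan(repl), np.interp(idx[flags], idx[good], z[good]), repl)
    else:
        repl = np.interp(idx[flags], idx[good], z[good])
    repl = np.clip(repl, 1.0, None)  # guard against a pathological undershoot
    z[flags] = repl
    new_flags = rr.flags.copy()
    new_flags[flags] = BeatFlag.CORRECTED
    return RRSeries(z, new_flags)


def _second_difference_penalty_bands(n: int, lam: float) -> np.ndarray:
    """Upper bands of I + lam^2 * D2'D2 for ``solveh_banded`` (n >= 6)."""
    d0 = np.full(n, 6.0)
    d0[[0, -1]] = 1.0
    d0[[1, -2]] = 5.0
    d1 = np.full(n - 1, -4.0)
    d1[[0, -1]] = -2.0
    d2 = np.ones(n - 2)
    lam2 = lam * lam
    ab = np.zeros((3, n))
    ab[0, 2:] = lam2 * d2
    ab[1, 1:] = lam2 * d1
    ab[2, :] = 1.0 + lam2 * d0
    return ab


def smoothness_priors_trend(z: np.ndarray, lam: float) -> np.ndarray:
    """Solve (I + lam^2 D2'D2) trend = z for the low-frequency trend."""
    z = np.asarray(z, dtype=float)
    n = z.size
    if n < 3:
        raise ValueError("need at least 3 samples to detrend")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        return z.copy()
    if n < 6:
        d2 = np.diff(np.eye(n), n=2, axis=0)
        m = np.eye(n) + lam * lam * d2.T @ d2
        return np.linalg.solve(m, z)
    return solveh_banded(_second_difference_penalty_bands(n, lam), z, lower=False)


def detrend_smoothness_priors(rr: RRSeries, lam: float = 500.0) -> RRSeries:
    """Remove the smoothness-priors trend, restoring the series mean.

    Output intervals are ``z - trend + mean(z)`` so time-domain metrics stay
    in milliseconds around the physiological mean.  Length and mean are
    preserved; variance never increases.
    """
    z = rr.intervals
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if z.size < 3:
        raise ValueError("need at least 3 samples to detrend")
    if np.ptp(z) == 0:  # constant series: trend is the series itself, exactly
        return rr.copy()
    trend = smoothness_priors_trend(z, lam)
    out = z - trend + z.mean()
    return RRSeries(np.clip(out, 1e-6, None), rr.flags.copy())


def preprocess(rr: RRSeries, cfg: PreprocessConfig | None = None) -> RRSeries:
    """Full chain: detect -> correct -> detrend (per the config)."""
    cfg = cfg or PreprocessConfig()
    flags = detect_artefacts(rr, cfg)
    out = correct_artefacts(rr, flags) if flags.any() else rr.copy()
    if cfg.detrend_lambda is not None and len(out) >= 3:
        out = detrend_smoothness_priors(out, cfg.detrend_lambda)
    return out
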