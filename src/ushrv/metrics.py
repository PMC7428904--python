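"""Time- and frequency-domain HRV metrics on an RR segment.

Six endpoints are computed per segment:

* SDNN — sample standard deviation of the intervals (ms),
* RMSSD — root mean square of successive differences (ms),
* pNN50 — percentage of successive differences exceeding 50 ms,
* nVLF, nLF, nHF — normalised band powers (nu) of the RR tachogram,
  nX = X / (VLF + LF + HF) x 100, with bands VLF [0, 0.04), LF [0.04, 0.15)
  and HF [0.15, 0.4) Hz.

The tachogram is resampled to an even 4 Hz grid by cubic spline, the mean
is removed, and the one-sided PSD is estimated by Welch's method (Hann
window, 256-sample segments — 64 s at 4 Hz — with 50% overlap, per-segment
linear detrend).  Windows shorter than 64 s therefore fall back to a single
full-length Hann periodogram.  Total power is defined as VLF+LF+HF, so the
three normalised powers always sum to 100 nu when defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import welch

from .preprocess import PreprocessConfig, correct_artefacts, detect_artefacts, detrend_smoothness_priors
from .rr import RRSeries

__all__ = [
    "DEFAULT_BANDS",
    "SpectralResult",
    "HRVMetrics",
    "sdnn",
    "rmssd",
    "pnn50",
    "interpolate_tachogram",
    "psd",
    "band_powers",
    "normalized_powers",
    "spectral_analysis",
    "compute_metrics",
]

#: [low, high) band edges in Hz
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "vlf": (0.0, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.4),
}

METRIC_NAMES = ("sdnn", "rmssd", "pnn50", "nvlf", "nlf", "nhf")
TIME_DOMAIN = ("sdnn", "rmssd", "pnn50")
FREQ_DOMAIN = ("nvlf", "nlf", "nhf")


@dataclass
class SpectralResult:
    """One-sided PSD of the RR tachogram plus band powers."""

    freqs: np.ndarray  # Hz
    psd: np.ndarray  # ms^2/Hz
    vlf: float
    lf: float
    hf: float
    total_power: float  # ms^2, = vlf + lf + hf
    nvlf: float
    nlf: float
    nhf: float
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))


@dataclass
class HRVMetrics:
    """The six per-segment endpoints plus bookkeeping."""

    sdnn: float
    rmssd: float
    pnn50: float
    nvlf: float
    nlf: float
    nhf: float
    n_intervals: int
    quality: str = "ok"

    def as_dict(self) -> dict:
        return {
            "sdnn": self.sdnn,
            "rmssd": self.rmssd,
            "pnn50": self.pnn50,
            "nvlf": self.nvlf,
            "nlf": self.nlf,
            "nhf": self.nhf,
            "n_intervals": self.n_intervals,
            "quality": self.quality,
        }


def _intervals(rr) -> np.ndarray:
    z = rr.intervals if isinstance(rr, RRSeries) else np.asarray(rr, dtype=float)
    return z


def sdnn(rr) -> float:
    """Sample (N-1) standard deviation of the intervals, ms."""
    z = _intervals(rr)
    if z.size < 2:
        raise ValueError("SDNN needs at least 2 intervals")
    return float(np.std(z, ddof=1))


def rmssd(rr) -> float:
    """Root mean square of successive differences, ms (mean over N-1 diffs)."""
    z = _intervals(rr)
    if z.size < 2:
        raise ValueError("RMSSD needs at least 2 intervals")
    d = np.diff(z)
    return float(np.sqrt(np.mean(d * d)))


def pnn50(rr) -> float:
    """Percentage of successive absolute differences strictly above 50 ms."""
    z = _intervals(rr)
    if z.size < 2:
        raise ValueError("pNN50 needs at least 2 intervals")
    d = np.abs(np.diff(z))
    return float(100.0 * np.count_nonzero(d > 50.0) / d.size)


def interpolate_tachogram(rr: RRSeries, fs: float = 4.0):
    """Cubic-spline resampling of (beat_times, intervals) onto an even grid.

    Returns ``(t_grid, signal)`` with the signal mean removed after
    interpolation.  The grid runs from the first to the last beat time with
    spacing ``1/fs``.
    """
    if len(rr) < 4:
        raise ValueError("tachogram interpolation needs at least 4 intervals")
    t = rr.beat_times
    span = t[-1] - t[0]
    if span < 2.0 / fs:
        raise ValueError("RR series spans less than two grid samples")
    spline = CubicSpline(t, rr.intervals)
    n = int(np.floor(span * fs)) + 1
    grid = t[0] + np.arange(n) / fs
    sig = spline(grid)
    return grid, sig - sig.mean()


def psd(signal: np.ndarray, fs: float = 4.0):
    """Welch PSD (one-sided, density scaling); returns ``(freqs, pxx)``."""
    signal = np.asarray(signal, dtype=float)
    if signal.size < 16:
        raise ValueError("PSD needs at least 16 samples")
    nperseg = min(signal.size, 256)
    return welch(
        signal,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="linear",
        scaling="density",
    )


def _band_integral(freqs: np.ndarray, pxx: np.ndarray, lo: float, hi: float) -> float:
    lo = max(lo, float(freqs[0]))
    hi = min(hi, float(freqs[-1]))
    if hi <= lo:
        return 0.0
    inner = freqs[(freqs > lo) & (freqs < hi)]
    fgrid = np.concatenate(([lo], inner, [hi]))
    pgrid = np.interp(fgrid, freqs, pxx)
    return float(np.trapezoid(pgrid, fgrid))


def band_powers(freqs: np.ndarray, pxx: np.ndarray, bands=None):
    """Trapezoidal band powers ``(vlf, lf, hf)`` in ms^2.

    Power above the HF upper edge is excluded by construction.  Raises if the
    frequency grid does not reach the top band edge.
    """
    bands = bands or DEFAULT_BANDS
    top = max(hi for _, hi in bands.values())
    if freqs[-1] < top - 1e-9:
        raise ValueError(f"frequency grid ends at {freqs[-1]:.3f} Hz, below {top} Hz")
    return tuple(_band_integral(freqs, pxx, lo, hi) for lo, hi in bands.values())


def normalized_powers(vlf: float, lf: float, hf: float):
    """nVLF, nLF, nHF = band / (VLF+LF+HF) x 100; NaN triple if total <= 0."""
    total = vlf + lf + hf
    if total <= 0:
        return (float("nan"),) * 3
    return (100.0 * vlf / total, 100.0 * lf / total, 100.0 * hf / total)


def spectral_analysis(rr: RRSeries, fs: float = 4.0, bands=None) -> SpectralResult:
    """Tachogram -> Welch PSD -> band powers -> normalised powers."""
    bands = bands or DEFAULT_BANDS
    _, sig = interpolate_tachogram(rr, fs)
    freqs, pxx = psd(sig, fs)
    vlf, lf, hf = band_powers(freqs, pxx, bands)
    nvlf, nlf, nhf = normalized_powers(vlf, lf, hf)
    return SpectralResult(
        freqs=freqs,
        psd=pxx,
        vlf=vlf,
        lf=lf,
        hf=hf,
        total_power=vlf + lf + hf,
        nvlf=nvlf,
        nlf=nlf,
        nhf=nhf,
        bands=dict(bands),
    )


def compute_metrics(
    rr: RRSeries,
    cfg: PreprocessConfig | None = None,
    fs: float = 4.0,
) -> HRVMetrics:
    """Preprocess a segment and compute all six endpoints.

    Applies artefact detection/correction and smoothness-priors detrending
    (per the config), then computes the time-domain metrics on the
    detrended, mean-restored series and the frequency-domain metrics on its
    tachogram.  Segments with fewer than 30 intervals are flagged
    ``low_confidence``; degenerate spectra (zero total power, or a segment
    too short to resample) yield NaN normalised powers flagged
    ``spectral_undefined``.
    """
    cfg = cfg or PreprocessConfig()
    if len(rr) < 2:
        raise ValueError("need at least 2 intervals")
    issues: list[str] = []
    if len(rr) < 30:
        issues.append("low_confidence")

    flags = detect_artefacts(rr, cfg)
    clean = correct_artefacts(rr, flags) if flags.any() else rr.copy()
    if cfg.detrend_lambda is not None and len(clean) >= 3:
        clean = detrend_smoothness_priors(clean, cfg.detrend_lambda)

    t_sdnn = sdnn(clean)
    t_rmssd = rmssd(clean)
    t_pnn50 = pnn50(clean)

    nvlf = nlf = nhf = float("nan")
    try:
        spec = spectral_analysis(clean, fs)
        nvlf, nlf, nhf = spec.nvlf, spec.nlf, spec.nhf
    except ValueError:
        pass
    if not np.isfinite(nvlf):
        issues.append("spectral_undefined")

    return HRVMetrics(
        sdnn=t_sdnn,
        rmssd=t_rmssd,
        pnn50=t_pnn50,
        nvlf=nvlf,
        nlf=nlf,
        nhf=nhf,
        n_intervals=len(rr),
        quality=";".join(issues) if issues else "ok",
    )
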