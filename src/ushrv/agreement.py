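"""Method-agreement statistics for paired HRV measurements.

The battery used throughout the package compares two paired vectors
(subject-matched) with four complementary statistics:

* Cohen's d (pooled-SD standardiser) with a large-sample 95% CI,
* ICC(2,1) — single-measure, two-way random effects, absolute agreement,
* Spearman's rank correlation,
* Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 SD of the
  paired differences).

Each continuous statistic comes with the qualitative magnitude scale used
in the sports/physiology agreement literature; boundary values (and values
falling in the printed gaps of the ICC and r scales) are assigned to the
lower class.  A paired-t post-hoc power routine based on the noncentral t
distribution rounds out the battery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "cohens_d",
    "interpret_es",
    "icc_2_1",
    "interpret_icc",
    "spearman",
    "interpret_r",
    "bland_altman",
    "BlandAltmanResult",
    "power_paired_t",
    "AgreementResult",
    "compare",
]


def _paired(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def cohens_d(x, y):
    """Cohen's d with pooled-SD standardiser and 95% CI.

    d = (mean(x) - mean(y)) / s_p with s_p = sqrt((var(x)+var(y))/2)
    (sample variances); CI = d +/- 1.96*sqrt(2/n + d^2/(4n)).

    Returns ``(d, lo, hi)``.  With zero pooled SD: d = 0 if the means agree,
    NaN otherwise.
    """
    x, y = _paired(x, y)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diff = x.mean() - y.mean()
    sp = math.sqrt((np.var(x, ddof=1) + np.var(y, ddof=1)) / 2.0)
    if sp == 0:
        d = 0.0 if diff == 0 else float("nan")
        return d, d, d
    d = diff / sp
    half = 1.96 * math.sqrt(2.0 / n + d * d / (4.0 * n))
    return d, d - half, d + half


def interpret_es(d: float) -> str:
    """Magnitude label for |d|: trivial/small/moderate/large/very large."""
    a = abs(d)
    if a <= 0.2:
        return "trivial"
    if a <= 0.6:
        return "small"
    if a <= 1.2:
        return "moderate"
    if a <= 2.0:
        return "large"
    return "very large"


def icc_2_1(table) -> float:
    """ICC(2,1): two-way random effects, single measure, absolute agreement.

    ``table`` is an (n subjects x k raters/devices) array with no missing
    cells.  Mean squares come from the two-way ANOVA decomposition:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    Returns NaN when the table has zero total variance.
    """
    m = np.asarray(table, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("need an (n >= 3) x (k >= 2) table")
    if not np.all(np.isfinite(m)):
        raise ValueError("table has missing cells")
    n, k = m.shape
    grand = m.mean()
    if np.allclose(m, grand):
        return float("nan")
    rows = m.mean(axis=1)
    cols = m.mean(axis=0)
    msr = k * np.sum((rows - grand) ** 2) / (n - 1)
    msc = n * np.sum((cols - grand) ** 2) / (k - 1)
    resid = m - rows[:, None] - cols[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def interpret_icc(icc: float) -> str:
    """Magnitude label for an ICC; gap values go to the lower class."""
    if icc < 0.31:
        return "small"
    if icc < 0.50:
        return "moderate"
    if icc < 0.70:
        return "large"
    if icc < 0.90:
        return "very large"
    return "nearly perfect"


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties); NaN if degenerate."""
    x, y = _paired(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def interpret_r(rho: float) -> str:
    """Magnitude label for |rho|; boundaries go to the lower class."""
    a = abs(rho)
    if a == 1.0:
        return "perfect"
    if a > 0.9:
        return "nearly perfect"
    if a > 0.7:
        return "very high"
    if a > 0.5:
        return "high"
    if a > 0.3:
        return "moderate"
    if a > 0.1:
        return "small"
    return "trivial"


@dataclass
class BlandAltmanResult:
    """Bias and 95% limits of agreement, plus the point cloud for plotting."""

    bias: float
    loa_lower: float
    loa_upper: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman analysis of paired vectors (d_i = x_i - y_i)."""
    x, y = _paired(x, y)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        means=(x + y) / 2.0,
        diffs=d,
    )


def power_paired_t(n: int, dz: float, alpha: float = 0.05) -> float:
    """Two-sided power of the paired t test via the noncentral t.

    ``dz`` is the standardised mean difference of the paired differences;
    the noncentrality parameter is dz*sqrt(n) with df = n - 1.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if dz < 0:
        raise ValueError("dz must be >= 0")
    df = n - 1
    ncp = dz * math.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(1 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


@dataclass
class AgreementResult:
    """The full battery for one paired comparison."""

    n: int
    d: float
    d_lo: float
    d_hi: float
    es_label: str
    icc: float
    icc_label: str
    rho: float
    rho_label: str
    bias: float
    loa_lower: float
    loa_upper: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compare(x, y) -> AgreementResult:
    """Run the four-statistic battery on paired vectors x (candidate) vs y."""
    x, y = _paired(x, y)
    d, lo, hi = cohens_d(x, y)
    icc = icc_2_1(np.column_stack([x, y])) if x.size >= 3 else float("nan")
    rho = spearman(x, y)
    ba = bland_altman(x, y)
    return AgreementResult(
        n=int(x.size),
        d=d,
        d_lo=lo,
        d_hi=hi,
        es_label=interpret_es(d) if np.isfinite(d) else "undefined",
        icc=icc,
        icc_label=interpret_icc(icc) if np.isfinite(icc) else "undefined",
        rho=rho,
        rho_label=interpret_r(rho) if np.isfinite(rho) else "undefined",
        bias=ba.bias,
        loa_lower=ba.loa_lower,
        loa_upper=ba.loa_upper,
    )
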