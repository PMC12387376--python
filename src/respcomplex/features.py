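"""Breath-series features: cycle timing, amplitude variability, multiscale entropy.

Three feature families are computed from a night's breath series:

* **cycle** — mean and coefficient of variation (CV, sample SD / mean x 100%)
  of the per-breath breathing rate (BR_i = 60/BBI_i), inspiratory time TI,
  expiratory time TE and expiratory fraction TE_ratio;
* **amplitude** — CV of the respiratory amplitude RA, CV of the relative
  rapid-shallow-breathing index (per-breath BR_i/RA_i; only its CV is
  meaningful because RA is in arbitrary units), and the respiratory
  instability index RII = IQR of per-breath RA_i/BBI_i;
* **multiscale entropy (MSE)** — sample entropy of the BBI and RA series
  after coarse-graining at scales 1..20, summarised as the area under the
  entropy-vs-scale curve over scales 1-5 and 6-20 (trapezoidal rule) and the
  OLS slope over scales 1-5.

Sample entropy follows the Richman-Moorman convention: with N - m templates
of length m and of length m+1, B counts template pairs (i < j) whose
Chebyshev distance is <= r, A the same for length m+1, and
SampEn = -ln(A/B); self-matches are excluded.  A = 0 or B = 0 leaves the
value undefined (flagged), never substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .breaths import BreathSeries

__all__ = [
    "CycleFeatures",
    "AmplitudeFeatures",
    "MSECurve",
    "MSEFeatures",
    "SampEnResult",
    "cycle_features",
    "amplitude_features",
    "coarse_grain",
    "sample_entropy",
    "mse_curve",
    "mse_summary",
    "feature_vector",
    "FEATURE_COLUMNS",
]

#: Canonical feature-table columns, one row per subject.
FEATURE_COLUMNS = [
    "mean_BR",
    "BR_cv",
    "mean_TI",
    "TI_cv",
    "mean_TE",
    "TE_cv",
    "mean_TE_ratio",
    "TE_ratio_cv",
    "RA_cv",
    "R_RSBI_cv",
    "RII",
    "BBI_slope_1_5",
    "BBI_area_1_5",
    "BBI_area_6_20",
    "RA_slope_1_5",
    "RA_area_1_5",
    "RA_area_6_20",
]


# ---------------------------------------------------------------------------
# sample entropy core
# ---------------------------------------------------------------------------


def _pair_counts_numpy(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Chunked vectorised template-pair counting (fallback path)."""
    n = len(x)
    nt = n - m
    if nt < 2:
        return 0, 0
    a = b = 0
    chunk = max(1, int(4_000_000 // max(nt, 1)))
    for s in range(0, nt, chunk):
        e = min(s + chunk, nt)
        d = np.abs(x[s:e, None] - x[None, :nt])
        for k in range(1, m):
            np.maximum(d, np.abs(x[s + k : e + k, None] - x[None, k : nt + k]), out=d)
        b += int((d <= r).sum()) - (e - s)  # remove self-matches
        np.maximum(d, np.abs(x[s + m : e + m, None] - x[None, m : nt + m]), out=d)
        a += int((d <= r).sum()) - (e - s)
    return a // 2, b // 2  # unordered pairs


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    @njit(cache=True)
    def _pair_counts_jit(x, m, r):  # pragma: no cover
        nt = x.shape[0] - m
        a = 0
        b = 0
        for i in range(nt - 1):
            for j in range(i + 1, nt):
                d = 0.0
                for k in range(m):
                    t = abs(x[i + k] - x[j + k])
                    if t > d:
                        d = t
                    if d > r:
                        break
                if d <= r:
                    b += 1
                    t = abs(x[i + m] - x[j + m])
                    if t > d:
                        d = t
                    if d <= r:
                        a += 1
        return a, b

    def _pair_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
        if len(x) - m < 2:
            return 0, 0
        a, b = _pair_counts_jit(np.ascontiguousarray(x, dtype=np.float64), m, r)
        return int(a), int(b)

except Exception:  # pragma: no cover
    _pair_counts = _pair_counts_numpy


@dataclass(frozen=True)
class SampEnResult:
    """Sample entropy with its raw match counts (unordered pairs)."""

    value: float  # nats; NaN when undefined
    a: int  # (m+1)-template matches
    b: int  # m-template matches
    defined: bool

    def __float__(self) -> float:
        return self.value


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2) -> SampEnResult:
    """SampEn(m, r) of a series; undefined (flagged) rather than raised.

    ``r`` is an absolute tolerance in the units of ``x``.  A series shorter
    than m + 2, or one with no template matches at either length, yields an
    undefined result with ``value`` NaN.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if r < 0:
        raise ValueError(f"r must be >= 0, got {r}")
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("sample_entropy expects a 1-D series")
    if len(x) < m + 2:
        return SampEnResult(math.nan, 0, 0, False)
    a, b = _pair_counts(x, m, r)
    if a == 0 or b == 0:
        return SampEnResult(math.nan, a, b, False)
    return SampEnResult(-math.log(a / b), a, b, True)


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping block means of length ``tau``; the remainder is dropped."""
    if tau < 1:
        raise ValueError(f"tau must be >= 1, got {tau}")
    x = np.asarray(x, dtype=float)
    n_blocks = len(x) // tau
    if n_blocks == 0:
        return np.array([], dtype=float)
    if tau == 1:
        return x.copy()
    return x[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)


@dataclass
class MSECurve:
    """Sample entropy across coarse-graining scales for one series."""

    series_name: str
    scales: np.ndarray  # int
    sampen: np.ndarray  # float, NaN where undefined
    defined: np.ndarray  # bool
    m: int
    r: float
    n_effective: np.ndarray  # coarse-grained lengths
    low_confidence: bool = False

    def value_at(self, scale: int) -> float:
        i = int(np.flatnonzero(self.scales == scale)[0])
        return float(self.sampen[i])


def mse_curve(
    x: np.ndarray,
    scales=range(1, 21),
    m: int = 2,
    r_factor: float = 0.2,
    series_name: str = "",
    min_length: int | None = None,
) -> MSECurve:
    """Multiscale entropy: SampEn of block-averaged series at each scale.

    The tolerance r = ``r_factor`` x sample SD of the scale-1 series is held
    fixed across scales, so the curve is invariant to rescaling the series.
    Curves computed from fewer than ``min_length`` samples (default
    20*(m+2)) are flagged ``low_confidence``.
    """
    x = np.asarray(x, dtype=float)
    scales = np.asarray(list(scales), dtype=int)
    if min_length is None:
        min_length = 20 * (m + 2)
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    r = r_factor * sd

    vals = np.full(len(scales), np.nan)
    defined = np.zeros(len(scales), dtype=bool)
    n_eff = np.zeros(len(scales), dtype=int)
    for i, tau in enumerate(scales):
        y = coarse_grain(x, int(tau))
        n_eff[i] = len(y)
        res = sample_entropy(y, m=m, r=r)
        vals[i] = res.value
        defined[i] = res.defined
    return MSECurve(
        series_name=series_name,
        scales=scales,
        sampen=vals,
        defined=defined,
        m=m,
        r=r,
        n_effective=n_eff,
        low_confidence=len(x) < min_length,
    )


@dataclass(frozen=True)
class MSEFeatures:
    """Scalar summaries of an MSE curve (NaN where any needed scale is undefined)."""

    area_1_5: float
    area_6_20: float
    slope_1_5: float


def mse_summary(curve: MSECurve, quadrature: str = "trapezoid") -> MSEFeatures:
    """Areas under the MSE curve (scales 1-5 and 6-20) and its initial slope.

    Areas use the trapezoidal rule over the scale axis by default
    (``quadrature="sum"`` uses plain summation); the slope is the OLS fit of
    SampEn on scale over scales 1-5.
    """
    if quadrature not in ("trapezoid", "sum"):
        raise ValueError(f"unknown quadrature {quadrature!r}")

    def _block(lo: int, hi: int):
        mask = (curve.scales >= lo) & (curve.scales <= hi)
        return curve.scales[mask], curve.sampen[mask], bool(curve.defined[mask].all())

    s15, y15, ok15 = _block(1, 5)
    s620, y620, ok620 = _block(6, 20)

    if quadrature == "trapezoid":
        area_fn = lambda s, y: float(np.trapezoid(y, s))  # noqa: E731
    else:
        area_fn = lambda s, y: float(np.sum(y))  # noqa: E731

    area_1_5 = area_fn(s15, y15) if ok15 else math.nan
    area_6_20 = area_fn(s620, y620) if ok620 else math.nan
    if ok15 and len(s15) >= 2:
        slope_1_5 = float(np.polyfit(s15.astype(float), y15, 1)[0])
    else:
        slope_1_5 = math.nan
    return MSEFeatures(area_1_5=area_1_5, area_6_20=area_6_20, slope_1_5=slope_1_5)


# ---------------------------------------------------------------------------
# cycle and amplitude features
# ---------------------------------------------------------------------------


def _cv_pct(x: np.ndarray) -> float:
    mean = float(np.mean(x))
    if mean == 0:
        return math.nan
    return float(np.std(x, ddof=1) / mean * 100.0)


@dataclass(frozen=True)
class CycleFeatures:
    mean_BR: float  # breaths/min
    BR_cv: float  # %
    mean_TI: float  # s
    TI_cv: float  # %
    mean_TE: float  # s
    TE_cv: float  # %
    mean_TE_ratio: float  # %
    TE_ratio_cv: float  # %


def cycle_features(series: BreathSeries) -> CycleFeatures:
    """Means and CVs of per-breath rate and timing quantities.

    The mean breathing rate is the mean of per-breath rates 60/BBI_i, not
    60 divided by the mean interval.
    """
    if len(series) < 2:
        raise ValueError(
            f"cycle features need >= 2 breaths (CV undefined), got {len(series)}"
        )
    br = 60.0 / series.bbi
    ratio_pct = series.te_ratio * 100.0
    return CycleFeatures(
        mean_BR=float(np.mean(br)),
        BR_cv=_cv_pct(br),
        mean_TI=float(np.mean(series.ti)),
        TI_cv=_cv_pct(series.ti),
        mean_TE=float(np.mean(series.te)),
        TE_cv=_cv_pct(series.te),
        mean_TE_ratio=float(np.mean(ratio_pct)),
        TE_ratio_cv=_cv_pct(ratio_pct),
    )


@dataclass(frozen=True)
class AmplitudeFeatures:
    RA_cv: float  # %
    R_RSBI_cv: float  # %
    RII: float  # IQR of RA_i/BBI_i, arbitrary units / s


def amplitude_features(series: BreathSeries) -> AmplitudeFeatures:
    """Amplitude variability: CV of RA, CV of BR/RA, IQR of RA/BBI.

    Quartiles use linear interpolation between order statistics.
    """
    if len(series) < 4:
        raise ValueError(
            f"amplitude features need >= 4 breaths, got {len(series)}"
        )
    ra = series.ra
    br = 60.0 / series.bbi
    ratio = ra / series.bbi
    q75, q25 = np.percentile(ratio, [75, 25], method="linear")
    return AmplitudeFeatures(
        RA_cv=_cv_pct(ra),
        R_RSBI_cv=_cv_pct(br / ra),
        RII=float(q75 - q25),
    )


def feature_vector(
    series: BreathSeries,
    m: int = 2,
    r_factor: float = 0.2,
    scales=range(1, 21),
    quadrature: str = "trapezoid",
) -> dict[str, float]:
    """All 17 per-subject features as a flat mapping (NaN where undefined)."""
    out = {k: math.nan for k in FEATURE_COLUMNS}
    if len(series) >= 2:
        c = cycle_features(series)
        out.update(
            mean_BR=c.mean_BR,
            BR_cv=c.BR_cv,
            mean_TI=c.mean_TI,
            TI_cv=c.TI_cv,
            mean_TE=c.mean_TE,
            TE_cv=c.TE_cv,
            mean_TE_ratio=c.mean_TE_ratio,
            TE_ratio_cv=c.TE_ratio_cv,
        )
    if len(series) >= 4:
        a = amplitude_features(series)
        out.update(RA_cv=a.RA_cv, R_RSBI_cv=a.R_RSBI_cv, RII=a.RII)
    for name, x in (("BBI", series.bbi), ("RA", series.ra)):
        curve = mse_curve(x, scales=scales, m=m, r_factor=r_factor, series_name=name)
        summ = mse_summary(curve, quadrature=quadrature)
        out[f"{name}_slope_1_5"] = summ.slope_1_5
        out[f"{name}_area_1_5"] = summ.area_1_5
        out[f"{name}_area_6_20"] = summ.area_6_20
    return out
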