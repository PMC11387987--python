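"""Comparison feature families for MFC stride series.

Three families of previously published gait-variability descriptors are
provided alongside the spectral features:

* descriptive statistics of the normalized series (mean, median, SD,
  quartiles, IQR);
* a 24-feature histogram + Poincaré set: twelve distribution statistics plus
  Poincaré short/long-term variability descriptors (SD1, SD2, their ratio and
  ellipse area) at lags 1-3;
* tone-entropy of the percentage-index (PI) series, the per-stride percent
  change of clearance;
* wavelet multiscale features: log2 detail-coefficient variances of a
  Daubechies-6 decomposition and the slope of those variances across scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import stats

from .mfc_core import DegenerateInputError, MFCSeries, ValidationError

__all__ = [
    "PISeries",
    "descriptive_features",
    "histogram_poincare_features",
    "percentage_index",
    "tone_entropy",
    "wavelet_multiscale_features",
    "poincare_descriptors",
]

_SQRT2 = np.sqrt(2.0)


@dataclass
class PISeries:
    """Percentage-index series: percent change between successive strides."""

    values: np.ndarray
    source_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1 or not np.all(np.isfinite(self.values)):
            raise ValidationError(f"PI series {self.source_id!r}: invalid values")

    def __len__(self) -> int:
        return int(self.values.size)


def percentage_index(s: MFCSeries) -> PISeries:
    """``PI_i = 100 * (x_{i+1} - x_i) / x_i`` for strides ``i = 1..n-1``.

    Requires strictly positive values; apply to raw or max-normalized series
    (minmax-normalized series contain an exact zero).
    """
    x = s.values
    zeros = np.flatnonzero(x[:-1] == 0.0)
    if zeros.size:
        raise DegenerateInputError(
            f"series {s.subject_id!r}: zero MFC value at stride {zeros[0] + 1} "
            "(percentage index undefined)"
        )
    return PISeries(100.0 * np.diff(x) / x[:-1], s.subject_id)


def tone_entropy(pi: PISeries, n_bins: int = 50) -> tuple[float, float]:
    """Tone (mean PI) and Shannon entropy (base 2) of the binned PI values.

    The histogram uses ``n_bins`` equal-width bins spanning [min, max] of the
    PI values; empty bins are skipped.  A constant PI series has entropy 0.
    """
    if len(pi) < 2:
        raise ValidationError("PI series must have length >= 2")
    vals = pi.values
    tone = float(vals.mean())
    if np.ptp(vals) == 0.0:
        return tone, 0.0
    counts, _ = np.histogram(vals, bins=n_bins)
    p = counts[counts > 0] / vals.size
    return tone, float(-(p * np.log2(p)).sum())


def descriptive_features(s: MFCSeries) -> dict[str, float]:
    """Mean, median, sample SD, quartiles (linear interpolation) and IQR."""
    if not s.normalized:
        raise ValidationError("descriptive features are defined on normalized series")
    if s.n < 4:
        raise DegenerateInputError("need at least 4 strides")
    x = s.values
    q1, q3 = np.quantile(x, [0.25, 0.75])
    return {
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "sd": float(x.std(ddof=1)),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(q3 - q1),
    }


def poincare_descriptors(x: np.ndarray, lag: int = 1) -> dict[str, float]:
    """SD1/SD2 of the lag-``lag`` Poincaré scatter of a series.

    SD1 (dispersion perpendicular to the identity line) is the sample SD of
    the lagged differences divided by sqrt(2); SD2 (dispersion along it) is
    the sample SD of the lagged sums divided by sqrt(2).  A zero SD2 (constant
    series) yields a ratio of 0 by convention.
    """
    if x.size < lag + 2:
        raise DegenerateInputError(f"need more than {lag + 1} samples for lag {lag}")
    d = x[lag:] - x[:-lag]
    u = x[lag:] + x[:-lag]
    sd1 = float(np.std(d, ddof=1) / _SQRT2)
    sd2 = float(np.std(u, ddof=1) / _SQRT2)
    ratio = sd1 / sd2 if sd2 > 0 else 0.0
    return {
        "sd1": sd1,
        "sd2": sd2,
        "sd1_sd2_ratio": ratio,
        "ellipse_area": float(np.pi * sd1 * sd2),
    }


def histogram_poincare_features(
    s: MFCSeries, n_mode_bins: int = 16, lags: tuple[int, ...] = (1, 2, 3)
) -> dict[str, float]:
    """The 24-feature histogram + Poincaré family.

    Twelve distribution statistics (the descriptive set plus skewness g1,
    excess kurtosis g2, histogram mode, min, max and the quartile coefficient
    of dispersion) and the four Poincaré descriptors at each of three lags.
    """
    if s.n < 4:
        raise DegenerateInputError("need at least 4 strides")
    x = s.values
    q1, q3 = np.quantile(x, [0.25, 0.75])
    if q1 + q3 == 0.0:
        raise DegenerateInputError(
            "quartile coefficient of dispersion undefined (Q1 + Q3 = 0)"
        )
    counts, edges = np.histogram(x, bins=n_mode_bins)
    imax = int(np.argmax(counts))
    feats: dict[str, float] = {
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "sd": float(x.std(ddof=1)),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(q3 - q1),
        "skewness": float(stats.skew(x)),
        "kurtosis": float(stats.kurtosis(x)),
        "mode": float(0.5 * (edges[imax] + edges[imax + 1])),
        "min": float(x.min()),
        "max": float(x.max()),
        "qcd": float((q3 - q1) / (q3 + q1)),
    }
    for lag in lags:
        pc = poincare_descriptors(x, lag)
        suffix = "" if lag == 1 else f"_lag{lag}"
        feats.update({k + suffix: v for k, v in pc.items()})
    return feats


def wavelet_multiscale_features(
    s: MFCSeries, wavelet: str = "db6", max_level: int = 8
) -> dict[str, float]:
    """Multiscale wavelet-variance features.

    The series is decomposed with a Daubechies wavelet with six vanishing
    moments (symmetric signal extension) to at most ``max_level`` levels,
    capped at ``floor(log2 n)`` with a warning for short series.  Per level
    ``l`` the feature ``v_l = log2 Var(d_l)`` is the log variance of the
    detail coefficients; the emitted six features are ``v_1..v_5`` and the
    least-squares slope of ``v_l`` against ``l`` over all available levels
    (a multiscale exponent: 0 for white noise, positive when coarse scales
    dominate).
    """
    x = s.values
    wav = pywt.Wavelet(wavelet)
    if x.size < wav.dec_len:
        raise DegenerateInputError(
            f"series length {x.size} shorter than the {wav.dec_len}-tap filter"
        )
    depth = min(max_level, int(np.floor(np.log2(x.size))))
    if depth < 5:
        raise DegenerateInputError(
            f"series length {x.size} supports only {depth} decomposition levels; "
            "need at least 32 samples for v_1..v_5"
        )
    if depth < max_level:
        warnings.warn(
            f"series length {x.size}: decomposition capped at {depth} levels "
            f"(< {max_level})",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        # pywt warns when level exceeds its boundary-effect-free maximum;
        # symmetric extension keeps the coefficients usable.
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet, mode="symmetric", level=depth)
    v = []
    for level in range(1, depth + 1):
        d = coeffs[-level]
        var = float(np.var(d, ddof=1)) if d.size > 1 else 0.0
        v.append(float(np.log2(max(var, 1e-300))))
    slope = float(np.polyfit(np.arange(1, depth + 1), v, 1)[0])
    feats = {f"wavelet_v{l}": v[l - 1] for l in range(1, 6)}
    feats["wavelet_slope"] = slope
    return feats
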