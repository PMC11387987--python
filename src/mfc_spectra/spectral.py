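"""Short-term Fourier magnitude spectrum of MFC stride series.

Each normalized series is divided into a fixed number of overlapping segments
(default eight, 50% overlap), each segment is multiplied by a symmetric
Hamming window, zero-padded to ``nfft`` points (default 256) and transformed
with an FFT.  The one-sided magnitudes (``nfft/2 + 1`` bins, 129 by default)
are averaged over the segments to give the mean magnitude spectrum; the
lowest-frequency bins of that average are the spectral features.  Because the
series is sampled once per stride, bin ``k`` corresponds to ``k / nfft``
cycles per stride.

No magnitude scaling is applied (no ``1/M`` or window-energy compensation):
the bin-0 magnitude of a frame is exactly the absolute windowed sum
``|sum w[n] x[n]|``, a window-weighted local mean of the clearance series.

Class separability of individual frequency bins is ranked with the F-ratio:
between-class variance of per-class bin means over the class-size-averaged
within-class variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .mfc_core import (
    DegenerateInputError,
    FeatureTable,
    MFCSeries,
    ValidationError,
)

__all__ = [
    "STFTConfig",
    "Spectrogram",
    "MeanSpectrum",
    "FRatioProfile",
    "frame_series",
    "short_term_spectrum",
    "mean_magnitude_spectrum",
    "spectral_features",
    "cohort_mean_spectra",
    "f_ratio_profile",
]

_WINDOW_ALIASES = {"hamming": "hamming", "hann": "hann", "rectangular": "boxcar"}


@dataclass(frozen=True)
class STFTConfig:
    """Framing and transform parameters.

    ``n_segments`` frames with fractional ``overlap`` are fit to the series:
    the segment length is ``floor(N / (1 + (n_segments - 1) * (1 - overlap)))``
    and the hop is ``floor(seg * (1 - overlap))``, so for the defaults a
    200-stride series gives 44-sample segments hopping by 22.  ``nfft`` must
    be at least the segment length (zero-padding only, never truncation).
    """

    n_segments: int = 8
    overlap: float = 0.5
    window: str = "hamming"
    nfft: int = 256

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValidationError("n_segments must be >= 1")
        if not (0.0 <= self.overlap < 1.0):
            raise ValidationError("overlap must be in [0, 1)")
        if self.window not in _WINDOW_ALIASES:
            raise ValidationError(
                f"window {self.window!r} not in {sorted(_WINDOW_ALIASES)}"
            )
        if self.nfft < 2:
            raise ValidationError("nfft must be >= 2")

    @property
    def n_bins(self) -> int:
        return self.nfft // 2 + 1

    def segment_length(self, n: int) -> int:
        denom = 1.0 + (self.n_segments - 1) * (1.0 - self.overlap)
        return int(np.floor(n / denom + 1e-9))

    def hop(self, seg: int) -> int:
        return max(1, int(np.floor(seg * (1.0 - self.overlap) + 1e-9)))

    def window_coefficients(self, seg: int) -> np.ndarray:
        """Symmetric window of length ``seg``."""
        return get_window(_WINDOW_ALIASES[self.window], seg, fftbins=False)


def frame_series(
    x: Sequence[float], cfg: STFTConfig | None = None
) -> tuple[np.ndarray, list[int]]:
    """Split a series into ``cfg.n_segments`` overlapping frames.

    Returns the ``(n_segments, seg)`` frame matrix and the 0-based start index
    of each frame.  Trailing samples beyond the last frame are discarded.
    """
    cfg = cfg or STFTConfig()
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < cfg.n_segments + 2:
        raise DegenerateInputError(
            f"series of length {n} too short for {cfg.n_segments} segments"
        )
    seg = cfg.segment_length(n)
    if seg < 2:
        raise DegenerateInputError(
            f"series of length {n} yields segment length {seg} < 2"
        )
    if cfg.nfft < seg:
        raise ValidationError(
            f"nfft={cfg.nfft} < segment length {seg}: truncation is forbidden"
        )
    hop = cfg.hop(seg)
    starts = [i * hop for i in range(cfg.n_segments)]
    assert starts[-1] + seg <= n
    frames = np.stack([x[s : s + seg] for s in starts])
    return frames, starts


@dataclass
class Spectrogram:
    """Frames x one-sided-frequency-bins magnitude matrix."""

    magnitudes: np.ndarray
    frame_starts: list[int]
    config: STFTConfig

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.magnitudes.ndim != 2:
            raise ValidationError("magnitudes must be a 2-d matrix")
        if self.magnitudes.shape[0] != len(self.frame_starts):
            raise ValidationError("frame_starts length != number of frames")
        if self.magnitudes.shape[1] != self.config.n_bins:
            raise ValidationError(
                f"expected {self.config.n_bins} bins, got {self.magnitudes.shape[1]}"
            )
        if self.magnitudes.size and self.magnitudes.min() < 0:
            raise ValidationError("magnitudes must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.magnitudes.shape[1]


def short_term_spectrum(
    x: Sequence[float], cfg: STFTConfig | None = None
) -> Spectrogram:
    """Windowed, zero-padded one-sided magnitude spectrum of every frame."""
    cfg = cfg or STFTConfig()
    frames, starts = frame_series(x, cfg)
    w = cfg.window_coefficients(frames.shape[1])
    mags = np.abs(np.fft.rfft(frames * w, n=cfg.nfft, axis=1))
    return Spectrogram(mags, starts, cfg)


@dataclass
class MeanSpectrum:
    """Frame-averaged magnitude spectrum with its frequency axis."""

    magnitudes: np.ndarray
    bin_frequencies: np.ndarray = field(default=None)  # cycles/stride

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.bin_frequencies is None:
            nfft = 2 * (self.magnitudes.size - 1)
            self.bin_frequencies = np.arange(self.magnitudes.size) / nfft
        self.bin_frequencies = np.asarray(self.bin_frequencies, dtype=float)
        if self.bin_frequencies.shape != self.magnitudes.shape:
            raise ValidationError("frequency axis does not match magnitudes")

    def __len__(self) -> int:
        return int(self.magnitudes.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(len(self)),
                "frequency_cycles_per_stride": self.bin_frequencies,
                "magnitude": self.magnitudes,
            }
        )


def mean_magnitude_spectrum(sg: Spectrogram) -> MeanSpectrum:
    """Arithmetic mean of the magnitudes over frames (one value per bin)."""
    if sg.n_frames == 0:
        raise DegenerateInputError("empty spectrogram")
    return MeanSpectrum(
        sg.magnitudes.mean(axis=0),
        np.arange(sg.n_bins) / sg.config.nfft,
    )


def spectral_features(
    s: MFCSeries, cfg: STFTConfig | None = None, n_features: int = 3
) -> dict[str, float]:
    """The first ``n_features`` mean-magnitude-spectrum bins of a series.

    Feature ``spec_k0`` is the DC value: the frame-averaged absolute windowed
    sum, a localized window-weighted mean of the normalized clearance series.
    """
    cfg = cfg or STFTConfig()
    if not s.normalized:
        raise ValidationError(
            f"series {s.subject_id!r} must be normalized before feature extraction"
        )
    if n_features < 1 or n_features > cfg.n_bins:
        raise ValidationError(
            f"n_features must be in [1, {cfg.n_bins}], got {n_features}"
        )
    ms = mean_magnitude_spectrum(short_term_spectrum(s.values, cfg))
    return {f"spec_k{k}": float(ms.magnitudes[k]) for k in range(n_features)}


def cohort_mean_spectra(
    cohort, cfg: STFTConfig | None = None, n_bins: int | None = None
) -> FeatureTable:
    """Per-subject mean magnitude spectra as a feature table.

    Columns are named ``spec_k0 .. spec_k{B-1}``; ``n_bins`` restricts the
    table to the lowest-frequency bins.
    """
    cfg = cfg or STFTConfig()
    records = []
    for s in cohort:
        feats = spectral_features(s, cfg, n_features=n_bins or cfg.n_bins)
        records.append((s.subject_id, s.label, feats))
    return FeatureTable.from_records(records)


@dataclass
class FRatioProfile:
    """Per-frequency-bin F statistic of class separability.

    ``f_values[k]`` is the ratio of the between-class variance of the class
    means to the class-size-averaged within-class variance at bin ``k``.  Bins
    whose within-class variance is exactly zero are flagged ``undefined`` and
    carry NaN rather than a silent zero or infinity.
    """

    f_values: np.ndarray
    undefined: np.ndarray
    class_means: dict[str, np.ndarray]
    grand_mean: np.ndarray
    class_sizes: dict[str, int]
    bin_frequencies: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return len(self.class_sizes)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"bin": np.arange(self.f_values.size), "f_ratio": self.f_values}
        )
        if self.bin_frequencies is not None:
            df.insert(1, "frequency_cycles_per_stride", self.bin_frequencies)
        df["undefined"] = self.undefined
        return df


def f_ratio_profile(
    table: FeatureTable | np.ndarray,
    labels: Sequence[str] | None = None,
    bin_frequencies: np.ndarray | None = None,
) -> FRatioProfile:
    """F-ratio of every column of a samples x bins magnitude matrix.

    For bin ``k`` with classes ``i = 1..C`` of sizes ``C_i``::

        F(k) = sum_i (m_i(k) - m(k))^2
               / sum_i (1/C_i) sum_j (x_ij(k) - m_i(k))^2

    where ``m_i`` are class means and ``m`` the pooled mean over all samples.
    The numerator is an unweighted sum over class means; the denominator
    averages squared deviations within each class, then sums over classes.
    """
    if isinstance(table, FeatureTable):
        X = table.matrix
        labels = table.labels
    else:
        X = np.asarray(table, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    if labels is None:
        raise ValidationError("labels are required")
    labels = np.asarray(labels, dtype=object)
    classes = sorted({l for l in labels if l is not None})
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    class_means: dict[str, np.ndarray] = {}
    class_sizes: dict[str, int] = {}
    num = np.zeros(X.shape[1])
    den = np.zeros(X.shape[1])
    grand = X[np.array([l is not None for l in labels])].mean(axis=0)
    for c in classes:
        Xc = X[labels == c]
        if Xc.shape[0] < 2:
            raise ValidationError(f"class {c!r} has fewer than 2 samples")
        m = Xc.mean(axis=0)
        class_means[c] = m
        class_sizes[c] = Xc.shape[0]
        num += (m - grand) ** 2
        den += ((Xc - m) ** 2).sum(axis=0) / Xc.shape[0]
    undefined = den == 0.0
    f = np.full(X.shape[1], np.nan)
    f[~undefined] = num[~undefined] / den[~undefined]
    return FRatioProfile(
        f, undefined, class_means, grand, class_sizes, bin_frequencies
    )
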