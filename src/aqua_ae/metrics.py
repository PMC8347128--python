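"""Reconstruction benchmarks and histogram distinguishability statistics.

The benchmark chain is, for two RGB images ``X`` and ``Y`` in [0, 1]:

* ``standardize`` — global min-max rescaling of an array to [0, 1],
* ``image_diff`` — the *standardized difference image*
  ``standardize(X - Y)``, the denoised view that reveals subject contours
  the reconstruction smooths away,
* ``color_diff`` — mean squared per-pixel difference on one color plane,
* ``benchmark`` — ``sqrt(sum_c color_diff(X, Y, c))``; larger means more
  visual contrast between the two images.

Histogram distinguishability summarises the pooled per-channel histogram
counts of a set of images by min, max, population standard deviation,
scale (max − min) and coefficient of variation (std/mean); models whose
difference images spread histogram mass widely are the ones whose DIFF
output is most useful for observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChannelHistogram",
    "HistogramStats",
    "standardize",
    "image_diff",
    "color_diff",
    "benchmark",
    "channel_histograms",
    "histogram_stats",
]


@dataclass(frozen=True)
class ChannelHistogram:
    """Per-channel histogram of an RGB image over equal-width bins on [0, 1].

    ``counts`` has shape (3, bins); each row sums to the pixel count.
    """

    bins: int
    counts: np.ndarray


@dataclass(frozen=True)
class HistogramStats:
    """Summary of pooled histogram counts.

    scale = max - min; cov = std_dev / mean (population std, divide by N).
    """

    min: float
    max: float
    std_dev: float
    scale: float
    cov: float


def standardize(x: np.ndarray) -> np.ndarray:
    """Min-max rescale an array to [0, 1] using its global extremes.

    A constant input (max == min) maps to all zeros rather than raising:
    constant difference images occur legitimately for identical frames.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("standardize: empty input")
    lo = x.min()
    hi = x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def image_diff(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Standardized difference image ``standardize(X - Y)``.

    Standardization is applied to the subtraction (not to X alone) so the
    result is guaranteed to lie in [0, 1].
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"image_diff: shape mismatch {x.shape} vs {y.shape}")
    return standardize(x - y)


def color_diff(x: np.ndarray, y: np.ndarray, c: int, reduction: str = "mean") -> float:
    """Squared difference between one color plane of X and of Y.

    ``reduction`` chooses the aggregation over pixels: ``"mean"`` (default;
    keeps the value independent of image area) or ``"sum"``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"color_diff: shape mismatch {x.shape} vs {y.shape}")
    if not 0 <= c < x.shape[-1]:
        raise ValueError(f"color_diff: channel {c} out of range for {x.shape[-1]} channels")
    if reduction not in ("mean", "sum"):
        raise ValueError(f"color_diff: unknown reduction {reduction!r}")
    sq = (x[..., c] - y[..., c]) ** 2
    return float(sq.mean() if reduction == "mean" else sq.sum())


def benchmark(x: np.ndarray, y: np.ndarray, reduction: str = "mean") -> float:
    """Total visual contrast between two RGB images.

    ``sqrt(sum_c color_diff(X, Y, c))`` over the three color planes. Zero iff
    the images are identical; bounded by sqrt(3) for inputs in [0, 1] under
    mean reduction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"benchmark: shape mismatch {x.shape} vs {y.shape}")
    if x.shape[-1] != 3:
        raise ValueError(f"benchmark: expected 3 channels, got {x.shape[-1]}")
    total = sum(color_diff(x, y, c, reduction=reduction) for c in range(3))
    return float(np.sqrt(total))


def channel_histograms(img: np.ndarray, bins: int = 256) -> ChannelHistogram:
    """Per-channel histograms over equal-width bins spanning [0, 1].

    The value 1.0 falls in the last bin (numpy's closed right edge).
    """
    img = np.asarray(img, dtype=np.float64)
    if bins < 2:
        raise ValueError(f"channel_histograms: bins must be >= 2, got {bins}")
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts = np.stack(
        [np.histogram(img[..., c].ravel(), bins=edges)[0] for c in range(img.shape[-1])]
    )
    return ChannelHistogram(bins=bins, counts=counts)


def histogram_stats(hists: list[ChannelHistogram] | ChannelHistogram) -> HistogramStats:
    """Pool histogram count vectors and summarise their spread.

    All per-channel count vectors of all histograms are concatenated into one
    sequence; the statistics are computed on that pooled sequence. Population
    standard deviation (divide by N) is used throughout.
    """
    if isinstance(hists, ChannelHistogram):
        hists = [hists]
    if len(hists) == 0:
        raise ValueError("histogram_stats: empty histogram list")
    pooled = np.concatenate([h.counts.ravel() for h in hists]).astype(np.float64)
    lo = float(pooled.min())
    hi = float(pooled.max())
    std = float(pooled.std())  # population
    mean = float(pooled.mean())
    cov = std / mean if mean != 0 else 0.0
    return HistogramStats(min=lo, max=hi, std_dev=std, scale=hi - lo, cov=cov)
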