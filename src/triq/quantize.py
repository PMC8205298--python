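"""Intensity quantization for ion images.

Mass spectrometry imaging (MSI) records an analog intensity per pixel;
rendering it on screen requires *quantization* — mapping intensities to a
finite set of integer gray levels.  The classic *zero-memory* quantizer
spreads ``n`` equal-width bins over ``[min(f), max(f)]``, which collapses
almost the whole image into the lowest levels whenever a few pixels carry
extreme intensities ("outliers"), a pathology typical of (ambient
ionization) MSI.

*Threshold intensity quantization* (TrIQ) fixes this by choosing a
saturation threshold ``T`` from the image's cumulative intensity
distribution: given a target probability ``q`` (default 0.98), ``T`` is the
upper edge of the first histogram bin whose CDF reaches ``q``.  Intensities
above ``T`` are grouped into the top gray level; the remaining range
``[B, T]`` (with ``B`` the image minimum, or an analogously chosen *black
level* suppressing diffuse background) is rebinned linearly into ``n - 1``
equal-width bins.  Unlike histogram equalization, the mapping from gray
level back to intensity stays linear, so color bars remain quantitatively
meaningful.

The estimators follow the scikit-learn transformer protocol (``fit`` learns
the thresholds from an image, ``transform`` maps intensities to levels);
the module-level functions are thin wrappers returning a
:class:`QuantizationResult` with full provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "Histogram",
    "TriqParams",
    "QuantizationResult",
    "ZeroMemoryQuantizer",
    "TriqQuantizer",
    "GlobalTriqQuantizer",
    "HistogramEqualizer",
    "compute_histogram",
    "zero_memory_quantize",
    "triq_threshold",
    "black_level_threshold",
    "triq_quantize",
    "global_triq",
    "histogram_equalize",
    "count_operations",
]


# Module-level counter of elementary per-pixel operations performed by the
# vectorized kernels.  Each full pass over an m-pixel array adds m.  Used to
# verify the O(N) complexity claim without asserting wall-clock time.
_OP_COUNT = 0


def _ops(n: int) -> None:
    global _OP_COUNT
    _OP_COUNT += int(n)


def _as_array(img) -> np.ndarray:
    """Accept an IonImage, QuantizationResult-like, or bare array."""
    if hasattr(img, "intensities"):
        img = img.intensities
    a = np.asarray(img, dtype=float)
    if a.ndim == 0:
        a = a.reshape(1, 1)
    if not np.all(np.isfinite(a)):
        raise ValueError("intensities must be finite")
    if np.any(a < 0):
        raise ValueError("intensities must be non-negative")
    return a


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class Histogram:
    """Binned frequency counts over an intensity range.

    Bin 0 is closed on both sides ``[edges[0], edges[1]]``; interior bins are
    left-open / right-closed ``(edges[i], edges[i+1]]`` so that the bin
    boundaries behave exactly like quantizer transition levels.  Values
    outside ``[edges[0], edges[-1]]`` are clamped into the outermost bins.
    """

    counts: np.ndarray
    edges: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        edges = np.asarray(self.edges, dtype=float)
        if edges.ndim != 1 or counts.ndim != 1 or len(edges) != len(counts) + 1:
            raise ValueError("edges must have length len(counts) + 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "edges", edges)

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def cumulative_fraction(self) -> np.ndarray:
        if self.n_pixels == 0:
            raise ValueError("histogram is empty")
        return np.cumsum(self.counts) / self.n_pixels


@dataclass(frozen=True)
class TriqParams:
    """Tunable parameters of the TrIQ quantizer.

    q : target cumulative probability; the fraction of pixels guaranteed to
        lie at or below the saturation threshold T.  Default 0.98.
    n : number of gray levels (color depth of the rendered image).
        Default 100.
    cdf_bins : histogram bin count used for the CDF threshold search; more
        bins approximate q more closely.  Defaults to n.
    q_black : lower-tail probability for the black level B; 0 disables it and
        B falls back to min(f).
    """

    q: float = 0.98
    n: int = 100
    cdf_bins: int | None = None
    q_black: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.q <= 1.0:
            raise ValueError(f"q must be in (0, 1], got {self.q}")
        if self.n < 2:
            raise ValueError(f"need at least 2 gray levels, got {self.n}")
        if self.cdf_bins is not None and self.cdf_bins < 2:
            raise ValueError(f"cdf_bins must be >= 2, got {self.cdf_bins}")
        if not 0.0 <= self.q_black < self.q:
            raise ValueError(
                f"q_black must satisfy 0 <= q_black < q, got {self.q_black}"
            )

    @property
    def effective_cdf_bins(self) -> int:
        return self.n if self.cdf_bins is None else self.cdf_bins


@dataclass(frozen=True)
class QuantizationResult:
    """Integer gray-level grid plus the parameters that produced it.

    Keeping the threshold ``T``, black level ``B``, bin width ``w`` and the
    transition levels alongside the levels grid lets a renderer label its
    color bar in original intensity units — the point of a linear quantizer.
    ``transition_levels`` holds the n-1 decision boundaries t_1..t_{n-1}
    (``None`` for histogram equalization, whose boundaries are data-driven
    and not equally spaced).
    """

    levels: np.ndarray
    n: int
    threshold: float
    black_level: float
    bin_width: float
    transition_levels: np.ndarray | None
    method: str = "triq"

    def __post_init__(self):
        levels = np.asarray(self.levels)
        if levels.min(initial=0) < 0 or levels.max(initial=0) > self.n - 1:
            raise ValueError("gray levels must lie in [0, n-1]")
        object.__setattr__(self, "levels", levels.astype(np.int64))

    @property
    def shape(self):
        return self.levels.shape


# ---------------------------------------------------------------------------
# histogram & thresholds


def compute_histogram(img, bins: int, lo: float | None = None,
                      hi: float | None = None) -> Histogram:
    """Equal-width histogram with left-open/right-closed bins.

    The first bin is closed at ``lo``; values below ``lo`` or above ``hi``
    are clamped into the outermost bins, so ``sum(counts)`` always equals the
    pixel count.
    """
    a = _as_array(img)
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    if lo is None:
        lo = float(a.min())
    if hi is None:
        hi = float(a.max())
    if lo >= hi:
        raise ValueError(f"need lo < hi, got lo={lo}, hi={hi}")
    edges = np.linspace(lo, hi, bins + 1)
    # (e_i, e_{i+1}] membership: insertion point to the left of ties puts a
    # value equal to an edge into the bin below it.
    idx = np.searchsorted(edges, a.ravel(), side="left") - 1
    idx = np.clip(idx, 0, bins - 1)
    _ops(a.size)
    counts = np.bincount(idx, minlength=bins)
    return Histogram(counts=counts, edges=edges)


def triq_threshold(hist: Histogram, q: float) -> tuple[float, int]:
    """Saturation threshold from the histogram CDF.

    Returns ``(T, k_hit)`` where ``k_hit`` is the smallest bin index whose
    cumulative fraction reaches ``q`` and ``T`` is that bin's upper edge.
    Choosing the *smallest* such bin guarantees that at least a fraction
    ``q`` of the pixels lies at or below ``T``.
    """
    if not 0.0 < q <= 1.0:
        raise ValueError(f"q must be in (0, 1], got {q}")
    cdf = hist.cumulative_fraction()
    k_hit = int(np.searchsorted(cdf, q, side="left"))
    k_hit = min(k_hit, hist.n_bins - 1)  # guard against float round-off at q=1
    return float(hist.edges[k_hit + 1]), k_hit


def black_level_threshold(hist: Histogram, q_black: float) -> float:
    """Background-suppressing black level B.

    Same CDF rule as :func:`triq_threshold` applied to the lower tail: B is
    the upper edge of the smallest bin whose cumulative fraction reaches
    ``q_black``.  Pixels at or below B map to gray level 0, replacing
    ``min(f)`` as the bottom of the quantized scale.
    """
    if not 0.0 < q_black < 1.0:
        raise ValueError(f"q_black must be in (0, 1), got {q_black}")
    cdf = hist.cumulative_fraction()
    k = int(np.searchsorted(cdf, q_black, side="left"))
    k = min(k, hist.n_bins - 1)
    return float(hist.edges[k + 1])


def _map_levels(a: np.ndarray, transitions: np.ndarray) -> np.ndarray:
    """Vectorized transition-level comparison.

    Level 0 iff f <= t_1; level k iff t_k < f <= t_{k+1}; level n-1 iff
    f > t_{n-1}.  ``side='left'`` places a value equal to a transition into
    the bin below it (closed upper bins).
    """
    levels = np.searchsorted(transitions, a.ravel(), side="left")
    _ops(a.size)
    return levels.reshape(a.shape)


# ---------------------------------------------------------------------------
# estimators


class ZeroMemoryQuantizer(TransformerMixin, BaseEstimator):
    """Equal-width quantizer over the full intensity range [min(f), max(f)].

    The textbook zero-memory quantizer: bin width ``w = (max - min) / n``,
    transition levels ``t_k = k*w + min``.  Sensitive to outliers by
    construction — it is the baseline TrIQ improves on.

    Parameters
    ----------
    n_levels : int, default=256
        Number of gray levels.

    Attributes
    ----------
    min_, max_ : float
        Intensity range observed in fit.
    bin_width_ : float
        ``(max_ - min_) / n_levels`` (0 for a constant image).
    transition_levels_ : ndarray of shape (n_levels - 1,)
        Decision boundaries t_1..t_{n-1}.
    """

    def __init__(self, n_levels: int = 256):
        self.n_levels = n_levels

    def fit(self, X, y=None):
        if self.n_levels < 2:
            raise ValueError(f"need at least 2 gray levels, got {self.n_levels}")
        a = _as_array(X)
        self.min_ = float(a.min())
        self.max_ = float(a.max())
        _ops(2 * a.size)
        self.bin_width_ = (self.max_ - self.min_) / self.n_levels
        k = np.arange(1, self.n_levels)
        self.transition_levels_ = self.min_ + k * self.bin_width_
        return self

    def transform(self, X) -> np.ndarray:
        a = _as_array(X)
        return _map_levels(a, self.transition_levels_)

    def quantize(self, X) -> QuantizationResult:
        self.fit(X)
        return QuantizationResult(
            levels=self.transform(X),
            n=self.n_levels,
            threshold=self.max_,
            black_level=self.min_,
            bin_width=self.bin_width_,
            transition_levels=self.transition_levels_,
            method="zero-memory",
        )


class TriqQuantizer(TransformerMixin, BaseEstimator):
    """Threshold intensity quantization.

    ``fit`` learns the saturation threshold ``T`` (upper edge of the first
    CDF bin reaching ``q``) and the black level ``B`` (``min(f)``, or the
    analogous lower-tail threshold when ``q_black > 0``), then lays out
    ``n - 1`` equal-width bins of width ``w = (T - B) / (n_levels - 1)``
    between them.  ``transform`` maps intensities to levels ``0..n-1``;
    everything above ``T`` saturates into level ``n - 1``.  The mapping is
    order-preserving and linear below ``T``.

    Parameters
    ----------
    q : float, default=0.98
        Target cumulative probability.
    n_levels : int, default=100
        Number of gray levels.
    cdf_bins : int or None, default=None
        Histogram resolution for the threshold search; ``None`` means
        ``n_levels``.
    q_black : float, default=0.0
        Lower-tail probability for the black level; 0 disables it.

    Attributes
    ----------
    threshold_ : float
        Saturation threshold T.
    black_level_ : float
        Black level B (equals ``min(f)`` when ``q_black == 0``).
    bin_width_ : float
        Equal bin width w.
    transition_levels_ : ndarray of shape (n_levels - 1,)
        t_k = B + k*w for k = 1..n_levels-1.
    k_hit_ : int
        Index of the histogram bin that determined T.
    """

    def __init__(self, q: float = 0.98, n_levels: int = 100,
                 cdf_bins: int | None = None, q_black: float = 0.0):
        self.q = q
        self.n_levels = n_levels
        self.cdf_bins = cdf_bins
        self.q_black = q_black

    def _params(self) -> TriqParams:
        return TriqParams(q=self.q, n=self.n_levels, cdf_bins=self.cdf_bins,
                          q_black=self.q_black)

    def fit(self, X, y=None):
        params = self._params()
        a = _as_array(X)
        lo, hi = float(a.min()), float(a.max())
        _ops(2 * a.size)
        if hi <= lo:
            # constant image: degenerate but valid; everything maps to level 0
            self.threshold_ = hi
            self.black_level_ = lo
            self.bin_width_ = 0.0
            self.transition_levels_ = np.full(self.n_levels - 1, lo)
            self.k_hit_ = 0
            return self
        hist = compute_histogram(a, params.effective_cdf_bins, lo, hi)
        self.threshold_, self.k_hit_ = triq_threshold(hist, params.q)
        if params.q_black > 0.0:
            self.black_level_ = black_level_threshold(hist, params.q_black)
        else:
            self.black_level_ = lo
        if self.threshold_ <= self.black_level_:
            raise ValueError(
                f"threshold T={self.threshold_:g} does not exceed black level "
                f"B={self.black_level_:g}; lower q_black or raise q"
            )
        self._finalize_scale()
        return self

    def _finalize_scale(self):
        """Derive w and t_1..t_{n-1} from threshold_ and black_level_."""
        self.bin_width_ = (self.threshold_ - self.black_level_) / (self.n_levels - 1)
        k = np.arange(1, self.n_levels)
        self.transition_levels_ = self.black_level_ + k * self.bin_width_

    def transform(self, X) -> np.ndarray:
        a = _as_array(X)
        return _map_levels(a, self.transition_levels_)

    def quantize(self, X) -> QuantizationResult:
        self.fit(X)
        return self._result_for(X)

    def _result_for(self, X) -> QuantizationResult:
        return QuantizationResult(
            levels=self.transform(X),
            n=self.n_levels,
            threshold=self.threshold_,
            black_level=self.black_level_,
            bin_width=self.bin_width_,
            transition_levels=self.transition_levels_,
            method="triq",
        )


class GlobalTriqQuantizer(TriqQuantizer):
    """TrIQ with one shared intensity scale across an image set.

    Fits a per-image TrIQ threshold on every image, then adopts the highest
    of them as the global threshold ``T`` and the lowest per-image minimum as
    the shared black level ``B``.  Every image is mapped with the identical
    transition levels, so equal raw intensities receive equal gray levels in
    all slices and the set can be rendered on a single color bar.

    ``fit`` accepts a sequence of images (arrays or IonImages); so does
    ``transform``, which returns a list of level grids.

    Attributes
    ----------
    threshold_ : float
        Global threshold, max of the per-image thresholds.
    per_image_thresholds_ : ndarray
        The individual TrIQ thresholds.
    """

    def fit(self, X: Sequence, y=None):
        self._params()  # validate q / n_levels / cdf_bins
        if self.q_black:
            raise ValueError(
                "q_black is a per-image adjustment; the global quantizer "
                "shares one black level (the minimum over the set)"
            )
        imgs = [_as_array(x) for x in X]
        if len(imgs) == 0:
            raise ValueError("need at least one image")
        thresholds = []
        minima = []
        for a in imgs:
            sub = TriqQuantizer(q=self.q, n_levels=self.n_levels,
                                cdf_bins=self.cdf_bins).fit(a)
            thresholds.append(sub.threshold_)
            minima.append(float(a.min()))
        self.per_image_thresholds_ = np.asarray(thresholds)
        self.threshold_ = float(self.per_image_thresholds_.max())
        self.black_level_ = float(min(minima))
        self.k_hit_ = int(np.argmax(self.per_image_thresholds_))
        if self.threshold_ <= self.black_level_:
            # whole set constant: degenerate, mirror the single-image case
            self.bin_width_ = 0.0
            self.transition_levels_ = np.full(self.n_levels - 1,
                                              self.black_level_)
        else:
            self._finalize_scale()
        return self

    def transform(self, X: Sequence) -> list[np.ndarray]:
        return [_map_levels(_as_array(a), self.transition_levels_) for a in X]

    def quantize(self, X: Sequence) -> list[QuantizationResult]:
        self.fit(X)
        return [
            QuantizationResult(
                levels=lv,
                n=self.n_levels,
                threshold=self.threshold_,
                black_level=self.black_level_,
                bin_width=self.bin_width_,
                transition_levels=self.transition_levels_,
                method="triq",
            )
            for lv in self.transform(X)
        ]


class HistogramEqualizer(TransformerMixin, BaseEstimator):
    """Global histogram equalization — the contrast baseline TrIQ replaces.

    The image is first zero-memory quantized to ``pre_levels`` gray levels,
    then the standard CDF remap redistributes those levels over ``n_levels``
    output levels.  Contrast improves, but the level→intensity relation
    becomes nonlinear and data-dependent, and on skewed images many output
    levels are never hit (gray-level loss).  Provided for comparison, not
    recommended for quantitative display.

    Attributes
    ----------
    lut_ : ndarray of shape (pre_levels,)
        Lookup table from pre-quantized level to output level.
    """

    def __init__(self, n_levels: int = 256, pre_levels: int = 256):
        self.n_levels = n_levels
        self.pre_levels = pre_levels

    def fit(self, X, y=None):
        if self.n_levels < 2:
            raise ValueError(f"need at least 2 gray levels, got {self.n_levels}")
        a = _as_array(X)
        self._zm = ZeroMemoryQuantizer(n_levels=self.pre_levels).fit(a)
        pre = self._zm.transform(a)
        counts = np.bincount(pre.ravel(), minlength=self.pre_levels)
        cdf = np.cumsum(counts)
        cdf_min = cdf[cdf > 0][0]
        total = cdf[-1]
        if total == cdf_min:
            # single occupied pre-level: map everything to 0
            self.lut_ = np.zeros(self.pre_levels, dtype=np.int64)
        else:
            self.lut_ = np.rint(
                (cdf - cdf_min) / (total - cdf_min) * (self.n_levels - 1)
            ).astype(np.int64)
            self.lut_ = np.clip(self.lut_, 0, self.n_levels - 1)
        return self

    def transform(self, X) -> np.ndarray:
        a = _as_array(X)
        pre = self._zm.transform(a)
        _ops(a.size)
        return self.lut_[pre]

    def quantize(self, X) -> QuantizationResult:
        self.fit(X)
        return QuantizationResult(
            levels=self.transform(X),
            n=self.n_levels,
            threshold=self._zm.max_,
            black_level=self._zm.min_,
            bin_width=float("nan"),
            transition_levels=None,
            method="equalized",
        )


# ---------------------------------------------------------------------------
# functional wrappers


def zero_memory_quantize(img, n: int) -> QuantizationResult:
    """Equal-width quantization over [min(f), max(f)] with n gray levels."""
    return ZeroMemoryQuantizer(n_levels=n).quantize(img)


def triq_quantize(img, params: TriqParams | None = None, **kwargs) -> QuantizationResult:
    """TrIQ quantization of a single image.

    Pass a :class:`TriqParams`, or keyword arguments ``q``, ``n``,
    ``cdf_bins``, ``q_black``.
    """
    params = _resolve_params(params, kwargs)
    est = TriqQuantizer(q=params.q, n_levels=params.n, cdf_bins=params.cdf_bins,
                        q_black=params.q_black)
    return est.quantize(img)


def global_triq(imgs: Sequence, params: TriqParams | None = None,
                **kwargs) -> list[QuantizationResult]:
    """TrIQ over an image set with one shared threshold and color scale."""
    params = _resolve_params(params, kwargs)
    est = GlobalTriqQuantizer(q=params.q, n_levels=params.n,
                              cdf_bins=params.cdf_bins)
    return est.quantize(list(imgs))


def histogram_equalize(img, n: int, pre_levels: int = 256) -> QuantizationResult:
    """Global histogram equalization after zero-memory pre-quantization."""
    return HistogramEqualizer(n_levels=n, pre_levels=pre_levels).quantize(img)


def _resolve_params(params: TriqParams | None, kwargs: dict) -> TriqParams:
    if params is not None and kwargs:
        raise TypeError("pass either a TriqParams or keyword arguments, not both")
    if params is None:
        params = TriqParams(**kwargs)
    return params


def count_operations(func, *args, **kwargs) -> tuple:
    """Run ``func`` and report the elementary per-pixel operations it used.

    Returns ``(result, op_count)``.  Every vectorized kernel in this module
    adds the number of array elements it touches, so the count reflects the
    algorithmic cost independent of machine speed.
    """
    global _OP_COUNT
    before = _OP_COUNT
    result = func(*args, **kwargs)
    return result, _OP_COUNT - before
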