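"""Post-quantization image operations.

Quantized ion images from noisy (ambient ionization) MSI keep isolated
salt-noise pixels; a 3×3 median filter removes them without blurring region
boundaries.  Regions of interest are then cut out as binary masks — every
non-zero level, a minimum-level cutoff, or Otsu's between-class-variance
threshold for comparison — and up to three masks or level grids can be
blended into an RGB overlay.

All operations act on gray-level grids (a :class:`~triq.quantize.QuantizationResult`
or a bare integer array) and are pure: the input is never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .quantize import QuantizationResult

__all__ = [
    "BinaryMask",
    "median_filter_3x3",
    "mask_nonzero",
    "mask_min_level",
    "otsu_threshold",
    "overlay_rgb",
]


@dataclass(frozen=True)
class BinaryMask:
    """Boolean grid marking a region of interest, with the rule that made it."""

    mask: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be a 2-D grid")
        object.__setattr__(self, "mask", m)

    @property
    def shape(self):
        return self.mask.shape


def _levels_of(x) -> np.ndarray:
    if isinstance(x, QuantizationResult):
        return x.levels
    a = np.asarray(x)
    if a.ndim != 2:
        raise ValueError("expected a 2-D gray-level grid")
    return a


def _n_of(x, default=None) -> int | None:
    if isinstance(x, QuantizationResult):
        return x.n
    return default


def median_filter_3x3(levels, passes: int = 1):
    """3×3 median filter with in-bounds-only neighborhoods.

    Each output pixel is the median of its existing neighbors (edge and
    corner pixels use 6 or 4 neighbors; no padding values are invented).
    With an even neighbor count the lower median is taken, so output levels
    are always levels present in the neighborhood and stay in [0, n-1].

    Accepts a QuantizationResult (returned with filtered levels and
    unchanged scale metadata) or a bare integer grid.
    """
    if passes < 1:
        raise ValueError(f"passes must be >= 1, got {passes}")
    grid = _levels_of(levels)
    out = grid
    for _ in range(passes):
        out = _median_pass(out)
    if isinstance(levels, QuantizationResult):
        return replace(levels, levels=out)
    return out


def _median_pass(grid: np.ndarray) -> np.ndarray:
    r, c = grid.shape
    padded = np.full((r + 2, c + 2), np.nan)
    padded[1:-1, 1:-1] = grid
    # 9 shifted views -> (r, c, 9); NaN marks out-of-bounds neighbors
    win = np.stack(
        [padded[i:i + r, j:j + c] for i in range(3) for j in range(3)],
        axis=-1,
    )
    win.sort(axis=-1)  # NaNs sort to the end
    n_valid = np.count_nonzero(~np.isnan(win), axis=-1)
    idx = (n_valid - 1) // 2  # lower median
    med = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    return med.astype(grid.dtype) if np.issubdtype(grid.dtype, np.integer) \
        else med


def mask_nonzero(levels) -> BinaryMask:
    """True wherever the gray level is non-zero."""
    grid = _levels_of(levels)
    return BinaryMask(mask=grid > 0, provenance="nonzero")


def mask_min_level(levels, min_level: int) -> BinaryMask:
    """True wherever the gray level is at least ``min_level``.

    ``mask_min_level(x, 1)`` is identical to :func:`mask_nonzero`;
    ``min_level=0`` selects everything.
    """
    grid = _levels_of(levels)
    n = _n_of(levels)
    upper = (n - 1) if n is not None else int(grid.max(initial=0))
    if not 0 <= min_level <= upper:
        raise ValueError(
            f"min_level must be in [0, {upper}], got {min_level}"
        )
    return BinaryMask(mask=grid >= min_level, provenance=f"level >= {min_level}")


def otsu_threshold(levels) -> tuple[int, BinaryMask]:
    """Otsu's threshold over the gray-level histogram.

    Exhaustively maximizes the between-class variance
    ``sigma_b^2(t) = w0 w1 (mu0 - mu1)^2`` over all candidate cuts; the mask
    is True where ``level > t``.  Ties take the smallest threshold.  A
    constant grid has no valid split and raises.
    """
    grid = _levels_of(levels)
    flat = np.asarray(grid, dtype=np.int64).ravel()
    if flat.min() == flat.max():
        raise ValueError("Otsu needs at least two distinct gray levels")
    n = _n_of(levels, default=int(flat.max()) + 1)
    counts = np.bincount(flat, minlength=n)
    p = counts / flat.size
    lv = np.arange(len(counts))
    omega0 = np.cumsum(p)[:-1]            # class 0: levels <= t, t = 0..n-2
    mu_cum = np.cumsum(p * lv)[:-1]
    mu_total = float(np.sum(p * lv))
    valid = (omega0 > 0) & (omega0 < 1)
    sigma_b = np.full(len(omega0), -np.inf)
    sigma_b[valid] = (mu_total * omega0[valid] - mu_cum[valid]) ** 2 / (
        omega0[valid] * (1.0 - omega0[valid])
    )
    t = int(np.argmax(sigma_b))
    return t, BinaryMask(mask=grid > t, provenance=f"otsu > {t}")


def overlay_rgb(channels, colors) -> np.ndarray:
    """Additive RGB blend of up to three masks or gray-level grids.

    Each channel contributes ``weight * color`` per pixel, where the weight
    is 1/0 for a mask and ``level / (n - 1)`` for a gray-level grid; the sum
    is clipped to [0, 1].  Returns an (rows, cols, 3) float array.
    """
    channels = list(channels)
    colors = [np.asarray(c, dtype=float) for c in colors]
    if not 1 <= len(channels) <= 3:
        raise ValueError("overlay takes 1 to 3 channels")
    if len(colors) != len(channels):
        raise ValueError("need one RGB color per channel")
    weights = []
    for ch in channels:
        if isinstance(ch, BinaryMask):
            weights.append(ch.mask.astype(float))
        else:
            grid = _levels_of(ch)
            if grid.dtype == bool:
                weights.append(grid.astype(float))
            else:
                n = _n_of(ch, default=None)
                top = (n - 1) if n is not None else max(int(grid.max(initial=0)), 1)
                weights.append(np.asarray(grid, dtype=float) / max(top, 1))
    shape = weights[0].shape
    for w in weights[1:]:
        if w.shape != shape:
            raise ValueError(f"channel shapes differ: {w.shape} vs {shape}")
    out = np.zeros(shape + (3,))
    for w, color in zip(weights, colors):
        if color.shape != (3,):
            raise ValueError("colors must be RGB triples")
        out += w[..., None] * color[None, None, :]
    return np.clip(out, 0.0, 1.0)
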