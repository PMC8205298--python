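"""Rendering quantized ion images to PNG.

The selling point of a linear quantizer is that the color bar still means
something: gray level 0 corresponds to the black level B, level n-1 to
"everything at or above the threshold T", and the ticks in between are
equally spaced in original intensity units.  The renderer therefore labels
the color bar in intensity units, marking the saturated top level as
``>= T``.

Viridis is the default colormap (perceptually ordered, CVD-safe).  A
log-intensity comparison mode exists for side-by-side figures but is never
the default.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

import matplotlib
matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .quantize import QuantizationResult

__all__ = ["RenderConfig", "render", "render_set"]


@dataclass(frozen=True)
class RenderConfig:
    """Rendering options.

    colormap : matplotlib colormap name; keep a perceptually ordered one.
    colorbar : label a color bar in original intensity units.  When False
        the grid is exported pixel-for-pixel with no decorations.
    log_comparison : render log1p(level) instead — an explicitly flagged
        comparison mode only.
    n_ticks : number of color-bar ticks (including the ends).
    dpi : figure resolution for the colorbar layout.
    """

    colormap: str = "viridis"
    colorbar: bool = True
    log_comparison: bool = False
    n_ticks: int = 5
    dpi: int = 150


def render(qr: QuantizationResult, path, cfg: RenderConfig | None = None) -> None:
    """Write a quantized image as PNG.

    Pure view: gray levels are never altered.  Without a color bar the
    output is a pixel-exact indexed export (one image pixel per grid cell,
    exactly the occupied colors).  With a color bar, tick labels map levels
    back to intensity units — level 0 at B, the top level labeled ``>= T``
    to mark saturation.
    """
    cfg = cfg or RenderConfig()
    path = os.fspath(path)
    levels = qr.levels.astype(float)
    vmax = qr.n - 1
    if cfg.log_comparison:
        levels = np.log1p(levels)
        vmax = float(np.log1p(qr.n - 1))
    cmap = plt.get_cmap(cfg.colormap)

    if not cfg.colorbar:
        rgba = cmap(levels / vmax if vmax > 0 else levels)
        plt.imsave(path, rgba, format="png")
        return

    fig, ax = plt.subplots(figsize=_figsize(qr.levels.shape), dpi=cfg.dpi)
    im = ax.imshow(levels, cmap=cmap, vmin=0, vmax=vmax,
                   interpolation="nearest", origin="upper")
    ax.set_xticks([])
    ax.set_yticks([])
    cbar = fig.colorbar(im, ax=ax, fraction=0.046, pad=0.04)
    ticks = np.linspace(0, vmax, cfg.n_ticks)
    cbar.set_ticks(ticks)
    cbar.set_ticklabels(_tick_labels(qr, ticks, cfg))
    fig.savefig(path, format="png", metadata={"Software": "triq"})
    plt.close(fig)


def render_set(qrs, paths, cfg: RenderConfig | None = None) -> None:
    """Render several results (e.g. a global-TrIQ set) with identical scales."""
    qrs, paths = list(qrs), list(paths)
    if len(qrs) != len(paths):
        raise ValueError("need one output path per image")
    for qr, path in zip(qrs, paths):
        render(qr, path, cfg)


def _figsize(shape):
    r, c = shape
    width = 5.0
    return (width * 1.25, max(width * r / max(c, 1), 1.0))


def _tick_labels(qr: QuantizationResult, ticks, cfg: RenderConfig) -> list[str]:
    labels = []
    top = ticks[-1]
    for t in ticks:
        lv = float(np.expm1(t)) if cfg.log_comparison else float(t)
        if qr.method == "equalized" or qr.transition_levels is None:
            # no linear level->intensity relation to annotate
            labels.append(f"{lv:.0f}")
            continue
        intensity = qr.black_level + lv * qr.bin_width
        if t == top and qr.method == "triq":
            labels.append(f"≥ {qr.threshold:g}")
        else:
            labels.append(f"{intensity:g}")
    return labels
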