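"""Synthetic ion images with the pathologies TrIQ is built for.

Real (ambient ionization) MSI ion images combine three ingredients: a
diffuse non-negative background noise floor, a contiguous sample region of
elevated intensity, and a handful of extreme-intensity outlier pixels that
wreck min–max scaling.  The generator reproduces exactly these ingredients
with known ground truth (region mask, outlier positions, per-slice scales),
so quantization, normalization and segmentation can be tested
quantitatively without external datasets.

Noise and region intensities are gamma-distributed (non-negative, right
skewed — Gaussian noise would produce impossible negative ion counts).
Everything is deterministic given the seed.

A minimal imzML writer is included so the reader can be exercised on
fixtures: each image pixel becomes a single-peak centroid spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imageops import BinaryMask
from .msi_io import IonImage, Spectrum

__all__ = [
    "SyntheticSpec",
    "generate_ion_image",
    "generate_slice_set",
    "write_fixture_imzml",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic ion image.

    Defaults mimic a DESI-scale slice: a 64×67 grid (the smallest of the
    acquisition grids the algorithm targets), a faint gamma background, an
    elliptical sample region ~40× above the background (samples in MSI
    figures stand clearly above the noise floor), and 2% of
    pixels replaced by outliers an order of magnitude above the region —
    reproducing the heavy right skew where naive min–max quantization packs
    nearly all pixels into the lowest gray levels.

    Attributes
    ----------
    shape : (rows, cols) of the grid.
    background_mean : mean of the gamma background noise (arbitrary units).
    background_shape : gamma shape parameter (smaller = more dispersed).
    region : 'disk' or 'rect' sample-region geometry.
    region_center : (row, col) center; None = grid center.
    region_size : disk radii (r_row, r_col) or rect half-sides.
    region_mean : mean region intensity.
    region_shape : gamma shape of the region intensity law.
    outlier_fraction : fraction of all pixels replaced by outliers.
    outlier_range : (lo, hi) uniform range of outlier intensities; lo must
        exceed any plausible region intensity so outliers are unambiguous.
    seed : RNG seed fixing the whole image.
    """

    shape: tuple = (64, 67)
    background_mean: float = 50.0
    background_shape: float = 2.0
    region: str = "disk"
    region_center: tuple | None = None
    region_size: tuple = (20, 22)
    region_mean: float = 2000.0
    region_shape: float = 4.0
    outlier_fraction: float = 0.02
    outlier_range: tuple = (20000.0, 70000.0)
    seed: int = 0

    def __post_init__(self):
        r, c = self.shape
        if r < 1 or c < 1:
            raise ValueError(f"grid shape must be positive, got {self.shape}")
        if self.region not in ("disk", "rect"):
            raise ValueError(f"region must be 'disk' or 'rect', got {self.region!r}")
        sr, sc = self.region_size
        if 2 * sr > r or 2 * sc > c:
            raise ValueError(
                f"region size {self.region_size} does not fit grid {self.shape}"
            )
        if self.background_mean < 0 or self.region_mean <= 0:
            raise ValueError("intensity means must be non-negative")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError(
                f"outlier_fraction must be in [0, 1), got {self.outlier_fraction}"
            )
        lo, hi = self.outlier_range
        if lo > hi or lo <= 0:
            raise ValueError(f"bad outlier_range {self.outlier_range}")
        # outliers must be unambiguously above anything the region produces
        if self.outlier_fraction > 0 and lo <= 5 * self.region_mean:
            raise ValueError(
                "outlier intensities must clearly exceed the region intensity "
                f"(need lo > {5 * self.region_mean:g}, got {lo:g})"
            )

    @property
    def n_outliers(self) -> int:
        r, c = self.shape
        return int(round(self.outlier_fraction * r * c))


def _region_mask(spec: SyntheticSpec) -> np.ndarray:
    r, c = spec.shape
    cr, cc = spec.region_center if spec.region_center is not None \
        else ((r - 1) / 2.0, (c - 1) / 2.0)
    sr, sc = spec.region_size
    rows, cols = np.ogrid[:r, :c]
    if spec.region == "disk":
        return ((rows - cr) / sr) ** 2 + ((cols - cc) / sc) ** 2 <= 1.0
    return (np.abs(rows - cr) <= sr) & (np.abs(cols - cc) <= sc)


def generate_ion_image(spec: SyntheticSpec) -> tuple[IonImage, BinaryMask]:
    """Generate one synthetic ion image plus its ground-truth region mask.

    Returns ``(image, region_mask)``.  With zero noise and zero outliers the
    image is the pure region template at ``region_mean``.  Non-outlier
    intensities are capped just below the outlier range so the requested
    outliers are exactly the top ``n_outliers`` pixels.
    """
    rng = np.random.default_rng(spec.seed)
    r, c = spec.shape
    region = _region_mask(spec)

    if spec.background_mean > 0:
        img = rng.gamma(spec.background_shape,
                        spec.background_mean / spec.background_shape,
                        size=(r, c))
    else:
        img = np.zeros((r, c))
    if spec.region_shape > 0 and spec.background_mean > 0:
        region_vals = rng.gamma(spec.region_shape,
                                spec.region_mean / spec.region_shape,
                                size=int(region.sum()))
    else:
        region_vals = np.full(int(region.sum()), spec.region_mean)
    img[region] += region_vals

    n_out = spec.n_outliers
    if n_out > 0:
        lo, hi = spec.outlier_range
        # keep regular pixels strictly below the outlier band
        np.minimum(img, 0.999 * lo, out=img)
        flat_idx = rng.choice(r * c, size=n_out, replace=False)
        img.ravel()[flat_idx] = rng.uniform(lo, hi, size=n_out)

    image = IonImage(intensities=img, note=f"synthetic seed={spec.seed}")
    return image, BinaryMask(mask=region, provenance="ground truth region")


def generate_slice_set(spec: SyntheticSpec, n_slices: int,
                       scale_jitter: float = 0.5,
                       scales=None) -> tuple[list[IonImage], np.ndarray, BinaryMask]:
    """A multi-slice set sharing one layout on one global intensity scale.

    All slices are the same base image multiplied by per-slice scale
    factors, emulating serial sections of one tissue with varying overall
    signal.  Scales are drawn uniformly from ``[1, 1 + scale_jitter]``
    (``scale_jitter=0`` gives identical slices) unless given explicitly.

    Returns ``(slices, scales, region_mask)``.
    """
    if n_slices < 2:
        raise ValueError(f"a slice set needs >= 2 slices, got {n_slices}")
    if scale_jitter < 0:
        raise ValueError(f"scale_jitter must be >= 0, got {scale_jitter}")
    base, region = generate_ion_image(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, n_slices]))
    if scales is None:
        scales = 1.0 + scale_jitter * rng.uniform(0.0, 1.0, size=n_slices)
    else:
        scales = np.asarray(scales, dtype=float)
        if len(scales) != n_slices or np.any(scales <= 0):
            raise ValueError("need one positive scale per slice")
    slices = [
        IonImage(intensities=base.intensities * s,
                 note=f"{base.note} slice={i} scale={s:g}")
        for i, s in enumerate(scales)
    ]
    return slices, np.asarray(scales), region


def image_to_spectra(img: IonImage, mz: float = 100.0) -> list[Spectrum]:
    """Turn an ion image into single-peak spectra (one centroid per pixel)."""
    a = img.intensities
    return [
        Spectrum(x=col + 1, y=row + 1,
                 mz=np.array([mz]),
                 intensities=np.array([a[row, col]], dtype=float))
        for row in range(a.shape[0]) for col in range(a.shape[1])
    ]


def write_fixture_imzml(spectra, path) -> None:
    """Write spectra as a minimal standard-conforming imzML/ibd pair.

    Processed mode, 32-bit floats, explicit 1-based coordinates — readable
    by :func:`triq.msi_io.load_imzml` and by mainstream imzML parsers.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    spectra = list(spectra)
    if not spectra:
        raise ValueError("cannot write an imzML fixture with no spectra")
    import os
    out = os.fspath(path)
    if out.lower().endswith(".imzml"):
        out = out[: -len(".imzML")]
    with ImzMLWriter(out, mz_dtype=np.float32, intensity_dtype=np.float32,
                     mode="processed") as writer:
        for s in spectra:
            writer.addSpectrum(s.mz, s.intensities, (s.x, s.y))
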