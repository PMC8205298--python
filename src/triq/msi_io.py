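"""Reading MSI data and extracting ion images.

An imzML dataset stores one mass spectrum per pixel of a rectangular scan
grid (1-based x/y coordinates).  An *ion image* is the 2D intensity map of
one target m/z: per pixel, the centroid intensities within ``mz ± tol`` are
aggregated (sum by default).  Plain delimited-text matrices are supported as
a format-free entry point so the quantizers can be used on any rectangular
non-negative data.

Grid convention: row = y, column = x, origin top-left; pixels with no
spectrum or no matching centroid carry intensity 0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Spectrum",
    "MSIDataset",
    "IonImage",
    "load_imzml",
    "extract_ion_image",
    "read_matrix",
    "write_matrix",
]


@dataclass(frozen=True)
class Spectrum:
    """One pixel's centroid list at 1-based grid coordinates (x, y)."""

    x: int
    y: int
    mz: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("m/z and intensity arrays must be 1-D and equal length")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        if self.x < 1 or self.y < 1:
            raise ValueError("imzML coordinates are 1-based")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensities", inten)


@dataclass(frozen=True)
class MSIDataset:
    """A parsed imzML run: spectra with coordinates on a width × height grid."""

    spectra: tuple
    width: int
    height: int
    source: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "spectra", tuple(self.spectra))
        for s in self.spectra:
            if not (1 <= s.x <= self.width and 1 <= s.y <= self.height):
                raise ValueError(
                    f"pixel ({s.x}, {s.y}) outside grid "
                    f"[1, {self.width}] x [1, {self.height}]"
                )

    def __len__(self) -> int:
        return len(self.spectra)

    def total_intensity(self) -> float:
        return float(sum(s.intensities.sum() for s in self.spectra))


@dataclass(frozen=True)
class IonImage:
    """Rectangular grid of non-negative intensities for one m/z slice."""

    intensities: np.ndarray
    mz: float | None = None
    tol: float | None = None
    note: str = ""

    def __post_init__(self):
        a = np.asarray(self.intensities, dtype=float)
        if a.ndim == 0:
            a = a.reshape(1, 1)
        if a.ndim != 2:
            raise ValueError(f"ion image must be a 2-D grid, got ndim={a.ndim}")
        if not np.all(np.isfinite(a)):
            raise ValueError("intensities must be finite")
        if np.any(a < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "intensities", a)

    @property
    def shape(self):
        return self.intensities.shape


def load_imzml(path) -> MSIDataset:
    """Read an imzML/ibd pair into an :class:`MSIDataset`.

    Both continuous and processed mode files are accepted; spectra are
    treated as centroid lists either way (no peak picking).  Grid dimensions
    are the maximum observed x and y coordinates.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"imzML file not found: {path}")
    ibd = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(ibd):
        raise IOError(f"binary companion (.ibd) not found for: {path}")
    try:
        parser = ImzMLParser(path)
    except Exception as exc:  # malformed XML / binary
        raise IOError(f"could not parse imzML file {path}: {exc}") from exc

    spectra = []
    for i, coords in enumerate(parser.coordinates):
        x, y = int(coords[0]), int(coords[1])
        mz, inten = parser.getspectrum(i)
        spectra.append(Spectrum(x=x, y=y, mz=mz, intensities=inten))
    if not spectra:
        raise IOError(f"no spectra found in {path}")

    width = max(s.x for s in spectra)
    height = max(s.y for s in spectra)
    declared_w = parser.imzmldict.get("max count of pixels x")
    declared_h = parser.imzmldict.get("max count of pixels y")
    if declared_w is not None and width > int(declared_w):
        raise ValueError(
            f"pixel x={width} exceeds declared extent {declared_w} in {path}"
        )
    if declared_h is not None and height > int(declared_h):
        raise ValueError(
            f"pixel y={height} exceeds declared extent {declared_h} in {path}"
        )

    metadata = {}
    for key in ("polarity", "spectrum mode"):
        if key in parser.imzmldict:
            metadata[key] = parser.imzmldict[key]
    # continuous vs processed: pyimzml exposes the accession flags
    for mode in ("continuous", "processed"):
        if parser.metadata is not None and \
                mode in getattr(parser.metadata, "file_description", {}).param_by_name:
            metadata["mode"] = mode
    return MSIDataset(spectra=tuple(spectra), width=width, height=height,
                      source=path, metadata=metadata)


def extract_ion_image(ds: MSIDataset, mz: float, tol: float,
                      agg: str = "sum") -> IonImage:
    """Ion image at ``mz ± tol``.

    Per pixel, all centroid intensities with m/z in the closed window
    ``[mz - tol, mz + tol]`` are aggregated — summed by default, or the
    maximum with ``agg='max'``.  Grid cells with no spectrum or no matching
    centroid are 0; an empty window yields an all-zero image, not an error.
    """
    if tol <= 0:
        raise ValueError(f"tolerance must be positive, got {tol}")
    if agg not in ("sum", "max"):
        raise ValueError(f"agg must be 'sum' or 'max', got {agg!r}")
    grid = np.zeros((ds.height, ds.width))
    lo, hi = mz - tol, mz + tol
    for s in ds.spectra:
        sel = (s.mz >= lo) & (s.mz <= hi)
        if np.any(sel):
            vals = s.intensities[sel]
            grid[s.y - 1, s.x - 1] = vals.sum() if agg == "sum" else vals.max()
    return IonImage(intensities=grid, mz=mz, tol=tol,
                    note=f"{agg} over [{lo:g}, {hi:g}] from {ds.source}")


def read_matrix(path, delimiter: str | None = None) -> IonImage:
    """Read a rectangular delimited-text intensity matrix.

    The delimiter is sniffed (comma, tab, semicolon, else whitespace) unless
    given.  Ragged rows or negative values are rejected.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"matrix file not found: {path}")
    if delimiter is None:
        with open(path) as fh:
            first = fh.readline()
        for cand in (",", "\t", ";"):
            if cand in first:
                delimiter = cand
                break
    try:
        a = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"not a rectangular numeric matrix: {path} ({exc})") from exc
    return IonImage(intensities=a, note=path)


def write_matrix(img, path, delimiter: str = "\t") -> None:
    """Write an ion image (or bare array) as delimited text, losslessly.

    Uses 17 significant digits so a read-back reproduces the float64 values
    exactly.
    """
    a = img.intensities if isinstance(img, IonImage) else np.asarray(img, dtype=float)
    np.savetxt(os.fspath(path), np.atleast_2d(a), fmt="%.17g", delimiter=delimiter)
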