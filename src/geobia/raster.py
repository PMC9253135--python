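"""Lightweight raster containers and TIFF I/O.

A :class:`Raster` is a 2-D grid of values with a square cell size; a
:class:`MultibandImage` bundles the three spectral bands (near-infrared,
red, green) on a congruent grid.  No georeferencing is carried: synthetic
scenes live in pixel coordinates with a configurable physical cell size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Raster", "MultibandImage", "read_raster", "write_raster"]

BAND_NAMES = ("nir", "red", "green")


@dataclass(frozen=True)
class Raster:
    """A single-band raster: 2-D array, row-major, 0-based (row, col)."""

    values: np.ndarray
    cell_size: float = 1.0
    nodata: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError(f"raster values must be 2-D, got shape {arr.shape}")
        if arr.size == 0:
            raise ValueError("raster must be non-empty")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of pixels that are not the nodata sentinel."""
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        return self.values != self.nodata

    def with_values(self, values: np.ndarray) -> "Raster":
        return Raster(values, cell_size=self.cell_size, nodata=self.nodata)


@dataclass(frozen=True)
class MultibandImage:
    """Named spectral bands {nir, red, green} on congruent grids."""

    nir: Raster
    red: Raster
    green: Raster

    def __post_init__(self) -> None:
        shapes = {b.shape for b in self.bands.values()}
        cells = {b.cell_size for b in self.bands.values()}
        if len(shapes) != 1 or len(cells) != 1:
            raise ValueError("bands must share dimensions and cell_size")

    @property
    def bands(self) -> dict[str, Raster]:
        return {"nir": self.nir, "red": self.red, "green": self.green}

    @property
    def shape(self) -> tuple[int, int]:
        return self.nir.shape

    @property
    def cell_size(self) -> float:
        return self.nir.cell_size

    def as_array(self) -> np.ndarray:
        """Stack bands into a (3, rows, cols) array in (nir, red, green) order."""
        return np.stack([self.nir.values, self.red.values, self.green.values])

    @classmethod
    def from_array(
        cls, arr: np.ndarray, cell_size: float = 1.0
    ) -> "MultibandImage":
        if arr.ndim != 3 or arr.shape[0] != 3:
            raise ValueError("expected a (3, rows, cols) array")
        return cls(*(Raster(a, cell_size=cell_size) for a in arr))


def check_congruent(*rasters: Raster) -> None:
    """Raise if the rasters do not share grid shape and cell size."""
    if not rasters:
        raise ValueError("no rasters given")
    ref = rasters[0]
    for r in rasters[1:]:
        if r.shape != ref.shape:
            raise ValueError(f"shape mismatch: {r.shape} vs {ref.shape}")
        if r.cell_size != ref.cell_size:
            raise ValueError("cell_size mismatch")


def write_raster(path: str | Path, raster: Raster | MultibandImage) -> None:
    """Write a raster (or 3-band image, band-interleaved) as a TIFF file."""
    path = Path(path)
    if isinstance(raster, MultibandImage):
        tifffile.imwrite(
            path,
            raster.as_array(),
            photometric="minisblack",
            planarconfig="separate",
        )
    else:
        tifffile.imwrite(path, raster.values)


def read_raster(
    path: str | Path, cell_size: float = 1.0, nodata: float | None = None
) -> Raster | MultibandImage:
    """Read a TIFF written by :func:`write_raster`.

    Returns a MultibandImage for 3-band files, a Raster otherwise.
    """
    arr = tifffile.imread(Path(path))
    if arr.ndim == 3:
        return MultibandImage.from_array(arr, cell_size=cell_size)
    return Raster(arr, cell_size=cell_size, nodata=nodata)
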