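"""Derived single-band rasters: NDVI, canopy height, grayscale, intensity.

These feed both the segmentation stage (the intensity image is the
watershed surface) and the per-object feature table.  All operations are
pixel-wise and commute with cropping.
"""

from __future__ import annotations

import numpy as np

from .raster import MultibandImage, Raster, check_congruent

__all__ = ["compute_ndvi", "compute_chm", "to_grayscale", "intensity_image"]


def compute_ndvi(nir: Raster, red: Raster) -> Raster:
    """Normalized difference vegetation index, (NIR - red) / (NIR + red).

    Pixels where NIR + red == 0 map to 0 by convention, so no non-finite
    values propagate into segmentation.  Output is bounded in [-1, 1] for
    non-negative reflectance inputs.
    """
    check_congruent(nir, red)
    num = nir.values - red.values
    den = nir.values + red.values
    out = np.divide(num, den, out=np.zeros_like(num, dtype=float), where=den != 0)
    return nir.with_values(out)


def compute_chm(dsm: Raster, dtm: Raster) -> Raster:
    """Canopy height model: surface minus terrain, clamped at zero.

    Negative differences (sensor noise, interpolation artifacts) are set
    to 0 m rather than kept, so heights are physically meaningful.
    """
    check_congruent(dsm, dtm)
    return dsm.with_values(np.maximum(dsm.values - dtm.values, 0.0))


def to_grayscale(image: MultibandImage) -> Raster:
    """Unweighted per-pixel mean of the three spectral bands."""
    return image.nir.with_values(image.as_array().mean(axis=0))


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        # constant layer carries no contrast; map to 0
        return np.zeros_like(values, dtype=float)
    return (values - lo) / (hi - lo)


def intensity_image(layers: list[Raster], normalize: bool = True) -> Raster:
    """Per-pixel mean across layers, the watershed segmentation surface.

    With ``normalize`` each layer is min-max rescaled to [0, 1] first so
    layers on different physical scales (an index in [-1, 1], heights in
    meters) contribute equally to the average.
    """
    if not layers:
        raise ValueError("at least one layer required")
    check_congruent(*layers)
    arrays = [l.values.astype(float) for l in layers]
    if normalize:
        arrays = [_minmax(a) for a in arrays]
    return layers[0].with_values(np.mean(arrays, axis=0))
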