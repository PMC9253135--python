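"""Segmentation/classification assessment: PR and landscape metrics.

PR (percentage of right segmented pixels) is the pixel-wise agreement
between a classified raster and a ground-truth raster, as a percent —
higher is better.

Landscape metrics follow the FRAGSTATS landscape-level definitions on
patches (connected components of same-class pixels, 8-connected by
default): number of patches (NP), patch area (AREA), fractal dimension
index FRAC = 2 ln(0.25 p) / ln(a), and perimeter-area ratio PARA = p/a,
each summarized by the area-weighted mean (AM) and the unweighted
standard deviation (SD).  Single-cell patches take FRAC = 1 (the log
ratio is undefined there).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label

from .raster import Raster

__all__ = [
    "Patch",
    "LandscapeMetricsReport",
    "pr_metric",
    "extract_patches",
    "landscape_metrics",
]


@dataclass(frozen=True)
class Patch:
    """One connected same-class region: class code, area, perimeter."""

    class_id: int
    area: float
    perimeter: float


@dataclass(frozen=True)
class LandscapeMetricsReport:
    NP: int
    AREA_AM: float
    AREA_SD: float
    FRAC_AM: float
    FRAC_SD: float
    PARA_AM: float
    PARA_SD: float

    def as_dict(self) -> dict[str, float]:
        return {
            "NP": self.NP,
            "AREA_AM": self.AREA_AM,
            "AREA_SD": self.AREA_SD,
            "FRAC_AM": self.FRAC_AM,
            "FRAC_SD": self.FRAC_SD,
            "PARA_AM": self.PARA_AM,
            "PARA_SD": self.PARA_SD,
        }


def pr_metric(classified: Raster, truth: Raster) -> float:
    """Percent of pixels whose classified label equals the truth label.

    Pixels where the truth raster is nodata (negative code) are excluded
    from both numerator and denominator.
    """
    if classified.shape != truth.shape:
        raise ValueError("classified and truth rasters must be congruent")
    t = truth.values
    c = classified.values
    valid = t >= 0
    if not valid.any():
        raise ValueError("truth raster has no valid pixels")
    return float(100.0 * np.mean(c[valid] == t[valid]))


def _component_perimeters(comp: np.ndarray, n: int, cell: float) -> np.ndarray:
    padded = np.pad(comp, 1, constant_values=0)
    per = np.zeros(n + 1, dtype=np.int64)
    for a, b in (
        (padded[:, :-1], padded[:, 1:]),
        (padded[:-1, :], padded[1:, :]),
    ):
        mask = a != b
        per += np.bincount(a[mask], minlength=n + 1)
        per += np.bincount(b[mask], minlength=n + 1)
    return per.astype(float) * cell


def extract_patches(class_raster: Raster, connectivity: int = 8) -> list[Patch]:
    """Connected components of same-class pixels across the whole map.

    ``connectivity`` 8 (the FRAGSTATS default) joins diagonal neighbors
    into one patch; 4 does not.  Perimeters always count exposed
    4-neighbor cell edges, including image borders.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    conn = 2 if connectivity == 8 else 1
    values = class_raster.values
    cell = class_raster.cell_size
    patches: list[Patch] = []
    for cls in np.unique(values):
        mask = values == cls
        comp = cc_label(mask, connectivity=conn)
        n = int(comp.max())
        areas = np.bincount(comp.ravel(), minlength=n + 1)[1:]
        pers = _component_perimeters(comp, n, cell)[1:]
        for a, p in zip(areas.tolist(), pers.tolist()):
            patches.append(
                Patch(class_id=int(cls), area=a * cell * cell, perimeter=p)
            )
    return patches


def landscape_metrics(patches: list[Patch]) -> LandscapeMetricsReport:
    """Landscape-level AM/SD summary of AREA, FRAC and PARA, plus NP."""
    if not patches:
        raise ValueError("at least one patch required")
    a = np.array([p.area for p in patches], dtype=float)
    per = np.array([p.perimeter for p in patches], dtype=float)
    w = a / a.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 2.0 * np.log(0.25 * per) / np.log(a)
    frac[np.log(a) <= 0] = 1.0
    para = per / a

    def am(x: np.ndarray) -> float:
        return float(np.sum(x * w))

    def sd(x: np.ndarray) -> float:
        return float(np.std(x))

    return LandscapeMetricsReport(
        NP=len(patches),
        AREA_AM=am(a),
        AREA_SD=sd(a),
        FRAC_AM=am(frac),
        FRAC_SD=sd(frac),
        PARA_AM=am(para),
        PARA_SD=sd(para),
    )
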