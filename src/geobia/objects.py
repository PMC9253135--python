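"""Per-object feature tables, label transfer, and the hierarchy attribute.

Each segment becomes one row: geometry statistics (area, perimeter,
compactness, elongation) plus mean and standard deviation of every
feature layer.  Training classes are transferred from a reference map by
majority pixel overlap; the hierarchical feature attaches the classified
super-object class to each sub-object the same way.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .raster import Raster
from .segmentation import SegmentMap

__all__ = [
    "compute_object_stats",
    "majority_overlap_label",
    "attach_super_class",
    "UNCLASSIFIED",
]

#: class code for segments with no valid reference coverage
UNCLASSIFIED = -1

GEOMETRY_FEATURES = ("area", "perimeter", "compactness", "elongation")


def _perimeters(labels: np.ndarray, n: int) -> np.ndarray:
    """Exposed pixel-edge count per label (index 0 unused).

    An edge is exposed when its neighbor lies outside the region or
    outside the image.
    """
    padded = np.pad(labels, 1, constant_values=0)
    per = np.zeros(n + 1, dtype=np.int64)
    for a, b in (
        (padded[:, :-1], padded[:, 1:]),
        (padded[:-1, :], padded[1:, :]),
    ):
        mask = a != b
        per += np.bincount(a[mask], minlength=n + 1)
        per += np.bincount(b[mask], minlength=n + 1)
    return per


def _elongations(labels: np.ndarray, n: int) -> np.ndarray:
    """Major/minor axis ratio of each region's pixel-coordinate covariance.

    A 1/12-pixel variance term (the variance of a unit pixel) regularizes
    degenerate regions, so a single pixel has elongation 1.
    """
    rows, cols = np.indices(labels.shape)
    flat = labels.ravel()
    r = rows.ravel().astype(float)
    c = cols.ravel().astype(float)
    cnt = np.bincount(flat, minlength=n + 1).astype(float)
    cnt[cnt == 0] = 1.0
    sr = np.bincount(flat, weights=r, minlength=n + 1) / cnt
    sc = np.bincount(flat, weights=c, minlength=n + 1) / cnt
    vrr = np.bincount(flat, weights=r * r, minlength=n + 1) / cnt - sr**2
    vcc = np.bincount(flat, weights=c * c, minlength=n + 1) / cnt - sc**2
    vrc = np.bincount(flat, weights=r * c, minlength=n + 1) / cnt - sr * sc
    vrr += 1.0 / 12.0
    vcc += 1.0 / 12.0
    tr = vrr + vcc
    det = vrr * vcc - vrc**2
    disc = np.sqrt(np.maximum(tr**2 / 4.0 - det, 0.0))
    lam1 = tr / 2.0 + disc
    lam2 = np.maximum(tr / 2.0 - disc, 1e-12)
    return np.sqrt(lam1 / lam2)


def compute_object_stats(
    segments: SegmentMap, layers: dict[str, Raster]
) -> pd.DataFrame:
    """One row per segment: geometry plus per-layer mean and sd.

    Columns are ordered deterministically: the geometry block first, then
    ``<layer>_mean``/``<layer>_sd`` in the order the layers are given.
    Standard deviations are population (ddof = 0) statistics.
    """
    labels = segments.labels
    n = segments.n_segments
    for name, layer in layers.items():
        if layer.shape != segments.shape:
            raise ValueError(f"layer {name!r} not congruent with segments")
    flat = labels.ravel()
    area = np.bincount(flat, minlength=n + 1)[1:]
    cell = segments.cell_size
    per = _perimeters(labels, n)[1:]
    area_u = area.astype(float) * cell * cell
    per_u = per.astype(float) * cell
    data: dict[str, np.ndarray] = {
        "area": area_u,
        "perimeter": per_u,
        "compactness": 4.0 * np.pi * area_u / per_u**2,
        "elongation": _elongations(labels, n)[1:],
    }
    cnt = area.astype(float)
    for name, layer in layers.items():
        vals = layer.values.ravel().astype(float)
        s1 = np.bincount(flat, weights=vals, minlength=n + 1)[1:]
        s2 = np.bincount(flat, weights=vals * vals, minlength=n + 1)[1:]
        mean = s1 / cnt
        var = np.maximum(s2 / cnt - mean**2, 0.0)
        data[f"{name}_mean"] = mean
        data[f"{name}_sd"] = np.sqrt(var)
    return pd.DataFrame(data, index=pd.RangeIndex(1, n + 1, name="label"))


def _majority_by_segment(
    labels: np.ndarray, reference: np.ndarray, n_segments: int
) -> np.ndarray:
    """Majority reference code per segment; ties go to the lowest code.

    Reference pixels with code < 0 count as nodata; a segment covered only
    by nodata maps to UNCLASSIFIED.
    """
    ref = reference.astype(np.int64)
    valid = ref >= 0
    n_classes = int(ref[valid].max()) + 1 if valid.any() else 0
    out = np.full(n_segments + 1, UNCLASSIFIED, dtype=np.int64)
    if n_classes == 0:
        return out
    enc = labels.astype(np.int64)[valid] * n_classes + ref[valid]
    counts = np.bincount(enc, minlength=(n_segments + 1) * n_classes)
    counts = counts.reshape(n_segments + 1, n_classes)
    covered = counts.sum(axis=1) > 0
    out[covered] = np.argmax(counts[covered], axis=1)  # argmax -> lowest index tie
    return out


def majority_overlap_label(segments: SegmentMap, reference: Raster) -> pd.Series:
    """Transfer the majority-overlap reference class to every segment."""
    if reference.shape != segments.shape:
        raise ValueError("reference raster not congruent with segments")
    maj = _majority_by_segment(
        segments.labels, reference.values, segments.n_segments
    )
    return pd.Series(
        maj[1:], index=pd.RangeIndex(1, segments.n_segments + 1, name="label"),
        name="training_class",
    )


def attach_super_class(
    sub_segments: SegmentMap,
    classified_super: Raster,
    table: pd.DataFrame,
    n_super_classes: int | None = None,
) -> pd.DataFrame:
    """Add the hierarchy attribute: majority-overlap super class per sub-object.

    ``classified_super`` is the rasterized super-object classification
    (integer class codes).  The returned table is a copy with one extra
    ``super_class`` column; dropping it reproduces the non-hierarchical
    feature set exactly.
    """
    if classified_super.shape != sub_segments.shape:
        raise ValueError("classified super raster not congruent with sub segments")
    codes = classified_super.values
    if n_super_classes is not None and codes.max() >= n_super_classes:
        raise ValueError("super classification uses codes outside the scheme")
    sup = majority_overlap_label(sub_segments, classified_super)
    out = table.copy()
    out["super_class"] = sup.reindex(out.index).astype("int64")
    return out
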