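"""Shared test utilities: independent oracles and toy-map builders."""

from __future__ import annotations

import numpy as np

from geobia.raster import Raster
from geobia.segmentation import SegmentMap


def greedy_merge_oracle(
    segments: SegmentMap, layers: list[Raster], merge_level: float
) -> list[tuple[int, int]]:
    """Brute-force full-lambda merge sequence.

    Re-derives areas, sums and boundary lengths from the evolving label
    image and rescans every adjacent pair at every step — no priority
    queue, no incremental statistics.  Ties break on the smaller (i, j).
    """
    labels = segments.labels.astype(np.int64).copy()
    arrays = [l.values.astype(float) for l in layers]
    if merge_level == 0:
        return []

    def pair_costs(lab: np.ndarray) -> dict[tuple[int, int], float]:
        pairs: dict[tuple[int, int], int] = {}
        for a, b in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
            mask = a != b
            for i, j in zip(a[mask].tolist(), b[mask].tolist()):
                key = (min(i, j), max(i, j))
                pairs[key] = pairs.get(key, 0) + 1
        costs = {}
        for (i, j), length in pairs.items():
            mi = np.array([arr[lab == i].mean() for arr in arrays])
            mj = np.array([arr[lab == j].mean() for arr in arrays])
            ai = float((lab == i).sum())
            aj = float((lab == j).sum())
            d = mi - mj
            costs[(i, j)] = (ai * aj / (ai + aj)) * float(d @ d) / length
        return costs

    initial = pair_costs(labels)
    if not initial:
        return []
    threshold = float(np.percentile(list(initial.values()), merge_level))
    sequence: list[tuple[int, int]] = []
    while True:
        costs = pair_costs(labels)
        if not costs:
            break
        (i, j), t = min(costs.items(), key=lambda kv: (kv[1], kv[0]))
        if t > threshold:
            break
        labels[labels == j] = i
        sequence.append((i, j))
    return sequence


def random_voronoi_partition(
    rng: np.random.Generator, size: int, n_seeds: int
) -> SegmentMap:
    """A small labeled partition from nearest-site assignment."""
    from scipy.spatial import cKDTree

    sites = rng.choice(size * size, size=n_seeds, replace=False)
    pts = np.stack([sites // size, sites % size], axis=1)
    rows, cols = np.mgrid[0:size, 0:size]
    grid = np.stack([rows.ravel(), cols.ravel()], axis=1)
    _, nearest = cKDTree(pts).query(grid)
    labels = (nearest + 1).reshape(size, size).astype(np.int32)
    # voronoi cells on a grid are connected; relabel to be safe
    from skimage.measure import label as cc_label

    comp = cc_label(labels, connectivity=1)
    return SegmentMap(comp.astype(np.int32))


def smooth_random_raster(rng: np.random.Generator, size: int) -> Raster:
    """Random surface with spatial structure (smoothed white noise)."""
    from scipy.ndimage import gaussian_filter

    return Raster(gaussian_filter(rng.standard_normal((size, size)), sigma=2.0))
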