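"""Brute-force reference implementations used as independent test oracles.

Each function here recomputes an operator by exhaustive per-pixel
enumeration, deliberately sharing no code with the package implementation.
They are O(pixels x footprint) and only meant for <= 64x64 fixtures.
"""
from __future__ import annotations

import numpy as np


def disc_footprint(radius: int) -> list[tuple[int, int]]:
    return [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]


def _order_filter(image: np.ndarray, radius: int, fn) -> np.ndarray:
    """Min/max over a disc footprint clipped at the image border."""
    h, w = image.shape
    fp = disc_footprint(radius)
    out = np.empty_like(image, dtype=float)
    for r in range(h):
        for c in range(w):
            vals = [
                image[r + dy, c + dx]
                for dy, dx in fp
                if 0 <= r + dy < h and 0 <= c + dx < w
            ]
            out[r, c] = fn(vals)
    return out


def grayscale_opening(image: np.ndarray, radius: int) -> np.ndarray:
    """Exhaustive min-then-max filtering with the exact disc."""
    eroded = _order_filter(np.asarray(image, dtype=float), radius, min)
    return _order_filter(eroded, radius, max)


def local_mean(image: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window mean with reflective borders, by direct summation."""
    pad = window // 2
    p = np.pad(np.asarray(image, dtype=float), pad, mode="reflect")
    h, w = image.shape
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            out[r, c] = p[r : r + window, c : c + window].sum() / (window * window)
    return out


def nearest_seed_dilation(nuclear: np.ndarray, radius: float) -> np.ndarray:
    """Exhaustive contested dilation: per pixel, scan every nucleus pixel.

    A pixel belongs to the label whose nucleus is nearest in Euclidean
    distance (ties to the lower label), provided that distance is within
    ``radius``. Distances are compared as sqrt of exact integer squares so
    ties are detected exactly.
    """
    nuclear = np.asarray(nuclear)
    h, w = nuclear.shape
    labels = sorted(set(np.unique(nuclear)) - {0})
    pix = {lab: np.argwhere(nuclear == lab) for lab in labels}
    out = np.zeros_like(nuclear)
    for r in range(h):
        for c in range(w):
            best_d2 = None
            best_lab = 0
            for lab in labels:  # ascending: ties keep the lower label
                pts = pix[lab]
                d2 = int(((pts[:, 0] - r) ** 2 + (pts[:, 1] - c) ** 2).min())
                if best_d2 is None or d2 < best_d2:
                    best_d2, best_lab = d2, lab
            if best_d2 is not None and np.sqrt(best_d2) <= radius:
                out[r, c] = best_lab
    return out


def upgma_heights(matrix: np.ndarray, method: str = "average") -> list[float]:
    """Agglomerative merge heights by naive full recomputation.

    Clusters are merged greedily at the smallest average (or single /
    complete) pairwise Euclidean distance, recomputed from cluster members
    at every step.
    """
    rows = [tuple(r) for r in np.asarray(matrix, dtype=float)]
    clusters: list[list[int]] = [[i] for i in range(len(rows))]

    def dist(a: list[int], b: list[int]) -> float:
        ds = [
            float(np.linalg.norm(np.array(rows[i]) - np.array(rows[j])))
            for i in a
            for j in b
        ]
        if method == "average":
            return sum(ds) / len(ds)
        if method == "single":
            return min(ds)
        return max(ds)

    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return heights
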