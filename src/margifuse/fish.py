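"""Single-molecule FISH spot detection and two-channel fusion calling.

Spots are connected components of pixels at or above an intensity
threshold, reduced to intensity-weighted centroids.  The working threshold
is not fixed but found by a robust-plateau scan: over a ladder of candidate
thresholds, the chosen one sits in the longest run of consecutive
thresholds that all yield the same spot count — the count there is
insensitive to the exact cutoff, which is what makes it trustworthy.

A fusion signal is a cross-channel colocalization: a mutual-nearest-
neighbour match between spot centers of the two channels within a radius,
each spot used at most once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

#: 8-connectivity structuring element for component labelling.
_STRUCTURE = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class ThresholdScan:
    """Diagnostics of the robust-threshold search."""

    thresholds: np.ndarray
    counts: np.ndarray
    chosen_threshold: float
    plateau_start: int
    plateau_length: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "n_spots": self.counts})


def default_thresholds(
    image: np.ndarray, n_thresholds: int = 100, percentile_range: tuple[float, float] = (50.0, 99.9)
) -> np.ndarray:
    """Evenly spaced candidate thresholds between two intensity percentiles."""
    lo, hi = np.percentile(image, percentile_range)
    return np.linspace(lo, hi, n_thresholds)


def count_spots_at(image: np.ndarray, threshold: float) -> tuple[np.ndarray, int]:
    """Label connected components of pixels >= threshold (8-connectivity)."""
    labels, n = ndimage.label(image >= threshold, structure=_STRUCTURE)
    return labels, int(n)


def _plateau(counts: np.ndarray) -> tuple[int, int]:
    """Longest run of identical consecutive counts; ties go to the lowest run."""
    best_start, best_len = 0, 1
    start = 0
    for i in range(1, len(counts)):
        if counts[i] != counts[start]:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = i
    if len(counts) - start > best_len:
        best_start, best_len = start, len(counts) - start
    return best_start, best_len


def detect_spots(
    image: np.ndarray,
    thresholds: np.ndarray | None = None,
    n_thresholds: int = 100,
    percentile_range: tuple[float, float] = (50.0, 99.9),
    channel: str = "",
) -> tuple[pd.DataFrame, ThresholdScan]:
    """Detect spots at the robust threshold of a plateau scan.

    Returns a spot table with sub-pixel intensity-weighted centroids
    (``x`` = column, ``y`` = row) and peak intensities, plus the scan
    diagnostics.  A flat image yields zero spots and a degenerate scan.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D single-channel image")
    empty = pd.DataFrame(columns=["x", "y", "peak_intensity", "channel"])
    if image.size == 0 or image.max() == image.min():
        scan = ThresholdScan(np.array([float(image.max()) if image.size else 0.0]),
                             np.array([0]), float(image.max()) if image.size else 0.0, 0, 1)
        return empty, scan
    if thresholds is None:
        thresholds = default_thresholds(image, n_thresholds, percentile_range)
    thresholds = np.asarray(thresholds, dtype=float)
    if len(thresholds) < 2:
        raise ValueError("need at least two candidate thresholds")

    counts = np.array([count_spots_at(image, t)[1] for t in thresholds])
    start, length = _plateau(counts)
    chosen_idx = start + (length - 1) // 2  # midpoint candidate of the run
    chosen = float(thresholds[chosen_idx])
    scan = ThresholdScan(thresholds, counts, chosen, start, length)

    labels, n = count_spots_at(image, chosen)
    if n == 0:
        return empty, scan
    idx = np.arange(1, n + 1)
    centroids = ndimage.center_of_mass(image, labels, idx)
    peaks = ndimage.maximum(image, labels, idx)
    spots = pd.DataFrame(
        {
            "x": [c[1] for c in centroids],
            "y": [c[0] for c in centroids],
            "peak_intensity": peaks,
            "channel": channel,
        }
    )
    return spots, scan


def call_fusions(
    spots_a: pd.DataFrame, spots_b: pd.DataFrame, radius_px: float = 2.0
) -> pd.DataFrame:
    """Match spots across channels by mutual nearest neighbours within a radius.

    Matching is one-to-one: in each round, pairs that are each other's
    nearest unmatched neighbour at distance <= ``radius_px`` are fixed,
    until no such pair remains.  Ties break on (distance, index) so the
    result is deterministic.  Returns a table of (index_a, index_b,
    distance_px); its length is the fusion-signal count.
    """
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    ax = spots_a[["x", "y"]].to_numpy(dtype=float)
    bx = spots_b[["x", "y"]].to_numpy(dtype=float)
    if len(ax) == 0 or len(bx) == 0:
        return pd.DataFrame(columns=["index_a", "index_b", "distance_px"])
    dist = np.sqrt(((ax[:, None, :] - bx[None, :, :]) ** 2).sum(axis=2))
    free_a = np.ones(len(ax), dtype=bool)
    free_b = np.ones(len(bx), dtype=bool)
    matches: list[tuple[int, int, float]] = []
    while True:
        sub = dist.copy()
        sub[~free_a, :] = np.inf
        sub[:, ~free_b] = np.inf
        nn_of_a = sub.argmin(axis=1)
        nn_of_b = sub.argmin(axis=0)
        added = False
        for i in np.flatnonzero(free_a):
            j = nn_of_a[i]
            if free_b[j] and nn_of_b[j] == i and dist[i, j] <= radius_px:
                matches.append((i, j, float(dist[i, j])))
                free_a[i] = False
                free_b[j] = False
                added = True
        if not added:
            break
    matches.sort()
    return pd.DataFrame(matches, columns=["index_a", "index_b", "distance_px"])


def count_per_cell(
    matches: pd.DataFrame, spots_a: pd.DataFrame, cell_mask: np.ndarray
) -> pd.Series:
    """Fusion-signal count per cell of a label mask (0 = outside any cell).

    Each match is assigned to the cell under the channel-A spot center.
    """
    mask = np.asarray(cell_mask)
    labels = []
    for i in matches["index_a"]:
        x, y = spots_a.iloc[int(i)][["x", "y"]]
        r = int(np.clip(round(y), 0, mask.shape[0] - 1))
        c = int(np.clip(round(x), 0, mask.shape[1] - 1))
        labels.append(int(mask[r, c]))
    counts = pd.Series(labels, dtype=int).value_counts().sort_index()
    counts = counts[counts.index != 0]
    counts.name = "n_fusion_signals"
    return counts
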