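"""Pairwise pixel synchrony: correlation matrices, distance curves, phases.

Network synchronization is quantified by the Pearson correlation of the
normalized per-pixel traces.  The correlation can be restricted to the
recording phases inside network-spike windows (IN phases) or outside them
(OUT phases); synchronized cultures show correlation driven almost entirely
by the IN phases.  Pixel coordinates give pairwise physical distances so
correlation can be resolved against distance across the well surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .movie_io import Trace, traces_to_matrix
from .network_analysis import NetworkWindows

__all__ = [
    "SynchronyResult",
    "pairwise_correlation",
    "correlation_vs_distance",
    "phase_masks",
    "cluster_order",
]


@dataclass
class SynchronyResult:
    """Pairwise Pearson correlation of pixel activity.

    ``matrix`` is (pixels x pixels) over the pixels that had nonzero variance
    in the analyzed (possibly phase-masked) segment; ``excluded`` lists the
    dropped zero-variance pixel indices (positions in the input list).
    """

    matrix: np.ndarray
    coords: np.ndarray          # (pixels, 2) tile-local (row, col)
    distances_um: np.ndarray    # (pixels, pixels)
    phase: str                  # full | in_phases | out_phases
    excluded: list[int]

    @property
    def mean_r(self) -> float:
        """Mean off-diagonal correlation (upper triangle)."""
        n = self.matrix.shape[0]
        if n < 2:
            return float("nan")
        iu = np.triu_indices(n, k=1)
        return float(self.matrix[iu].mean())


def pairwise_correlation(
    pixel_traces: list[Trace],
    phase_mask: np.ndarray | None = None,
    pixel_pitch_um: float = 284.0,
    phase: str = "full",
) -> SynchronyResult:
    """Pearson correlation across pixels, optionally restricted to a phase.

    ``phase_mask`` is a boolean frame mask (e.g. from :func:`phase_masks`).
    Pixels whose masked segment has zero variance are excluded from the
    matrix and reported.  Correlation is scale-invariant, so whether traces
    are normalized only affects which pixels are degenerate.
    """
    if len(pixel_traces) < 2:
        raise ValueError("need at least 2 pixel traces")
    mat = traces_to_matrix(pixel_traces)
    if phase_mask is not None:
        phase_mask = np.asarray(phase_mask, dtype=bool)
        if phase_mask.sum() < 10:
            raise ValueError("phase mask keeps fewer than 10 frames")
        mat = mat[:, phase_mask]
    sd = mat.std(axis=1)
    keep = sd > 0
    excluded = np.flatnonzero(~keep).tolist()
    if keep.sum() < 2:
        raise ValueError("fewer than 2 pixels with variance in the analyzed segment")
    coords = np.array(
        [pixel_traces[i].source for i in np.flatnonzero(keep)], dtype=float
    )
    r = np.corrcoef(mat[keep])
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    d = np.hypot(
        coords[:, 0][:, None] - coords[:, 0][None, :],
        coords[:, 1][:, None] - coords[:, 1][None, :],
    ) * pixel_pitch_um
    return SynchronyResult(matrix=r, coords=coords, distances_um=d, phase=phase, excluded=excluded)


def correlation_vs_distance(result: SynchronyResult, n_bins: int = 10) -> pd.DataFrame:
    """Bin pairwise r by distance; mean and 95% CI per bin.

    Returns columns bin_center_um, mean_r, ci_lo, ci_hi, n_pairs.
    """
    n = result.matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    r = result.matrix[iu]
    d = result.distances_um[iu]
    if d.size == 0:
        raise ValueError("no pixel pairs")
    if np.ptp(d) == 0:
        edges = np.array([d[0] - 0.5, d[0] + 0.5])
    else:
        edges = np.linspace(d.min(), d.max(), n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = r[idx == b]
        if sel.size == 0:
            continue
        m = sel.mean()
        if sel.size > 1:
            half = sel.std(ddof=1) / np.sqrt(sel.size) * stats.t.ppf(0.975, sel.size - 1)
        else:
            half = np.nan
        rows.append(
            ((edges[b] + edges[b + 1]) / 2.0, m, m - half, m + half, int(sel.size))
        )
    return pd.DataFrame(rows, columns=["bin_center_um", "mean_r", "ci_lo", "ci_hi", "n_pairs"])


def phase_masks(
    windows: NetworkWindows, n_frames: int, frame_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean frame masks for IN and OUT phases.

    A frame belongs to the IN phase when its midpoint time lies inside a
    (closed) network window.  The two masks partition the frames.
    """
    mid = (np.arange(n_frames) + 0.5) / frame_rate
    in_mask = windows.contains(mid)
    return in_mask, ~in_mask


def cluster_order(matrix: np.ndarray) -> np.ndarray:
    """Display permutation from average-linkage clustering on 1 - r.

    Deterministic: scipy's linkage on the condensed distance with ties
    broken by pixel index.  Single-pixel input returns the identity.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    n = matrix.shape[0]
    if n <= 1:
        return np.arange(n)
    dist = 1.0 - matrix
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return np.asarray(hierarchy.leaves_list(z))
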