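"""Pixel-resolution local-field analysis.

Treats every growth pixel of a well as a sensor for local calcium activity,
analogous to an electrode of a multi-electrode array.  On min-max
normalized per-pixel traces the same prominence-based detector used for
network spikes is applied (default threshold 0.4).  Each pixel spike is
classified *IN* if its peak falls inside a network-spike participation
window of the well-average trace, else *OUT*.

Additional tools: ranking pixels by activity to select the top-N "active
electrodes" (with a shoulder estimate of how many pixels are genuinely
active), a detection-threshold sweep (0.10..1.00, step 0.01) reporting the
retained spike fraction per class, and per-well summaries of frequency,
amplitude and FWHM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .movie_io import Trace
from .network_analysis import NetworkWindows, detect_spikes

__all__ = [
    "PixelRanking",
    "PixelSpikeTable",
    "ThresholdSweep",
    "rank_active_pixels",
    "detect_pixel_spikes",
    "classify_in_out",
    "threshold_sweep",
    "summarize_local_fields",
    "DEFAULT_PIXEL_THRESHOLD",
    "DEFAULT_TOP_N",
]

DEFAULT_PIXEL_THRESHOLD = 0.4
#: Active-pixel selection size per plate format (growth-area coverage).
DEFAULT_TOP_N = {96: 400, 384: 130}

SWEEP_THRESHOLDS = np.round(np.arange(0.10, 1.0 + 1e-9, 0.01), 2)

_NORM_TOL = 1e-9


def _check_normalized(traces: list[Trace]) -> None:
    for t in traces:
        if t.values.min() < -_NORM_TOL or t.values.max() > 1.0 + _NORM_TOL:
            raise ValueError(
                "pixel traces must be min-max normalized to [0, 1] "
                f"(pixel {t.source} spans [{t.values.min():.3g}, {t.values.max():.3g}])"
            )


@dataclass
class PixelRanking:
    """Pixels ordered by mean maximal fluorescence across their spikes."""

    order: np.ndarray          # permutation: order[0] = most active pixel index
    scores: np.ndarray         # per pixel (original indexing)
    selected: np.ndarray       # boolean, per pixel
    shoulder: int              # rank (1-based) at the drop-off of the rank-score curve
    degenerate: bool = False   # all pixels silent
    flagged_short: bool = False  # fewer pixels than requested N

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)


def _shoulder_rank(sorted_scores: np.ndarray) -> int:
    """Rank maximizing the distance to the chord of the rank-score curve.

    The chord runs from the first to the last point of the descending
    score-vs-rank curve; the knee/shoulder is the point farthest below it.
    """
    n = len(sorted_scores)
    if n < 3:
        return n
    x = np.arange(n, dtype=float)
    y = sorted_scores.astype(float)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    if norm == 0:
        return n
    # perpendicular distance of each point to the chord
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    return int(np.argmax(dist)) + 1


def rank_active_pixels(
    pixel_traces: list[Trace],
    base_threshold: float = DEFAULT_PIXEL_THRESHOLD,
    n_select: int = 400,
) -> PixelRanking:
    """Rank pixels by mean spike peak value and select the top N.

    A pixel's score is the mean of the trace values at its detected spike
    peaks ("mean maximum fluorescence across all spikes"); pixels with no
    spikes score 0.  Ties and the final ordering break deterministically by
    pixel index.
    """
    _check_normalized(pixel_traces)
    scores = np.zeros(len(pixel_traces))
    for i, tr in enumerate(pixel_traces):
        spikes = detect_spikes(tr, base_threshold)
        if len(spikes):
            scores[i] = np.mean([e.peak_value for e in spikes.events])
    order = np.argsort(-scores, kind="stable")
    flagged_short = n_select > len(pixel_traces)
    n_sel = min(n_select, len(pixel_traces))
    selected = np.zeros(len(pixel_traces), dtype=bool)
    selected[order[:n_sel]] = True
    degenerate = bool(np.all(scores == 0))
    return PixelRanking(
        order=order,
        scores=scores,
        selected=selected,
        shoulder=_shoulder_rank(scores[order]),
        degenerate=degenerate,
        flagged_short=flagged_short,
    )


@dataclass
class PixelSpikeTable:
    """Long-format table of per-pixel spike events.

    Columns: well, pixel_row, pixel_col, pixel_index, peak_time, peak_index,
    peak_value, prominence, fwhm, left_half_time, right_half_time, label.
    """

    df: pd.DataFrame
    duration: float
    frame_rate: float

    def __len__(self) -> int:
        return len(self.df)

    def counts(self) -> dict[str, int]:
        lab = self.df["label"]
        return {
            "IN": int((lab == "IN").sum()),
            "OUT": int((lab == "OUT").sum()),
            "all": len(self.df),
        }


_COLUMNS = [
    "well", "pixel_row", "pixel_col", "pixel_index", "peak_time", "peak_index",
    "peak_value", "prominence", "fwhm", "left_half_time", "right_half_time", "label",
]


def detect_pixel_spikes(
    pixel_traces: list[Trace],
    prominence_threshold: float = DEFAULT_PIXEL_THRESHOLD,
    well: str = "",
    pixel_indices: np.ndarray | None = None,
) -> PixelSpikeTable:
    """Detect spikes on each normalized pixel trace (unlabeled table)."""
    _check_normalized(pixel_traces)
    if not pixel_traces:
        raise ValueError("no pixel traces given")
    rows: list[tuple] = []
    for i, tr in enumerate(pixel_traces):
        idx = int(pixel_indices[i]) if pixel_indices is not None else i
        r, c = tr.source if isinstance(tr.source, tuple) else (-1, -1)
        for e in detect_spikes(tr, prominence_threshold).events:
            rows.append(
                (well, r, c, idx, e.peak_time, e.peak_index, e.peak_value,
                 e.prominence, e.fwhm, e.left_half_time, e.right_half_time, "unlabeled")
            )
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return PixelSpikeTable(
        df=df, duration=pixel_traces[0].duration, frame_rate=pixel_traces[0].frame_rate
    )


def classify_in_out(table: PixelSpikeTable, windows: NetworkWindows) -> PixelSpikeTable:
    """Label each pixel spike IN (peak inside a merged window, closed
    intervals) or OUT.  Classification uses peak time only, not spike extent."""
    df = table.df.copy()
    if len(df):
        inside = windows.contains(df["peak_time"].to_numpy())
        df["label"] = np.where(inside, "IN", "OUT")
    return PixelSpikeTable(df=df, duration=table.duration, frame_rate=table.frame_rate)


@dataclass
class ThresholdSweep:
    """Retained spike fraction vs detection threshold, per class.

    Fractions are relative to the counts at the lowest threshold (0.10, just
    above noise), which defines 100%.  ``undefined`` flags classes with zero
    spikes at the reference threshold.
    """

    thresholds: np.ndarray
    fractions: pd.DataFrame   # columns: threshold, class, n, fraction
    undefined: list[str]

    def curve(self, cls: str) -> np.ndarray:
        sel = self.fractions[self.fractions["class"] == cls].sort_values("threshold")
        return sel["fraction"].to_numpy()


def threshold_sweep(
    pixel_traces: list[Trace],
    windows: NetworkWindows,
    thresholds: np.ndarray = SWEEP_THRESHOLDS,
) -> ThresholdSweep:
    """Re-detect and classify spikes at each threshold; report fractions.

    Spikes are re-detected per threshold (not filtered from one detection)
    so the detector's own threshold dependence is measured.
    """
    _check_normalized(pixel_traces)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    counts = {cls: np.zeros(len(thresholds), dtype=int) for cls in ("IN", "OUT", "all")}
    for j, thr in enumerate(thresholds):
        table = classify_in_out(detect_pixel_spikes(pixel_traces, float(thr)), windows)
        c = table.counts()
        for cls in counts:
            counts[cls][j] = c[cls]
    undefined = [cls for cls in ("IN", "OUT", "all") if counts[cls][0] == 0]
    rows = []
    for cls, n in counts.items():
        ref = n[0]
        frac = n / ref if ref > 0 else np.full(len(thresholds), np.nan)
        for thr, nn, ff in zip(thresholds, n, frac):
            rows.append((float(thr), cls, int(nn), float(ff)))
    return ThresholdSweep(
        thresholds=thresholds,
        fractions=pd.DataFrame(rows, columns=["threshold", "class", "n", "fraction"]),
        undefined=undefined,
    )


def summarize_local_fields(
    table: PixelSpikeTable,
    n_pixels: int,
    duration: float | None = None,
) -> dict:
    """Per-well summary of local-field activity.

    ``mean_pixel_frequency`` averages per-pixel spike rates over all
    ``n_pixels`` selected pixels (silent pixels count as 0/min); amplitude
    and FWHM means are over spikes, overall and per IN/OUT class.
    """
    duration = duration if duration is not None else table.duration
    if duration <= 0 or n_pixels <= 0:
        raise ValueError("duration and n_pixels must be positive")
    df = table.df
    # mean over pixels of per-pixel rate == total spikes / n_pixels / duration
    mean_freq = len(df) / n_pixels / duration * 60.0

    def class_stats(sub: pd.DataFrame) -> dict:
        if len(sub) == 0:
            return {"n": 0, "mean_amplitude": float("nan"), "mean_fwhm": float("nan")}
        return {
            "n": len(sub),
            "mean_amplitude": float(sub["prominence"].mean()),
            "mean_fwhm": float(sub["fwhm"].mean()),
        }

    out = {
        "mean_pixel_frequency": float(mean_freq),
        "all": class_stats(df),
        "IN": class_stats(df[df["label"] == "IN"]),
        "OUT": class_stats(df[df["label"] == "OUT"]),
    }
    return out
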