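"""Well-resolution network-spike analysis.

Network spikes are synchronized calcium transients visible in the
well-average trace.  Detection uses topographic peak prominence: a local
maximum is a spike when its prominence (height above the highest contour
line enclosing no higher peak) exceeds a threshold.  Spike *amplitude* is
defined as the prominence, and FWHM is the width at half-prominence above
the contour base.

The plate-wide detection threshold is calibrated from the background signal
of empty wells at the plate edge.  Around each detected network spike a
participation window (half-max interval padded by one frame) is constructed;
pixel-resolution spikes falling inside these windows are later classified
as IN spikes, all others as OUT spikes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, signal, stats

from .movie_io import PlateLayout, PlateMovie, Trace, WellZoneMask

__all__ = [
    "SpikeEvent",
    "SpikeSet",
    "NetworkWindows",
    "DoseResponseFit",
    "DrugResponse",
    "detect_spikes",
    "global_threshold",
    "spike_frequency",
    "mean_spike_amplitude",
    "drug_response",
    "paired_drug_test",
    "fit_dose_response",
    "network_windows",
]

#: Minimum peak separation in frames; suppresses noise doublets riding on
#: the same transient.
MIN_PEAK_DISTANCE = 2

#: Floor added to the empty-well threshold so a zero-noise plate still has a
#: strictly positive threshold.
THRESHOLD_FLOOR = 1e-6

#: Seconds discarded after compound addition (dispense artifact).
DISPENSE_GUARD_S = 10.0


@dataclass(frozen=True)
class SpikeEvent:
    """One detected calcium spike.

    ``amplitude`` equals ``prominence``; both are kept so reports can name
    the quantity they mean.  Half-times are the interpolated crossings of the
    half-prominence level, so ``fwhm = right_half_time - left_half_time``.
    """

    peak_time: float
    peak_index: int
    peak_value: float
    prominence: float
    fwhm: float
    left_half_time: float
    right_half_time: float
    label: str = "unlabeled"

    @property
    def amplitude(self) -> float:
        return self.prominence


@dataclass
class SpikeSet:
    """Ordered spikes detected on one trace."""

    events: list[SpikeEvent]
    source: str | tuple[int, int]
    detection_threshold: float
    duration_analyzed: float
    frame_rate: float = 8.0

    def __len__(self) -> int:
        return len(self.events)

    @property
    def peak_times(self) -> np.ndarray:
        return np.array([e.peak_time for e in self.events])

    @property
    def prominences(self) -> np.ndarray:
        return np.array([e.prominence for e in self.events])

    def to_json(self, path) -> None:
        """Write the spike list (all event fields) as JSON."""
        import dataclasses
        import json
        from pathlib import Path

        data = {
            "source": str(self.source),
            "detection_threshold": self.detection_threshold,
            "duration_analyzed": self.duration_analyzed,
            "frame_rate": self.frame_rate,
            "events": [dataclasses.asdict(e) for e in self.events],
        }
        Path(path).write_text(json.dumps(data, indent=1))


@dataclass
class NetworkWindows:
    """Merged [start, end] intervals (s) around network spikes."""

    intervals: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=np.float64).reshape(-1, 2)

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask: which of ``times`` fall inside any window (closed)."""
        times = np.atleast_1d(np.asarray(times, dtype=np.float64))
        inside = np.zeros(len(times), dtype=bool)
        for lo, hi in self.intervals:
            inside |= (times >= lo) & (times <= hi)
        return inside


def detect_spikes(trace: Trace, threshold: float) -> SpikeSet:
    """Prominence-thresholded peak detection on one trace.

    Uses :func:`scipy.signal.find_peaks` with a minimum separation of
    ``MIN_PEAK_DISTANCE`` frames.  Plateau peaks are reported at the leftmost
    plateau sample.  FWHM is measured at half the prominence above the
    contour base with linear interpolation of the crossings.
    """
    x = np.asarray(trace.values, dtype=np.float64)
    if len(x) < 3:
        raise ValueError("trace too short for peak detection (need >= 3 samples)")
    peaks, props = signal.find_peaks(
        x, prominence=max(threshold, 0.0) or None, distance=MIN_PEAK_DISTANCE,
        plateau_size=1,
    )
    if threshold <= 0:
        # find_peaks(prominence=None) returns no prominences; recompute
        prom, lb, rb = signal.peak_prominences(x, peaks)
        props = dict(props)
        props["prominences"], props["left_bases"], props["right_bases"] = prom, lb, rb
    widths, _, left_ips, right_ips = signal.peak_widths(
        x, peaks, rel_height=0.5,
        prominence_data=(props["prominences"], props["left_bases"], props["right_bases"]),
    )
    fs = trace.frame_rate
    events = []
    for k, p in enumerate(peaks):
        idx = int(props["left_edges"][k]) if "left_edges" in props else int(p)
        events.append(
            SpikeEvent(
                peak_time=idx / fs,
                peak_index=idx,
                peak_value=float(x[p]),
                prominence=float(props["prominences"][k]),
                fwhm=float(widths[k] / fs),
                left_half_time=float(left_ips[k] / fs),
                right_half_time=float(right_ips[k] / fs),
            )
        )
    return SpikeSet(
        events=events,
        source=trace.source,
        detection_threshold=threshold,
        duration_analyzed=trace.duration,
        frame_rate=fs,
    )


def global_threshold(
    movie: PlateMovie,
    mask: WellZoneMask | None = None,
    layout: PlateLayout | None = None,
    n_sd: float = 3.0,
    safety_factor: float = 2.0,
) -> tuple[float, dict]:
    """Plate detection threshold from empty-well background.

    For each empty well the background trace is scanned for local maxima at
    zero threshold; the maximal prominence per well summarises its noise
    excursions.  The threshold is ``safety_factor * (mean + n_sd * SD)`` of
    those maxima (plus a small floor).  ``mean + n_sd*SD`` alone sits at the
    typical maximum excursion of an equivalent background trace, so roughly
    half of all culture wells would show one or two false events from their
    own background; the safety factor clears the whole extreme-value
    distribution plus background components dry wells cannot exhibit (e.g.
    un-synchronized local activity), while network spikes an order of
    magnitude above background still pass.

    When a zone mask is given, the empty-well trace averages the same growth
    pixels the analysis traces use (matching the noise reduction of the
    well-average); without one, or when masking an empty well is degenerate,
    the whole tile is averaged.
    """
    layout = layout or movie.layout
    if not layout.empty_wells:
        raise ValueError(
            "layout names no empty wells; pass an explicit detection threshold instead"
        )
    maxima = []
    per_well = {}
    for well in layout.empty_wells:
        tile = movie.well_tile(well)
        values = None
        if mask is not None and well in mask.labels:
            sel = mask.labels[well] == 2  # growth zone
            if sel.any():
                values = tile[:, sel].mean(axis=1)
        if values is None:
            values = tile.mean(axis=(1, 2))
        trace = Trace(values=values, frame_rate=movie.frame_rate, source=well)
        spikes = detect_spikes(trace, threshold=0.0)
        m = float(spikes.prominences.max()) if len(spikes) else 0.0
        maxima.append(m)
        per_well[well] = m
    maxima = np.asarray(maxima)
    threshold = (
        safety_factor * float(maxima.mean() + n_sd * maxima.std(ddof=0)) + THRESHOLD_FLOOR
    )
    stats_out = {
        "per_well_max_prominence": per_well,
        "mean": float(maxima.mean()),
        "sd": float(maxima.std(ddof=0)),
        "n_sd": n_sd,
        "safety_factor": safety_factor,
    }
    return threshold, stats_out


def spike_frequency(spikeset: SpikeSet) -> float:
    """Spikes per minute over the analyzed duration."""
    if spikeset.duration_analyzed <= 0:
        raise ValueError("duration_analyzed must be positive")
    return len(spikeset) / spikeset.duration_analyzed * 60.0


def mean_spike_amplitude(spikeset: SpikeSet) -> float:
    """Arithmetic mean of event prominences; NaN (undefined) for no events."""
    if len(spikeset) == 0:
        return float("nan")
    return float(spikeset.prominences.mean())


@dataclass
class DrugResponse:
    """Baseline vs post-addition activity of one well."""

    baseline: SpikeSet
    post: SpikeSet
    baseline_frequency: float
    post_frequency: float
    baseline_amplitude: float
    post_amplitude: float
    frequency_ratio: float
    amplitude_ratio: float
    post_window_short: bool


def drug_response(
    trace: Trace,
    addition_time: float,
    threshold: float,
    guard_s: float = DISPENSE_GUARD_S,
) -> DrugResponse:
    """Paired baseline/post metrics around an acute compound addition.

    Frequency and mean amplitude are computed separately on
    ``[0, addition_time)`` and ``[addition_time + guard_s, end)``; the guard
    interval skips the dispense artifact.
    """
    if not 0 < addition_time < trace.duration:
        raise ValueError("addition_time must fall inside the recording")
    fs = trace.frame_rate
    i_add = int(round(addition_time * fs))
    i_post = int(round((addition_time + guard_s) * fs))
    base = Trace(trace.values[:i_add], fs, trace.source, trace.normalization)
    post = Trace(trace.values[i_post:], fs, trace.source, trace.normalization)
    s_base = detect_spikes(base, threshold)
    s_post = detect_spikes(post, threshold)
    f_base, f_post = spike_frequency(s_base), spike_frequency(s_post)
    a_base, a_post = mean_spike_amplitude(s_base), mean_spike_amplitude(s_post)
    return DrugResponse(
        baseline=s_base,
        post=s_post,
        baseline_frequency=f_base,
        post_frequency=f_post,
        baseline_amplitude=a_base,
        post_amplitude=a_post,
        frequency_ratio=f_post / f_base if f_base > 0 else float("nan"),
        amplitude_ratio=a_post / a_base if a_base > 0 else float("nan"),
        post_window_short=post.duration < 60.0,
    )


def paired_drug_test(responses: list[DrugResponse], metric: str = "frequency") -> dict:
    """Paired t-test of post vs baseline across wells (within-well design)."""
    if metric == "frequency":
        pre = np.array([r.baseline_frequency for r in responses])
        post = np.array([r.post_frequency for r in responses])
    elif metric == "amplitude":
        pre = np.array([r.baseline_amplitude for r in responses])
        post = np.array([r.post_amplitude for r in responses])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    ok = np.isfinite(pre) & np.isfinite(post)
    if ok.sum() < 2:
        raise ValueError("need at least 2 wells with defined metrics")
    t, p = stats.ttest_rel(post[ok], pre[ok])
    return {"t": float(t), "p": float(p), "n": int(ok.sum()),
            "mean_baseline": float(pre[ok].mean()), "mean_post": float(post[ok].mean())}


@dataclass
class DoseResponseFit:
    """Four-parameter logistic (Hill) fit in log-dose."""

    top: float
    bottom: float
    ic50: float
    hill_slope: float
    residual_sse: float
    fitted: np.ndarray
    doses: np.ndarray
    responses: np.ndarray
    poor_fit: bool
    message: str = ""


def _hill(dose: np.ndarray, top: float, bottom: float, log_ic50: float, slope: float) -> np.ndarray:
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (1.0 + (dose / 10.0**log_ic50) ** slope)


def fit_dose_response(doses: np.ndarray, responses: np.ndarray) -> DoseResponseFit:
    """Least-squares 4-parameter logistic fit; IC50 in concentration units.

    Initialization: top/bottom from the data extremes, IC50 from the dose
    closest to half-response, slope 1.  Flat or non-monotone data are
    returned with ``poor_fit=True`` and residual diagnostics rather than a
    silent bogus IC50.
    """
    doses = np.asarray(doses, dtype=np.float64)
    responses = np.asarray(responses, dtype=np.float64)
    if np.unique(doses).size < 4:
        raise ValueError("need at least 4 distinct doses")
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")

    span = responses.max() - responses.min()
    if span <= 1e-12 * max(1.0, abs(responses).max()):
        return DoseResponseFit(
            top=float(responses.mean()), bottom=float(responses.mean()),
            ic50=float("nan"), hill_slope=float("nan"),
            residual_sse=0.0, fitted=np.full_like(responses, responses.mean()),
            doses=doses, responses=responses, poor_fit=True,
            message="flat response; IC50 undefined",
        )

    pos = doses[doses > 0]
    half = responses.min() + span / 2.0
    ic50_guess = pos[np.argmin(np.abs(responses[doses > 0] - half))] if pos.size else 1.0
    p0 = [responses.max(), responses.min(), np.log10(ic50_guess), 1.0]
    try:
        popt, _ = optimize.curve_fit(
            _hill, doses, responses, p0=p0, maxfev=20000,
            bounds=([-np.inf, -np.inf, -12, 0.05], [np.inf, np.inf, 12, 20]),
        )
    except RuntimeError as exc:
        return DoseResponseFit(
            top=float("nan"), bottom=float("nan"), ic50=float("nan"),
            hill_slope=float("nan"), residual_sse=float("nan"),
            fitted=np.full_like(responses, np.nan), doses=doses,
            responses=responses, poor_fit=True, message=f"fit failed: {exc}",
        )
    fitted = _hill(doses, *popt)
    sse = float(((responses - fitted) ** 2).sum())
    sst = float(((responses - responses.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    poor = r2 < 0.5
    return DoseResponseFit(
        top=float(popt[0]), bottom=float(popt[1]), ic50=float(10.0 ** popt[2]),
        hill_slope=float(popt[3]), residual_sse=sse, fitted=fitted,
        doses=doses, responses=responses, poor_fit=poor,
        message="" if not poor else f"poor fit (R2={r2:.3f})",
    )


def network_windows(spikeset: SpikeSet, pad: float | None = None) -> NetworkWindows:
    """Participation windows: half-max intervals padded by ``pad`` seconds
    (default one frame period) and merged where they overlap."""
    if pad is None:
        pad = 1.0 / spikeset.frame_rate
    raw = sorted(
        (e.left_half_time - pad, e.right_half_time + pad) for e in spikeset.events
    )
    merged: list[list[float]] = []
    for lo, hi in raw:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return NetworkWindows(intervals=np.asarray(merged).reshape(-1, 2))
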