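"""Synthetic plate-movie generator with recoverable ground truth.

Emulates a fluorescence plate reader recording spontaneous calcium activity
of neuron–astrocyte cocultures in multi-well plates.  Each well tile has a
bright border ring, a darker growth disc carrying the cells, and a dim
outside background.  Two kinds of calcium transients are superposed on the
growth pixels:

* **network events** — plate-wide synchronized spikes; at each event every
  growth pixel participates independently with ``participation_prob``;
* **OUT events** — independent per-pixel local transients, modelling
  cell-autonomous activity uncoupled from the network.

Transients use a difference-of-exponentials kernel normalized to unit peak
(fast-rise, sub-second-decay indicator kinetics, GCaMP6f-like), overlapping
transients sum linearly, and Gaussian read noise is added.  Acute compound
addition scales event rate and amplitude from a configured time onward, and
a Hill dose term scales the network rate for dose–response studies.

Every injected event is recorded in a :class:`GroundTruth` so downstream
detection, classification and synchrony analyses can be validated against a
known answer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .movie_io import (
    ZONE_BORDER,
    ZONE_GROWTH,
    ZONE_OUTSIDE,
    PlateLayout,
    PlateMovie,
    WellZoneMask,
    save_movie,
    well_name,
)

__all__ = [
    "SimConfig",
    "WellSimSpec",
    "GroundTruth",
    "SimConfigError",
    "simulate_plate",
    "simulate_dose_series",
    "hill_scale",
    "transient_kernel",
    "geometry_zone_labels",
]

PLATE_GRIDS = {96: (8, 12), 384: (16, 24)}
# Growth-disc / border-ring radii chosen so the growth zone covers ~400
# pixels in 96-well tiles and ~130 in 384-well tiles (the virtual-MEA
# electrode counts the pixel analysis is designed around).
DEFAULT_TILE = {96: (28, 28), 384: (18, 18)}
DEFAULT_RADII = {96: (11.4, 13.0), 384: (6.5, 8.0)}


class SimConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


def hill_scale(dose: float, top: float, bottom: float, ic50: float, slope: float) -> float:
    """Four-parameter Hill response at ``dose``; ``dose == 0`` returns ``top``."""
    if ic50 <= 0:
        raise SimConfigError("hill_params: ic50 must be positive")
    if dose < 0:
        raise SimConfigError("dose must be non-negative")
    if dose == 0:
        return float(top)
    return float(bottom + (top - bottom) / (1.0 + (dose / ic50) ** slope))


def transient_kernel(t: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Difference-of-exponentials calcium transient, unit peak, zero for t<0."""
    if rise_tau <= 0 or decay_tau <= 0:
        raise SimConfigError("kernel taus must be positive")
    if rise_tau >= decay_tau:
        raise SimConfigError("kernel_rise_tau must be smaller than kernel_decay_tau")
    t = np.asarray(t, dtype=np.float64)
    raw = np.zeros_like(t)
    pos = t >= 0
    raw[pos] = np.exp(-t[pos] / decay_tau) - np.exp(-t[pos] / rise_tau)
    # analytic peak location/height of the difference of exponentials
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    return raw / peak


@dataclass
class WellSimSpec:
    """Activity parameters of one simulated well.

    Rates are per minute; amplitudes are in arbitrary fluorescence units on
    top of the growth-zone baseline and are drawn lognormally (strictly
    positive, right-skewed) with the stated mean and coefficient of
    variation.  ``drug_*`` fields model an acute compound addition;
    ``dose``/``hill_params`` apply a Hill scale to the network rate.
    """

    network_rate: float = 3.3
    participation_prob: float = 0.9
    in_amplitude_mean: float = 60.0
    in_amplitude_cv: float = 0.1
    out_rate_per_pixel: float = 2.6
    out_amplitude_mean: float = 55.0
    out_amplitude_cv: float = 0.15
    kernel_rise_tau: float = 0.1
    kernel_decay_tau: float = 0.6
    jitter_sd: float = 0.05
    refractory_s: float = 1.25
    drug_time: float | None = None
    drug_frequency_scale: float = 1.0
    drug_amplitude_scale: float = 1.0
    dose: float | None = None
    hill_params: tuple[float, float, float, float] | None = None  # top, bottom, ic50, slope

    def validate(self) -> None:
        if not 0.0 <= self.participation_prob <= 1.0:
            raise SimConfigError("participation_prob must lie in [0, 1]")
        for name in ("network_rate", "out_rate_per_pixel"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be non-negative")
        for name in ("in_amplitude_mean", "out_amplitude_mean"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        if self.kernel_rise_tau <= 0 or self.kernel_decay_tau <= 0:
            raise SimConfigError("kernel taus must be positive")
        if self.jitter_sd < 0:
            raise SimConfigError("jitter_sd must be non-negative")
        if self.refractory_s < 0:
            raise SimConfigError("refractory_s must be non-negative")
        if self.drug_time is not None and self.drug_time < 0:
            raise SimConfigError("drug_time must be non-negative")


@dataclass
class SimConfig:
    """Plate-level simulation settings.

    ``wells`` maps well ids (``"A1"`` style) to :class:`WellSimSpec`; wells
    not listed (and wells in ``empty_wells``) contain only the zone baseline
    plus noise.  ``plate_rows``/``plate_cols`` may shrink the grid below the
    nominal plate format so small test movies stay small.
    """

    plate_format: int = 96
    wells: dict[str, WellSimSpec] = field(default_factory=dict)
    frame_rate: float = 8.0
    duration: float = 300.0
    tile_shape: tuple[int, int] | None = None
    zone_brightness: tuple[float, float, float] = (10.0, 60.0, 100.0)  # outside, border, growth
    noise_sd: float = 2.0
    common_noise_sd: float = 1.0
    rng_seed: int = 0
    plate_rows: int | None = None
    plate_cols: int | None = None
    empty_wells: list[str] = field(default_factory=list)
    growth_radius: float | None = None
    border_radius: float | None = None

    def __post_init__(self) -> None:
        if self.plate_format not in PLATE_GRIDS:
            raise SimConfigError("plate_format must be 96 or 384")
        if self.tile_shape is None:
            self.tile_shape = DEFAULT_TILE[self.plate_format]
        self.tile_shape = tuple(self.tile_shape)
        if self.growth_radius is None:
            self.growth_radius = DEFAULT_RADII[self.plate_format][0]
        if self.border_radius is None:
            self.border_radius = DEFAULT_RADII[self.plate_format][1]
        rows, cols = PLATE_GRIDS[self.plate_format]
        if self.plate_rows is None:
            self.plate_rows = rows
        if self.plate_cols is None:
            self.plate_cols = cols
        if self.duration * self.frame_rate < 2:
            raise SimConfigError("duration x frame_rate must cover at least 2 frames")
        if min(self.tile_shape) < 4:
            raise SimConfigError("tile_shape dimensions must be at least 4x4")
        if self.noise_sd < 0:
            raise SimConfigError("noise_sd must be non-negative")
        if self.common_noise_sd < 0:
            raise SimConfigError("common_noise_sd must be non-negative")
        out, border, growth = self.zone_brightness
        if not (out < border and out < growth):
            raise SimConfigError(
                "zone_brightness: outside must be dimmer than border and growth"
            )
        for w, spec in self.wells.items():
            spec.validate()
            if w in self.empty_wells:
                raise SimConfigError(f"well {w} is listed both as active and empty")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def layout(self) -> PlateLayout:
        return PlateLayout(
            n_rows=self.plate_rows,
            n_cols=self.plate_cols,
            tile_shape=self.tile_shape,
            empty_wells=list(self.empty_wells),
        )

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["wells"] = {w: dataclasses.asdict(s) for w, s in self.wells.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["wells"] = {
            w: WellSimSpec(**{**s, "hill_params": tuple(s["hill_params"]) if s.get("hill_params") else None})
            for w, s in (data.get("wells") or {}).items()
        }
        for key in ("tile_shape", "zone_brightness"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruth:
    """Injected events and parameters, per well.

    ``network_times[w]`` — event times (s); ``participation[w]`` — per event,
    the indices (into the growth-pixel list) of pixels that fired;
    ``in_amplitudes[w]`` — matching drawn amplitudes; ``out_times[w]`` /
    ``out_amplitudes[w]`` — per growth pixel, local-event times/amplitudes;
    ``growth_coords[w]`` — tile-local (row, col) of the growth pixels, in the
    same row-major order the analysis modules use.
    """

    network_times: dict[str, np.ndarray]
    participation: dict[str, list[np.ndarray]]
    in_amplitudes: dict[str, list[np.ndarray]]
    out_times: dict[str, list[np.ndarray]]
    out_amplitudes: dict[str, list[np.ndarray]]
    growth_coords: dict[str, np.ndarray]
    frequency_scale: dict[str, float]
    amplitude_scale: dict[str, float]

    def n_network_events(self, well: str) -> int:
        return len(self.network_times[well])

    def n_events_injected(self, well: str) -> int:
        n_in = sum(len(p) for p in self.participation[well])
        n_out = sum(len(t) for t in self.out_times[well])
        return n_in + n_out

    def pixel_in_times(self, well: str, pixel: int) -> np.ndarray:
        """Network-event times in which ``pixel`` participated."""
        times = [
            t
            for t, part in zip(self.network_times[well], self.participation[well])
            if pixel in part
        ]
        return np.asarray(times)

    def to_json(self, path: str | Path) -> None:
        def conv(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [conv(v) for v in obj]
            return obj

        Path(path).write_text(json.dumps(conv(dataclasses.asdict(self)), indent=1))


def geometry_zone_labels(
    tile_shape: tuple[int, int], growth_radius: float, border_radius: float
) -> np.ndarray:
    """Ground-truth zone labels: concentric growth disc and border ring."""
    ty, tx = tile_shape
    cy, cx = (ty - 1) / 2.0, (tx - 1) / 2.0
    yy, xx = np.mgrid[0:ty, 0:tx]
    d = np.hypot(yy - cy, xx - cx)
    lab = np.full(tile_shape, ZONE_OUTSIDE, dtype=int)
    lab[d <= border_radius] = ZONE_BORDER
    lab[d <= growth_radius] = ZONE_GROWTH
    return lab


def true_zone_mask(config: SimConfig) -> WellZoneMask:
    """The simulator's own zone mask (the answer brightness clustering should find)."""
    lab = geometry_zone_labels(config.tile_shape, config.growth_radius, config.border_radius)
    layout = config.layout()
    return WellZoneMask(labels={w: lab.copy() for w in layout.well_ids()}, layout=layout)


def _poisson_times(rng: np.random.Generator, rate_per_s: float, t0: float, t1: float) -> np.ndarray:
    """Homogeneous Poisson event times on [t0, t1)."""
    if rate_per_s <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate_per_s * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    if cv <= 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _add_transient(
    out: np.ndarray,
    frame_times: np.ndarray,
    t_event: float,
    amplitude: float,
    rise_tau: float,
    decay_tau: float,
) -> None:
    """Accumulate one kernel transient into a single-pixel trace, in place."""
    cutoff = 12.0 * decay_tau + 3.0 * rise_tau
    fs = 1.0 / (frame_times[1] - frame_times[0]) if len(frame_times) > 1 else 1.0
    i0 = max(0, int(np.ceil((t_event - frame_times[0]) * fs)))
    i1 = min(len(frame_times), int(np.ceil((t_event + cutoff - frame_times[0]) * fs)) + 1)
    if i0 >= i1:
        return
    out[i0:i1] += amplitude * transient_kernel(
        frame_times[i0:i1] - t_event, rise_tau, decay_tau
    )


def _simulate_well(
    spec: WellSimSpec,
    config: SimConfig,
    rng: np.random.Generator,
    growth_coords: np.ndarray,
    frame_times: np.ndarray,
) -> tuple[np.ndarray, dict]:
    """Simulate one well's growth-pixel signal matrix (pixels, time) and truth."""
    npix = growth_coords.shape[0]
    T = config.duration

    freq_scale = 1.0
    if spec.hill_params is not None and spec.dose is not None:
        freq_scale = hill_scale(spec.dose, *spec.hill_params)
    base_rate = spec.network_rate / 60.0 * freq_scale

    # network event times, with the post-addition rate scaled by the drug
    if spec.drug_time is not None and spec.drug_time < T:
        times = np.concatenate(
            [
                _poisson_times(rng, base_rate, 0.0, spec.drug_time),
                _poisson_times(rng, base_rate * spec.drug_frequency_scale, spec.drug_time, T),
            ]
        )
    else:
        times = _poisson_times(rng, base_rate, 0.0, T)
    if spec.refractory_s > 0 and len(times) > 1:
        # network bursts cannot follow each other arbitrarily closely
        # (synaptic depression); thin events inside the refractory period
        kept = [times[0]]
        for tt in times[1:]:
            if tt - kept[-1] >= spec.refractory_s:
                kept.append(tt)
        times = np.asarray(kept)

    signal = np.zeros((npix, len(frame_times)))
    participation: list[np.ndarray] = []
    in_amps: list[np.ndarray] = []
    for t_evt in times:
        part = np.flatnonzero(rng.random(npix) < spec.participation_prob)
        amp_mean = spec.in_amplitude_mean
        if spec.drug_time is not None and t_evt >= spec.drug_time:
            amp_mean *= spec.drug_amplitude_scale
        amps = _lognormal(rng, amp_mean, spec.in_amplitude_cv, len(part))
        jit = rng.normal(0.0, spec.jitter_sd, len(part)) if spec.jitter_sd > 0 else np.zeros(len(part))
        for p, a, j in zip(part, amps, jit):
            _add_transient(
                signal[p], frame_times, t_evt + j, a, spec.kernel_rise_tau, spec.kernel_decay_tau
            )
        participation.append(part)
        in_amps.append(amps)

    out_times: list[np.ndarray] = []
    out_amps: list[np.ndarray] = []
    for p in range(npix):
        ts = _poisson_times(rng, spec.out_rate_per_pixel / 60.0, 0.0, T)
        amps = _lognormal(rng, spec.out_amplitude_mean, spec.out_amplitude_cv, len(ts))
        for t_evt, a in zip(ts, amps):
            _add_transient(
                signal[p], frame_times, t_evt, a, spec.kernel_rise_tau, spec.kernel_decay_tau
            )
        out_times.append(ts)
        out_amps.append(amps)

    truth = {
        "network_times": times,
        "participation": participation,
        "in_amplitudes": in_amps,
        "out_times": out_times,
        "out_amplitudes": out_amps,
        "frequency_scale": freq_scale,
        "amplitude_scale": spec.drug_amplitude_scale if spec.drug_time is not None else 1.0,
    }
    return signal, truth


def simulate_plate(config: SimConfig) -> tuple[PlateMovie, GroundTruth]:
    """Render the configured plate movie and its ground truth.

    Deterministic: the same config and seed give a bit-identical movie.  Each
    well consumes an independent RNG substream derived from
    ``(rng_seed, well_index)`` so per-well results do not depend on which
    other wells are simulated.
    """
    layout = config.layout()
    n_frames = config.n_frames
    frame_times = np.arange(n_frames) / config.frame_rate
    H, W = layout.frame_shape
    out_b, border_b, growth_b = config.zone_brightness

    zone_lab = geometry_zone_labels(config.tile_shape, config.growth_radius, config.border_radius)
    baseline_tile = np.choose(zone_lab, [out_b, border_b, growth_b]).astype(np.float64)
    rr, cc = np.nonzero(zone_lab == ZONE_GROWTH)
    growth_coords = np.column_stack([rr, cc])

    frames = np.empty((n_frames, H, W), dtype=np.float64)
    truth = GroundTruth(
        network_times={}, participation={}, in_amplitudes={}, out_times={},
        out_amplitudes={}, growth_coords={}, frequency_scale={}, amplitude_scale={},
    )

    for well_idx, (well, (r0, c0, r1, c1)) in enumerate(layout.iter_wells()):
        rng = np.random.default_rng([config.rng_seed, well_idx])
        tile = np.broadcast_to(baseline_tile, (n_frames, *config.tile_shape)).copy()
        spec = config.wells.get(well)
        if spec is not None and well not in config.empty_wells:
            signal, well_truth = _simulate_well(spec, config, rng, growth_coords, frame_times)
            tile[:, rr, cc] += signal.T
            truth.network_times[well] = well_truth["network_times"]
            truth.participation[well] = well_truth["participation"]
            truth.in_amplitudes[well] = well_truth["in_amplitudes"]
            truth.out_times[well] = well_truth["out_times"]
            truth.out_amplitudes[well] = well_truth["out_amplitudes"]
            truth.growth_coords[well] = growth_coords
            truth.frequency_scale[well] = well_truth["frequency_scale"]
            truth.amplitude_scale[well] = well_truth["amplitude_scale"]
        if config.common_noise_sd > 0:
            # illumination flicker: shared across the tile, does not average
            # away in the well mean (what empty wells actually calibrate)
            tile = tile + rng.normal(0.0, config.common_noise_sd, size=n_frames)[:, None, None]
        if config.noise_sd > 0:
            tile = tile + rng.normal(0.0, config.noise_sd, size=tile.shape)
        frames[:, r0:r1, c0:c1] = tile

    np.clip(frames, 0.0, None, out=frames)  # camera counts cannot go negative
    movie = PlateMovie(frames=frames, frame_rate=config.frame_rate, layout=layout)
    return movie, truth


def simulate_dose_series(base: WellSimSpec, doses: list[float]) -> list[WellSimSpec]:
    """Well specs for a dose series: network rate Hill-scaled per dose."""
    if base.hill_params is None:
        raise SimConfigError("hill_params: base spec must define (top, bottom, ic50, slope)")
    top, bottom, ic50, slope = base.hill_params
    if ic50 <= 0:
        raise SimConfigError("hill_params: ic50 must be positive")
    specs = []
    for dose in doses:
        if dose < 0:
            raise SimConfigError("dose must be non-negative")
        spec = dataclasses.replace(
            base,
            dose=dose,
            hill_params=None,
            network_rate=base.network_rate * hill_scale(dose, top, bottom, ic50, slope),
        )
        specs.append(spec)
    return specs


def write_simulation(
    config: SimConfig,
    out_dir: str | Path,
    movie_format: str = "tif",
) -> tuple[Path, Path, Path]:
    """Simulate and write movie + ground-truth JSON + config YAML to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    movie, truth = simulate_plate(config)
    movie_path = out_dir / f"movie.{movie_format}"
    save_movie(movie, movie_path)
    truth_path = out_dir / "ground_truth.json"
    truth.to_json(truth_path)
    config_path = out_dir / "sim_config.yaml"
    config.to_yaml(config_path)
    return movie_path, truth_path, config_path
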