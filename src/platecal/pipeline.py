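"""End-to-end pipeline: simulate/load -> mask -> well -> pixel -> synchrony -> report.

RunConfig holds every tunable the stages need (detection thresholds, sweep
grid, top-N policy, addition time, seeds, output formats) so a run is fully
described by one YAML file and reproducible from it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import movie_io, network_analysis as net, pixel_fields as pix, synchrony as syn
from .movie_io import PlateLayout, traces_to_matrix
from .stats_report import render_report
from .synthetic_plate import SimConfig, simulate_plate

__all__ = ["RunConfig", "run_pipeline", "analyze_well"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    movie_path: str | None = None          # None -> simulate from sim_config
    layout_path: str | None = None
    sim_config_path: str | None = None
    out_dir: str = "platecal_run"
    network_threshold: str | float = "auto"  # "auto" = empty-well calibration
    pixel_prominence: float = 0.4
    sweep_floor: float = 0.1
    sweep_step: float = 0.01
    top_n: int | str = "auto"              # "auto" = per plate format
    addition_time: float | None = None
    frame_rate: float | None = None        # required for TIFF movies
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.pixel_prominence <= 1):
            raise ValueError("pixel_prominence must lie in (0, 1]")
        if not (0 < self.sweep_floor < 1):
            raise ValueError("sweep_floor must lie in (0, 1)")
        if self.sweep_step <= 0:
            raise ValueError("sweep_step must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def analyze_well(
    movie: movie_io.PlateMovie,
    mask: movie_io.WellZoneMask,
    well: str,
    network_threshold: float,
    pixel_prominence: float = 0.4,
    top_n: int = 400,
    sweep: bool = True,
    sweep_thresholds=None,
) -> dict:
    """All per-well stages for one well; returns a dict of stage results."""
    well_trace = movie_io.extract_well_trace(movie, mask, well)
    net_spikes = net.detect_spikes(well_trace, network_threshold)
    windows = net.network_windows(net_spikes)
    traces = movie_io.extract_pixel_traces(movie, mask, well, normalization="minmax")
    ranking = pix.rank_active_pixels(traces, pixel_prominence, top_n)
    sel = ranking.selected_indices
    sel_traces = [traces[i] for i in sel]
    table = pix.classify_in_out(
        pix.detect_pixel_spikes(sel_traces, pixel_prominence, well=well, pixel_indices=sel),
        windows,
    )
    summary = pix.summarize_local_fields(table, n_pixels=len(sel_traces))
    result = {
        "well_trace": well_trace,
        "network_spikes": net_spikes,
        "network_frequency": net.spike_frequency(net_spikes),
        "network_amplitude": net.mean_spike_amplitude(net_spikes),
        "windows": windows,
        "ranking": ranking,
        "spike_table": table,
        "pixel_summary": summary,
        "pixel_traces": sel_traces,
    }
    if sweep:
        if sweep_thresholds is None:
            sweep_thresholds = pix.SWEEP_THRESHOLDS
        result["sweep"] = pix.threshold_sweep(sel_traces, windows, sweep_thresholds)
    corr = syn.pairwise_correlation(
        sel_traces, pixel_pitch_um=movie.layout.pixel_pitch_um
    )
    result["correlation"] = corr
    result["distance_curve"] = syn.correlation_vs_distance(corr)
    in_mask, out_mask = syn.phase_masks(windows, movie.n_frames, movie.frame_rate)
    for name, m in (("in_phases", in_mask), ("out_phases", out_mask)):
        try:
            result[f"correlation_{name}"] = syn.pairwise_correlation(
                sel_traces, phase_mask=m, pixel_pitch_um=movie.layout.pixel_pitch_um,
                phase=name,
            )
        except ValueError:
            result[f"correlation_{name}"] = None
    return result


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and write the report; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.movie_path is None:
        if config.sim_config_path is None:
            raise ValueError("run_pipeline needs either movie_path or sim_config_path")
        sim = SimConfig.from_yaml(config.sim_config_path)
        sim.rng_seed = config.seed
        movie, _truth = simulate_plate(sim)
        layout = movie.layout
    else:
        if config.layout_path is None:
            raise ValueError("layout_path is required when loading a movie file")
        if not Path(config.layout_path).exists():
            raise FileNotFoundError(f"layout file not found: {config.layout_path}")
        layout = PlateLayout.from_yaml(config.layout_path)
        movie = movie_io.load_movie(config.movie_path, layout, frame_rate=config.frame_rate)

    mask = movie_io.build_zone_mask(movie, layout)

    if config.network_threshold == "auto":
        threshold, _stats = net.global_threshold(movie, mask, layout)
    else:
        threshold = float(config.network_threshold)

    n_wells_total = {(8, 12): 96, (16, 24): 384}.get((layout.n_rows, layout.n_cols))
    if config.top_n == "auto":
        top_n = pix.DEFAULT_TOP_N.get(n_wells_total or 96, 400)
    else:
        top_n = int(config.top_n)

    active_wells = [w for w in layout.well_ids() if w not in layout.empty_wells]
    well_rows, pixel_rows, sweep_frames = [], [], []
    first_result = None
    for well in active_wells:
        if mask.growth_pixel_count.get(well, 0) == 0:
            continue
        grid = np.round(
            np.arange(config.sweep_floor, 1.0 + 1e-9, config.sweep_step), 6
        )
        res = analyze_well(
            movie, mask, well, threshold, config.pixel_prominence, top_n,
            sweep_thresholds=grid,
        )
        if first_result is None:
            first_result = res
        spikes = res["network_spikes"]
        well_rows.append(
            {
                "well": well,
                "n_spikes": len(spikes),
                "freq_per_min": res["network_frequency"],
                "mean_amplitude": res["network_amplitude"],
                "mean_fwhm": float(pd.Series([e.fwhm for e in spikes.events]).mean())
                if len(spikes) else float("nan"),
            }
        )
        s = res["pixel_summary"]
        pixel_rows.append(
            {
                "well": well,
                "mean_pixel_frequency": s["mean_pixel_frequency"],
                "mean_amplitude_all": s["all"]["mean_amplitude"],
                "mean_amplitude_in": s["IN"]["mean_amplitude"],
                "mean_amplitude_out": s["OUT"]["mean_amplitude"],
                "mean_fwhm_in": s["IN"]["mean_fwhm"],
                "mean_fwhm_out": s["OUT"]["mean_fwhm"],
                "mean_r": res["correlation"].mean_r,
            }
        )
        sw = res["sweep"].fractions.copy()
        sw.insert(0, "well", well)
        sweep_frames.append(sw)

    results = {
        "well_summary": pd.DataFrame(well_rows),
        "pixel_summary": pd.DataFrame(pixel_rows),
        "sweep": pd.concat(sweep_frames, ignore_index=True) if sweep_frames else None,
        "distance_curve": first_result["distance_curve"] if first_result else None,
        "heatmap": traces_to_matrix(first_result["pixel_traces"]) if first_result else None,
        "parameters": {
            "network_threshold": threshold,
            "pixel_prominence": config.pixel_prominence,
            "top_n": top_n,
            "seed": config.seed,
        },
    }
    render_report(results, out, seed=config.seed)
    return out
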