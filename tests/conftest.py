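import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from platecal import movie_io
from platecal import network_analysis as net
from platecal import pixel_fields as pix
from platecal.synthetic_plate import SimConfig, WellSimSpec, simulate_plate


def small_config(**kwargs) -> SimConfig:
    """1 active + 1 empty well, 5 min at 8 fps — the standard test plate."""
    defaults = dict(
        plate_rows=1,
        plate_cols=2,
        duration=300.0,
        wells={"A1": WellSimSpec()},
        empty_wells=["A2"],
        rng_seed=7,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def sim_plate():
    """Simulated standard plate with its ground truth."""
    config = small_config()
    movie, truth = simulate_plate(config)
    return config, movie, truth


@pytest.fixture(scope="session")
def analyzed(sim_plate):
    """Full single-well analysis of the standard plate, computed once."""
    config, movie, truth = sim_plate
    mask = movie_io.build_zone_mask(movie)
    threshold, thr_stats = net.global_threshold(movie, mask)
    well_trace = movie_io.extract_well_trace(movie, mask, "A1")
    spikes = net.detect_spikes(well_trace, threshold)
    windows = net.network_windows(spikes)
    traces = movie_io.extract_pixel_traces(movie, mask, "A1", normalization="minmax")
    table = pix.classify_in_out(
        pix.detect_pixel_spikes(traces, pix.DEFAULT_PIXEL_THRESHOLD, well="A1"), windows
    )
    return {
        "config": config,
        "movie": movie,
        "truth": truth,
        "mask": mask,
        "threshold": threshold,
        "threshold_stats": thr_stats,
        "well_trace": well_trace,
        "spikes": spikes,
        "windows": windows,
        "pixel_traces": traces,
        "table": table,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
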