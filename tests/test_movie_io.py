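"""Movie I/O, zone masking and trace extraction."""

import numpy as np
import pytest

from platecal import movie_io
from platecal.movie_io import (
    DegenerateMaskError,
    MovieFormatError,
    PlateLayout,
    PlateMovie,
    Trace,
    build_zone_mask,
    extract_pixel_traces,
    extract_well_trace,
    load_movie,
    save_movie,
    traces_to_matrix,
)
from platecal.synthetic_plate import geometry_zone_labels, simulate_plate, true_zone_mask

from .conftest import small_config


def _tiny_layout(n_rows=1, n_cols=1, tile=(8, 8), **kw):
    return PlateLayout(n_rows=n_rows, n_cols=n_cols, tile_shape=tile, **kw)


def _zone_movie(n_frames=12):
    """Movie with three exact brightness plateaus per tile."""
    lab = geometry_zone_labels((12, 12), 4.2, 5.2)
    img = np.choose(lab, [5.0, 40.0, 90.0])
    frames = np.repeat(img[None], n_frames, axis=0)
    layout = _tiny_layout(tile=(12, 12))
    return PlateMovie(frames=frames, frame_rate=5.0, layout=layout), lab


class TestFileRoundTrip:
    @pytest.mark.parametrize("ext", ["tif", "h5"])
    def test_round_trip_bit_identical(self, tmp_path, sim_plate, ext):
        _, movie, _ = sim_plate
        path = tmp_path / f"movie.{ext}"
        save_movie(movie, path)
        loaded = load_movie(path, movie.layout, frame_rate=movie.frame_rate)
        assert np.array_equal(loaded.frames, movie.frames)
        assert loaded.frame_rate == movie.frame_rate

    def test_cross_format_equality(self, tmp_path, sim_plate):
        _, movie, _ = sim_plate
        save_movie(movie, tmp_path / "m.tif")
        save_movie(movie, tmp_path / "m.h5")
        a = load_movie(tmp_path / "m.tif", movie.layout, frame_rate=8.0)
        b = load_movie(tmp_path / "m.h5", movie.layout)
        assert np.array_equal(a.frames, b.frames)

    def test_hdf5_carries_frame_rate_metadata(self, tmp_path, sim_plate):
        _, movie, _ = sim_plate
        save_movie(movie, tmp_path / "m.h5")
        loaded = load_movie(tmp_path / "m.h5", movie.layout)
        assert loaded.frame_rate == 8.0

    def test_single_frame_rejected(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "one.tif", np.zeros((1, 8, 8), dtype=np.float32))
        with pytest.raises(MovieFormatError, match="too short"):
            load_movie(tmp_path / "one.tif", _tiny_layout(), frame_rate=5.0)

    def test_tiff_requires_frame_rate(self, tmp_path, sim_plate):
        _, movie, _ = sim_plate
        save_movie(movie, tmp_path / "m.tif")
        with pytest.raises(MovieFormatError, match="frame_rate"):
            load_movie(tmp_path / "m.tif", movie.layout)

    def test_shape_layout_mismatch(self, tmp_path, sim_plate):
        _, movie, _ = sim_plate
        save_movie(movie, tmp_path / "m.h5")
        with pytest.raises(MovieFormatError, match="does not match layout"):
            load_movie(tmp_path / "m.h5", _tiny_layout())


class TestZoneMask:
    def test_recovers_exact_brightness_plateaus(self):
        movie, lab = _zone_movie()
        mask = build_zone_mask(movie)
        assert np.array_equal(mask.labels["A1"], lab)
        assert mask.growth_pixel_count["A1"] == int((lab == 2).sum())

    def test_uniform_tile_degenerate(self):
        layout = _tiny_layout()
        movie = PlateMovie(np.full((12, 8, 8), 7.0), 5.0, layout)
        with pytest.raises(DegenerateMaskError):
            build_zone_mask(movie)

    def test_needs_ten_frames(self):
        movie, _ = _zone_movie(n_frames=5)
        with pytest.raises(MovieFormatError, match="10 frames"):
            build_zone_mask(movie)

    def test_partition_property(self, analyzed):
        for well, lab in analyzed["mask"].labels.items():
            assert set(np.unique(lab)) <= {0, 1, 2}
            counts = [(lab == z).sum() for z in (0, 1, 2)]
            assert sum(counts) == lab.size

    def test_affine_intensity_invariance(self, sim_plate):
        _, movie, _ = sim_plate
        mask = build_zone_mask(movie)
        scaled = PlateMovie(movie.frames * 3.7 + 12.0, movie.frame_rate, movie.layout)
        mask2 = build_zone_mask(scaled)
        for w in mask.labels:
            assert np.array_equal(mask.labels[w], mask2.labels[w])

    def test_default_96well_geometry_covers_about_400_pixels(self, analyzed):
        """The default well-tile geometry is calibrated to ~400 growth pixels,
        the virtual-MEA coverage the pixel analysis is designed around."""
        assert analyzed["mask"].growth_pixel_count["A1"] == 400

    def test_default_384well_geometry_covers_about_130_pixels(self):
        cfg = small_config(plate_format=384, plate_rows=1, plate_cols=1,
                           wells={}, empty_wells=[], duration=5.0)
        movie, _ = simulate_plate(cfg)
        mask = build_zone_mask(movie)
        assert abs(mask.growth_pixel_count["A1"] - 130) <= 10

    def test_matches_simulated_geometry(self, analyzed):
        tm = true_zone_mask(analyzed["config"])
        assert np.array_equal(analyzed["mask"].labels["A1"], tm.labels["A1"])


class TestTraces:
    def test_constant_growth_pixels_give_constant_trace(self):
        movie, lab = _zone_movie()
        mask = build_zone_mask(movie)
        tr = extract_well_trace(movie, mask, "A1")
        assert np.allclose(tr.values, 90.0)

    def test_well_trace_is_mean_of_pixel_traces(self, analyzed):
        movie, mask = analyzed["movie"], analyzed["mask"]
        tr = extract_well_trace(movie, mask, "A1")
        raw = extract_pixel_traces(movie, mask, "A1", normalization="none")
        assert np.allclose(tr.values, traces_to_matrix(raw).mean(axis=0))

    def test_two_pixel_average(self):
        layout = _tiny_layout(tile=(4, 4))
        frames = np.zeros((12, 4, 4))
        frames[:, 0, 0] = 0.0
        frames[:, 0, 1] = 2.0
        movie = PlateMovie(frames + 0.0, 5.0, layout)
        lab = np.zeros((4, 4), dtype=int)
        lab[0, 0] = lab[0, 1] = 2
        mask = movie_io.WellZoneMask(labels={"A1": lab}, layout=layout)
        tr = extract_well_trace(movie, mask, "A1")
        assert np.allclose(tr.values, 1.0)

    def test_minmax_normalization_bounds_and_flag(self, analyzed):
        traces = analyzed["pixel_traces"]
        assert len(traces) == analyzed["mask"].growth_pixel_count["A1"]
        for t in traces[:50]:
            assert t.values.min() == pytest.approx(0.0)
            assert t.values.max() == pytest.approx(1.0)
            assert not t.degenerate

    def test_zero_range_pixel_flagged_not_raised(self):
        movie, _ = _zone_movie()
        mask = build_zone_mask(movie)
        traces = extract_pixel_traces(movie, mask, "A1", normalization="minmax")
        assert all(t.degenerate for t in traces)
        assert all(np.all(t.values == 0) for t in traces)

    def test_well_trace_peaks_match_ground_truth(self):
        """With full participation, well-trace peak times align with the
        simulated network events to within one frame."""
        from platecal.network_analysis import detect_spikes

        cfg = small_config(
            duration=120.0,
            wells={"A1": __import__("platecal").synthetic_plate.WellSimSpec(
                participation_prob=1.0, jitter_sd=0.0, out_rate_per_pixel=0.0)},
            noise_sd=0.0, common_noise_sd=0.0,
        )
        movie, truth = simulate_plate(cfg)
        mask = build_zone_mask(movie)
        tr = extract_well_trace(movie, mask, "A1")
        spikes = detect_spikes(tr, 10.0)
        true_times = truth.network_times["A1"]
        assert len(spikes) == len(true_times)
        # peak of the kernel lags the event onset by its analytic rise time
        t_lag = 0.1 * 0.6 / 0.5 * np.log(6.0)
        for e, tt in zip(spikes.events, true_times):
            assert abs(e.peak_time - (tt + t_lag)) <= 1.5 / movie.frame_rate


def test_gain_map_divides_frames(tmp_path, sim_plate):
    """A user-supplied spatial-uniformity map rescales each pixel."""
    _, movie, _ = sim_plate
    save_movie(movie, tmp_path / "m.h5")
    gain = np.full(movie.layout.frame_shape, 2.0)
    corrected = load_movie(tmp_path / "m.h5", movie.layout, gain_map=gain)
    assert np.allclose(corrected.frames, movie.frames / 2.0)
    with pytest.raises(MovieFormatError, match="gain map"):
        load_movie(tmp_path / "m.h5", movie.layout, gain_map=np.ones((3, 3)))


def test_mask_exports(tmp_path, analyzed):
    mask = analyzed["mask"]
    mask.to_csv(tmp_path / "mask.csv")
    mask.to_png(tmp_path / "mask.png")
    import pandas as pd

    df = pd.read_csv(tmp_path / "mask.csv")
    assert set(df["zone"]) == {"outside", "border", "growth"}
    assert (tmp_path / "mask.png").stat().st_size > 0


def test_layout_yaml_round_trip(tmp_path):
    lay = _tiny_layout(n_rows=2, n_cols=3, empty_wells=["A1", "B3"],
                       compound_addition_time=300.0)
    lay.to_yaml(tmp_path / "layout.yaml")
    back = PlateLayout.from_yaml(tmp_path / "layout.yaml")
    assert back == lay


def test_layout_rejects_unknown_empty_wells():
    with pytest.raises(ValueError, match="empty_wells"):
        _tiny_layout(empty_wells=["Z9"])
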