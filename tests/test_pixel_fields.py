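"""Pixel-resolution local fields: ranking, IN/OUT labels, threshold sweeps."""

import numpy as np
import pytest

from platecal.movie_io import Trace
from platecal.network_analysis import NetworkWindows
from platecal.pixel_fields import (
    DEFAULT_TOP_N,
    classify_in_out,
    detect_pixel_spikes,
    rank_active_pixels,
    summarize_local_fields,
    threshold_sweep,
)
from platecal.synthetic_plate import transient_kernel


def _pulse_trace(peaks, n=800, fs=8.0, amp=1.0, noise=0.0, seed=0):
    """Normalized trace with kernel transients at the given times."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    x = np.zeros(n)
    for tp in np.atleast_1d(peaks):
        x += amp * transient_kernel(t - tp, 0.1, 0.6)
    if noise:
        x += rng.normal(0, noise, n)
    x -= x.min()
    if x.max() > 0:
        x /= x.max()
    return Trace(x, fs, (0, 0), normalization="minmax")


class TestRanking:
    def test_spiking_pixels_rank_above_silent_and_shoulder_near_truth(self):
        """500 pixels, 400 with transients, 100 silent: the shoulder of the
        rank-score curve falls near 400 and every active pixel outranks
        every silent one."""
        rng = np.random.default_rng(9)
        traces = []
        for i in range(500):
            if i < 400:
                times = np.linspace(10, 90, 5) + rng.uniform(-3, 3, size=5)
                tr = _pulse_trace(times, n=800, amp=rng.uniform(0.8, 1.0),
                                  noise=0.02, seed=i)
            else:
                x = rng.normal(0, 0.02, 800)
                x -= x.min()
                x /= max(x.max(), 1e-9)
                tr = Trace(x * 0.08, 8.0, (0, i), normalization="minmax")
            traces.append(tr)
        ranking = rank_active_pixels(traces, base_threshold=0.4, n_select=400)
        assert abs(ranking.shoulder - 400) <= 25
        active_scores = ranking.scores[:400]
        silent_scores = ranking.scores[400:]
        assert active_scores.min() > silent_scores.max()
        assert set(ranking.selected_indices) == set(range(400))

    def test_all_silent_flagged_degenerate(self):
        traces = [Trace(np.zeros(100), 8.0, (0, i), "minmax") for i in range(10)]
        ranking = rank_active_pixels(traces, n_select=5)
        assert ranking.degenerate
        assert np.all(ranking.scores == 0)

    def test_fewer_pixels_than_n_flagged(self):
        traces = [_pulse_trace([10.0], seed=i) for i in range(3)]
        ranking = rank_active_pixels(traces, n_select=400)
        assert ranking.flagged_short
        assert ranking.selected.sum() == 3

    def test_default_top_n_constants(self):
        assert DEFAULT_TOP_N[96] == 400
        assert DEFAULT_TOP_N[384] == 130


class TestPixelSpikes:
    def test_full_range_transient_prominence_near_one(self):
        table = detect_pixel_spikes([_pulse_trace([20.0])], 0.4)
        assert len(table) == 1
        assert table.df.iloc[0].prominence == pytest.approx(1.0, abs=0.01)

    def test_gaussian_pulse_fwhm_closed_form(self):
        """FWHM of a Gaussian pulse (sigma = 0.5 s) is 2*sqrt(2 ln 2)*sigma,
        recovered to within one frame period at 8 fps."""
        fs, sigma = 8.0, 0.5
        t = np.arange(800) / fs
        x = np.exp(-0.5 * ((t - 50.0) / sigma) ** 2)
        table = detect_pixel_spikes([Trace(x, fs, (0, 0), "minmax")], 0.4)
        assert len(table) == 1
        expected = 2 * np.sqrt(2 * np.log(2)) * sigma
        assert table.df.iloc[0].fwhm == pytest.approx(expected, abs=1 / fs)

    def test_noise_below_threshold_silent(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 800)
        x = (x - x.min()) / np.ptp(x) * 0.09  # noise amplitude < 0.1
        table = detect_pixel_spikes([Trace(x, 8.0, (0, 0), "minmax")], 0.4)
        assert len(table) == 0

    def test_unnormalized_trace_rejected(self):
        with pytest.raises(ValueError, match="min-max normalized"):
            detect_pixel_spikes([Trace(np.linspace(0, 5, 100), 8.0, (0, 0))], 0.4)


class TestClassification:
    def test_peak_inside_window_is_in(self):
        table = detect_pixel_spikes([_pulse_trace([10.3])], 0.4)
        w = NetworkWindows(np.array([[10.0, 11.2]]))
        labeled = classify_in_out(table, w)
        assert labeled.df.iloc[0].label == "IN"

    def test_peak_outside_any_window_is_out(self):
        table = detect_pixel_spikes([_pulse_trace([20.0])], 0.4)
        w = NetworkWindows(np.array([[10.0, 11.2]]))
        labeled = classify_in_out(table, w)
        assert labeled.df.iloc[0].label == "OUT"

    def test_partition_in_plus_out_is_total(self, analyzed):
        counts = analyzed["table"].counts()
        assert counts["IN"] + counts["OUT"] == counts["all"]
        per_pixel = analyzed["table"].df.groupby("pixel_index")["label"]
        for _, labels in per_pixel:
            assert set(labels) <= {"IN", "OUT"}

    def test_simulated_label_accuracy(self, analyzed):
        """IN/OUT labels agree with the simulator's ground truth for >= 95%
        of detected spikes."""
        truth, df = analyzed["truth"], analyzed["table"].df
        correct = 0
        for row in df.itertuples():
            tin = truth.pixel_in_times("A1", row.pixel_index)
            truly_in = len(tin) > 0 and np.min(np.abs(tin - row.peak_time)) < 0.5
            correct += (row.label == "IN") == truly_in
        assert correct / len(df) >= 0.95


class TestThresholdSweep:
    def test_reference_fraction_is_one_and_monotone(self, analyzed):
        sweep = threshold_sweep(analyzed["pixel_traces"][:60], analyzed["windows"])
        assert sweep.thresholds[0] == 0.10
        assert sweep.thresholds[-1] == 1.00
        assert len(sweep.thresholds) == 91
        for cls in ("IN", "OUT", "all"):
            curve = sweep.curve(cls)
            assert curve[0] == pytest.approx(1.0)
            assert np.all(np.diff(curve) <= 1e-12)
            assert np.nanmin(curve) >= 0.0 and np.nanmax(curve) <= 1.0

    def test_single_pulse_step_function(self):
        """One pulse of prominence 0.5: retained up to threshold 0.5, lost
        above."""
        x = np.zeros(200)
        x[100] = 0.5
        tr = Trace(x, 8.0, (0, 0), "minmax")
        sweep = threshold_sweep([tr], NetworkWindows(np.empty((0, 2))))
        curve = sweep.curve("all")
        thr = sweep.thresholds
        assert np.all(curve[thr <= 0.5] == 1.0)
        assert np.all(curve[thr > 0.5] == 0.0)

    def test_no_spikes_at_reference_flagged(self):
        tr = Trace(np.zeros(200), 8.0, (0, 0), "minmax")
        sweep = threshold_sweep([tr], NetworkWindows(np.empty((0, 2))))
        assert set(sweep.undefined) == {"IN", "OUT", "all"}


class TestSummary:
    def test_frequency_arithmetic(self):
        """Every pixel exactly 3 spikes in 300 s -> 0.6 spikes/min."""
        traces = [_pulse_trace([50.0, 150.0, 250.0], n=2400, seed=i) for i in range(4)]
        table = detect_pixel_spikes(traces, 0.4)
        s = summarize_local_fields(table, n_pixels=4, duration=300.0)
        assert s["mean_pixel_frequency"] == pytest.approx(0.6)

    def test_class_means(self):
        import pandas as pd

        from platecal.pixel_fields import PixelSpikeTable, _COLUMNS

        rows = [
            ("w", 0, 0, 0, 10.0, 80, 0.9, 0.8, 0.5, 9.8, 10.3, "IN"),
            ("w", 0, 1, 1, 20.0, 160, 0.5, 0.4, 0.4, 19.8, 20.2, "OUT"),
        ]
        table = PixelSpikeTable(pd.DataFrame(rows, columns=_COLUMNS), 300.0, 8.0)
        s = summarize_local_fields(table, n_pixels=2)
        assert s["IN"]["mean_amplitude"] == pytest.approx(0.8)
        assert s["OUT"]["mean_amplitude"] == pytest.approx(0.4)

    def test_overall_mean_is_count_weighted_class_mean(self, analyzed):
        s = summarize_local_fields(analyzed["table"], n_pixels=400)
        n_in, n_out = s["IN"]["n"], s["OUT"]["n"]
        weighted = (
            n_in * s["IN"]["mean_amplitude"] + n_out * s["OUT"]["mean_amplitude"]
        ) / (n_in + n_out)
        assert s["all"]["mean_amplitude"] == pytest.approx(weighted, rel=1e-12)

    def test_in_amplitude_exceeds_out_when_configured_larger(self, analyzed):
        """Network-event transients are configured larger than local events,
        so the IN class mean must exceed the OUT class mean."""
        s = summarize_local_fields(analyzed["table"], n_pixels=400)
        assert s["IN"]["mean_amplitude"] > s["OUT"]["mean_amplitude"]
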