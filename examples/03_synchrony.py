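"""Pairwise pixel synchrony, full-trace and phase-restricted.

Computes the pixel-pixel Pearson correlation matrix, its clustered display
order, the correlation-vs-distance curve, and the same correlation
restricted to recording phases inside (IN) or outside (OUT) network spikes.
"""

from platecal import movie_io
from platecal import network_analysis as net
from platecal import synchrony as syn
from platecal.synthetic_plate import SimConfig, WellSimSpec, simulate_plate

config = SimConfig(
    plate_rows=1, plate_cols=2, duration=300.0,
    wells={"A1": WellSimSpec()}, empty_wells=["A2"], rng_seed=1,
)
movie, _ = simulate_plate(config)
mask = movie_io.build_zone_mask(movie)
threshold, _ = net.global_threshold(movie, mask)
trace = movie_io.extract_well_trace(movie, mask, "A1")
windows = net.network_windows(net.detect_spikes(trace, threshold))
traces = movie_io.extract_pixel_traces(movie, mask, "A1", "minmax")[:120]

full = syn.pairwise_correlation(traces, pixel_pitch_um=284.0)
in_mask, out_mask = syn.phase_masks(windows, movie.n_frames, movie.frame_rate)
r_in = syn.pairwise_correlation(traces, phase_mask=in_mask, phase="in_phases")
r_out = syn.pairwise_correlation(traces, phase_mask=out_mask, phase="out_phases")

print(f"mean pairwise r, full trace: {full.mean_r:.3f}")
print(f"mean pairwise r, IN phases:  {r_in.mean_r:.3f}")
print(f"mean pairwise r, OUT phases: {r_out.mean_r:.3f}")
# Correlation is driven almost entirely by network-spike phases: outside
# them the local activity is close to uncorrelated.

curve = syn.correlation_vs_distance(full, n_bins=6)
print("\ncorrelation vs distance (um):")
for row in curve.itertuples():
    print(f"  {row.bin_center_um:7.0f}  mean r {row.mean_r:.3f}  ({row.n_pairs} pairs)")

order = syn.cluster_order(full.matrix)
print(f"\nclustered display order starts with pixels {order[:5].tolist()}")
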