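# Methods

## The measurement being modelled

A fluorescence plate reader images whole multi-well plates at 5–8 frames/s
while cocultured neurons (expressing a calcium indicator) fire. Synchronized
network firing appears as plate-wide calcium transients in the well-average
trace ("network spikes"). At pixel resolution each pixel integrates the
fluorescence of on the order of a hundred neurons (~284 × 284 μm on the
plate for the 96-well setting used here), so a single pixel's trace is a
*local field* signal, analogous to an extracellular MEA electrode: it shows
both the network spikes and additional local transients that average out of
the well signal.

## Spike detection

Detection is topographic-prominence thresholding of local maxima
(`scipy.signal.find_peaks`), with a minimum peak separation of 2 frames to
suppress noise doublets riding one transient. Spike amplitude is defined as
the prominence, not the absolute peak height, so a slow baseline drift does
not inflate amplitudes. FWHM is measured at half the prominence above the
contour base, with linear interpolation of the crossings, and converted to
seconds by the frame rate. Plateau peaks are reported at the leftmost
plateau sample. The implementation is validated in the test suite against
an independent brute-force scanner that enumerates local maxima and derives
prominence and widths by explicit flank scans.

### Plate threshold from empty wells

Dry wells at the plate edge carry no cells; their traces exhibit only the
instrument background (read noise plus illumination flicker). Each empty
well contributes the maximum prominence found in its trace; the plate
threshold is

    threshold = safety_factor × (mean + 3·SD of those maxima) + ε

with `safety_factor = 2` and floor `ε = 1e-6`. The safety factor exists
because `mean + 3·SD` of per-well *maxima* is itself an estimate of the
typical extreme excursion of an equivalent background trace — a culture
well's own background then exceeds it roughly every other recording, and
dry wells cannot exhibit background components of biological origin
(un-synchronized local activity bleeding faintly into the well average).
Doubling the statistic clears the whole extreme-value distribution while
network spikes, an order of magnitude above background in practice, still
pass. When a zone mask is available the empty-well trace averages the same
growth pixels the analysis traces use, so its noise scale matches; with no
empty wells the user must supply an explicit threshold.

## Zone masks

Per well, the temporal-mean brightness of each tile pixel is clustered into
3 classes by 1-D k-means with deterministic initialization at the minimum,
median and maximum brightness (falling back to evenly spaced centers when
those coincide). Ascending class centers map to outside < border < growth.
Clustering is per-well so illumination gradients across the plate cannot
bleed zones between wells, and the mask is invariant to affine intensity
rescaling. Tiles with fewer than 3 distinct brightness values raise a
degenerate-mask error. The default 96-well tile geometry (28 × 28 px,
growth disc radius 11.4 px) yields exactly 400 growth pixels per well; the
384-well default (18 × 18 px, radius 6.5 px) yields 124, near the ~130
pixels such wells cover.

## IN/OUT classification and windows

A network-spike *participation window* is the half-max interval of the
well-average spike, padded by one frame on each side; overlapping windows
merge. A pixel spike is IN if its peak time falls inside any merged window
(closed intervals, peak time only — extent overlap is deliberately not
used, as the simplest well-defined rule), else OUT. Phase masks assign a
frame to the IN phase when its midpoint time lies inside a window; IN and
OUT masks partition the frames exactly.

## Normalization and thresholds at pixel level

Pixel traces are min-max normalized to [0, 1] over their own range, so
prominence thresholds are comparable across pixels of different brightness;
a zero-range pixel becomes an all-zeros trace flagged degenerate rather
than an error. The standard local-field detection threshold is 0.4; the
threshold sweep re-detects (not merely filters) at 0.10…1.00 in 0.01 steps
and reports per-class retained fractions relative to the 0.10 counts, 0.10
being a floor just above the noise band. Because detection at 0.4 by design
loses part of the spikes counted at 0.10, per-pixel *rate recovery*
validation runs at 0.2 — high enough to exclude noise, low enough for
near-complete detection.

## Synchrony

Pearson correlation across (optionally phase-masked) normalized pixel
traces; pixels with zero variance in the analyzed segment are excluded and
reported. Distances are Euclidean in μm from pixel coordinates times the
pixel pitch; the distance curve uses 10 equal-width bins with t-based 95%
CIs. Display ordering of correlation matrices uses average-linkage
hierarchical clustering on 1 − r with deterministic tie-breaking.

## Dose–response fitting

Four-parameter logistic, least squares in log10(IC50) parameterization with
slope bounded to [0.05, 20]; initialization from the data extremes and the
dose nearest half-response. Flat data return a flagged fit with undefined
IC50; fits with R² < 0.5 are flagged poor rather than silently reported.

## Statistics

Unpaired t-tests for across-well comparisons, paired for within-well
baseline-vs-treatment; two-way ANOVA with type-II sums of squares (types
coincide on the balanced designs used in tests) and Tukey HSD posthoc;
Bonferroni for families of t-tests. Fold difference is
mean(condition)/mean(control). The type-I error of all three procedures is
calibrated on null simulations in the acceptance suite.

## The simulator and what it does (not) capture

Each well tile has a dim outside, a brighter border ring (well-wall
autofluorescence) and a growth disc carrying signal. Two event classes are
superposed on growth pixels: network events, at which each pixel
participates independently with probability `participation_prob` and a
small timing jitter (SD 0.05 s); and per-pixel OUT events from a
homogeneous Poisson process, modelling cell-autonomous activity. Transients
are difference-of-exponentials kernels normalized to unit peak (rise 0.1 s,
decay 0.6 s — fast-indicator kinetics spanning several frames at 8 fps);
overlaps sum linearly. Amplitudes are lognormal.

Default activity parameters are the control coculture condition of the
assay this models: network rate 3.3/min with participation 0.9 and OUT rate
2.6/min/pixel give a ground-truth per-pixel rate of ≈5.6 spikes/min.
Amplitude CVs are small (0.10 network, 0.15 local) because a pixel
integrates ~10² neurons and averaging suppresses per-cell variability.
Network events carry a 1.25 s refractory period (synaptic depression):
bursts closer than the transient width are physically one burst, and a pure
Poisson train would make ~10% of events unresolvable at these rates.

Noise has two components. Independent read noise (SD 2 a.u. against a
growth baseline of 100) sets the pixel-level noise band: after
normalization the 0.1 sweep floor sits at ≈4σ of it, i.e. just outside
high-intensity noise. Common-mode illumination flicker (SD 1 a.u., ~1% of
baseline, shared across a tile per frame) models lamp/LED fluctuation; it
is the component that does *not* average away in the well mean and is
therefore what the empty-well threshold actually calibrates. Without it a
simulated (or real) instrument with purely independent pixel noise would
give empty-well thresholds far below the biological background of culture
wells.

Acute drug effects scale the network rate and network amplitude from the
addition time onward; a Hill term scales the rate with dose. Ground truth
records every event, per-pixel participation, amplitudes and applied
scales.

Not modelled: photobleaching, indicator saturation, optical distortion
(tile rectangles stand in for the camera-perspective correction), spatially
structured connectivity (OUT events are independent across pixels; IN
participation is spatially exchangeable), and any biophysical
membrane-potential dynamics. Consequently, passing tests demonstrate that
the *analysis* recovers known event structure under realistic noise — not
that real cultures obey these generative assumptions; in particular the
distance dependence of correlation in real wells has no counterpart in the
default simulator (participation is distance-free, and the flat
correlation-distance curve verifies exactly that).

## Numerical and design choices

- Coordinates are 0-based (row, col); tile rectangles half-open; well ids
  are letter-number ("A1").
- One RNG substream per well, derived from `(seed, well_index)`, so any
  subset of wells reproduces bit-identically.
- Identical config + seed ⇒ bit-identical movies; camera counts are clipped
  at zero.
- Problem sizes in tests and the acceptance script (1–3 culture wells,
  5–10 min recordings, 8 doses × 3 replicate wells) were chosen as the
  smallest sizes at which the statistical checks are well-powered.
- Test-oracle values (e.g. the Jensen–Shannon divergence of a uniform
  3-cluster profile against a one-hot target, 0.45915 bits) are frozen from
  the direct-summation oracle in `tests/oracles.py`.

## Known limitations

- The empty-well threshold rule assumes the instrument background in dry
  wells is representative of culture-well background; strong biological
  clutter (dense un-synchronized activity) can still require an explicit
  threshold.
- Min-max normalization couples a pixel's threshold scale to its single
  largest transient; a few very large events compress all other spikes of
  that pixel toward the noise floor.
- FWHM of strongly overlapping spikes is measured on the merged shape.
- The 4PL fit reports a flagged, not refused, result on weakly monotone
  data; IC50s from single-well dose series carry Poisson counting error
  (see `examples/04_dose_response.py` versus the replicated design in
  `scripts/acceptance.py`).
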