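"""Plate-movie containers, file I/O, zone masks and trace extraction.

A plate-reader calcium movie is a grayscale frame stack ``(time, y, x)``
covering a grid of well tiles.  Each tile is partitioned by brightness into
three zones: the cell *growth* area, a *border* ring (well wall
autofluorescence) and the *outside* background.  Only growth pixels carry
signal; all downstream well- and pixel-resolution analyses operate on them.

Coordinates are 0-based ``(row, col)`` and tile rectangles are half-open.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np
import tifffile
import yaml
from sklearn.cluster import KMeans

__all__ = [
    "PlateLayout",
    "PlateMovie",
    "WellZoneMask",
    "Trace",
    "MovieFormatError",
    "DegenerateMaskError",
    "load_movie",
    "save_movie",
    "build_zone_mask",
    "extract_well_trace",
    "extract_pixel_traces",
]

ZONE_OUTSIDE, ZONE_BORDER, ZONE_GROWTH = 0, 1, 2
ZONE_NAMES = {ZONE_OUTSIDE: "outside", ZONE_BORDER: "border", ZONE_GROWTH: "growth"}


class MovieFormatError(ValueError):
    """Raised when a movie file or array does not match the expected layout."""


class DegenerateMaskError(ValueError):
    """Raised when a well tile has too little brightness structure to cluster."""


def well_name(row: int, col: int) -> str:
    """Plate-style well id, e.g. row 0 / col 0 -> ``A1``."""
    return f"{chr(ord('A') + row)}{col + 1}"


@dataclass
class PlateLayout:
    """Well-grid geometry of a plate movie.

    ``tile_bounds`` maps a well id to its half-open pixel rectangle
    ``(r0, c0, r1, c1)``.  ``empty_wells`` are instrument-background wells at
    the plate edge used for global threshold calibration.  ``pixel_pitch_um``
    is the physical edge length one movie pixel covers on the plate.
    """

    n_rows: int
    n_cols: int
    tile_shape: tuple[int, int]
    empty_wells: list[str] = field(default_factory=list)
    well_pitch_um: float = 9000.0
    pixel_pitch_um: float = 284.0
    compound_addition_time: float | None = None

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")
        unknown = set(self.empty_wells) - set(self.well_ids())
        if unknown:
            raise ValueError(f"empty_wells not on the plate: {sorted(unknown)}")

    def well_ids(self) -> list[str]:
        return [well_name(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]

    def iter_wells(self) -> Iterator[tuple[str, tuple[int, int, int, int]]]:
        ty, tx = self.tile_shape
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield well_name(r, c), (r * ty, c * tx, (r + 1) * ty, (c + 1) * tx)

    def tile_bounds(self, well: str) -> tuple[int, int, int, int]:
        for name, bounds in self.iter_wells():
            if name == well:
                return bounds
        raise KeyError(f"unknown well {well!r}")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.n_rows * self.tile_shape[0], self.n_cols * self.tile_shape[1]

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["tile_shape"] = list(self.tile_shape)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlateLayout":
        data = yaml.safe_load(Path(path).read_text())
        data["tile_shape"] = tuple(data["tile_shape"])
        return cls(**data)


@dataclass
class PlateMovie:
    """Frame stack ``(time, y, x)`` with acquisition metadata."""

    frames: np.ndarray
    frame_rate: float
    layout: PlateLayout
    binning: int = 1
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise MovieFormatError("frame_rate must be positive")
        if self.frames.ndim != 3:
            raise MovieFormatError("frames must be a (time, y, x) stack")
        if self.frames.shape[0] < 2:
            raise MovieFormatError("time axis too short (need at least 2 frames)")
        if self.frames.shape[1:] != self.layout.frame_shape:
            raise MovieFormatError(
                f"frame shape {self.frames.shape[1:]} does not match layout "
                f"{self.layout.frame_shape}"
            )
        self.frames = np.asarray(self.frames, dtype=np.float64)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def frame_times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_frames) / self.frame_rate

    def well_tile(self, well: str) -> np.ndarray:
        r0, c0, r1, c1 = self.layout.tile_bounds(well)
        return self.frames[:, r0:r1, c0:c1]


@dataclass
class WellZoneMask:
    """Per-pixel zone labels (growth / border / outside) for each well tile.

    ``labels[well]`` is an int array of the tile shape with values
    ``ZONE_OUTSIDE``, ``ZONE_BORDER``, ``ZONE_GROWTH``.
    """

    labels: dict[str, np.ndarray]
    layout: PlateLayout

    @property
    def growth_pixel_count(self) -> dict[str, int]:
        return {w: int((lab == ZONE_GROWTH).sum()) for w, lab in self.labels.items()}

    def zone_coords(self, well: str, zone: int = ZONE_GROWTH) -> np.ndarray:
        """Tile-local (row, col) coordinates of pixels in ``zone``, row-major."""
        rr, cc = np.nonzero(self.labels[well] == zone)
        return np.column_stack([rr, cc])

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        rows = []
        for well, lab in self.labels.items():
            rr, cc = np.indices(lab.shape)
            rows.append(
                pd.DataFrame(
                    {
                        "well": well,
                        "row": rr.ravel(),
                        "col": cc.ravel(),
                        "zone": [ZONE_NAMES[z] for z in lab.ravel()],
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)

    def to_png(self, path: str | Path) -> None:
        """Write the plate-wide zone labels as a color-coded image."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        H, W = self.layout.frame_shape
        full = np.zeros((H, W), dtype=int)
        for well, (r0, c0, r1, c1) in self.layout.iter_wells():
            if well in self.labels:
                full[r0:r1, c0:c1] = self.labels[well]
        fig, ax = plt.subplots(figsize=(max(4, W / 40), max(3, H / 40)))
        ax.imshow(full, cmap="viridis", vmin=0, vmax=2, interpolation="nearest")
        ax.set_title("zones: 0 outside, 1 border, 2 growth")
        fig.savefig(path, dpi=120)
        plt.close(fig)


@dataclass
class Trace:
    """A single intensity time series, from a well average or one pixel."""

    values: np.ndarray
    frame_rate: float
    source: str | tuple[int, int]
    normalization: str = "none"
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.frame_rate

    @property
    def duration(self) -> float:
        return len(self.values) / self.frame_rate


# ---------------------------------------------------------------------------
# file I/O


def save_movie(movie: PlateMovie, path: str | Path) -> None:
    """Write a movie as multi-page grayscale TIFF or HDF5 (by extension)."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, movie.frames)
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("movie", data=movie.frames)
            ds.attrs["frame_rate"] = movie.frame_rate
            ds.attrs["binning"] = movie.binning
            ds.attrs["start_time"] = movie.start_time
    else:
        raise MovieFormatError(f"unsupported movie format {path.suffix!r}")


def load_movie(
    path: str | Path,
    layout: PlateLayout,
    frame_rate: float | None = None,
    binning: int = 1,
    gain_map: np.ndarray | None = None,
) -> PlateMovie:
    """Load a TIFF stack or HDF5 dataset as a :class:`PlateMovie`.

    HDF5 files carry their frame rate as a dataset attribute; for TIFF the
    rate must be supplied (the instrument metadata is not standardised).
    ``gain_map`` is an optional user-supplied per-pixel spatial-uniformity
    correction (frame shape, strictly positive); frames are divided by it.
    The package never infers such a map from the data.
    """
    path = Path(path)
    start_time = 0.0
    if path.suffix in (".tif", ".tiff"):
        frames = tifffile.imread(path)
        if frame_rate is None:
            raise MovieFormatError("frame_rate required when loading TIFF movies")
    elif path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ds = f["movie"]
            frames = ds[...]
            if frame_rate is None:
                if "frame_rate" not in ds.attrs:
                    raise MovieFormatError("missing frame_rate metadata in HDF5 movie")
                frame_rate = float(ds.attrs["frame_rate"])
            binning = int(ds.attrs.get("binning", binning))
            start_time = float(ds.attrs.get("start_time", 0.0))
    else:
        raise MovieFormatError(f"unsupported movie format {path.suffix!r}")
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[0] < 2:
        raise MovieFormatError("time axis too short (need at least 2 frames)")
    if np.nanmin(frames) < 0:
        frames = np.clip(frames, 0, None)
    if gain_map is not None:
        gain_map = np.asarray(gain_map, dtype=np.float64)
        if gain_map.shape != frames.shape[1:]:
            raise MovieFormatError(
                f"gain map shape {gain_map.shape} does not match frames {frames.shape[1:]}"
            )
        if np.any(gain_map <= 0):
            raise MovieFormatError("gain map must be strictly positive")
        frames = frames / gain_map
    return PlateMovie(
        frames=frames,
        frame_rate=float(frame_rate),
        layout=layout,
        binning=binning,
        start_time=start_time,
    )


# ---------------------------------------------------------------------------
# zone masking


def _cluster_tile(mean_img: np.ndarray) -> np.ndarray:
    """3-class 1-D k-means on pixel brightness, deterministic init.

    Centers start at the minimum, median and maximum brightness so repeated
    runs give identical masks.  Classes are relabelled by ascending center:
    outside < border < growth.
    """
    vals = mean_img.ravel()
    if np.unique(vals).size < 3:
        raise DegenerateMaskError(
            "well tile has fewer than 3 distinct brightness values; "
            "cannot separate growth/border/outside zones"
        )
    init = np.array([[vals.min()], [np.median(vals)], [vals.max()]])
    if np.unique(init.ravel()).size < 3:
        # median coincides with an extreme; fall back to evenly spaced init
        init = np.linspace(vals.min(), vals.max(), 3)[:, None]
    km = KMeans(n_clusters=3, init=init, n_init=1, max_iter=300)
    raw = km.fit_predict(vals[:, None])
    order = np.argsort(km.cluster_centers_.ravel())
    remap = np.empty(3, dtype=int)
    remap[order] = [ZONE_OUTSIDE, ZONE_BORDER, ZONE_GROWTH]
    return remap[raw].reshape(mean_img.shape)


def build_zone_mask(
    movie: PlateMovie, layout: PlateLayout | None = None, wells: list[str] | None = None
) -> WellZoneMask:
    """Cluster temporal-mean brightness into growth/border/outside per well.

    Clustering is per-well so plate-wide illumination gradients do not bleed
    zones across wells.  The mask is invariant to affine intensity rescaling
    of the movie because k-means class boundaries scale with the data.
    """
    layout = layout or movie.layout
    if movie.n_frames < 10:
        raise MovieFormatError("zone masking needs at least 10 frames")
    mean_img = movie.frames.mean(axis=0)
    labels: dict[str, np.ndarray] = {}
    for well, (r0, c0, r1, c1) in layout.iter_wells():
        if wells is not None and well not in wells:
            continue
        labels[well] = _cluster_tile(mean_img[r0:r1, c0:c1])
    return WellZoneMask(labels=labels, layout=layout)


# ---------------------------------------------------------------------------
# trace extraction


def extract_well_trace(movie: PlateMovie, mask: WellZoneMask, well: str) -> Trace:
    """Mean intensity over growth pixels per frame (the network-spike signal)."""
    lab = mask.labels[well]
    sel = lab == ZONE_GROWTH
    if not sel.any():
        raise ValueError(f"well {well} has no growth pixels")
    tile = movie.well_tile(well)
    return Trace(
        values=tile[:, sel].mean(axis=1),
        frame_rate=movie.frame_rate,
        source=well,
    )


def extract_pixel_traces(
    movie: PlateMovie,
    mask: WellZoneMask,
    well: str,
    normalization: str = "none",
) -> list[Trace]:
    """One trace per growth pixel of a well, optionally min-max normalized.

    Under ``minmax`` each trace is rescaled to [0, 1] over its own range so
    prominence thresholds are comparable across pixels.  A zero-range pixel
    is returned as an all-zeros trace flagged ``degenerate`` rather than an
    error: silent pixels are expected in sparse cultures.
    """
    if normalization not in ("none", "minmax"):
        raise ValueError(f"unknown normalization {normalization!r}")
    tile = movie.well_tile(well)
    coords = mask.zone_coords(well, ZONE_GROWTH)
    if coords.shape[0] == 0:
        raise ValueError(f"well {well} has no growth pixels")
    traces: list[Trace] = []
    for r, c in coords:
        v = tile[:, r, c].astype(np.float64)
        degenerate = False
        if normalization == "minmax":
            lo, hi = v.min(), v.max()
            if hi > lo:
                v = (v - lo) / (hi - lo)
            else:
                v = np.zeros_like(v)
                degenerate = True
        traces.append(
            Trace(
                values=v,
                frame_rate=movie.frame_rate,
                source=(int(r), int(c)),
                normalization=normalization,
                degenerate=degenerate,
            )
        )
    return traces


def traces_to_matrix(traces: list[Trace]) -> np.ndarray:
    """Stack traces into a (pixels, time) matrix."""
    return np.stack([t.values for t in traces])


def trace_from_csv(path: str | Path, source: str = "csv") -> Trace:
    """Read a (time, value) CSV as a Trace; frame rate from the time column."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("trace CSV needs (time, value) columns")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) < 1 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("time column must be evenly spaced")
    return Trace(values=df.iloc[:, 1].to_numpy(dtype=float),
                 frame_rate=1.0 / dt[0], source=source)
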