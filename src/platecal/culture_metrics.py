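"""Culture composition metrics from nuclei-count tables.

Deterministic arithmetic linking endpoint nuclei densities (per mm², from
automated nuclei detection and classification) to seeded cell numbers:
per-cell-type survival percentages, neuron-to-astrocyte ratios, total
survival rates, and the expected cell coverage per movie pixel.  Also the
Jensen–Shannon specificity score used to confirm cluster marker genes in
expression data.

Ratio conventions: for group comparisons both the ratio of group means and
the per-well mean of ratios are available — the two differ for skewed data
and are labelled explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

__all__ = [
    "CultureCounts",
    "survival_percent",
    "cell_type_ratio",
    "total_survival_rate",
    "cells_per_pixel",
    "marker_specificity_jsd",
    "counts_table_metrics",
    "WELL_AREA_384_MM2",
    "PIXEL_AREA_96_UM2",
]

#: Growth area of one 384-well plate well.
WELL_AREA_384_MM2 = 10.6276
#: Upper-estimate plate area covered by one movie pixel in the 96-well
#: pixel-resolution setting (~284 x 284 um).
PIXEL_AREA_96_UM2 = 80425.0


@dataclass
class CultureCounts:
    """Per-well seeded and endpoint counts."""

    well: str
    neuron_density: float      # nuclei / mm^2 at endpoint
    astro_density: float       # nuclei / mm^2 at endpoint
    well_area: float           # mm^2
    seeded_neurons: int
    seeded_astros: int
    group: str = ""

    def __post_init__(self) -> None:
        if self.neuron_density < 0 or self.astro_density < 0:
            raise ValueError("densities must be non-negative")
        if self.well_area <= 0:
            raise ValueError("well_area must be positive")


def survival_percent(density: float, well_area: float, seeded: float) -> float:
    """Endpoint survival as percent of seeded cells.

    ``100 * density(/mm^2) * well_area(mm^2) / seeded``.  Can exceed 100%
    when the cell type proliferated after seeding.
    """
    if seeded <= 0:
        raise ValueError("seeded count must be positive")
    if well_area <= 0:
        raise ValueError("well_area must be positive")
    return 100.0 * density * well_area / seeded


def cell_type_ratio(neuron_density: float, astro_density: float) -> float:
    """Neuron-to-astrocyte density ratio (dimensionless)."""
    if astro_density <= 0:
        raise ValueError("astro_density must be positive")
    return neuron_density / astro_density


def total_survival_rate(counts: CultureCounts) -> float:
    """Endpoint total cells / total seeded cells (fraction)."""
    seeded = counts.seeded_neurons + counts.seeded_astros
    if seeded <= 0:
        raise ValueError("total seeded count must be positive")
    return (counts.neuron_density + counts.astro_density) * counts.well_area / seeded


def cells_per_pixel(
    density_per_mm2: float, pixel_area_um2: float = PIXEL_AREA_96_UM2, round_int: bool = False
) -> float:
    """Cells covered by one movie pixel at the given nuclei density."""
    if pixel_area_um2 <= 0:
        raise ValueError("pixel_area_um2 must be positive")
    cells = density_per_mm2 * pixel_area_um2 * 1e-6
    return float(round(cells)) if round_int else float(cells)


def marker_specificity_jsd(
    profile: pd.DataFrame | np.ndarray,
    gene: str | int,
    target_cluster: str | int,
) -> float:
    """Specificity of a gene for one cluster, 1 = perfectly specific.

    The gene's mean-expression vector over clusters is normalized to a
    probability distribution and compared by Jensen–Shannon divergence
    (base 2, so bounded by 1) to the one-hot distribution of a hypothetical
    perfectly specific gene; the score is ``1 - JSD``.
    """
    if isinstance(profile, pd.DataFrame):
        expr = profile.loc[gene].to_numpy(dtype=float)
        clusters = list(profile.columns)
        t_idx = clusters.index(target_cluster)
    else:
        expr = np.asarray(profile, dtype=float)[gene]
        t_idx = int(target_cluster)
    if np.any(expr < 0):
        raise ValueError("expression values must be non-negative")
    total = expr.sum()
    if total <= 0:
        raise ValueError(f"gene {gene!r} has zero total expression")
    if expr.size < 2:
        raise ValueError("need at least 2 clusters")
    p = expr / total
    q = np.zeros_like(p)
    q[t_idx] = 1.0
    jsd = float(jensenshannon(p, q, base=2) ** 2)
    return 1.0 - jsd


def counts_table_metrics(counts: list[CultureCounts]) -> pd.DataFrame:
    """Per-well metrics table for a list of culture counts.

    Columns: well, group, neuron_survival_pct, astro_survival_pct,
    in_pa_ratio, total_survival.
    """
    rows = []
    for c in counts:
        rows.append(
            {
                "well": c.well,
                "group": c.group,
                "neuron_survival_pct": survival_percent(
                    c.neuron_density, c.well_area, c.seeded_neurons
                ),
                "astro_survival_pct": survival_percent(
                    c.astro_density, c.well_area, c.seeded_astros
                ),
                "in_pa_ratio": cell_type_ratio(c.neuron_density, c.astro_density),
                "total_survival": total_survival_rate(c),
            }
        )
    return pd.DataFrame(rows)
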