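"""Survival and composition metrics from endpoint nuclei counts.

Uses a published-scale example: a 384-well coculture (10.6276 mm² growth
area) seeded with 15,000 neurons and 2,500 astrocytes, with endpoint
densities from automated nuclei classification.
"""

from platecal.culture_metrics import (
    PIXEL_AREA_96_UM2,
    WELL_AREA_384_MM2,
    CultureCounts,
    cell_type_ratio,
    cells_per_pixel,
    marker_specificity_jsd,
    survival_percent,
    total_survival_rate,
)

neuron_density, astro_density = 998.4, 194.4  # nuclei/mm^2 at day 28

print(f"neuron survival: {survival_percent(neuron_density, WELL_AREA_384_MM2, 15000):.1f} %")
print(f"astro survival:  {survival_percent(astro_density, WELL_AREA_384_MM2, 2500):.1f} %")
print(f"iN/pA ratio:     {cell_type_ratio(neuron_density, astro_density):.2f}")
counts = CultureCounts("A1", neuron_density, astro_density,
                       WELL_AREA_384_MM2, 15000, 2500)
print(f"total survival:  {total_survival_rate(counts):.2f}")

# 96-well pixel-resolution setting: cells covered by one 284x284 um pixel
print(f"neurons/pixel:   {cells_per_pixel(1307, PIXEL_AREA_96_UM2, round_int=True):.0f}")
print(f"astros/pixel:    {cells_per_pixel(331, PIXEL_AREA_96_UM2):.1f}")

# marker-gene specificity: 1 = expressed in the target cluster only
import pandas as pd

profile = pd.DataFrame(
    {"neuron": [12.0, 0.1, 2.0], "astro": [0.2, 9.0, 2.0], "gaba": [0.1, 0.2, 2.0]},
    index=["MAP2", "CD44", "ACTB"],
)
for gene, cluster in [("MAP2", "neuron"), ("CD44", "astro"), ("ACTB", "neuron")]:
    s = marker_specificity_jsd(profile, gene, cluster)
    print(f"specificity of {gene} for {cluster}: {s:.3f}")
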