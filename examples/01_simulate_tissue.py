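"""Generate a synthetic dystrophic-muscle section with a planted lesion.

Builds a 40x40 hex spot lattice (100 um spacing) with one r = 300 um
necrotic lesion, zone-structured negative-binomial counts for the A/B/C
marker panels and an immunofluorescence-style labeled cell layer, then
prints what was planted.
"""

import rizmap as rz

tissue = rz.simulate_tissue(seed=1, condition="organized")

print(f"lattice: {tissue.lattice.n_spots} spots "
      f"({tissue.lattice.lattice_kind}, {tissue.lattice.spacing_um:.0f} um spacing)")
print(f"lesion center (um): {tissue.truth.lesion_centers[0].round(1)}, "
      f"radius {tissue.truth.lesion_radii[0]:.0f} um")
print("true zone occupancy (spots):")
print(tissue.truth.true_zone_per_spot.value_counts().to_string())
print(f"expression: {tissue.adata.n_vars} genes "
      f"({len(tissue.panel.genes)} zone markers + background)")
print(f"cell layer: {len(tissue.cells)} labeled cells in classes "
      f"{sorted(tissue.cells.cell_class.unique())}")

# Zone A spots sit inside the lesion disk, zone B in the 100-um barrier
# annulus, zone C in the 440-um regenerating periphery; the cell classes
# mirror the IF markers CCL2 (A), MMP12 (B) and eMyHC (C).
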