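"""Boundary-referenced radial cell-density profiles.

Bins the simulated immunofluorescence-style cell layer by signed distance
to the necrotic lesion boundary (negative inside, positive outside, 50-um
bins from -100 to +450 um) and prints densities per class, plus each
class's mean boundary distance within +-500 um.
"""

import rizmap as rz

tissue = rz.simulate_tissue(seed=1, condition="organized")
geometry = tissue.truth.geometry  # analytic disk geometry of the planted lesion

profile = rz.radial_density(tissue.cells, geometry)
table = profile.table.pivot(index=["lo_um", "hi_um"], columns="cell_class",
                            values="density_per_mm2").round(1)
print("cell density (per mm^2) by signed-distance bin:")
print(table.to_string())
print(f"\npoints beyond the binned range: {profile.overflow}")

for cls in sorted(tissue.cells["cell_class"].unique()):
    m = rz.mean_boundary_distance(tissue.cells, geometry, cls)
    print(f"mean boundary distance of {cls}: {m:+.0f} um")

# CCL2+ cells concentrate inside the boundary (zone A), MMP12+ in the
# first outside bins (zone B barrier) and eMyHC+ regenerating fibers
# peak 100-440 um outside (zone C), so their mean distances order
# CCL2 < MMP12 < eMyHC.
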