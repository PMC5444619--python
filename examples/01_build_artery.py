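"""Build the voxelized coronary artery and inspect its geometry.

The vessel is a straight cylinder on a 100 um voxel lattice: an 1800 um
lumen, a one-voxel endothelial shell and a 600 um wall, 6 mm long.
"""

import numpy as np

from atherosim import GeometrySpec, build_artery, insert_spherical_plaque, \
    plane_areas

lat = build_artery(GeometrySpec())
print(f"lattice dims: {lat.dims}  (voxels of {lat.patch_size_um:.0f} um)")
print(f"lumen voxels per plane: {lat.lumen_count_per_plane()[0]}")
print(f"total lumen volume: {lat.total_lumen_voxels()} patches")

# carve a 1 mm plaque bulging from the endothelium at mid-artery
cx, cy = lat.axis_xy
h = lat.patch_size_um
insert_spherical_plaque(lat, (cx * h + 1800.0, cy * h, 3000.0), 1000.0)

z = lat.nz // 2
lumen, plaque = plane_areas(lat, z)
print(f"\nafter plaque insertion, mid-plane {z}:")
print(f"  lumen area  = {lumen} patches")
print(f"  plaque area = {plaque} patches (wall voxels holding foam cells)")
print(f"  stenosis severity = {lat.severity(z):.1%} of the healthy lumen")
# The severity is the fraction of the healthy cross-section the plaque has
# swallowed; ~14 % puts this fixture in the 'medium' (5-20 %) class.
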