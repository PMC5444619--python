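"""Export the luminal surface as STL and a lattice snapshot as VTK/CSV.

The endothelial voxel ring is saw-toothed; the exporter sorts EC centroids
azimuthally, smooths each ring and stitches a watertight triangle mesh --
the same surface a CFD package would receive for a 3D flow solve.
"""

import pathlib

from atherosim import GeometrySpec, build_artery, export_lumen_surface, \
    insert_spherical_plaque

out = pathlib.Path("surfaces")
out.mkdir(exist_ok=True)

lat = build_artery(GeometrySpec())
cx, cy = lat.axis_xy
h = lat.patch_size_um
insert_spherical_plaque(lat, (cx * h + 1800.0, cy * h, 3000.0), 1500.0)

mesh = export_lumen_surface(lat, out / "lumen.stl")
print(f"lumen.stl: {len(mesh.vertices)} vertices, {len(mesh.faces)} "
      f"triangles, watertight={mesh.is_watertight}")

lat.write_csv(out / "lattice.csv")
lat.write_vtk(out / "lattice.vtk")
print("lattice.csv / lattice.vtk: per-voxel class, cell count and "
      "occupied volume")
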