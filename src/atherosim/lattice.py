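"""The 3D voxel world: artery geometry, voxel classes and occupancy.

The artery is a straight cylinder discretized into cubic 100 um voxels
("patches"). Each voxel carries exactly one class:

* ``LUMEN``    -- blood-filled interior,
* ``EC``       -- the single-voxel endothelial shell facing the lumen,
* ``WALL``     -- media/adventitia tissue (uniform composition),
* ``EXTERIOR`` -- space outside the vessel, available for outward remodeling.

Voxel membership is decided by a center-in-region test: the voxel at integer
index ``(i, j, k)`` has its center at ``(i + 0.5, j + 0.5, k + 0.5) * 100 um``
and belongs to the lumen when the center lies within the lumen radius of the
z-axis (the flow axis, inlet at ``z = 0``). The endothelium is re-derived from
adjacency whenever the geometry changes: every wall-material voxel that is
face-adjacent to a lumen voxel is EC, the rest are WALL. This keeps the EC
shell closed under plaque insertion and remodeling.

Occupancy bookkeeping (cell counts and occupied cell volume per voxel) lives
on the lattice so that area queries such as :func:`plane_areas` need no other
object. The agent population (see :mod:`atherosim.agents`) mutates these
arrays in place.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from . import params

LUMEN: int = 0
EC: int = 1
WALL: int = 2
EXTERIOR: int = 3

CLASS_NAMES = {LUMEN: "LUMEN", EC: "EC", WALL: "WALL", EXTERIOR: "EXTERIOR"}

#: face-adjacent (6-connected) neighbor offsets
FACE_OFFSETS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
)


class ConfigurationError(ValueError):
    """Raised when a geometry spec cannot produce a valid artery."""


class TopologyError(RuntimeError):
    """Raised when a geometry edit would break the vessel topology."""


@dataclasses.dataclass(frozen=True)
class GeometrySpec:
    """Cylindrical artery geometry in physical units.

    All lengths must be positive multiples of the 100 um patch size.
    ``plaques`` is an optional list of ``(center_xyz_um, radius_um)`` spheres
    inserted after the healthy vessel is built.
    """

    lumen_radius_um: float = params.LUMEN_RADIUS_UM
    wall_thickness_um: float = params.WALL_THICKNESS_UM
    length_um: float = params.ARTERY_LENGTH_UM
    plaques: tuple[tuple[tuple[float, float, float], float], ...] = ()

    def __post_init__(self) -> None:
        h = params.PATCH_SIZE_UM
        for name in ("lumen_radius_um", "wall_thickness_um", "length_um"):
            value = getattr(self, name)
            if value < h or abs(value / h - round(value / h)) > 1e-9:
                raise ConfigurationError(
                    f"{name}={value} must be a positive multiple of the "
                    f"{h} um patch size"
                )


class ArteryLattice:
    """Voxelized artery with per-voxel class, occupancy and species support.

    Attributes
    ----------
    patch_class : (nx, ny, nz) uint8 array of voxel classes.
    occupied_volume_um3 : per-voxel occupied cell volume (float64).
    agent_count : per-voxel count of leukocyte-derived agents (int32).
    capacity_fraction : cell-available fraction of a wall voxel (0.40
        normally, 0.04 in accelerated mode).
    """

    def __init__(
        self,
        spec: GeometrySpec,
        patch_class: np.ndarray,
        axis_xy: tuple[float, float],
        capacity_fraction: float = params.CAPACITY_FRACTION_NORMAL,
    ) -> None:
        self.spec = spec
        self.patch_size_um = params.PATCH_SIZE_UM
        self.patch_class = patch_class
        self.dims = patch_class.shape
        self.axis_xy = axis_xy                      # in voxel units
        self.ecm_fraction = params.ECM_FRACTION
        self.capacity_fraction = float(capacity_fraction)
        self.occupied_volume_um3 = np.zeros(self.dims, dtype=np.float64)
        self.agent_count = np.zeros(self.dims, dtype=np.int32)
        # healthy per-plane lumen count, the stenosis reference
        self.reference_lumen_count = int(np.count_nonzero(patch_class[:, :, 0] == LUMEN))

    # -- basic queries --------------------------------------------------------

    @property
    def nx(self) -> int:
        return self.dims[0]

    @property
    def ny(self) -> int:
        return self.dims[1]

    @property
    def nz(self) -> int:
        return self.dims[2]

    @property
    def voxel_capacity_um3(self) -> float:
        """Cell-available volume of one wall voxel."""
        return self.capacity_fraction * params.PATCH_VOLUME_UM3

    def lumen_count_per_plane(self) -> np.ndarray:
        """Number of lumen voxels in each z-plane (length nz)."""
        return np.count_nonzero(self.patch_class == LUMEN, axis=(0, 1))

    def total_lumen_voxels(self) -> int:
        return int(np.count_nonzero(self.patch_class == LUMEN))

    def severity(self, z: int) -> float:
        """Per-plane stenosis severity, 1 - lumen_count / healthy count."""
        count = int(np.count_nonzero(self.patch_class[:, :, z] == LUMEN))
        return 1.0 - count / self.reference_lumen_count

    def radial_distance(self) -> np.ndarray:
        """(nx, ny) distances of voxel centers from the axis, voxel units."""
        cx, cy = self.axis_xy
        dx = np.arange(self.nx) + 0.5 - cx
        dy = np.arange(self.ny) + 0.5 - cy
        return np.hypot(dx[:, None], dy[None, :])

    def voxel_centers_um(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h = self.patch_size_um
        x = (np.arange(self.nx) + 0.5) * h
        y = (np.arange(self.ny) + 0.5) * h
        z = (np.arange(self.nz) + 0.5) * h
        return x, y, z

    # -- geometry edits -------------------------------------------------------

    def recompute_shell(self) -> None:
        """Re-derive the EC shell from lumen adjacency.

        Wall-material voxels (EC or WALL) that are 6-adjacent to at least one
        LUMEN voxel become EC; all other wall material becomes WALL.
        """
        cls = self.patch_class
        is_lumen = cls == LUMEN
        is_material = (cls == EC) | (cls == WALL)
        touches = np.zeros(self.dims, dtype=bool)
        for dx, dy, dz in FACE_OFFSETS:
            shifted = np.zeros(self.dims, dtype=bool)
            src = _shift_slices(self.dims, dx, dy, dz)
            dst = _shift_slices(self.dims, -dx, -dy, -dz)
            shifted[dst] = is_lumen[src]
            touches |= shifted
        cls[is_material & touches] = EC
        cls[is_material & ~touches] = WALL

    def class_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.patch_class, return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))

    # -- serialization --------------------------------------------------------

    def to_dataframe(self, species: Optional[dict[str, np.ndarray]] = None):
        """Voxel table (x, y, z, class, agent count, occupied volume, fields)."""
        import pandas as pd

        ii, jj, kk = np.indices(self.dims)
        data = {
            "x": ii.ravel(),
            "y": jj.ravel(),
            "z": kk.ravel(),
            "patch_class": [CLASS_NAMES[c] for c in self.patch_class.ravel()],
            "agent_count": self.agent_count.ravel(),
            "occupied_volume_um3": self.occupied_volume_um3.ravel(),
        }
        if species:
            for name, field in species.items():
                data[name] = field.ravel()
        return pd.DataFrame(data)

    def write_csv(self, path, species: Optional[dict[str, np.ndarray]] = None) -> None:
        self.to_dataframe(species).to_csv(path, index=False)

    def write_vtk(self, path, species: Optional[dict[str, np.ndarray]] = None) -> None:
        """Legacy ASCII VTK STRUCTURED_POINTS snapshot for visualization."""
        fields: dict[str, np.ndarray] = {
            "patch_class": self.patch_class.astype(np.int32),
            "agent_count": self.agent_count,
            "occupied_volume_um3": self.occupied_volume_um3,
        }
        if species:
            fields.update(species)
        nx, ny, nz = self.dims
        with open(path, "w") as fh:
            fh.write("# vtk DataFile Version 3.0\n")
            fh.write("atherosim lattice snapshot\nASCII\n")
            fh.write("DATASET STRUCTURED_POINTS\n")
            fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
            fh.write("ORIGIN 0 0 0\n")
            h = self.patch_size_um
            fh.write(f"SPACING {h} {h} {h}\n")
            fh.write(f"POINT_DATA {nx * ny * nz}\n")
            for name, field in fields.items():
                kind = "int" if np.issubdtype(field.dtype, np.integer) else "float"
                fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
                # VTK expects x varying fastest
                flat = np.transpose(field, (2, 1, 0)).ravel()
                np.savetxt(fh, flat[None] if flat.ndim == 1 else flat, fmt="%g",
                           delimiter=" ", newline="\n")


def _shift_slices(dims, dx, dy, dz):
    """Slices selecting the source region for a shift by (dx, dy, dz)."""
    out = []
    for n, d in zip(dims, (dx, dy, dz)):
        if d > 0:
            out.append(slice(d, n))
        elif d < 0:
            out.append(slice(0, n + d))
        else:
            out.append(slice(0, n))
    return tuple(out)


def build_artery(
    spec: GeometrySpec,
    capacity_fraction: float = params.CAPACITY_FRACTION_NORMAL,
    exterior_padding_voxels: int = 12,
) -> ArteryLattice:
    """Build the healthy cylindrical artery described by ``spec``.

    Voxels whose center lies within the lumen radius of the z-axis are LUMEN;
    the single-voxel shell of wall material around them is EC; the remaining
    ``wall_thickness / 100`` shells are WALL; everything else is EXTERIOR
    (with ``exterior_padding_voxels`` of outward-growth headroom).
    """
    h = params.PATCH_SIZE_UM
    r_lumen = spec.lumen_radius_um / h
    n_wall = int(round(spec.wall_thickness_um / h))
    if n_wall < 1:
        raise ConfigurationError("wall must contain at least one 100 um shell")
    outer = int(np.ceil(r_lumen)) + 1 + n_wall
    half = outer + exterior_padding_voxels
    nx = ny = 2 * half
    nz = int(round(spec.length_um / h))
    cx = cy = half  # axis position in voxel units

    dx = np.arange(nx) + 0.5 - cx
    dy = np.arange(ny) + 0.5 - cy
    d = np.hypot(dx[:, None], dy[None, :])
    cross = np.full((nx, ny), EXTERIOR, dtype=np.uint8)
    cross[d < r_lumen + 1 + n_wall] = WALL
    cross[d < r_lumen] = LUMEN
    patch_class = np.repeat(cross[:, :, None], nz, axis=2)

    lat = ArteryLattice(spec, patch_class, (cx, cy), capacity_fraction)
    lat.recompute_shell()
    if not np.any(lat.patch_class == LUMEN):
        raise ConfigurationError("spec produces no lumen voxels")
    for center, radius in spec.plaques:
        insert_spherical_plaque(lat, center, radius)
    return lat


def insert_spherical_plaque(
    lattice: ArteryLattice,
    center_um: Sequence[float],
    radius_um: float,
    population=None,
    inert: bool = False,
) -> ArteryLattice:
    """Carve a spherical plaque into the vessel.

    Lumen voxels whose center lies inside the sphere become WALL; the EC shell
    is re-derived; wall voxels inside the sphere are then filled to capacity
    with foam-cell agents (the plaque body; with ``inert=True`` the body is
    cytokine-silent plaque mass instead of active foam cells). ``population``, when given, is an
    :class:`atherosim.agents.Population` receiving those agents; otherwise
    only the occupancy arrays are updated.

    Raises
    ------
    TopologyError
        if the sphere would swallow every lumen voxel of some plane
        (total occlusion is unsupported).
    """
    if radius_um <= 0:
        return lattice
    h = lattice.patch_size_um
    x, y, z = lattice.voxel_centers_um()
    dist2 = (
        (x[:, None, None] - center_um[0]) ** 2
        + (y[None, :, None] - center_um[1]) ** 2
        + (z[None, None, :] - center_um[2]) ** 2
    )
    inside = dist2 < radius_um ** 2
    cls = lattice.patch_class
    converting = inside & (cls == LUMEN)

    lumen_per_plane = lattice.lumen_count_per_plane()
    converted_per_plane = np.count_nonzero(converting, axis=(0, 1))
    if np.any((lumen_per_plane > 0) & (converted_per_plane >= lumen_per_plane)):
        raise TopologyError("plaque sphere would occlude an entire plane")

    cls[converting] = WALL
    lattice.recompute_shell()

    body = inside & (cls == WALL)
    _fill_with_foam(lattice, body, population, inert)
    return lattice


def _fill_with_foam(lattice: ArteryLattice, mask: np.ndarray, population,
                    inert: bool = False) -> None:
    foam_volume = params.CELL_VOLUME_UM3["FOAM"]
    per_voxel = int(lattice.voxel_capacity_um3 // foam_volume)
    per_voxel = max(per_voxel, 1)
    voxels = np.argwhere(mask)
    if population is not None:
        from .agents import FOAM, PLAQUE  # local import to avoid a cycle

        code = PLAQUE if inert else FOAM
        for i, j, k in voxels:
            population.add_agents(code, (int(i), int(j), int(k)), per_voxel,
                                  enforce_capacity=False)
    else:
        lattice.agent_count[mask] += per_voxel
        lattice.occupied_volume_um3[mask] += per_voxel * foam_volume


def plane_areas(lattice: ArteryLattice, z: int) -> tuple[int, int]:
    """Lumen and plaque areas of plane ``z`` in integer patch counts.

    Lumen area is the number of LUMEN voxels; plaque area is the number of
    wall voxels that contain at least one leukocyte-derived agent
    (leukocytes, macrophages or foam cells).
    """
    if not 0 <= z < lattice.nz:
        raise IndexError(f"plane index {z} out of range 0..{lattice.nz - 1}")
    cls = lattice.patch_class[:, :, z]
    lumen = int(np.count_nonzero(cls == LUMEN))
    plaque = int(np.count_nonzero((cls == WALL) & (lattice.agent_count[:, :, z] > 0)))
    return lumen, plaque
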