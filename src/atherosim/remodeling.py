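"""Glagov compensatory remodeling: outward growth first, then encroachment.

Per z-plane, whenever accumulated plaque mass demands a new voxel of wall,
the vessel remodels. While the plaque occupies less than 40 % of the plane's
lumen area the artery compensates purely outward -- an exterior voxel next
to the most burdened wall sector becomes wall, and the lumen is preserved.
At or beyond the 40 % threshold each growth event is inward with probability
0.65 (a lumen voxel adjacent to the most burdened endothelial segment
becomes wall, the endothelial shell is re-derived and the lumen shrinks by
exactly one patch) and outward otherwise.

Growth demand is driven by crowding: transmigrating cells may transiently
overfill their entry voxel when the local neighborhood is saturated, and
macrophage-to-foam-cell conversion swells resident volume. The demand of a
plane is the overflow volume (occupied minus capacity, summed over its
voxels) in units of one voxel's cell capacity, floored. After conversion the
overflow agents are rehomed into freed space -- tissue displacement: even
foam cells, which chemotaxis never moves, are pushed along by the growing
wall -- so voxel capacity is respected again at the end of the tick up to
the sub-capacity floor residual.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import params
from .agents import VOLUMES, Population
from .lattice import (EC, EXTERIOR, LUMEN, WALL, ArteryLattice, TopologyError,
                      plane_areas)


@dataclasses.dataclass(frozen=True)
class RemodelingPolicy:
    glagov_threshold: float = params.GLAGOV_THRESHOLD
    inward_fraction: float = params.INWARD_FRACTION

    @property
    def outward_fraction(self) -> float:
        return 1.0 - self.inward_fraction


@dataclasses.dataclass
class RemodelEvent:
    tick: int
    z: int
    direction: str          # "inward" | "outward"
    voxel: tuple[int, int, int]


def plane_overflow_volume(lattice: ArteryLattice, z: int) -> float:
    """Occupied volume beyond capacity, summed over the plane's wall voxels."""
    cls = lattice.patch_class[:, :, z]
    wall = cls == WALL
    over = lattice.occupied_volume_um3[:, :, z][wall] - lattice.voxel_capacity_um3
    return float(np.sum(np.maximum(0.0, over)))


def growth_demand(lattice: ArteryLattice, z: int) -> int:
    """Voxels of new wall required by plane ``z`` (floor of excess/capacity)."""
    return int(plane_overflow_volume(lattice, z) // lattice.voxel_capacity_um3)


def _burden_map(lattice: ArteryLattice, z: int) -> np.ndarray:
    """Occupied cell volume per (x, y) in plane z and its two axial neighbors."""
    lo, hi = max(0, z - 1), min(lattice.nz, z + 2)
    return lattice.occupied_volume_um3[:, :, lo:hi].sum(axis=2)


def _neighbor_sum(field: np.ndarray) -> np.ndarray:
    """Sum of a 2D field over the 8-neighborhood of each cell (plus itself)."""
    out = np.zeros_like(field)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            out += np.roll(np.roll(field, dx, axis=0), dy, axis=1)
    return out


def _grow_outward(lattice: ArteryLattice, z: int,
                  rng: np.random.Generator) -> tuple[int, int, int]:
    cls = lattice.patch_class[:, :, z]
    burden = _neighbor_sum(_burden_map(lattice, z))
    is_ext = cls == EXTERIOR
    wall_adjacent = np.zeros_like(is_ext)
    is_wall = cls == WALL
    for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        wall_adjacent |= np.roll(np.roll(is_wall, dx, axis=0), dy, axis=1)
    candidates = np.argwhere(is_ext & wall_adjacent)
    if candidates.size == 0:
        raise TopologyError(f"no exterior voxel available in plane {z}")
    scores = burden[candidates[:, 0], candidates[:, 1]]
    best = candidates[scores == scores.max()]
    i, j = best[int(rng.integers(len(best)))]
    lattice.patch_class[i, j, z] = WALL
    return int(i), int(j), z


def _grow_inward(lattice: ArteryLattice, z: int,
                 rng: np.random.Generator) -> tuple[int, int, int]:
    cls = lattice.patch_class[:, :, z]
    lumen_count = int(np.count_nonzero(cls == LUMEN))
    if lumen_count <= 1:
        raise TopologyError(f"inward growth would occlude plane {z}")
    burden = _neighbor_sum(_burden_map(lattice, z))
    is_lumen = cls == LUMEN
    ec_adjacent = np.zeros_like(is_lumen)
    is_ec = cls == EC
    for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ec_adjacent |= np.roll(np.roll(is_ec, dx, axis=0), dy, axis=1)
    candidates = np.argwhere(is_lumen & ec_adjacent)
    if candidates.size == 0:
        raise TopologyError(f"no lumen voxel borders the endothelium, plane {z}")
    scores = burden[candidates[:, 0], candidates[:, 1]]
    best = candidates[scores == scores.max()]
    i, j = best[int(rng.integers(len(best)))]
    lattice.patch_class[i, j, z] = WALL
    return int(i), int(j), z


def relieve_overflow(lattice: ArteryLattice, population: Population,
                     planes: set[int]) -> int:
    """Move agents out of over-capacity voxels into free wall space.

    Works plane by plane, nearest free voxel first. Returns the number of
    agents relocated. Unlike chemotaxis (where foam cells are fixed), this
    models tissue displacement by the remodeling wall, so any cell type may
    be pushed into the newly created voxels; otherwise a foam-packed voxel
    would re-demand growth every tick forever.
    """
    moved = 0
    cap = lattice.voxel_capacity_um3
    size = population.size
    live = population.alive[:size]
    vox = population.voxel[:size]
    codes = population.type_code[:size]
    # slot lookup by voxel via one sort of the live agents
    eligible = np.flatnonzero(live)
    order = eligible[np.argsort(vox[eligible], kind="stable")]
    sorted_vox = vox[order]
    for z in planes:
        cls = lattice.patch_class[:, :, z]
        over_xy = np.argwhere(
            (cls == WALL)
            & (lattice.occupied_volume_um3[:, :, z] > cap + 1e-9))
        if over_xy.size == 0:
            continue
        for i, j in over_xy:
            flat = int(np.ravel_multi_index((i, j, z), lattice.dims))
            lo = np.searchsorted(sorted_vox, flat, side="left")
            hi = np.searchsorted(sorted_vox, flat, side="right")
            here = order[lo:hi]
            # newest agents leave first (they caused the overflow)
            for slot in here[::-1]:
                if lattice.occupied_volume_um3[i, j, z] <= cap + 1e-9:
                    break
                free = cap - lattice.occupied_volume_um3[:, :, z]
                ok = (cls == WALL) & (free >= float(VOLUMES[codes[slot]]))
                targets = np.argwhere(ok)
                if targets.size == 0:
                    break
                d2 = (targets[:, 0] - i) ** 2 + (targets[:, 1] - j) ** 2
                ti, tj = targets[int(np.argmin(d2))]
                population._move(slot, int(np.ravel_multi_index(
                    (ti, tj, z), lattice.dims)))
                moved += 1
    return moved


def glagov_tick(lattice: ArteryLattice, population: Population,
                policy: RemodelingPolicy, rng: np.random.Generator,
                tick: int = 0) -> list[RemodelEvent]:
    """One remodeling pass over all planes; returns the growth events."""
    events: list[RemodelEvent] = []
    touched: set[int] = set()
    shell_dirty = False
    for z in range(lattice.nz):
        demand = growth_demand(lattice, z)
        for _ in range(demand):
            lumen, plaque = plane_areas(lattice, z)
            at_threshold = plaque >= policy.glagov_threshold * lumen
            inward = at_threshold and (rng.random() < policy.inward_fraction)
            if inward:
                voxel = _grow_inward(lattice, z, rng)
                events.append(RemodelEvent(tick, z, "inward", voxel))
            else:
                voxel = _grow_outward(lattice, z, rng)
                events.append(RemodelEvent(tick, z, "outward", voxel))
            shell_dirty = True
            touched.add(z)
    if shell_dirty:
        lattice.recompute_shell()
    if touched:
        relieve_overflow(lattice, population, touched)
    return events
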