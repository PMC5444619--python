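"""Leukocyte-derived agents inside the artery wall.

Agents are stored structure-of-arrays (type code, voxel, age, alive flag) and
mutate the lattice occupancy arrays in place. Seven types exist: the three
blood leukocytes (neutrophil, monocyte, lymphocyte), the two macrophage
phenotypes a monocyte differentiates into on wall entry (M1 pro-inflammatory
: M2 anti-inflammatory = 2:1), foam cells, which macrophages become in
voxels whose oxLDL exceeds 100 ug/ml, and inert seeded plaque mass (the
body of a synthetic plaque fixture). Foam cells and plaque mass are
immobile and immortal; every other type chemotaxes and dies of old age
(neutrophils after 72 ticks, the monocyte lineage and lymphocytes after
168).

Chemotaxis follows a space-first rule: an agent surveys its 26-connected
neighborhood, keeps only WALL voxels with enough free capacity for its own
volume, and moves to the admissible neighbor with the highest
pro-inflammatory cytokine concentration (TNF-alpha + IL-1beta) -- but only
if that beats the concentration where it stands, unless its current voxel is
over capacity, in which case vacating takes priority. Ties break uniformly
at random from a dedicated RNG stream. The default step budget is one voxel
(100 um) per 1 h tick.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import params
from .lattice import ArteryLattice, WALL

#: PLAQUE is seeded, inert plaque mass (a synthetic fixture body): it holds
#: volume and counts toward plaque area like a foam cell, but produces no
#: cytokines, never moves in chemotaxis, and never dies.
NEUTROPHIL, MONOCYTE, LYMPHOCYTE, M1, M2, FOAM, PLAQUE = range(7)
TYPE_NAMES = ("NEUTROPHIL", "MONOCYTE", "LYMPHOCYTE", "M1", "M2", "FOAM",
              "PLAQUE")
TYPE_CODES = {name: code for code, name in enumerate(TYPE_NAMES)}

VOLUMES = np.array([params.CELL_VOLUME_UM3.get(t, params.CELL_VOLUME_UM3["FOAM"])
                    for t in TYPE_NAMES])
_NO_DEATH = np.iinfo(np.int32).max
LIFESPANS = np.array(
    [params.LIFESPAN_TICKS.get(t) if params.LIFESPAN_TICKS.get(t) is not None
     else _NO_DEATH for t in TYPE_NAMES], dtype=np.int64)
MOVABLE = np.array([True, True, True, True, True, False, False])


def moore_offsets() -> np.ndarray:
    """The 26 offsets of the 3D Moore neighborhood."""
    out = [(dx, dy, dz)
           for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
           if (dx, dy, dz) != (0, 0, 0)]
    return np.array(out, dtype=np.int64)


_MOORE = moore_offsets()


class Population:
    """All wall agents of one simulation, bound to a lattice."""

    def __init__(self, lattice: ArteryLattice, initial_capacity: int = 1024):
        self.lattice = lattice
        n = initial_capacity
        self.type_code = np.zeros(n, dtype=np.int8)
        self.voxel = np.zeros(n, dtype=np.int64)       # flat C-order index
        self.age = np.zeros(n, dtype=np.int32)
        self.alive = np.zeros(n, dtype=bool)
        self.size = 0
        # per-type per-voxel counts, kept in sync for cytokine production
        self.counts = {name: np.zeros(lattice.dims, dtype=np.int32)
                       for name in TYPE_NAMES}

    # -- low-level bookkeeping ------------------------------------------------

    def _grow(self, needed: int) -> None:
        cap = self.type_code.size
        if self.size + needed <= cap:
            return
        new_cap = max(2 * cap, self.size + needed)
        for name in ("type_code", "voxel", "age", "alive"):
            arr = getattr(self, name)
            grown = np.zeros(new_cap, dtype=arr.dtype)
            grown[: self.size] = arr[: self.size]
            setattr(self, name, grown)

    def add_agents(self, type_code: int, voxel_ijk, count: int = 1,
                   enforce_capacity: bool = False) -> int:
        """Append ``count`` agents of one type to a voxel; returns #added."""
        if count <= 0:
            return 0
        lat = self.lattice
        flat = int(np.ravel_multi_index(tuple(voxel_ijk), lat.dims))
        vol = VOLUMES[type_code]
        if enforce_capacity:
            free = lat.voxel_capacity_um3 - lat.occupied_volume_um3.ravel()[flat]
            count = min(count, int(free // vol))
            if count <= 0:
                return 0
        self._grow(count)
        sl = slice(self.size, self.size + count)
        self.type_code[sl] = type_code
        self.voxel[sl] = flat
        self.age[sl] = 0
        self.alive[sl] = True
        self.size += count
        i, j, k = voxel_ijk
        lat.agent_count[i, j, k] += count
        lat.occupied_volume_um3[i, j, k] += count * vol
        self.counts[TYPE_NAMES[type_code]][i, j, k] += count
        return count

    def _apply_delta(self, flats: np.ndarray, codes: np.ndarray,
                     sign: float) -> None:
        """Batch occupancy update for agents at flat voxels ``flats``."""
        lat = self.lattice
        count = lat.agent_count.ravel()
        volume = lat.occupied_volume_um3.ravel()
        np.add.at(count, flats, int(sign))
        np.add.at(volume, flats, sign * VOLUMES[codes])
        for code in np.unique(codes):
            sel = flats[codes == code]
            np.add.at(self.counts[TYPE_NAMES[code]].ravel(), sel, int(sign))

    def _remove(self, mask: np.ndarray) -> None:
        """Mark agents dead and release their voxel volume (``mask`` over slots)."""
        idx = np.flatnonzero(mask[: self.size] & self.alive[: self.size])
        if idx.size == 0:
            return
        self._apply_delta(self.voxel[idx], self.type_code[idx], -1.0)
        self.alive[idx] = False

    def _move(self, slot: int, new_flat: int) -> None:
        lat = self.lattice
        code = self.type_code[slot]
        old = np.unravel_index(self.voxel[slot], lat.dims)
        new = np.unravel_index(new_flat, lat.dims)
        vol = VOLUMES[code]
        lat.agent_count[old] -= 1
        lat.occupied_volume_um3[old] -= vol
        lat.agent_count[new] += 1
        lat.occupied_volume_um3[new] += vol
        self.counts[TYPE_NAMES[code]][old] -= 1
        self.counts[TYPE_NAMES[code]][new] += 1
        self.voxel[slot] = new_flat

    def _retype(self, slots: np.ndarray, new_code: int) -> None:
        if len(slots) == 0:
            return
        flats = self.voxel[slots]
        codes = self.type_code[slots]
        self._apply_delta(flats, codes, -1.0)
        self.type_code[slots] = new_code
        self._apply_delta(flats, self.type_code[slots], +1.0)

    def compact(self) -> None:
        keep = self.alive[: self.size]
        n = int(np.count_nonzero(keep))
        for name in ("type_code", "voxel", "age", "alive"):
            arr = getattr(self, name)
            arr[:n] = arr[: self.size][keep]
            setattr(self, name, arr)
        self.size = n

    # -- census / audits ------------------------------------------------------

    def census(self) -> dict[str, int]:
        out = {}
        alive = self.alive[: self.size]
        codes = self.type_code[: self.size][alive]
        for code, name in enumerate(TYPE_NAMES):
            out[name] = int(np.count_nonzero(codes == code))
        return out

    def total_alive(self) -> int:
        return int(np.count_nonzero(self.alive[: self.size]))

    def recount(self) -> tuple[np.ndarray, np.ndarray]:
        """Occupancy recomputed from scratch (count, volume per voxel)."""
        lat = self.lattice
        count = np.zeros(lat.dims, dtype=np.int64).ravel()
        volume = np.zeros(lat.dims).ravel()
        alive = self.alive[: self.size]
        vox = self.voxel[: self.size][alive]
        codes = self.type_code[: self.size][alive]
        np.add.at(count, vox, 1)
        np.add.at(volume, vox, VOLUMES[codes])
        return count.reshape(lat.dims), volume.reshape(lat.dims)

    def audit(self, atol: float = 1e-6) -> None:
        """Assert incremental occupancy bookkeeping matches a full recount."""
        count, volume = self.recount()
        if not np.array_equal(count, self.lattice.agent_count):
            raise AssertionError("agent_count bookkeeping out of sync")
        if not np.allclose(volume, self.lattice.occupied_volume_um3, atol=atol):
            raise AssertionError("occupied volume bookkeeping out of sync")
        by_type = np.zeros((len(TYPE_NAMES),) + self.lattice.dims, dtype=np.int32)
        alive = self.alive[: self.size]
        for code in range(len(TYPE_NAMES)):
            sel = self.voxel[: self.size][alive & (self.type_code[: self.size] == code)]
            flat = by_type[code].ravel()
            np.add.at(flat, sel, 1)
        for code, name in enumerate(TYPE_NAMES):
            if not np.array_equal(by_type[code].reshape(self.lattice.dims),
                                  self.counts[name]):
                raise AssertionError(f"per-type count map out of sync for {name}")

    # -- per-tick biology -----------------------------------------------------

    def differentiate_and_transform(self, oxldl: np.ndarray,
                                    rng: np.random.Generator) -> None:
        """Monocyte -> M1/M2 at wall entry; macrophage -> foam above threshold.

        Every undifferentiated monocyte present in the wall draws its
        permanent phenotype (P(M1) = 2/3). M1/M2 agents sitting in a voxel
        with oxLDL > 100 ug/ml become foam cells; the volume difference is
        charged to the voxel (remodeling absorbs any resulting excess).
        """
        live = self.alive[: self.size]
        codes = self.type_code[: self.size]
        monos = np.flatnonzero(live & (codes == MONOCYTE))
        if monos.size:
            draw = rng.random(monos.size) < params.M1_FRACTION
            self._retype(monos[draw], M1)
            self._retype(monos[~draw], M2)
        macs = np.flatnonzero(live & ((codes == M1) | (codes == M2)))
        if macs.size:
            ox_here = oxldl.ravel()[self.voxel[macs]]
            to_foam = macs[ox_here > params.OXLDL_FOAM_THRESHOLD_UG_ML]
            if to_foam.size:
                self._retype(to_foam, FOAM)

    def age_and_die(self) -> int:
        """Increment ages, remove agents past their lifespan; returns #deaths."""
        live = self.alive[: self.size]
        self.age[: self.size][live] += 1
        over = live & (self.age[: self.size] > LIFESPANS[self.type_code[: self.size]])
        n = int(np.count_nonzero(over))
        self._remove(over)
        if self.size and self.total_alive() < self.size // 2:
            self.compact()
        return n

    def chemotaxis_tick(self, attractant: np.ndarray,
                        rng: np.random.Generator,
                        step_budget: int = 1) -> int:
        """One tick of space-constrained chemotactic migration.

        Returns the number of moves performed. Agents are processed in slot
        order; the free-capacity map is updated as each agent moves, so later
        agents see earlier moves (sequential update, as in the underlying
        cellular-automaton formulation).
        """
        lat = self.lattice
        live = np.flatnonzero(self.alive[: self.size]
                              & MOVABLE[self.type_code[: self.size]])
        if live.size == 0:
            return 0
        free = (lat.voxel_capacity_um3 - lat.occupied_volume_um3).ravel().copy()
        is_wall = (lat.patch_class == WALL).ravel()
        moves = 0
        new_voxel = self.voxel.copy()
        for _ in range(step_budget):
            u = rng.random(live.size)
            moved = _chemo_kernel(
                new_voxel, live, self.type_code, VOLUMES,
                attractant.ravel(), free, is_wall,
                np.array(lat.dims, dtype=np.int64), _MOORE, u)
            moves += moved
            if moved == 0:
                break
        changed = np.flatnonzero(new_voxel[: self.size] != self.voxel[: self.size])
        if changed.size:
            codes = self.type_code[changed]
            self._apply_delta(self.voxel[changed], codes, -1.0)
            self._apply_delta(new_voxel[changed], codes, +1.0)
            self.voxel[changed] = new_voxel[changed]
        return moves

    def _append_batch(self, type_code: int, flats: np.ndarray) -> None:
        n = flats.size
        if n == 0:
            return
        self._grow(n)
        sl = slice(self.size, self.size + n)
        self.type_code[sl] = type_code
        self.voxel[sl] = flats
        self.age[sl] = 0
        self.alive[sl] = True
        self.size += n
        self._apply_delta(flats, np.full(n, type_code, dtype=np.int8), +1.0)

    def place_tem_cohorts(self, type_code: int, entry_flats: np.ndarray,
                          counts: np.ndarray, attractant: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
        """Place all TEM cohorts of one type for one tick (shared-path rule).

        Per entry patch, the first agent's chemotactic step is computed once
        and cohort members reuse that destination until its capacity fills;
        the remainder stay at the entry voxel (to be routed by the next
        chemotaxis tick). Entry voxels may transiently exceed capacity;
        remodeling relieves the overflow. Returns the flat destination
        voxel of every placed agent.
        """
        lat = self.lattice
        vol = VOLUMES[type_code]
        free = (lat.voxel_capacity_um3 - lat.occupied_volume_um3).ravel().copy()
        is_wall = (lat.patch_class == WALL).ravel()
        attract = attractant.ravel()
        dims = np.array(lat.dims, dtype=np.int64)
        us = rng.random(len(entry_flats))
        dests = []
        for n in range(len(entry_flats)):
            flat = int(entry_flats[n])
            cnt = int(counts[n])
            dest = int(_single_step_kernel(flat, vol, attract, free, is_wall,
                                           dims, _MOORE, us[n]))
            n_dest = cnt
            if dest != flat:
                n_dest = min(cnt, max(0, int(free[dest] // vol)))
            if n_dest:
                free[dest] -= n_dest * vol
                dests.append(np.full(n_dest, dest, dtype=np.int64))
            if cnt - n_dest:
                free[flat] -= (cnt - n_dest) * vol
                dests.append(np.full(cnt - n_dest, flat, dtype=np.int64))
        if not dests:
            return np.empty(0, dtype=np.int64)
        flats = np.concatenate(dests)
        self._append_batch(type_code, flats)
        return flats

    def shared_path_shortcut(self, type_code: int, entry_ijk, count: int,
                             attractant: np.ndarray,
                             rng: np.random.Generator) -> list[int]:
        """One TEM cohort entering through a single EC patch this tick."""
        lat = self.lattice
        entry_flat = np.ravel_multi_index(tuple(entry_ijk), lat.dims)
        return list(self.place_tem_cohorts(
            type_code, np.array([entry_flat]), np.array([count]),
            attractant, rng))


@njit(cache=True)
def _single_step_kernel(flat, vol, attract, free, is_wall, dims, moore,
                        u):  # pragma: no cover
    """Best admissible Moore neighbor for one agent (or its own voxel)."""
    nx, ny, nz = dims[0], dims[1], dims[2]
    k = flat % nz
    j = (flat // nz) % ny
    i = flat // (ny * nz)
    best = attract[flat]
    if free[flat] < 0.0:
        best = -1.0
    chosen = -1
    n_best = 0
    uu = u
    for a in range(moore.shape[0]):
        x = i + moore[a, 0]
        y = j + moore[a, 1]
        z = k + moore[a, 2]
        if x < 0 or x >= nx or y < 0 or y >= ny or z < 0 or z >= nz:
            continue
        nb = (x * ny + y) * nz + z
        if not is_wall[nb] or free[nb] < vol:
            continue
        val = attract[nb]
        if val > best:
            best = val
            chosen = nb
            n_best = 1
        elif val == best and n_best > 0:
            n_best += 1
            if uu * n_best < 1.0:
                chosen = nb
            uu = (uu * 16807.0 + 0.3721) % 1.0
    if chosen < 0:
        return flat
    return chosen


@njit(cache=True)
def _chemo_kernel(voxel, live, type_code, volumes, attract, free, is_wall,
                  dims, moore, u):  # pragma: no cover
    nx, ny, nz = dims[0], dims[1], dims[2]
    moved = 0
    for idx in range(live.size):
        slot = live[idx]
        flat = voxel[slot]
        vol = volumes[type_code[slot]]
        k = flat % nz
        j = (flat // nz) % ny
        i = flat // (ny * nz)
        over = free[flat] < 0.0       # current voxel beyond capacity
        best = attract[flat]
        if over:
            best = -1.0               # vacating dominates the gradient
        chosen = -1
        n_best = 0
        uu = u[idx]                   # hash-chained uniform for tie-breaks
        for a in range(moore.shape[0]):
            x = i + moore[a, 0]
            y = j + moore[a, 1]
            z = k + moore[a, 2]
            if x < 0 or x >= nx or y < 0 or y >= ny or z < 0 or z >= nz:
                continue
            nb = (x * ny + y) * nz + z
            if not is_wall[nb] or free[nb] < vol:
                continue
            val = attract[nb]
            if val > best:
                best = val
                chosen = nb
                n_best = 1
            elif val == best and n_best > 0:
                # reservoir-sample among ties; refresh the uniform each draw
                n_best += 1
                if uu * n_best < 1.0:
                    chosen = nb
                uu = (uu * 16807.0 + 0.3721) % 1.0
        if chosen >= 0:
            voxel[slot] = chosen
            free[flat] += vol
            free[chosen] -= vol
            moved += 1
    return moved
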