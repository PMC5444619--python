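"""Reaction-diffusion of cytokines and lipoproteins on the wall lattice.

Five scalar fields live on the wall domain (WALL plus EC voxels): the
pro-inflammatory cytokines TNF-alpha and IL-1beta, the anti-inflammatory
IL-10 (all in U/ml), and LDL / oxidized LDL (ng/ul, equivalently ug/ml).
Each 1 h tick applies, in order:

1. production by wall agents (per-cell rates),
2. IL-10-mediated clearance of the pro-inflammatory cytokines,
3. WSS-gated LDL influx at the endothelium,
4. LDL -> oxLDL oxidation (1.2 %/h),
5. Fickian diffusion with perfect-sink boundaries at the lumen and the outer
   wall surface (luminal convection washes solutes away).

The diffusion number of a full tick is D*dt/h^2 ~ 10.8 for the cytokines, far
beyond the explicit stability limit of 1/6 on a 3D lattice, so each tick is
split into sub-steps with per-step diffusion number <= 1/6. The sub-stepped
explicit kernel (numba) is the default; an unconditionally stable implicit
(backward Euler, scipy sparse) variant is available for cross-checking and
for coarse single-step use on small domains.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from numba import njit

from . import params
from .lattice import ArteryLattice, EC, WALL

SPECIES = ("TNFA", "IL1B", "IL10", "LDL", "OXLDL")

_NEIGHBOR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


class ValidationError(ValueError):
    pass


def make_stencil(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a boolean domain mask into an active-voxel neighbor table.

    Returns ``(active_index, neighbors)`` where ``active_index`` holds the
    flat (C-order) lattice indices of active voxels and ``neighbors`` is an
    ``(n_active, 6)`` int32 array of positions *within the active list*;
    ``-1`` marks a neighbor outside the domain (a sink, or a reflecting
    boundary in sealed mode).
    """
    dims = mask.shape
    flat_to_active = -np.ones(mask.size, dtype=np.int32)
    active_index = np.flatnonzero(mask.ravel())
    flat_to_active[active_index] = np.arange(active_index.size, dtype=np.int32)

    coords = np.array(np.unravel_index(active_index, dims)).T  # (n, 3)
    neighbors = np.full((active_index.size, 6), -1, dtype=np.int32)
    for a, (dx, dy, dz) in enumerate(_NEIGHBOR_OFFSETS):
        shifted = coords + np.array([dx, dy, dz])
        ok = np.all((shifted >= 0) & (shifted < np.array(dims)), axis=1)
        flat = np.ravel_multi_index(
            (shifted[ok, 0], shifted[ok, 1], shifted[ok, 2]), dims
        )
        neighbors[ok, a] = flat_to_active[flat]
    return active_index, neighbors


@njit(cache=True, fastmath=True)
def _diffuse_kernel(values, neighbors, degree, lam, n_steps):  # pragma: no cover
    # degree[i] = number of flux-carrying faces (6 with sinks outside the
    # domain, #inside-neighbors when sealed)
    n = values.shape[0]
    cur = values
    new = np.empty_like(values)
    for _ in range(n_steps):
        for i in range(n):
            s = 0.0
            for a in range(6):
                nb = neighbors[i, a]
                if nb >= 0:
                    s += cur[nb]
            new[i] = cur[i] * (1.0 - lam * degree[i]) + lam * s
        cur, new = new, cur
    return cur


def substep_count(diffusivity_m2_s: float, dt_s: float = params.TICK_SECONDS,
                  h_um: float = params.PATCH_SIZE_UM) -> int:
    """Sub-steps needed to keep the per-step diffusion number at or below
    1/7 -- strictly inside the 1/6 explicit stability limit, so the marginal
    checkerboard mode (amplification 1 - 12 lambda) decays rapidly instead
    of persisting."""
    lam_total = diffusivity_m2_s * dt_s / (h_um * 1e-6) ** 2
    return max(1, int(np.ceil(7.0 * lam_total)))


def diffuse(values: np.ndarray, neighbors: np.ndarray,
            diffusivity_m2_s: float, dt_s: float = params.TICK_SECONDS,
            sealed: bool = False, h_um: float = params.PATCH_SIZE_UM) -> np.ndarray:
    """One tick of Fickian diffusion on the flattened active domain."""
    if np.any(values < 0):
        raise ValidationError("negative input concentration")
    if diffusivity_m2_s == 0 or values.size == 0:
        return values.copy()
    lam_total = diffusivity_m2_s * dt_s / (h_um * 1e-6) ** 2
    n_steps = substep_count(diffusivity_m2_s, dt_s, h_um)
    lam = lam_total / n_steps
    if sealed:
        degree = np.count_nonzero(neighbors >= 0, axis=1).astype(np.float64)
    else:
        degree = np.full(values.shape[0], 6.0)
    out = _diffuse_kernel(values.astype(np.float64), neighbors, degree, lam,
                          n_steps)
    return out


def diffuse_implicit(values: np.ndarray, neighbors: np.ndarray,
                     diffusivity_m2_s: float, dt_s: float = params.TICK_SECONDS,
                     sealed: bool = False, n_steps: int = 1,
                     h_um: float = params.PATCH_SIZE_UM) -> np.ndarray:
    """Backward-Euler diffusion step(s); unconditionally stable.

    Assembles the discrete Laplacian with the same sink/sealed boundary
    treatment as the explicit kernel. Intended for small domains and
    cross-validation; the factorization is not cached.
    """
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    if np.any(values < 0):
        raise ValidationError("negative input concentration")
    n = values.shape[0]
    lam = diffusivity_m2_s * (dt_s / n_steps) / (h_um * 1e-6) ** 2
    rows, cols, data = [], [], []
    diag = np.zeros(n)
    for a in range(6):
        nb = neighbors[:, a]
        inside = nb >= 0
        rows.append(np.flatnonzero(inside))
        cols.append(nb[inside])
        data.append(-lam * np.ones(np.count_nonzero(inside)))
        if sealed:
            diag[inside] += lam
        else:
            diag += lam  # sinks keep the full 6-neighbor loss
    mat = sp.csc_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ) + sp.diags(1.0 + diag, format="csc")
    solve = spla.factorized(mat)
    out = values.astype(np.float64)
    for _ in range(n_steps):
        out = solve(out)
    return out


# --- per-tick reaction terms -------------------------------------------------

def produce_cytokines(counts_by_type: dict[str, np.ndarray],
                      extended_producers: bool = True) -> dict[str, np.ndarray]:
    """Per-voxel cytokine increments (U/ml per tick) from wall agents.

    Neutrophils, monocytes and lymphocytes produce at the per-cell rates of
    the rule table. With ``extended_producers`` (default), M1 macrophages and
    foam cells produce the pro-inflammatory cytokines at the monocyte rates
    and M2 macrophages produce IL-10 at the lymphocyte rate.
    """
    neut = counts_by_type.get("NEUTROPHIL", 0)
    mono = counts_by_type.get("MONOCYTE", 0)
    lymph = counts_by_type.get("LYMPHOCYTE", 0)
    mono_lineage = mono
    il10_producers = lymph
    if extended_producers:
        mono_lineage = mono + counts_by_type.get("M1", 0) + counts_by_type.get("FOAM", 0)
        il10_producers = lymph + counts_by_type.get("M2", 0)
    return {
        "TNFA": (params.PRODUCTION_TNFA_PER_NEUTROPHIL * neut
                 + params.PRODUCTION_TNFA_PER_MONOCYTE * mono_lineage),
        "IL1B": (params.PRODUCTION_IL1B_PER_NEUTROPHIL * neut
                 + params.PRODUCTION_IL1B_PER_MONOCYTE * mono_lineage),
        "IL10": params.PRODUCTION_IL10_PER_LYMPHOCYTE * il10_producers,
    }


def il10_clearance(tnfa, il1b, il10):
    """IL-10-mediated removal of the pro-inflammatory cytokines (per tick).

    IL-1beta is scaled by max(0, 1 - 0.0096 * IL10) and TNF-alpha by
    max(0, 1 - 0.0095 * IL10).
    """
    f_il1b = np.maximum(0.0, 1.0 - params.IL10_CLEARANCE_SLOPE_IL1B * il10)
    f_tnfa = np.maximum(0.0, 1.0 - params.IL10_CLEARANCE_SLOPE_TNFA * il10)
    return tnfa * f_tnfa, il1b * f_il1b


def ldl_wall_concentration(wss_pa, c0_ng_ul: float = params.LDL_BLOOD_NG_UL,
                           duplicated_cubic: bool = False):
    """Wall-surface LDL concentration C_w = C0 * P(WSS), clamped at >= 0."""
    coeffs = (params.LDL_POLY_COEFFS_DUPLICATED_CUBIC if duplicated_cubic
              else params.LDL_POLY_COEFFS)
    return np.maximum(0.0, c0_ng_ul * np.polyval(coeffs, wss_pa))


def ldl_wall_influx(wss_pa, c0_ng_ul: float = params.LDL_BLOOD_NG_UL,
                    duplicated_cubic: bool = False):
    """Concentration entering the wall per tick: 70 % of C_w."""
    return params.LDL_WALL_ENTRY_FRACTION * ldl_wall_concentration(
        wss_pa, c0_ng_ul, duplicated_cubic)


def oxidize_ldl(ldl, oxldl, rate: float = params.LDL_OXIDATION_RATE_PER_H):
    """Move ``rate`` of the local LDL into the oxLDL pool (one tick)."""
    delta = rate * np.asarray(ldl)
    return ldl - delta, oxldl + delta


# --- orchestration -----------------------------------------------------------

class TransportModel:
    """All five species fields bound to a lattice, advanced tick by tick.

    Fields are stored as full (nx, ny, nz) arrays, identically zero outside
    the wall domain. ``rebuild()`` must be called after any geometry edit so
    the stencil follows the evolving wall.
    """

    def __init__(self, lattice: ArteryLattice,
                 c0_blood_ng_ul: float = params.LDL_BLOOD_NG_UL,
                 duplicated_cubic: bool = False,
                 extended_producers: bool = True,
                 diffusivities: Optional[dict[str, float]] = None) -> None:
        self.lattice = lattice
        self.c0_blood_ng_ul = c0_blood_ng_ul
        self.duplicated_cubic = duplicated_cubic
        self.extended_producers = extended_producers
        self.diffusivities = dict(params.DIFFUSIVITY_M2_S)
        if diffusivities:
            self.diffusivities.update(diffusivities)
        self.fields: dict[str, np.ndarray] = {
            name: np.zeros(lattice.dims) for name in SPECIES
        }
        self.last_boundary_outflux: dict[str, float] = {}
        self.rebuild()

    def rebuild(self) -> None:
        cls = self.lattice.patch_class
        self.domain_mask = (cls == WALL) | (cls == EC)
        self.active_index, self.neighbors = make_stencil(self.domain_mask)
        for name in SPECIES:
            self.fields[name][~self.domain_mask] = 0.0

    def tick(self, counts_by_type: dict[str, np.ndarray],
             wss_at_ec: Optional[np.ndarray] = None) -> None:
        """Advance every species by one simulated hour.

        ``wss_at_ec`` is a full-lattice array holding the shear stress (Pa)
        at EC voxels; when given, LDL influx resets the EC boundary
        concentration to 70 % of C_w before diffusion.
        """
        f = self.fields
        inc = produce_cytokines(counts_by_type, self.extended_producers)
        mask = self.domain_mask
        for name, delta in inc.items():
            if np.isscalar(delta):
                continue
            f[name][mask] += delta[mask]
        f["TNFA"], f["IL1B"] = il10_clearance(f["TNFA"], f["IL1B"], f["IL10"])
        if wss_at_ec is not None:
            ec_mask = self.lattice.patch_class == EC
            f["LDL"][ec_mask] = ldl_wall_influx(
                wss_at_ec[ec_mask], self.c0_blood_ng_ul, self.duplicated_cubic)
        f["LDL"], f["OXLDL"] = oxidize_ldl(f["LDL"], f["OXLDL"])
        self.last_boundary_outflux = {}
        for name in SPECIES:
            d = self.diffusivities[name]
            if d == 0.0:
                continue
            flat = f[name].ravel()[self.active_index]
            if not flat.any():
                continue
            before = flat.sum()
            out = diffuse(flat, self.neighbors, d)
            self.last_boundary_outflux[name] = float(before - out.sum())
            full = np.zeros(self.lattice.dims).ravel()
            full[self.active_index] = out
            f[name] = full.reshape(self.lattice.dims)

    def total_mass(self) -> dict[str, float]:
        return {name: float(self.fields[name].sum()) for name in SPECIES}
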