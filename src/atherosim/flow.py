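"""Steady laminar axisymmetric Navier-Stokes in stream-function-vorticity form.

Solves the incompressible axisymmetric flow through a tube of axially varying
radius on a uniform structured (z, r) grid, with

    u_z = (1/r) dpsi/dr,   u_r = -(1/r) dpsi/dz,
    E^2 psi = psi_zz + psi_rr - psi_r / r = -r * omega,

and the steady vorticity transport equation

    u_z w_z + u_r w_r - u_r w / r = nu (w_zz + w_rr + w_r / r - w / r^2),

advanced in pseudo-time (first-order upwind convection) alternating with SOR
sweeps of the psi Poisson problem until the stream function is stationary.

Boundary conditions: Poiseuille inflow at the inlet, zero-gradient outflow
(standing in for a constant-pressure outlet), symmetry on the axis, and
no-slip on the stair-stepped wall with wall vorticity from Thom's formula.
At the Reynolds numbers of coronary flow (~100-500) a stenosed profile
develops a post-stenotic separation bubble, i.e. a distal zone of near-zero
and reversed wall shear -- the hemodynamic feature that drives leukocyte
recruitment in the coupled model.

The wall shear stress reported per axial station is tau = mu * |omega_wall|
evaluated from the radial Thom formula at that column's wall node.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from . import params


@dataclasses.dataclass
class AxisymSolution:
    """Converged fields of one steady solve (also usable as a warm start)."""

    psi: np.ndarray          # (nz, nr) stream function, m^3/s / (2 pi)
    omega: np.ndarray        # (nz, nr) azimuthal vorticity, 1/s
    j_wall: np.ndarray       # first solid radial node per column
    r: np.ndarray            # radial node positions, m
    z: np.ndarray            # axial node positions, m
    tau_wall: np.ndarray     # signed wall shear stress per column, Pa
    converged: bool
    iterations: int


@njit(cache=True)
def _sfv_iterate(psi, omega, j_wall, r, dz, dr, nu, psi_max, dt,
                 max_iter, tol, sor_omega, sor_sweeps):  # pragma: no cover
    nz, nr = psi.shape
    omega_new = omega.copy()
    check_every = 50
    psi_prev = psi.copy()
    it = 0
    converged = False
    while it < max_iter:
        it += 1
        # --- wall vorticity (Thom) on solid nodes adjacent to fluid --------
        for i in range(nz):
            jw = j_wall[i]
            for j in range(jw, nr):
                omega[i, j] = 0.0
            # radial wall face
            omega[i, jw] = 2.0 * (psi_max - psi[i, jw - 1]) / (r[jw] * dr * dr)
        # axial faces at stair steps
        for i in range(1, nz - 1):
            jw = j_wall[i]
            jw_m = j_wall[i - 1]
            jw_p = j_wall[i + 1]
            if jw_m > jw:      # solid at i, fluid at i-1 for j in [jw, jw_m)
                for j in range(jw, jw_m):
                    omega[i, j] += 2.0 * (psi_max - psi[i - 1, j]) / (r[j] * dz * dz)
            if jw_p > jw:
                for j in range(jw, jw_p):
                    omega[i, j] += 2.0 * (psi_max - psi[i + 1, j]) / (r[j] * dz * dz)
        # --- vorticity transport, explicit pseudo-time step ----------------
        for i in range(1, nz - 1):
            jw = j_wall[i]
            for j in range(1, jw):
                rj = r[j]
                uz = (psi[i, j + 1] - psi[i, j - 1]) / (2.0 * dr * rj)
                ur = -(psi[i + 1, j] - psi[i - 1, j]) / (2.0 * dz * rj)
                w = omega[i, j]
                # upwind convection
                if uz >= 0.0:
                    dwdz = (w - omega[i - 1, j]) / dz
                else:
                    dwdz = (omega[i + 1, j] - w) / dz
                if ur >= 0.0:
                    dwdr = (w - omega[i, j - 1]) / dr
                else:
                    dwdr = (omega[i, j + 1] - w) / dr
                conv = uz * dwdz + ur * dwdr - ur * w / rj
                lap = ((omega[i + 1, j] - 2.0 * w + omega[i - 1, j]) / (dz * dz)
                       + (omega[i, j + 1] - 2.0 * w + omega[i, j - 1]) / (dr * dr)
                       + (omega[i, j + 1] - omega[i, j - 1]) / (2.0 * dr * rj)
                       - w / (rj * rj))
                omega_new[i, j] = w + dt * (nu * lap - conv)
            omega_new[i, 0] = 0.0
        # outlet: zero gradient
        for j in range(nr):
            omega_new[nz - 1, j] = omega_new[nz - 2, j]
        for i in range(1, nz):
            jw = j_wall[i]
            for j in range(1, jw):
                omega[i, j] = omega_new[i, j]
            omega[i, 0] = 0.0
        # --- psi Poisson: SOR sweeps ---------------------------------------
        for _ in range(sor_sweeps):
            for i in range(1, nz - 1):
                jw = j_wall[i]
                for j in range(1, jw):
                    rj = r[j]
                    rhs = -rj * omega[i, j]
                    num = ((psi[i + 1, j] + psi[i - 1, j]) / (dz * dz)
                           + (psi[i, j + 1] + psi[i, j - 1]) / (dr * dr)
                           - (psi[i, j + 1] - psi[i, j - 1]) / (2.0 * dr * rj)
                           - rhs)
                    denom = 2.0 / (dz * dz) + 2.0 / (dr * dr)
                    new = num / denom
                    psi[i, j] = (1.0 - sor_omega) * psi[i, j] + sor_omega * new
            for j in range(nr):
                psi[nz - 1, j] = psi[nz - 2, j]
        # --- convergence check ---------------------------------------------
        if it % check_every == 0:
            dmax = 0.0
            for i in range(nz):
                for j in range(nr):
                    d = abs(psi[i, j] - psi_prev[i, j])
                    if d > dmax:
                        dmax = d
                    psi_prev[i, j] = psi[i, j]
            if dmax < tol * psi_max:
                converged = True
                break
    return it, converged


def solve_axisym(
    r_wall_m: np.ndarray,
    q_m3_s: float,
    density: float = params.BLOOD_DENSITY,
    viscosity: float = params.BLOOD_VISCOSITY,
    dz_m: float | None = None,
    nr: int = 37,
    length_m: float | None = None,
    max_iter: int = 8000,
    tol: float = 2e-4,
    warm_start: AxisymSolution | None = None,
) -> AxisymSolution:
    """Steady flow through the axisymmetric profile ``r_wall_m(z)``.

    Parameters
    ----------
    r_wall_m : wall radius at each axial station (uniformly spaced).
    q_m3_s : volumetric flow rate.
    nr : radial nodes from the axis to the widest wall radius.
    warm_start : a previous solution on the same grid (e.g. an adjacent
        waveform phase) used as the initial iterate.
    """
    r_wall_m = np.asarray(r_wall_m, dtype=float)
    nz = r_wall_m.size
    r_max = float(r_wall_m.max())
    dr = r_max / (nr - 1.5)          # wall of the widest section inside grid
    if length_m is None:
        if dz_m is None:
            raise ValueError("need dz_m or length_m")
    else:
        dz_m = length_m / nz
    r = np.arange(nr) * dr
    z = (np.arange(nz) + 0.5) * dz_m

    j_wall = np.clip(np.round(r_wall_m / dr).astype(np.int64), 3, nr - 1)
    psi_max = q_m3_s / (2.0 * np.pi)
    nu = viscosity / density

    if warm_start is not None and warm_start.psi.shape == (nz, nr) and \
            np.array_equal(warm_start.j_wall, j_wall):
        scale = psi_max / (warm_start.psi.max() or 1.0)
        psi = warm_start.psi * scale
        omega = warm_start.omega * scale
    else:
        psi = np.empty((nz, nr))
        omega = np.zeros((nz, nr))
        for i in range(nz):
            R = r[j_wall[i]]
            eta = np.minimum(r / R, 1.0)
            psi[i] = psi_max * (2.0 * eta ** 2 - eta ** 4)
            omega[i] = 4.0 * q_m3_s * np.minimum(r, R) / (np.pi * R ** 4)
    # enforce BCs
    R0 = r[j_wall[0]]
    eta0 = np.minimum(r / R0, 1.0)
    psi[0] = psi_max * (2.0 * eta0 ** 2 - eta0 ** 4)
    omega[0] = 4.0 * q_m3_s * np.minimum(r, R0) / (np.pi * R0 ** 4)
    for i in range(nz):
        psi[i, j_wall[i]:] = psi_max
        psi[i, 0] = 0.0

    u_ref = 2.5 * q_m3_s / (np.pi * r[j_wall].min() ** 2)
    dt = 0.3 / (2.0 * nu * (1.0 / dr ** 2 + 1.0 / dz_m ** 2)
                + u_ref * (1.0 / dz_m + 1.0 / dr) + 1e-30)

    iterations, converged = _sfv_iterate(
        psi, omega, j_wall, r, dz_m, dr, nu, psi_max, dt,
        max_iter, tol, 1.6, 4)

    tau = np.empty(nz)
    for i in range(nz):
        jw = j_wall[i]
        tau[i] = viscosity * 2.0 * (psi_max - psi[i, jw - 1]) / (r[jw] * dr * dr)
        # stair-step correction: the wall node sits at r[jw], the physical
        # wall at r_wall; rescale by the local Poiseuille cubic law
        tau[i] *= (r[jw] / r_wall_m[i]) ** 3
    return AxisymSolution(psi, omega, j_wall, r, z, tau, converged, iterations)


def poiseuille_wss(q_m3_s: float, radius_m,
                   viscosity: float = params.BLOOD_VISCOSITY) -> np.ndarray:
    """Closed-form fully developed wall shear stress, tau = 4 mu Q / (pi r^3)."""
    return 4.0 * viscosity * q_m3_s / (np.pi * np.asarray(radius_m) ** 3)


def flow_for_wss(tau_pa: float, radius_m: float,
                 viscosity: float = params.BLOOD_VISCOSITY) -> float:
    """Flow rate giving a target Poiseuille wall shear in a straight tube."""
    return tau_pa * np.pi * radius_m ** 3 / (4.0 * viscosity)
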