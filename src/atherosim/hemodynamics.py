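"""Per-EC-patch wall shear stress: waveform, backends, policies, handshake.

The agent-based model consumes a single scalar per endothelial voxel: the
wall shear stress in Pa. This module provides three interchangeable ways to
produce it:

``poiseuille`` (fast 1D)
    Per z-plane, an effective radius from the lumen patch count and the
    fully developed closed form tau = 4 mu Q / (pi r_eff^3), azimuthally
    modulated by each EC voxel's own distance from the axis (closer wall,
    higher shear).

``axisym`` (default for benchmarks)
    The steady laminar axisymmetric stream-function-vorticity solve of
    :mod:`atherosim.flow` on the area-equivalent axisymmetric profile.
    Captures the post-stenotic separation bubble (low/reversed wall shear
    distal to a stenosis) that the 1D estimate cannot produce.

``imported``
    A tabulated (voxel index -> Pa) field, e.g. from an external 3D CFD
    solve, read from CSV with columns x, y, z, tau_pa.

Coronary inflow is pulsatile with a 0.8 s period; the waveform is sampled at
0.01 s (80 samples per cycle). Three evaluation policies exist: a single
solve at peak systolic flow (the model's standard operating point), a single
solve at the mean flow, or all 80 phases ("full cycle", used by the
timescale experiment). The handshake schedule decides *when* the WSS field
is recomputed as the geometry evolves: at every change of the lumen voxel
count, or -- in accelerated growth mode -- after a per-severity quota of
cumulative lumen changes (80 / 35 / 10 patches for small / medium / big
plaques).
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Optional

import numpy as np

from . import params
from .flow import AxisymSolution, flow_for_wss, poiseuille_wss, solve_axisym
from .lattice import EC, ArteryLattice, TopologyError


class CoverageError(ValueError):
    """An imported WSS table does not cover every EC voxel."""


@dataclasses.dataclass(frozen=True)
class BloodProperties:
    density: float = params.BLOOD_DENSITY            # kg/m^3
    dynamic_viscosity: float = params.BLOOD_VISCOSITY  # Pa s; Newtonian


@dataclasses.dataclass
class FlowWaveform:
    """One cardiac cycle of volumetric inflow, sampled uniformly."""

    period_s: float
    times_s: np.ndarray
    q_m3_s: np.ndarray

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.q_m3_s = np.asarray(self.q_m3_s, dtype=float)
        if self.times_s.shape != self.q_m3_s.shape:
            raise ValueError("times and flows must align")

    @property
    def mean_q(self) -> float:
        return float(self.q_m3_s.mean())

    @property
    def peak_systolic_q(self) -> float:
        return float(self.q_m3_s.max())

    @property
    def peak_phase_s(self) -> float:
        return float(self.times_s[int(np.argmax(self.q_m3_s))])

    @classmethod
    def default(cls, mean_q: Optional[float] = None,
                period_s: float = params.CARDIAC_PERIOD_S,
                dt_s: float = params.WSS_SAMPLE_DT_S) -> "FlowWaveform":
        """LAD-like biphasic waveform, normalized to a target mean flow.

        The shape is a low baseline plus a dominant systolic peak (at 30 % of
        the cycle) and a broader secondary hump; by default the mean flow is
        the rate giving the healthy 1.4 Pa Poiseuille wall shear in the
        1.8 mm-radius straight artery.
        """
        if mean_q is None:
            mean_q = flow_for_wss(params.HEALTHY_WSS_PA,
                                  params.LUMEN_RADIUS_UM * 1e-6)
        t = np.arange(0.0, period_s, dt_s)
        s = t / period_s
        shape = (0.25
                 + 1.20 * np.exp(-(((s - 0.30) / 0.12) ** 2))
                 + 0.55 * np.exp(-(((s - 0.70) / 0.15) ** 2)))
        q = mean_q * shape / shape.mean()
        return cls(period_s, t, q)

    @classmethod
    def from_csv(cls, path, period_s: Optional[float] = None) -> "FlowWaveform":
        import pandas as pd

        df = pd.read_csv(path)
        t = df.iloc[:, 0].to_numpy(float)
        q = df.iloc[:, 1].to_numpy(float)
        if period_s is None:
            period_s = float(t[-1] + (t[1] - t[0]))
        return cls(period_s, t, q)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"t_s": self.times_s, "q_m3_s": self.q_m3_s}).to_csv(
            path, index=False)


@dataclasses.dataclass
class WSSField:
    """Shear stress (Pa) defined on every EC voxel of a lattice."""

    values: np.ndarray                     # full (nx, ny, nz), Pa, >= 0
    provenance: Literal["BUILTIN_1D", "BUILTIN_AXISYM", "IMPORTED"]
    at_time: str = "steady"                # waveform phase label

    def at_ec(self, lattice: ArteryLattice) -> np.ndarray:
        return self.values[lattice.patch_class == EC]


def effective_radii_m(lattice: ArteryLattice) -> np.ndarray:
    """Area-equivalent lumen radius per z-plane, meters."""
    counts = lattice.lumen_count_per_plane().astype(float)
    if np.any(counts <= 0):
        raise TopologyError("plane without lumen voxels")
    h_m = lattice.patch_size_um * 1e-6
    return np.sqrt(counts * h_m ** 2 / np.pi)


def estimate_wss(
    lattice: ArteryLattice,
    q_m3_s: float,
    blood: BloodProperties = BloodProperties(),
    backend: str = "axisym",
    at_time: str = "steady",
    warm_start: Optional[AxisymSolution] = None,
    refine: int = 2,
    nr: int = 37,
) -> WSSField:
    """Compute the per-EC-voxel WSS field for one flow rate."""
    if backend == "poiseuille":
        return _wss_poiseuille(lattice, q_m3_s, blood, at_time)
    if backend == "axisym":
        return _wss_axisym(lattice, q_m3_s, blood, at_time, warm_start,
                           refine, nr)
    raise ValueError(f"unknown WSS backend {backend!r}")


def _plane_tau_to_field(lattice: ArteryLattice, tau_plane: np.ndarray,
                        modulate: bool, provenance, at_time) -> WSSField:
    values = np.zeros(lattice.dims)
    ec = lattice.patch_class == EC
    radial = lattice.radial_distance()      # (nx, ny), voxel units
    for z in range(lattice.nz):
        mask = ec[:, :, z]
        if not mask.any():
            continue
        tau = tau_plane[z]
        if modulate:
            r_vox = radial[mask]
            r_ref = r_vox.mean()
            values[:, :, z][mask] = tau * (r_ref / r_vox) ** 3
        else:
            values[:, :, z][mask] = tau
    return WSSField(np.maximum(values, 0.0), provenance, at_time)


def _wss_poiseuille(lattice, q, blood, at_time) -> WSSField:
    r_eff = effective_radii_m(lattice)
    tau_plane = poiseuille_wss(q, r_eff, blood.dynamic_viscosity)
    return _plane_tau_to_field(lattice, tau_plane, True, "BUILTIN_1D", at_time)


def _wss_axisym(lattice, q, blood, at_time, warm_start, refine, nr) -> WSSField:
    r_eff = effective_radii_m(lattice)
    # refine the axial profile for the solver grid
    z_abm = np.arange(lattice.nz) + 0.5
    z_fine = (np.arange(lattice.nz * refine) + 0.5) / refine
    r_fine = np.interp(z_fine, z_abm, r_eff)
    h_m = lattice.patch_size_um * 1e-6
    sol = solve_axisym(r_fine, q, blood.density, blood.dynamic_viscosity,
                       dz_m=h_m / refine, nr=nr, warm_start=warm_start)
    tau_fine = np.abs(sol.tau_wall)
    tau_plane = tau_fine.reshape(lattice.nz, refine).mean(axis=1)
    field = _plane_tau_to_field(lattice, tau_plane, False, "BUILTIN_AXISYM",
                                at_time)
    field.solution = sol  # keep for warm starts / diagnostics
    return field


def make_uniform_wss(lattice: ArteryLattice, tau_pa: float,
                     at_time: str = "steady") -> WSSField:
    """A uniform imported field (e.g. the healthy 1.4 Pa baseline)."""
    values = np.zeros(lattice.dims)
    values[lattice.patch_class == EC] = tau_pa
    return WSSField(values, "IMPORTED", at_time)


def load_wss_csv(lattice: ArteryLattice, path) -> WSSField:
    """Import a per-voxel WSS table (columns x, y, z, tau_pa)."""
    import pandas as pd

    df = pd.read_csv(path)
    values = np.zeros(lattice.dims)
    idx = (df["x"].to_numpy(int), df["y"].to_numpy(int), df["z"].to_numpy(int))
    values[idx] = df["tau_pa"].to_numpy(float)
    ec = lattice.patch_class == EC
    covered = np.zeros(lattice.dims, dtype=bool)
    covered[idx] = True
    if not np.all(covered[ec]):
        missing = int(np.count_nonzero(ec & ~covered))
        raise CoverageError(f"imported WSS table misses {missing} EC voxels")
    return WSSField(values, "IMPORTED", "imported")


def save_wss_csv(lattice: ArteryLattice, field: WSSField, path) -> None:
    import pandas as pd

    ec = np.argwhere(lattice.patch_class == EC)
    pd.DataFrame({
        "x": ec[:, 0], "y": ec[:, 1], "z": ec[:, 2],
        "tau_pa": field.values[ec[:, 0], ec[:, 1], ec[:, 2]],
    }).to_csv(path, index=False)


# --- evaluation policies -----------------------------------------------------

def select_wss_policy(waveform: FlowWaveform,
                      policy: str) -> list[tuple[float, float]]:
    """Return the (time, flow) pairs at which WSS must be solved.

    ``peak_systole``: one solve at maximum flow. ``steady_mean``: one solve
    at the time-averaged flow. ``full_cycle``: one solve per waveform sample
    (80 for the default 0.8 s / 0.01 s waveform).
    """
    if policy == "peak_systole":
        return [(waveform.peak_phase_s, waveform.peak_systolic_q)]
    if policy == "steady_mean":
        return [(-1.0, waveform.mean_q)]
    if policy == "full_cycle":
        return list(zip(waveform.times_s.tolist(), waveform.q_m3_s.tolist()))
    raise ValueError(f"unknown WSS policy {policy!r}")


#: cumulative lumen-patch-change quotas between WSS updates in accelerated
#: mode, per plaque-severity class
ACCELERATED_QUOTAS = {"small": 80, "medium": 35, "big": 10}


def should_update_wss(mode: str, lumen_now: int, lumen_at_last_update: int,
                      quota: int = 0) -> bool:
    """The ABM <-> WSS handshake schedule.

    ``per_lumen_change`` triggers whenever the total lumen voxel count
    differs from the count at the last update; ``accelerated`` triggers when
    the cumulative change reaches the severity-class quota.
    """
    change = abs(lumen_now - lumen_at_last_update)
    if mode == "per_lumen_change":
        return change > 0
    if mode == "accelerated":
        return change >= quota > 0
    raise ValueError(f"unknown handshake mode {mode!r}")


# --- lumen surface reconstruction (STL export) -------------------------------

def export_lumen_surface(lattice: ArteryLattice, path=None,
                         ring_points: int = 64, smooth_window: int = 5):
    """Reconstruct the luminal surface as a watertight triangle mesh.

    Per z-plane the EC voxel centroids are sorted azimuthally, consecutive
    pairs averaged, and a circular moving average applied (the voxel ring is
    saw-toothed; smoothing recovers the underlying surface). Each smoothed
    ring is resampled to ``ring_points`` uniform azimuths, rings are stitched
    with triangles, and the ends capped. Returns a ``trimesh.Trimesh``;
    writes binary STL when ``path`` is given.
    """
    import trimesh

    h = lattice.patch_size_um
    cx, cy = lattice.axis_xy
    rings = []
    theta_u = np.linspace(0.0, 2.0 * np.pi, ring_points, endpoint=False)
    for z in range(lattice.nz):
        mask = lattice.patch_class[:, :, z] == EC
        pts = np.argwhere(mask)
        if pts.shape[0] < 8:
            raise TopologyError(f"EC ring too sparse in plane {z}")
        x = (pts[:, 0] + 0.5 - cx) * h
        y = (pts[:, 1] + 0.5 - cy) * h
        theta = np.arctan2(y, x)
        order = np.argsort(theta)
        x, y, theta = x[order], y[order], theta[order]
        if np.max(np.diff(np.concatenate([theta, [theta[0] + 2 * np.pi]]))) > 1.0:
            raise TopologyError(f"EC ring not closed in plane {z}")
        # consecutive-pair averaging (circular)
        x = 0.5 * (x + np.roll(x, -1))
        y = 0.5 * (y + np.roll(y, -1))
        # circular moving average
        if smooth_window > 1:
            kernel = np.ones(smooth_window) / smooth_window
            pad = smooth_window // 2
            xp = np.concatenate([x[-pad:], x, x[:pad]])
            yp = np.concatenate([y[-pad:], y, y[:pad]])
            x = np.convolve(xp, kernel, mode="valid")[: x.size]
            y = np.convolve(yp, kernel, mode="valid")[: y.size]
        r = np.hypot(x, y)
        th = np.unwrap(np.arctan2(y, x))
        order = np.argsort(th % (2 * np.pi))
        th_s = (th % (2 * np.pi))[order]
        r_s = r[order]
        r_u = np.interp(theta_u, np.concatenate([th_s, [th_s[0] + 2 * np.pi]]),
                        np.concatenate([r_s, [r_s[0]]]), period=2 * np.pi)
        ring = np.column_stack([
            cx * h + r_u * np.cos(theta_u),
            cy * h + r_u * np.sin(theta_u),
            np.full(ring_points, (z + 0.5) * h),
        ])
        rings.append(ring)

    vertices = np.concatenate(rings)
    faces = []
    n = ring_points
    for z in range(lattice.nz - 1):
        a0, b0 = z * n, (z + 1) * n
        for k in range(n):
            k2 = (k + 1) % n
            faces.append([a0 + k, b0 + k, a0 + k2])
            faces.append([a0 + k2, b0 + k, b0 + k2])
    # end caps (fan to centroid)
    c_in = vertices[:n].mean(axis=0)
    c_out = vertices[-n:].mean(axis=0)
    vi = len(vertices)
    vertices = np.concatenate([vertices, [c_in, c_out]])
    last = (lattice.nz - 1) * n
    for k in range(n):
        k2 = (k + 1) % n
        faces.append([vi, k2, k])
        faces.append([vi + 1, last + k, last + k2])
    mesh = trimesh.Trimesh(vertices=vertices, faces=np.array(faces),
                           process=False)
    if path is not None:
        mesh.export(path, file_type="stl")
    return mesh
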