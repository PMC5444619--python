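"""Physical constants and empirical rule parameters of the model.

Everything here is a model input: artery geometry, blood composition, species
kinetics and the empirical dose-response prefactors used by the recruitment
rules. Units are stated next to each constant. Values are the model defaults;
every one of them can be overridden through the relevant config dataclass.
"""

from __future__ import annotations

import numpy as np

# --- lattice -----------------------------------------------------------------
PATCH_SIZE_UM: float = 100.0          # cubic voxel edge, um
PATCH_VOLUME_UM3: float = PATCH_SIZE_UM ** 3
TICK_SECONDS: float = 3600.0          # one tick = one simulated hour

ECM_FRACTION: float = 0.60            # fixed extracellular-matrix fraction of a wall voxel
CAPACITY_FRACTION_NORMAL: float = 0.40     # cell-available fraction of a wall voxel
CAPACITY_FRACTION_ACCELERATED: float = 0.04

# --- artery geometry (healthy LAD-like vessel) -------------------------------
LUMEN_RADIUS_UM: float = 1800.0
WALL_THICKNESS_UM: float = 600.0      # media + adventitia, modeled as uniform
ARTERY_LENGTH_UM: float = 6000.0

# --- blood -------------------------------------------------------------------
BLOOD_DENSITY: float = 1060.0         # kg/m^3
BLOOD_VISCOSITY: float = 3.5e-3       # Pa*s, Newtonian
LEUKOCYTES_PER_MM3: float = 7000.0    # 7e9 / liter
BLOOD_FRACTIONS = {                   # of total leukocytes
    "NEUTROPHIL": 0.62,
    "MONOCYTE": 0.053,
    "LYMPHOCYTE": 0.30,
}
LDL_BLOOD_NG_UL: float = 960.0        # normal range 950-970 ng/ul
LDL_BLOOD_NG_UL_UNHEALTHY: float = 1950.0

HEALTHY_WSS_PA: float = 1.4
WALL_STIFFNESS_KPA: float = 3.0       # normal arterial wall

# --- cell sizes (sphere volumes from diameters) ------------------------------
def _sphere_volume(diameter_um: float) -> float:
    return (np.pi / 6.0) * diameter_um ** 3

CELL_VOLUME_UM3 = {
    "NEUTROPHIL": _sphere_volume(12.0),   # 904.78
    "LYMPHOCYTE": _sphere_volume(12.0),
    "MONOCYTE": _sphere_volume(24.0),     # 7238.23
    "M1": _sphere_volume(24.0),
    "M2": _sphere_volume(24.0),
    "FOAM": _sphere_volume(25.0),         # 8181.23
}

# --- lifespans in wall (ticks = hours) ---------------------------------------
LIFESPAN_TICKS = {
    "NEUTROPHIL": 72,     # 3 days
    "MONOCYTE": 168,      # 7 days
    "LYMPHOCYTE": 168,
    "M1": 168,            # inherit the monocyte clock
    "M2": 168,
    "FOAM": None,         # persistent plaque constituent
}

# --- species transport -------------------------------------------------------
DIFFUSIVITY_M2_S = {
    "TNFA": 3.0e-11,
    "IL1B": 3.0e-11,
    "IL10": 3.0e-11,
    "LDL": 2.5e-11,
    "OXLDL": 0.0,         # immobile; consumed locally by macrophages
}

# Effective lattice diffusivity of one patch-hop per tick (D h^-2 dt = 1/6),
# i.e. the per-tick neighbor transfer of a cellular-automaton `diffuse`
# primitive on a 100 um / 1 h lattice. The physical molecular diffusivities
# above are ~20-60x faster; with the perfect-sink boundaries of a 600 um
# wall they wash every solute out within a single tick, so the wall could
# never accumulate the 1e-3..1e-1 U/ml endothelial concentrations the
# coupled model's feedback loop (and its published behavior) operates at.
# Simulation presets therefore transport the soluble species at this
# lattice rate by default; the molecular values remain available through
# the transport model's `diffusivities` override.
LATTICE_DIFFUSIVITY_M2_S: float = (PATCH_SIZE_UM * 1e-6) ** 2 / (6.0 * TICK_SECONDS)
PRESET_DIFFUSIVITY_M2_S = {
    "TNFA": LATTICE_DIFFUSIVITY_M2_S,
    "IL1B": LATTICE_DIFFUSIVITY_M2_S,
    "IL10": LATTICE_DIFFUSIVITY_M2_S,
    "LDL": LATTICE_DIFFUSIVITY_M2_S,
    "OXLDL": 0.0,
}

# per-cell cytokine production, U/ml per hour per cell
PRODUCTION_TNFA_PER_NEUTROPHIL: float = 5.0e-6
PRODUCTION_TNFA_PER_MONOCYTE: float = 6.7e-4
PRODUCTION_IL1B_PER_NEUTROPHIL: float = 5.0e-7
PRODUCTION_IL1B_PER_MONOCYTE: float = 5.0e-5
PRODUCTION_IL10_PER_LYMPHOCYTE: float = 3.75e-5

# IL-10-mediated clearance per hour: field *= max(0, 1 - slope * IL10)
IL10_CLEARANCE_SLOPE_IL1B: float = 0.0096
IL10_CLEARANCE_SLOPE_TNFA: float = 0.0095

LDL_OXIDATION_RATE_PER_H: float = 0.012     # 1.2 %/h of local LDL
LDL_WALL_ENTRY_FRACTION: float = 0.70       # fraction of C_w entering the wall
OXLDL_FOAM_THRESHOLD_UG_ML: float = 100.0   # macrophage -> foam cell above this

# wall-surface LDL concentration polynomial  C_w = C0 * P(wss)
# Adopted reading: degree sequence 6,5,4,3,2,1,0 (the source table prints two
# cubic terms; the second is taken as quadratic).  The literal two-cubic
# reading is selectable via `duplicated_cubic=True`.
LDL_POLY_COEFFS = np.array([2e-8, -2e-6, 6e-5, -1.1e-3, 1.04e-2, -0.05, 1.15])
LDL_POLY_COEFFS_DUPLICATED_CUBIC = np.array(
    [2e-8, -2e-6, 6e-5, (-1.1e-3 + 1.04e-2), 0.0, -0.05, 1.15]
)

# Minimal cytokine concentration that activates endothelium (U/ml). The
# fitted adhesion sigmoids carry nonzero intercepts, so without a floor an
# infinitesimal trace concentration would already count as an activating
# stimulus; physiologically activation is confined to endothelium adjacent
# to a lesion. The floor is set at the signal one secreting cell sustains:
# ~2 neutrophil-hours of IL-1beta production (2 x 5e-7 U/ml). Below it a
# concentration is treated as no stimulus.
CYTOKINE_ACTIVATION_THRESHOLD_U_ML: float = 1e-6

# --- macrophage fate ---------------------------------------------------------
M1_FRACTION: float = 2.0 / 3.0        # M1:M2 = 2:1 at monocyte wall entry

# --- Glagov remodeling -------------------------------------------------------
GLAGOV_THRESHOLD: float = 0.40        # plaque area >= 40% of lumen area
INWARD_FRACTION: float = 0.65
OUTWARD_FRACTION: float = 0.35

# --- cardiac cycle -----------------------------------------------------------
CARDIAC_PERIOD_S: float = 0.8
WSS_SAMPLE_DT_S: float = 0.01         # waveform sampling interval (80 samples)
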