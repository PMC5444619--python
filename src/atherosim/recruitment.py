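"""Leukocyte adhesion and transendothelial migration at the endothelium.

Adhesion is driven by three stimuli per leukocyte type: wall shear stress
(WSS, Pa) and endothelial exposure to the pro-inflammatory cytokines
TNF-alpha and IL-1beta (U/ml). Each (type, stimulus) pair carries an
empirical dose-response ``f(x)`` fitted from flow-chamber experiments
(sigmoids for the cytokines, low-order polynomials with a hard cut-off for
WSS: neutrophil adhesion requires WSS < 1.2 Pa, monocyte < 1.0 Pa,
lymphocyte < 0.41 Pa; at the healthy 1.4 Pa all three pathways are silent).

``f`` has units carrying the (unpublished) exposure durations of the source
experiments, so its absolute scale is not interpretable. The per-tick
adhesion probability is

    p = clamp(kappa * f(x) * h * tick / t_norm, 0, 1)

where ``h`` is the patch length (mm), ``tick`` the time step (s), ``t_norm``
a nominal exposure time (s), and ``kappa`` a single dimensionless calibration
scalar fixed once by matching the full-cardiac-cycle TEM rate on the 1.0 mm
spherical-plaque fixture to 16 leukocytes/hour (see
:func:`atherosim.experiments.calibrate_kappa`), then frozen for every other
experiment. The three stimulus pathways combine as independent competing
causes: p_total = 1 - (1-p_wss)(1-p_tnfa)(1-p_il1b).

Adherent cells are sampled per EC patch from the luminal reservoir (which
blood replenishes every tick): available N ~ Poisson(c_type * V), adherent
M ~ Binomial(N, p_total), and each adherent cell transmigrates with the
stiffness-dependent %TEM of its type.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np

from . import params

LEUKOCYTE_TYPES = ("NEUTROPHIL", "MONOCYTE", "LYMPHOCYTE")
STIMULI = ("WSS", "TNFA", "IL1B")

#: Calibrated WSS-pathway probability scale (see module docstring).
#: Reproduce with ``experiments.calibrate_kappa()``; frozen here as the
#: package default.
DEFAULT_KAPPA: float = 2.625e-5

#: Cytokine-pathway probability scale. The source experiments behind the
#: WSS and cytokine dose-response fits ran for different (unpublished)
#: exposure durations, so the two pathway families need separate scales.
#: This one is anchored on the model's published sensitivity probabilities
#: (p = 0.247 / 0.253 for IL-1beta at 0.04 / 0.006 U/ml and p = 0.003 /
#: 0.008 for TNF-alpha at 0.04 / 0.07 U/ml): the geometric mean of p/f over
#: those four points gives p = 9.2e-4 * f per tick, i.e. kappa = 4.6e-3 in
#: the p = kappa * f * h * tick / t_norm parameterization.
DEFAULT_KAPPA_CYTOKINE: float = 4.6e-3


# --- the empirical dose-response functions (rule table) ----------------------

#: concentrations below this floor do not activate endothelium (the fitted
#: sigmoids have nonzero intercepts; without a floor, vanishing trace
#: concentrations would activate the whole artery)
CYTOKINE_FLOOR = params.CYTOKINE_ACTIVATION_THRESHOLD_U_ML


def _f_tnfa(x):
    """Adhesion response to TNF-alpha (same fit for all three types)."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        upper = 0.80 - 0.68 * (1.0 - np.exp(-0.33 * np.log10(
            np.where(x > 1.0, x, 1.0)) - 0.56))
    out = np.where(x > 1.0, 1180.0 * upper, 1180.0 * 0.0996 * x)
    return np.where(x >= CYTOKINE_FLOOR, np.maximum(out, 0.0), 0.0)


def _f_il1b_sigmoid(prefactor, base, amp, rate, power):
    def f(x):
        x = np.asarray(x, dtype=float)
        out = prefactor * (base + amp * (1.0 - np.exp(-rate * np.power(
            np.where(x > 0, x, 0.0), power))))
        return np.where(x >= CYTOKINE_FLOOR, np.maximum(out, 0.0), 0.0)
    return f


def _f_wss_poly(prefactor, coeffs, lo, hi):
    def f(x):
        x = np.asarray(x, dtype=float)
        inside = (x > lo) & (x < hi)
        out = prefactor * np.polyval(coeffs, x)
        return np.where(inside, np.maximum(out, 0.0), 0.0)
    return f


@dataclasses.dataclass(frozen=True)
class AdhesionRule:
    """One (leukocyte type, stimulus) dose-response with its domain."""

    leukocyte_type: str
    stimulus: str
    f: Callable[[np.ndarray], np.ndarray]
    domain: tuple[float, float]  # open interval outside which f = 0 (WSS rules)

    def __call__(self, x):
        return self.f(x)


#: WSS cut-offs per type (upper edge of the open domain)
WSS_DOMAIN_UPPER = {"NEUTROPHIL": 1.2, "MONOCYTE": 1.0, "LYMPHOCYTE": 0.41}

ADHESION_RULES: dict[tuple[str, str], AdhesionRule] = {}


def _register(t, s, f, domain):
    ADHESION_RULES[(t, s)] = AdhesionRule(t, s, f, domain)


_register("NEUTROPHIL", "TNFA", _f_tnfa, (0.0, np.inf))
_register("MONOCYTE", "TNFA", _f_tnfa, (0.0, np.inf))
_register("LYMPHOCYTE", "TNFA", _f_tnfa, (0.0, np.inf))
_register("NEUTROPHIL", "IL1B",
          _f_il1b_sigmoid(1900.0, 0.10, 0.19, 28.29, 1.46), (0.0, np.inf))
_register("MONOCYTE", "IL1B",
          _f_il1b_sigmoid(1600.0, 0.14, 0.80, 0.58, 1.19), (0.0, np.inf))
_register("LYMPHOCYTE", "IL1B",
          _f_il1b_sigmoid(1900.0, 0.10, 0.19, 28.29, 1.46), (0.0, np.inf))
_register("NEUTROPHIL", "WSS",
          _f_wss_poly(1300.0, [0.26, -0.8, 0.63], 0.0, 1.2), (0.0, 1.2))
_register("MONOCYTE", "WSS",
          _f_wss_poly(1600.0, [-0.3295, 1.4, -1.8, 0.79], 0.0, 1.0), (0.0, 1.0))
_register("LYMPHOCYTE", "WSS",
          _f_wss_poly(125.0, [-9.93, 11.0, -4.1, 0.55], 0.04, 0.41), (0.04, 0.41))


def eval_rule(rule: AdhesionRule, x) -> np.ndarray:
    """Evaluate a dose-response; zero outside its domain, never negative."""
    if np.any(np.asarray(x) < 0):
        raise ValueError("stimulus must be non-negative")
    return rule(x)


# --- transmigration fractions (stiffness rules) ------------------------------

def tem_fraction(stiffness_kpa: float, leukocyte_type: str) -> float:
    """Percent of adherent cells transmigrating, as a function of wall
    stiffness (kPa). Monocytes/lymphocytes: 0.78x^2 + 4.8x + 51.06 on (1, 5),
    95 above; neutrophils: 9.18x + 46.96 on (0.42, 5), 91 above. Below the
    domain the lower-edge value applies."""
    if stiffness_kpa <= 0:
        raise ValueError("stiffness must be positive")
    x = float(stiffness_kpa)
    if leukocyte_type == "NEUTROPHIL":
        lo, plateau = 0.42, 91.0
        poly = lambda v: 9.18 * v + 46.96
    elif leukocyte_type in ("MONOCYTE", "LYMPHOCYTE"):
        lo, plateau = 1.0, 95.0
        poly = lambda v: 0.78 * v * v + 4.8 * v + 51.06
    else:
        raise KeyError(leukocyte_type)
    if x >= 5.0:
        return plateau
    return poly(max(x, lo))


# --- probability assembly and sampling ---------------------------------------

@dataclasses.dataclass
class RecruitmentConfig:
    """Scales and environment for per-tick recruitment sampling."""

    h_mm: float = params.PATCH_SIZE_UM / 1000.0
    tick_s: float = params.TICK_SECONDS
    t_norm_s: float = 1800.0
    kappa: float = DEFAULT_KAPPA                      # WSS pathway
    kappa_cytokine: float = DEFAULT_KAPPA_CYTOKINE    # TNF/IL-1 pathways
    blood_conc_per_mm3: dict = dataclasses.field(
        default_factory=lambda: {
            t: params.LEUKOCYTES_PER_MM3 * params.BLOOD_FRACTIONS[t]
            for t in LEUKOCYTE_TYPES})
    stiffness_kpa: float = params.WALL_STIFFNESS_KPA
    combination: str = "independent_or"   # or "additive"

    def expected_available(self, leukocyte_type: str) -> float:
        """Mean leukocytes of one type in a patch-sized blood volume."""
        volume_mm3 = self.h_mm ** 3
        return self.blood_conc_per_mm3[leukocyte_type] * volume_mm3


def adhesion_probability(f_value, cfg: RecruitmentConfig,
                         stimulus: str = "WSS") -> np.ndarray:
    """Map a dose-response value to a per-tick probability (clamped to [0,1]).

    The WSS pathway uses ``cfg.kappa``; the cytokine pathways use
    ``cfg.kappa_cytokine`` (separate source-experiment exposure scales).
    """
    f_value = np.asarray(f_value, dtype=float)
    if np.any(f_value < 0):
        raise ValueError("f must be non-negative")
    kappa = cfg.kappa if stimulus == "WSS" else cfg.kappa_cytokine
    p = kappa * f_value * cfg.h_mm * cfg.tick_s / cfg.t_norm_s
    return np.clip(p, 0.0, 1.0)


def combined_probability(wss, tnfa, il1b, cfg: RecruitmentConfig,
                         leukocyte_type: str) -> np.ndarray:
    """Total per-tick adhesion probability for one type over EC patches."""
    ps = [
        adhesion_probability(
            eval_rule(ADHESION_RULES[(leukocyte_type, "WSS")], wss), cfg,
            "WSS"),
        adhesion_probability(
            eval_rule(ADHESION_RULES[(leukocyte_type, "TNFA")], tnfa), cfg,
            "TNFA"),
        adhesion_probability(
            eval_rule(ADHESION_RULES[(leukocyte_type, "IL1B")], il1b), cfg,
            "IL1B"),
    ]
    if cfg.combination == "additive":
        return np.clip(ps[0] + ps[1] + ps[2], 0.0, 1.0)
    out = 1.0
    for p in ps:
        out = out * (1.0 - p)
    return 1.0 - out


def expected_tem(wss, tnfa, il1b, cfg: RecruitmentConfig) -> float:
    """Expected transmigration events per tick, summed over EC patches.

    Uses E[Binomial(Poisson(N), p)] = N p; deterministic, used by the
    calibration bisection.
    """
    total = 0.0
    for t in LEUKOCYTE_TYPES:
        p = combined_probability(wss, tnfa, il1b, cfg, t)
        frac = tem_fraction(cfg.stiffness_kpa, t) / 100.0
        total += float(np.sum(cfg.expected_available(t) * p * frac))
    return total


def combine_and_sample(wss, tnfa, il1b, cfg: RecruitmentConfig,
                       rng: np.random.Generator
                       ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Sample adherent and transmigrating counts per EC patch and type.

    Returns ``{type: (adherent, transmigrated)}`` integer arrays, one entry
    per EC patch. The luminal reservoir is replenished every tick, so draws
    are independent across ticks.
    """
    wss = np.atleast_1d(np.asarray(wss, dtype=float))
    tnfa = np.broadcast_to(np.asarray(tnfa, dtype=float), wss.shape)
    il1b = np.broadcast_to(np.asarray(il1b, dtype=float), wss.shape)
    out = {}
    for t in LEUKOCYTE_TYPES:
        p = combined_probability(wss, tnfa, il1b, cfg, t)
        n_avail = rng.poisson(cfg.expected_available(t), size=wss.shape)
        adherent = rng.binomial(n_avail, p)
        frac = tem_fraction(cfg.stiffness_kpa, t) / 100.0
        transmigrated = rng.binomial(adherent, frac)
        out[t] = (adherent, transmigrated)
    return out
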