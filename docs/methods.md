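# Methods

`atherosim` simulates the initiation and growth of an atherosclerotic
plaque in a straight, LAD-like coronary artery as a hybrid of a cellular
automaton (the artery wall and its resident cells) and a continuum flow
estimate (wall shear stress on the endothelium). This note records the
model, its assumptions, the parameters that matter, and the places where
the design was genuinely open and a choice had to be made.

## The voxel world

The artery is discretized into cubic patches of 100 um; one tick is one
hour. The healthy vessel is a cylinder: lumen radius 1800 um (18 voxels),
a single-voxel endothelial (EC) shell, and a 600 um wall modeled as uniform
tissue (no media/adventitia distinction). Voxel membership uses a
center-in-region test, matching patch-count bookkeeping throughout: lumen
area, plaque area and stenosis severity are all integer patch counts.
60 % of every wall voxel is fixed extracellular matrix; the remaining 40 %
(4 % in accelerated mode, see below) is capacity available to cells.

The EC shell is *derived*, not stored: after any geometry edit, every
wall-material voxel face-adjacent to the lumen is EC and the rest are WALL.
This keeps the shell closed under plaque insertion and remodeling by
construction.

Spherical plaques of configurable radius are carved centered on the EC
shell: lumen voxels inside the sphere become wall and the sphere's body is
filled with foam cells at voxel capacity. The three standard severity
fixtures are spheres of 0.5 / 1.0 / 1.5 mm radius, giving maximal
stenoses of 3.7 / 13.5 / 28.8 % — inside the small (0–5 %), medium
(5–20 %) and big (20–35 %) classes.

## Species transport

Five scalar fields live on the wall domain (WALL plus EC voxels): TNF-a,
IL-1b, IL-10 (U/ml), LDL and oxidized LDL (ng/ul = ug/ml). Each tick:
production by wall cells, IL-10-mediated clearance
(`IL1b *= max(0, 1 - 0.0096*IL10)`, `TNFa *= max(0, 1 - 0.0095*IL10)`),
shear-gated LDL entry at the endothelium (`C_w = C0 * P(tau)` with the
degree-6 polynomial boundary profile; 70 % of `C_w` is imposed at EC
voxels), oxidation of 1.2 %/h of local LDL into immobile oxLDL, and
Fickian diffusion with perfect sinks at the lumen and outer wall surface
(luminal convection washes solutes away).

Per-cell production rates (U/ml per hour): TNF-a 5e-6 per neutrophil and
6.7e-4 per monocyte-lineage cell; IL-1b 5e-7 and 5e-5; IL-10 3.75e-5 per
lymphocyte. By default M1 macrophages and foam cells produce at the
monocyte rates and M2 at the lymphocyte IL-10 rate (`extended_producers`,
switchable): a plaque should not go silent the moment its monocytes
differentiate.

**Numerics.** The explicit stencil is sub-stepped so the per-step
diffusion number stays at or below 1/7 — strictly inside the 3D stability
limit of 1/6, because exactly *at* the limit the checkerboard mode has
amplification −1 and persists (verified against the heat kernel: 67 %
error at 1/6, 0.7 % at 1/7 on a point source). An unconditionally stable
backward-Euler variant (scipy sparse) exists for cross-checks. Mass is
conserved to machine precision on sealed domains, the operator is linear,
and each tick's balance (production − clearance − boundary outflux) is
checkable as an accounting identity.

**Two diffusivities.** The module's default diffusivities are the
molecular values (cytokines 3e-11 m²/s, LDL 2.5e-11 m²/s). At the
100 um / 1 h discretization these are extremely fast (D·dt/h² ≈ 10.8):
with sink boundaries 300 um away, a continuously producing cell sustains
a steady maximum of only ~5e-7 U/ml — far below the 1e-3..1e-1 U/ml range
at which the endothelial activation feedback operates, so a lesion could
never ignite. Cellular-automaton models of this process move solute at
about one patch-share per tick instead. The simulation presets therefore
transport the soluble species at the lattice-equivalent rate of one
patch-hop per tick (D·dt/h² = 1/6, i.e. 4.63e-13 m²/s), which restores
both the concentration scale (1e-3..1e-1 U/ml near a lesion) and the
spatial confinement of endothelial activation to plaque-adjacent
endothelium. Both settings are plain config values; every transport
operator is exercised by tests at both rates.

## Recruitment (adhesion + transmigration)

Each EC patch is exposed to three stimuli per leukocyte type: wall shear
stress and the local TNF-a and IL-1b concentrations. Each (type, stimulus)
pair has an empirical dose-response `f(x)` — polynomials with hard
cut-offs for shear (neutrophil adhesion requires < 1.2 Pa, monocyte
< 1.0 Pa, lymphocyte 0.04–0.41 Pa; at the healthy 1.4 Pa all are silent),
saturating sigmoids for the cytokines. Probability per tick:

    p = clamp(kappa_pathway * f(x) * h * dt / t_norm, 0, 1)

with `h` = 0.1 mm, `dt` = 3600 s, `t_norm` = 1800 s. The pathways combine
as independent competing causes, `p_tot = 1 − Π(1 − p_i)` (an additive
variant is available). Available leukocytes per luminal patch are
Poisson with mean `c_type × h³` (7000/mm³ total; 62 % neutrophils, 5.3 %
monocytes, 30 % lymphocytes → 4.34 / 0.37 / 2.1 per patch), adherent
cells are Binomial in `p_tot`, and each adherent cell transmigrates with
the stiffness-dependent %TEM of its type (72.5 % for monocytes and
lymphocytes, 74.5 % for neutrophils at the normal 3 kPa wall).

**Calibration.** The dose-response fits carry the (unpublished) exposure
durations of their source experiments, so their absolute scales are not
interpretable and the two pathway families need separate scales:

* `kappa` (WSS pathways) is fixed by one documented calibration: the
  cycle-averaged *expected* TEM on the 1.0 mm-plaque fixture equals
  16 per hour. The expectation is deterministic, so a bisection
  reproduces the same value exactly (2.63e-5 under the default waveform
  and solver); it is then frozen for every other experiment.
* `kappa_cytokine` (TNF/IL-1 pathways) is anchored on the model's
  published sensitivity probabilities (p = 0.247/0.253 for IL-1b and
  0.003/0.008 for TNF-a at stated concentrations): the geometric mean of
  `p/f` over those four points gives `p = 9.2e-4 · f`, i.e.
  `kappa_cytokine = 4.6e-3`.

**Activation floor.** The fitted cytokine sigmoids have nonzero
intercepts (IL-1b response ≈ 190 at x → 0+), so a literal reading lets
vanishing trace concentrations activate endothelium arbitrarily far from
a lesion. Concentrations below 1e-6 U/ml (about two neutrophil-hours of
IL-1b secretion) are treated as no stimulus. At the 15-cell insult steady
state this leaves ~0.6–3 % of EC patches active, all adjacent to the
lesion — endothelial activation locality is emergent, not hard-coded.

## Wall agents

Six types: the three blood leukocytes, M1/M2 macrophages, foam cells.
Volumes from sphere diameters (12 um neutrophil/lymphocyte ≈ 905 um³,
24 um monocyte lineage ≈ 7238 um³, 25 um foam ≈ 8181 um³). Monocytes
draw a permanent phenotype on wall entry (P(M1) = 2/3); an M1/M2 in a
voxel with oxLDL > 100 ug/ml becomes a foam cell. Lifespans: neutrophils
72 ticks, monocyte lineage and lymphocytes 168; foam cells are immortal
plaque mass.

Chemotaxis is space-first: one voxel per tick (100 um/h) into the
26-connected (3D Moore) neighbor with free capacity and the highest
TNF-a + IL-1b, only if strictly better than the current voxel — unless
the current voxel is over capacity, in which case vacating dominates.
Ties break uniformly from a dedicated RNG stream. Cohorts transmigrating
through the same EC patch in one tick reuse the first agent's path until
the destination fills (the shared-path shortcut).

## Remodeling (Glagov)

Growth demand is crowding: TEM cohorts may transiently overfill their
entry voxel, and foam conversion swells resident volume; per plane,
`demand = floor(overflow / voxel capacity)`. Each demanded voxel is added
outward (exterior voxel next to the most burdened wall sector) while
plaque area < 40 % of lumen area in that plane — the lumen is exactly
preserved — and inward with probability 0.65 (lumen voxel next to the
most burdened endothelial segment; the shell is re-derived, the lumen
shrinks by exactly one patch) once the 40 % threshold is met. After
growth, overflowing cells are displaced into the freed space; this
displacement moves any cell type including foam (a foam-packed voxel
would otherwise re-demand growth forever), whereas chemotaxis never moves
foam. A sub-capacity floor residual (< 1 voxel capacity per plane) can
remain within a tick.

Inward site selection via local burden reproduces the observed pattern
that the first luminal protrusions appear lateral to the plaque
centerline, as emergent behavior.

## Hemodynamics

The agent model consumes one scalar per EC voxel: wall shear stress (Pa).
Three backends:

* `poiseuille` — per plane, area-equivalent radius from the lumen patch
  count and τ = 4μQ/(πr³), azimuthally modulated by each EC voxel's own
  axis distance (cubic law). Fast; no separation physics.
* `axisym` (default) — steady laminar axisymmetric Navier–Stokes in
  stream-function–vorticity form on the area-equivalent profile
  (uniform (z, r) grid, stair-step wall, Thom wall vorticity, upwind
  pseudo-time transport, SOR Poisson sweeps; inlet Poiseuille, outlet
  zero-gradient, rigid wall). Validated against the closed form on
  straight tubes (< 5 % mid-tube). At coronary Reynolds numbers
  (Re ≈ 200 at mean flow) a stenosis sheds a distal separation zone of
  near-zero wall shear — the recruitment-permissive region that drives
  the coupled dynamics. Wall shear is reported as μ|ω_wall| with a local
  cubic stair-step correction; each plane's value maps uniformly to its
  EC ring (the backend is axisymmetric by construction).
* `imported` — a per-voxel CSV table (e.g. from an external 3D CFD
  package); it must cover every EC voxel.

Blood: Newtonian, ρ = 1060 kg/m³, μ = 3.5e-3 Pa·s. The coronary inflow
waveform is a parameterized biphasic curve with period 0.8 s sampled at
0.01 s (80 points): a baseline, a dominant peak at 30 % of the cycle and
a broad secondary hump, normalized so the mean flow gives the healthy
1.4 Pa in the straight artery (Q_mean = 1.83 ml/s; peak/mean ≈ 2.3,
min/mean ≈ 0.39). Any sampled waveform can be supplied instead.

Evaluation policies: `full_cycle` (one WSS field per waveform sample; the
timescale experiment), `peak_systole` (single field at maximum flow; the
standard operating point), `steady_mean` (single field at mean flow).
The handshake schedule recomputes WSS either at every change of the total
lumen voxel count or, in accelerated mode, after a per-severity quota of
cumulative changes (80/35/10 patches for small/medium/big).

The luminal surface exporter sorts EC centroids azimuthally per plane,
averages consecutive pairs, applies a circular moving average, resamples
64 uniform azimuths and stitches a watertight triangle mesh (binary STL)
— the shape a 3D CFD package would mesh.

## Experiments and calibrated behavior

With `kappa` calibrated on the 1.0 mm fixture (cycle average = 16 TEM/h)
and then frozen, the model *predicts* ≈ 26–27 TEM/h on the 1.5 mm fixture
and ≈ 7–8 TEM/h under a single mean-steady-flow field — bigger plaques
carve larger low-shear zones, and a steady mean never visits the low-flow
phases that recruit most cells. The peak-systole single snapshot
*under*-recruits relative to the full cycle under this backend (≈ 2/h on
the 1.0 mm fixture): in an axisymmetric solve of a mild area-equivalent
stenosis the peak-flow separation zone is small, so the peak snapshot
cannot stand in for the cycle average. This is a known, documented
divergence between the built-in solver and a full 3D solve of the
one-sided plaque geometry; the ordering full_cycle > steady_mean is
robust across both fixtures.

The accelerated mode (capacity 4 % instead of 40 %) reaches geometric
milestones quickly while preserving the WSS-driven recruitment dynamics;
the constant-zone experiment tracks TEM rate against cumulative
lumen-voxel change with a WSS update at every change, and detects the
end of the flat zone as the first sustained excursion of the
per-change-interval TEM rate above its early baseline (z > 3, two
consecutive intervals, the pre-change ignition era excluded).

The stenosis-response protocol runs with active foam-cell fixture bodies
and the full rule set: the cytokine output of the seeded plaque keeps the
adjacent endothelium activated, which is the only mechanism under the
axisymmetric backend that crowds voxels fast enough to drive geometry.
Two alternatives were evaluated and rejected, and remain available as
flags: silencing the cytokine pathways ("TEM as a function of WSS only")
leaves the per-patch influx so dilute — the axisymmetric low-shear zone
is an entire endothelial ring per plane, not a localized 3D shoulder —
that zero to forty lumen changes occur in thousands of hours; an inert
(cytokine-silent) fixture body never ignites the small fixture at all.
Under the adopted protocol the measured constant zones are roughly
40–60 / 35 / 24 lumen patches for the small / medium / big fixtures
(seed-dependent; the change-point statistic is noisy), against published
values of 80 / 35 / 10: the monotone ordering and the middle value
reproduce, the extremes compress toward the middle.

## Problem sizes used by the test suite

The test suite and the acceptance script re-run every protocol at sizes
chosen to keep a full run on one CPU within minutes: the cardiac-cycle
and accelerated experiments use the published geometry; the long
atherogenesis protocols (Glagov onset, lineage knockout, seed-to-seed
spread) run on the published geometry but with capped durations, and the
knockout/stochasticity comparisons use a shortened artery (stated in each
test) with proportionally shortened horizons. Each test states its own
scale; the quantities it checks are reported at that scale.

## Known limitations

* The wall is rigid and the centerline straight; no bifurcations,
  curvature or patient-specific geometry.
* The built-in flow backends are axisymmetric on the area-equivalent
  profile: a one-sided plaque's true 3D separation pattern (and hence the
  peak-systole equivalence discussed above) needs an imported 3D field.
* oxLDL is immobile and is not depleted by foam-cell formation (no
  stoichiometry is specified for uptake); its concentration grows
  monotonically where LDL enters.
* ECM is fixed at 60 % of every wall voxel: no matrix degradation or
  smooth-muscle contribution, so plaque mass is leukocyte-derived only.
* Cytokine "U/ml" units are assay-defined in the source fits; no
  conversion to mass concentrations is attempted.
* The recruitment feedback loop, parameterized from the published pathway
  probabilities, ignites vigorously: the plaque/lumen ratio reaches the
  40 % remodeling threshold at ~2.8 simulated months (measured on the
  full-size and half-length presets alike) — about twice as fast as the
  ~6 months the qualitative narrative suggests — and the wall populations
  grow to ~10^5–10^6 cells, so the seed-to-seed census spread is on the
  order of thousands of cells rather than the published bound of ~220.
  The timeline and population scale depend on the product of the cytokine
  pathway scale and the activation footprint, which the available
  constants pin only to within a factor of a few. The monocyte-knockout
  contrast lands close to the published one (~91 % plaque-area reduction
  at 10 weeks vs ~80 %).
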