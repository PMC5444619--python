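"""The tick loop: configuration, RNG streams, event logs and audits.

A simulation advances in 1 h ticks with a fixed intra-tick order:

    species transport -> recruitment / TEM -> chemotaxis ->
    differentiation & death -> Glagov remodeling -> (conditional) WSS update

All stochastic draws come from named substreams (recruitment, chemotaxis,
differentiation, remodeling) spawned from one master seed, so a run is fully
reproducible and each sub-process can be replayed independently. Identical
config and seed give byte-identical census tables.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import params
from .agents import TYPE_CODES, TYPE_NAMES, Population
from .hemodynamics import (BloodProperties, FlowWaveform, WSSField,
                           estimate_wss, make_uniform_wss, select_wss_policy,
                           should_update_wss)
from .lattice import (EC, WALL, GeometrySpec, build_artery,
                      insert_spherical_plaque, plane_areas)
from .recruitment import LEUKOCYTE_TYPES, RecruitmentConfig, combine_and_sample
from .remodeling import RemodelingPolicy, glagov_tick
from .species import TransportModel

#: default composition of the 15-leukocyte initial insult (rounded from the
#: 62 / 5.3 / 30 % blood proportions)
DEFAULT_INSULT = {"NEUTROPHIL": 9, "MONOCYTE": 1, "LYMPHOCYTE": 5}


@dataclasses.dataclass
class WSSSettings:
    backend: str = "axisym"                 # "axisym" | "poiseuille"
    policy: str = "peak_systole"            # "peak_systole" | "steady_mean"
    handshake: str = "per_lumen_change"     # or "accelerated"
    quota: int = 0                          # accelerated-mode patch quota
    fixed_wss_pa: Optional[float] = None    # uniform imported field, overrides
    waveform: Optional[FlowWaveform] = None

    def resolve_waveform(self) -> FlowWaveform:
        return self.waveform if self.waveform is not None else FlowWaveform.default()


@dataclasses.dataclass
class SimulationConfig:
    geometry: GeometrySpec = dataclasses.field(default_factory=GeometrySpec)
    capacity_fraction: float = params.CAPACITY_FRACTION_NORMAL
    duration_ticks: int = 24
    seed: int = 0
    recruitment: RecruitmentConfig = dataclasses.field(
        default_factory=RecruitmentConfig)
    wss: WSSSettings = dataclasses.field(default_factory=WSSSettings)
    remodeling: RemodelingPolicy = dataclasses.field(
        default_factory=RemodelingPolicy)
    insult: Optional[dict[str, int]] = None       # e.g. DEFAULT_INSULT
    knockout: Optional[str] = None                # leukocyte type removed
    c0_blood_ng_ul: float = params.LDL_BLOOD_NG_UL
    extended_producers: bool = True
    duplicated_cubic: bool = False
    #: per-species diffusivity overrides; presets transport solutes at the
    #: one-patch-hop-per-tick lattice rate (see params.PRESET_DIFFUSIVITY_M2_S)
    diffusivities: dict = dataclasses.field(
        default_factory=lambda: dict(params.PRESET_DIFFUSIVITY_M2_S))
    chemo_step_budget: int = 1
    audit_every: int = 24
    log_tem_events: bool = False

    def manifest(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj
        return enc(self)


@dataclasses.dataclass
class RunOutputs:
    census: pd.DataFrame
    tem_log: pd.DataFrame
    remodel_log: pd.DataFrame
    manifest: dict

    def write(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.census.to_csv(out / "census.csv", index=False)
        self.tem_log.to_csv(out / "tem_log.csv", index=False)
        self.remodel_log.to_csv(out / "remodel_log.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


class Simulation:
    """One configured run; construct, then :meth:`run`."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        bare_spec = dataclasses.replace(config.geometry, plaques=())
        self.lattice = build_artery(bare_spec, config.capacity_fraction)
        self.population = Population(self.lattice)
        for center, radius in config.geometry.plaques:
            insert_spherical_plaque(self.lattice, center, radius,
                                    self.population)
        self.transport = TransportModel(
            self.lattice, config.c0_blood_ng_ul, config.duplicated_cubic,
            config.extended_producers, config.diffusivities)
        self.recruitment_cfg = dataclasses.replace(config.recruitment)
        if config.knockout:
            conc = dict(self.recruitment_cfg.blood_conc_per_mm3)
            conc[config.knockout] = 0.0
            self.recruitment_cfg.blood_conc_per_mm3 = conc

        ss = np.random.SeedSequence(config.seed)
        streams = ss.spawn(4)
        self.rng_recruit = np.random.Generator(np.random.PCG64(streams[0]))
        self.rng_chemo = np.random.Generator(np.random.PCG64(streams[1]))
        self.rng_diff = np.random.Generator(np.random.PCG64(streams[2]))
        self.rng_remodel = np.random.Generator(np.random.PCG64(streams[3]))

        if config.insult:
            self._place_insult(config.insult)

        self.blood = BloodProperties()
        self.waveform = config.wss.resolve_waveform()
        self.tick_index = 0
        self.wss_updates = 0
        self._warm = None
        self.wss_field = self._compute_wss()
        self.lumen_at_last_update = self.lattice.total_lumen_voxels()
        self.cumulative_lumen_change = 0
        self._census_rows: list[dict] = []
        self._tem_rows: list[dict] = []
        self._remodel_rows: list[dict] = []
        self._refresh_ec()

    # -- setup helpers --------------------------------------------------------

    def _place_insult(self, counts: dict[str, int]) -> None:
        """Seed leukocytes in the middle of the arterial wall."""
        lat = self.lattice
        z = lat.nz // 2
        r_mid = (self.config.geometry.lumen_radius_um
                 + 0.5 * self.config.geometry.wall_thickness_um) / lat.patch_size_um
        cx, cy = lat.axis_xy
        i = int(cx + r_mid)
        j = int(cy)
        # nudge to an actual WALL voxel
        cls = lat.patch_class
        if cls[i, j, z] != WALL:
            wall_xy = np.argwhere(cls[:, :, z] == WALL)
            d2 = (wall_xy[:, 0] - i) ** 2 + (wall_xy[:, 1] - j) ** 2
            i, j = wall_xy[int(np.argmin(d2))]
        for name, n in counts.items():
            self.population.add_agents(TYPE_CODES[name], (int(i), int(j), z), n)

    def _refresh_ec(self) -> None:
        self.ec_voxels = np.argwhere(self.lattice.patch_class == EC)
        self._ec_entry = self._entry_voxels(self.ec_voxels)
        self._ec_entry_flat = np.ravel_multi_index(
            (self._ec_entry[:, 0], self._ec_entry[:, 1], self._ec_entry[:, 2]),
            self.lattice.dims)

    def _entry_voxels(self, ec_voxels: np.ndarray) -> np.ndarray:
        """For each EC voxel, the face-adjacent WALL voxel furthest from the
        axis (the radially outward entry into the wall)."""
        lat = self.lattice
        cls = lat.patch_class
        cx, cy = lat.axis_xy
        out = np.empty((len(ec_voxels), 3), dtype=np.int64)
        for n, (i, j, k) in enumerate(ec_voxels):
            best = None
            best_d = -1.0
            for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                               (0, 0, 1), (0, 0, -1)):
                x, y, z = i + dx, j + dy, k + dz
                if not (0 <= x < lat.nx and 0 <= y < lat.ny and 0 <= z < lat.nz):
                    continue
                if cls[x, y, z] != WALL:
                    continue
                d = (x + 0.5 - cx) ** 2 + (y + 0.5 - cy) ** 2
                if d > best_d:
                    best_d = d
                    best = (x, y, z)
            out[n] = best if best is not None else (i, j, k)
        return out

    def _compute_wss(self) -> WSSField:
        cfg = self.config.wss
        if cfg.fixed_wss_pa is not None:
            return make_uniform_wss(self.lattice, cfg.fixed_wss_pa)
        phases = select_wss_policy(self.waveform, cfg.policy)
        t, q = phases[0]
        field = estimate_wss(self.lattice, q, self.blood, cfg.backend,
                             at_time=f"t={t:.3f}s", warm_start=self._warm)
        self._warm = getattr(field, "solution", None)
        self.wss_updates += 1
        return field

    # -- the tick loop --------------------------------------------------------

    def step(self) -> None:
        cfg = self.config
        lat = self.lattice
        pop = self.population
        tick = self.tick_index

        # 1. species transport
        self.transport.tick(pop.counts, self.wss_field.values)
        fields = self.transport.fields

        # 2. recruitment / TEM
        tem_by_type = dict.fromkeys(LEUKOCYTE_TYPES, 0)
        adherent_by_type = dict.fromkeys(LEUKOCYTE_TYPES, 0)
        ec = self.ec_voxels
        if len(ec):
            ei, ej, ek = ec[:, 0], ec[:, 1], ec[:, 2]
            wss = self.wss_field.values[ei, ej, ek]
            tnfa = fields["TNFA"][ei, ej, ek]
            il1b = fields["IL1B"][ei, ej, ek]
            attractant = fields["TNFA"] + fields["IL1B"]
            sampled = combine_and_sample(wss, tnfa, il1b,
                                         self.recruitment_cfg,
                                         self.rng_recruit)
            for t_name, (adherent, migrated) in sampled.items():
                adherent_by_type[t_name] = int(adherent.sum())
                tem_by_type[t_name] = int(migrated.sum())
                hits = np.flatnonzero(migrated)
                if hits.size == 0:
                    continue
                pop.place_tem_cohorts(
                    TYPE_CODES[t_name], self._ec_entry_flat[hits],
                    migrated[hits], attractant, self.rng_chemo)
                if cfg.log_tem_events:
                    for n in hits:
                        self._tem_rows.append({
                            "tick": tick, "x": int(ec[n, 0]), "y": int(ec[n, 1]),
                            "z": int(ec[n, 2]), "type": t_name,
                            "count": int(migrated[n]),
                            "wss_pa": float(wss[n]), "tnfa": float(tnfa[n]),
                            "il1b": float(il1b[n])})

        # 3. chemotaxis
        attractant = fields["TNFA"] + fields["IL1B"]
        pop.chemotaxis_tick(attractant, self.rng_chemo, cfg.chemo_step_budget)

        # 4. differentiation and death
        pop.differentiate_and_transform(fields["OXLDL"], self.rng_diff)
        pop.age_and_die()

        # 5. remodeling
        events = glagov_tick(lat, pop, cfg.remodeling, self.rng_remodel, tick)
        if events:
            self.transport.rebuild()
            self._refresh_ec()
            for ev in events:
                self._remodel_rows.append({
                    "tick": ev.tick, "z": ev.z, "direction": ev.direction,
                    "x": ev.voxel[0], "y": ev.voxel[1]})

        # 6. conditional WSS update
        lumen_now = lat.total_lumen_voxels()
        if cfg.wss.fixed_wss_pa is None and should_update_wss(
                cfg.wss.handshake, lumen_now, self.lumen_at_last_update,
                cfg.wss.quota):
            self.cumulative_lumen_change += abs(
                lumen_now - self.lumen_at_last_update)
            self.wss_field = self._compute_wss()
            self.lumen_at_last_update = lumen_now
        elif cfg.wss.fixed_wss_pa is not None:
            self.cumulative_lumen_change += abs(
                lumen_now - self.lumen_at_last_update)
            self.lumen_at_last_update = lumen_now

        # census and audits
        census = pop.census()
        row = {"tick": tick, "lumen_voxels": lumen_now,
               "cumulative_lumen_change": self.cumulative_lumen_change,
               "wss_updates": self.wss_updates,
               "tem_total": sum(tem_by_type.values()),
               "adherent_total": sum(adherent_by_type.values())}
        for name in TYPE_NAMES:
            row[name.lower()] = census[name]
        for name in LEUKOCYTE_TYPES:
            row[f"tem_{name.lower()}"] = tem_by_type[name]
        row["plaque_patches"] = int(np.count_nonzero(
            (lat.patch_class == WALL) & (lat.agent_count > 0)))
        self._census_rows.append(row)

        if cfg.audit_every and (tick + 1) % cfg.audit_every == 0:
            self.audit()
        self.tick_index += 1

    def audit(self) -> None:
        """Reconcile incremental bookkeeping against from-scratch recounts."""
        self.population.audit()
        lat = self.lattice
        n_classes = np.bincount(lat.patch_class.ravel(), minlength=4).sum()
        assert n_classes == lat.patch_class.size
        # EC shell closure: every lumen-adjacent wall-material voxel is EC
        from .lattice import LUMEN as _L
        cls = lat.patch_class
        lumen = cls == _L
        for off in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                    (0, 0, 1), (0, 0, -1)):
            shifted = np.roll(lumen, off, axis=(0, 1, 2))
            bad = shifted & (cls == WALL)
            # roll wraps around; ignore wrapped borders (exterior there)
            if off[0]:
                bad[0 if off[0] > 0 else -1, :, :] = False
            if off[1]:
                bad[:, 0 if off[1] > 0 else -1, :] = False
            if off[2]:
                bad[:, :, 0 if off[2] > 0 else -1] = False
            assert not bad.any(), "EC shell not closed"

    def run(self, until: Optional[Callable[["Simulation"], bool]] = None
            ) -> RunOutputs:
        for _ in range(self.config.duration_ticks):
            self.step()
            if until is not None and until(self):
                break
        return self.outputs()

    def outputs(self) -> RunOutputs:
        census = pd.DataFrame(self._census_rows)
        tem = pd.DataFrame(self._tem_rows)
        remodel = pd.DataFrame(self._remodel_rows)
        return RunOutputs(census, tem, remodel, self.config.manifest())

    # -- convenience ----------------------------------------------------------

    def total_plaque_patches(self) -> int:
        lat = self.lattice
        return int(np.count_nonzero((lat.patch_class == WALL)
                                    & (lat.agent_count > 0)))

    def max_plaque_to_lumen_ratio(self) -> float:
        best = 0.0
        for z in range(self.lattice.nz):
            lumen, plaque = plane_areas(self.lattice, z)
            if lumen:
                best = max(best, plaque / lumen)
        return best
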