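"""Wall-agent life: chemotaxis, differentiation, aging, bookkeeping."""

import numpy as np

from atherosim import params
from atherosim.agents import (FOAM, LYMPHOCYTE, M1, M2, MONOCYTE, NEUTROPHIL,
                              Population, VOLUMES)
from atherosim.lattice import WALL
from atherosim.species import TransportModel


def wall_line(lattice, length):
    """A straight run of WALL voxels along z at one (i, j) column."""
    cls = lattice.patch_class
    for i in range(lattice.nx):
        for j in range(lattice.ny):
            if np.all(cls[i, j, :] == WALL):
                assert lattice.nz >= length
                return i, j
    raise AssertionError("no wall column found")


class TestChemotaxis:
    def test_uniform_field_no_move(self, small_artery, rng):
        pop = Population(small_artery)
        i, j = wall_line(small_artery, 6)
        pop.add_agents(NEUTROPHIL, (i, j, 3), 1)
        before = pop.voxel[0]
        moves = pop.chemotaxis_tick(np.zeros(small_artery.dims), rng)
        assert moves == 0
        assert pop.voxel[0] == before

    def test_moves_up_gradient_one_voxel_per_tick(self, small_artery, rng):
        pop = Population(small_artery)
        i, j = wall_line(small_artery, 8)
        pop.add_agents(NEUTROPHIL, (i, j, 1), 1)
        attract = np.zeros(small_artery.dims)
        attract[i, j, :] = np.arange(small_artery.nz)  # rises along z
        pop.chemotaxis_tick(attract, rng)
        z1 = pop.voxel[0] % small_artery.nz
        assert z1 == 2
        pop.chemotaxis_tick(attract, rng)
        assert pop.voxel[0] % small_artery.nz == 3

    def test_all_neighbors_full_agent_stays(self, small_artery, rng):
        lat = small_artery
        pop = Population(lat)
        i, j = wall_line(lat, 6)
        pop.add_agents(NEUTROPHIL, (i, j, 3), 1)
        # saturate every voxel except the agent's own
        flat = pop.voxel[0]
        occ = lat.occupied_volume_um3
        occ[lat.patch_class == WALL] = lat.voxel_capacity_um3
        ijk = np.unravel_index(flat, lat.dims)
        occ[ijk] = VOLUMES[NEUTROPHIL]
        attract = np.zeros(lat.dims)
        attract[i, j, :] = np.arange(lat.nz)       # gradient exists
        moves = pop.chemotaxis_tick(attract, rng)
        assert moves == 0

    def test_settled_agents_sit_at_local_maxima(self, small_artery, rng):
        """Iterating chemotaxis on a static field converges, and at
        convergence no agent has an admissible strictly better neighbor."""
        lat = small_artery
        pop = Population(lat)
        wall = np.argwhere(lat.patch_class == WALL)
        for i, j, k in wall[:: max(1, len(wall) // 40)]:
            pop.add_agents(NEUTROPHIL, (int(i), int(j), int(k)), 1)
        attract = np.zeros(lat.dims)
        attract[lat.patch_class == WALL] = rng.random(
            int((lat.patch_class == WALL).sum()))
        for _ in range(200):
            if pop.chemotaxis_tick(attract, rng) == 0:
                break
        else:
            raise AssertionError("chemotaxis did not settle")
        flat_attr = attract.ravel()
        free = (lat.voxel_capacity_um3 - lat.occupied_volume_um3).ravel()
        is_wall = (lat.patch_class == WALL).ravel()
        nx, ny, nz = lat.dims
        for slot in range(pop.size):
            here = pop.voxel[slot]
            k = here % nz
            j = (here // nz) % ny
            i = here // (ny * nz)
            vol = VOLUMES[pop.type_code[slot]]
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        x, y, z = i + dx, j + dy, k + dz
                        if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
                            continue
                        nb = (x * ny + y) * nz + z
                        if is_wall[nb] and free[nb] >= vol:
                            # admissible neighbor never strictly beats home
                            assert flat_attr[nb] <= flat_attr[here] + 1e-12

    def test_capacity_respected_after_chemotaxis(self, small_artery, rng):
        lat = small_artery
        pop = Population(lat)
        i, j = wall_line(lat, 6)
        for z in range(4):
            pop.add_agents(NEUTROPHIL, (i, j, z), 5)
        attract = np.zeros(lat.dims)
        attract[i, j, :] = 1.0
        pop.chemotaxis_tick(attract, rng)
        pop.audit()
        assert np.all(lat.occupied_volume_um3 <= lat.voxel_capacity_um3 + 1e-9)


class TestWorkedChemotaxisSchedule:
    def test_agent_reaches_source_by_tick_8(self, small_artery, rng):
        """The worked chemotaxis example: an agent five patches from a
        producing source starts moving when the diffusing gradient arrives
        and stands on the source patch at tick 8 (one move per tick)."""
        lat = small_artery
        pop = Population(lat)
        i, j = wall_line(lat, 10)
        z_agent, z_source = 2, 7
        pop.add_agents(LYMPHOCYTE, (i, j, z_agent), 1)     # non-producing
        # one-substep-per-tick diffusivity: the front advances one patch/tick
        d_hop = (params.PATCH_SIZE_UM * 1e-6) ** 2 / (7.0 * params.TICK_SECONDS)
        model = TransportModel(lat, diffusivities={
            "TNFA": d_hop, "IL1B": 0.0, "IL10": 0.0, "LDL": 0.0})
        counts = {"NEUTROPHIL": np.zeros(lat.dims)}
        counts["NEUTROPHIL"][i, j, z_source] = 20
        arrival = None
        for tick in range(1, 13):
            model.tick(counts)
            attract = model.fields["TNFA"] + model.fields["IL1B"]
            pop.chemotaxis_tick(attract, rng)
            z_now = pop.voxel[0] % lat.nz
            if z_now == z_source and arrival is None:
                arrival = tick
        assert arrival == 8

    def test_waits_until_gradient_arrives(self, small_artery, rng):
        lat = small_artery
        pop = Population(lat)
        i, j = wall_line(lat, 10)
        pop.add_agents(LYMPHOCYTE, (i, j, 2), 1)
        d_hop = (params.PATCH_SIZE_UM * 1e-6) ** 2 / (7.0 * params.TICK_SECONDS)
        model = TransportModel(lat, diffusivities={
            "TNFA": d_hop, "IL1B": 0.0, "IL10": 0.0, "LDL": 0.0})
        counts = {"NEUTROPHIL": np.zeros(lat.dims)}
        counts["NEUTROPHIL"][i, j, 7] = 20
        model.tick(counts)
        pop.chemotaxis_tick(model.fields["TNFA"], rng)
        assert pop.voxel[0] % lat.nz == 2      # gradient not here yet


class TestSharedPath:
    def test_cohort_shares_destination_until_full(self, small_artery, rng):
        lat = small_artery
        pop = Population(lat)
        i, j = wall_line(lat, 6)
        attract = np.zeros(lat.dims)
        attract[i, j, 4] = 5.0          # best neighbor of (i, j, 3)
        cap_cells = int(lat.voxel_capacity_um3 // VOLUMES[MONOCYTE])
        placed = pop.shared_path_shortcut(MONOCYTE, (i, j, 3),
                                          cap_cells + 10, attract, rng)
        dest = np.ravel_multi_index((i, j, 4), lat.dims)
        entry = np.ravel_multi_index((i, j, 3), lat.dims)
        assert placed.count(dest) == cap_cells
        assert placed.count(entry) == 10
        # destination filled exactly to capacity
        assert lat.occupied_volume_um3[i, j, 4] <= lat.voxel_capacity_um3
        pop.audit()

    def test_cohort_of_one_matches_single_step(self, small_artery, rng):
        lat = small_artery
        pop = Population(lat)
        i, j = wall_line(lat, 6)
        attract = np.zeros(lat.dims)
        attract[i, j, 4] = 1.0
        placed = pop.shared_path_shortcut(NEUTROPHIL, (i, j, 3), 1,
                                          attract, rng)
        assert placed == [np.ravel_multi_index((i, j, 4), lat.dims)]


class TestDifferentiation:
    def test_m1_m2_ratio(self, small_artery, rng):
        """30,000 monocyte entries split 2:1 into M1:M2 within binomial
        tolerance."""
        lat = small_artery
        pop = Population(lat)
        wall = np.argwhere(lat.patch_class == WALL)
        n = 30000
        for m, (i, j, k) in enumerate(wall[:60]):
            pop.add_agents(MONOCYTE, (int(i), int(j), int(k)), n // 60,
                           enforce_capacity=False)
        pop.differentiate_and_transform(np.zeros(lat.dims), rng)
        census = pop.census()
        frac = census["M1"] / n
        sd = np.sqrt(2 / 3 * 1 / 3 / n)
        assert abs(frac - 2 / 3) < 4 * sd
        assert census["MONOCYTE"] == 0

    def test_foam_conversion_threshold(self, small_artery, rng):
        lat = small_artery
        pop = Population(lat)
        i, j = wall_line(lat, 4)
        pop.add_agents(M1, (i, j, 0), 1)
        pop.add_agents(M2, (i, j, 1), 1)
        ox = np.zeros(lat.dims)
        ox[i, j, 0] = 99.0      # below the 100 ug/ml threshold
        ox[i, j, 1] = 101.0
        pop.differentiate_and_transform(ox, rng)
        census = pop.census()
        assert census["M1"] == 1
        assert census["M2"] == 0
        assert census["FOAM"] == 1
        pop.audit()


class TestAgingAndDeath:
    def test_lifespans(self, small_artery):
        lat = small_artery
        pop = Population(lat)
        i, j = wall_line(lat, 4)
        pop.add_agents(NEUTROPHIL, (i, j, 0), 1)
        pop.add_agents(MONOCYTE, (i, j, 1), 1)
        pop.add_agents(FOAM, (i, j, 2), 1)
        for _ in range(73):
            pop.age_and_die()
        census = pop.census()
        assert census["NEUTROPHIL"] == 0      # gone after 72 ticks
        assert census["MONOCYTE"] == 1
        assert census["FOAM"] == 1
        for _ in range(96):
            pop.age_and_die()
        census = pop.census()
        assert census["MONOCYTE"] == 0        # gone after 168 ticks
        assert census["FOAM"] == 1            # plaque mass persists

    def test_non_foam_population_vanishes_without_recruitment(
            self, small_artery, rng):
        lat = small_artery
        pop = Population(lat)
        i, j = wall_line(lat, 6)
        for z, code in enumerate((NEUTROPHIL, MONOCYTE, LYMPHOCYTE, M1, M2)):
            pop.add_agents(code, (i, j, z), 3)
        for _ in range(169):
            pop.age_and_die()
        census = pop.census()
        assert sum(census[t] for t in
                   ("NEUTROPHIL", "MONOCYTE", "LYMPHOCYTE", "M1", "M2")) == 0

    def test_bookkeeping_survives_deaths_and_moves(self, small_artery, rng):
        lat = small_artery
        pop = Population(lat)
        wall = np.argwhere(lat.patch_class == WALL)
        gens = np.random.Generator(np.random.PCG64(7))
        for i, j, k in wall[:: max(1, len(wall) // 100)]:
            code = int(gens.integers(0, 6))
            pop.add_agents(code, (int(i), int(j), int(k)),
                           int(gens.integers(1, 4)), enforce_capacity=False)
        attract = np.zeros(lat.dims)
        attract[lat.patch_class == WALL] = gens.random(
            int((lat.patch_class == WALL).sum()))
        for _ in range(80):
            pop.chemotaxis_tick(attract, rng)
            pop.age_and_die()
        pop.audit()      # incremental bookkeeping == recount from scratch
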