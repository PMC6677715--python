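"""Population layer: pressure, currents, nutrient, proliferation and the
event-driven sampler."""

import numpy as np
import pytest

from stochtissue import (
    EventLog,
    GrowthParams,
    PopulationGrid,
    build_hex_lattice,
    build_square_lattice,
    movement_rates,
    nutrient_field,
    proliferation_rates,
    simulate_population,
    solve_pressure,
)
from stochtissue.dlcm import boundary_outflux


@pytest.fixture
def chain121():
    lat = build_square_lattice(5, 1)
    return PopulationGrid.from_occupancy(lat, [0, 1, 2, 1, 0])


class TestPressure:
    def test_no_overcrowding_means_zero_pressure(self):
        lat = build_hex_lattice(6, 6)
        u = np.zeros(36, dtype=int)
        u[[14, 15, 20, 21]] = 1
        grid = PopulationGrid.from_occupancy(lat, u)
        assert np.all(solve_pressure(grid) == 0.0)

    def test_chain_oracle(self, chain121):
        """Hand-solved tridiagonal system for occupancies (1,2,1)."""
        p = solve_pressure(chain121)
        assert np.allclose(p[[1, 2, 3]], [0.5, 1.0, 0.5], atol=1e-10)
        assert p[0] == p[4] == 0.0

    def test_discrete_divergence_identity_randomized(self, rng):
        """Total source equals total boundary outflux (to solver
        tolerance) for random 2-D configurations."""
        lat = build_hex_lattice(9, 9)
        for _ in range(100):
            u = np.zeros(lat.n_cells, dtype=int)
            # random connected-ish blob around the center
            picks = rng.choice(lat.n_cells, size=rng.integers(2, 30),
                               replace=False)
            u[picks] = rng.integers(1, 3, size=len(picks))
            if np.all(u < 2):
                u[picks[0]] = 2
            grid = PopulationGrid.from_occupancy(lat, u)
            p = solve_pressure(grid)
            source = float((u == 2).sum())
            assert boundary_outflux(grid, p) == pytest.approx(source,
                                                              abs=1e-10)
            assert np.all(p >= -1e-12)  # maximum principle

    def test_fully_occupied_lattice_is_an_error(self):
        lat = build_hex_lattice(3, 3)
        grid = PopulationGrid.from_occupancy(lat, np.ones(9, dtype=int))
        grid.u[4] = 2
        grid.cells[4].append(grid.next_cell_id)
        grid.cell_voxel[grid.next_cell_id] = 4
        grid.next_cell_id += 1
        with pytest.raises(ValueError):
            solve_pressure(grid)

    def test_symmetric_configuration_gives_symmetric_pressure(self):
        """A doubly occupied voxel at the center of a symmetric cross on
        a square lattice: the four arms see identical pressure."""
        lat = build_square_lattice(5, 5)
        u = np.zeros(25, dtype=int)
        center = 12
        arms = [7, 11, 13, 17]
        u[center] = 2
        u[arms] = 1
        grid = PopulationGrid.from_occupancy(lat, u)
        p = solve_pressure(grid)
        assert np.allclose(p[arms], p[arms[0]], atol=1e-12)


class TestMovementRates:
    def test_equilibrium_no_moves(self):
        lat = build_hex_lattice(5, 5)
        u = np.zeros(25, dtype=int)
        u[12] = 1
        grid = PopulationGrid.from_occupancy(lat, u)
        p = solve_pressure(grid)
        assert movement_rates(grid, p, GrowthParams()) == []

    def test_chain_rates(self, chain121):
        p = solve_pressure(chain121)
        rates = dict(((i, j), r) for i, j, r in
                     movement_rates(chain121, p,
                                    GrowthParams(prevent_detachment=False)))
        # doubly occupied center pushes both ways at 1 - 1/2
        assert rates[(2, 1)] == pytest.approx(0.5)
        assert rates[(2, 3)] == pytest.approx(0.5)
        # edge cells leak into the empty ends at 1/2 - 0
        assert rates[(1, 0)] == pytest.approx(0.5)
        assert rates[(3, 4)] == pytest.approx(0.5)
        # no uphill or equal-occupancy moves
        assert (1, 2) not in rates and (3, 2) not in rates

    def test_detachment_guard_blocks_fragmenting_moves(self, chain121):
        """With the default type-dependent conversion factor, a sole
        occupant may not hop somewhere that severs it from the rest."""
        p = solve_pressure(chain121)
        moves = {(i, j) for i, j, _ in
                 movement_rates(chain121, p, GrowthParams())}
        # end cells may not pop into the empty ends (they would detach),
        # but the double may still push into its lighter neighbors
        assert (1, 0) not in moves and (3, 4) not in moves
        assert (2, 1) in moves and (2, 3) in moves

    def test_equal_occupancy_blocked(self):
        """u_i = u_j = 1 across an edge admits no move even under a
        pressure difference."""
        lat = build_square_lattice(4, 1)
        grid = PopulationGrid.from_occupancy(lat, [2, 1, 1, 0])
        p = solve_pressure(grid)
        moves = {(i, j) for i, j, _ in
                 movement_rates(grid, p, GrowthParams())}
        assert (1, 2) not in moves  # p[1] > p[2] but equal occupancy


class TestNutrient:
    def test_no_consumption_flat_field(self):
        lat = build_hex_lattice(5, 5)
        u = np.zeros(25, dtype=int)
        u[[11, 12, 13]] = 1
        grid = PopulationGrid.from_occupancy(lat, u)
        c = nutrient_field(grid, GrowthParams(kappa=0.0, c_b=1.0))
        assert np.allclose(c, 1.0)

    def test_single_cell_consumption(self):
        lat = build_hex_lattice(5, 5)
        u = np.zeros(25, dtype=int)
        u[12] = 1
        grid = PopulationGrid.from_occupancy(lat, u)
        gp = GrowthParams(kappa=0.12, c_b=1.0)
        c = nutrient_field(grid, gp)
        deg = 6  # interior hex voxel
        assert c[12] == pytest.approx(1.0 - 0.12 / deg)

    def test_interior_depleted_boundary_maximal(self):
        lat = build_hex_lattice(9, 9)
        u = np.zeros(lat.n_cells, dtype=int)
        center = 40
        u[center] = 1
        for j in lat.neighbors(center):
            u[j] = 1
            for k in lat.neighbors(int(j)):
                u[k] = 1
        grid = PopulationGrid.from_occupancy(lat, u)
        gp = GrowthParams(kappa=0.2, c_b=1.0)
        c = nutrient_field(grid, gp)
        occ = grid.occupied
        assert c[center] == min(c[i] for i in occ)
        assert max(c[i] for i in occ) <= 1.0 + 1e-12


class TestProliferation:
    def test_zero_threshold_everyone_divides(self):
        lat = build_hex_lattice(4, 4)
        u = np.zeros(16, dtype=int)
        u[[5, 6, 9]] = 1
        grid = PopulationGrid.from_occupancy(lat, u)
        gp = GrowthParams(c_thr=0.0, mu=2.0)
        c = nutrient_field(grid, gp)
        rates = proliferation_rates(grid, c, gp)
        assert len(rates) == 3
        assert all(r == 2.0 for _, r in rates)

    def test_threshold_above_boundary_level_blocks_all(self):
        lat = build_hex_lattice(4, 4)
        u = np.zeros(16, dtype=int)
        u[[5, 6]] = 1
        grid = PopulationGrid.from_occupancy(lat, u)
        gp = GrowthParams(c_thr=2.0, c_b=1.0)
        c = nutrient_field(grid, gp)
        assert proliferation_rates(grid, c, gp) == []

    def test_double_voxels_do_not_divide(self):
        lat = build_hex_lattice(4, 4)
        u = np.zeros(16, dtype=int)
        u[5] = 2
        u[6] = 1
        grid = PopulationGrid.from_occupancy(lat, u)
        gp = GrowthParams(c_thr=0.0)
        c = nutrient_field(grid, gp)
        assert [v for v, _ in proliferation_rates(grid, c, gp)] == [6]


class TestSimulatePopulation:
    def test_single_cell_no_growth_is_equilibrium(self):
        lat = build_hex_lattice(5, 5)
        grid = PopulationGrid.single_cell(lat)
        log = simulate_population(grid, GrowthParams(mu=0.0), seed=0,
                                  target_size=10)
        assert log == []
        assert grid.n_cells == 1

    def test_chain_relaxes_to_equilibrium(self, chain121):
        """The (1,2,1) chain relaxes by finitely many moves to all
        u <= 1 and zero pressure."""
        log = simulate_population(chain121, GrowthParams(mu=0.0), seed=2,
                                  target_size=100)
        assert all(ev.kind == "move" for ev in log)
        assert np.all(chain121.u <= 1)
        assert np.all(solve_pressure(chain121) == 0.0)

    def test_growth_contract_small(self):
        """Growth from one cell to a 60-cell target: capacity respected,
        connectivity preserved, count changes only at divisions."""
        lat = build_hex_lattice(20, 20)
        grid = PopulationGrid.single_cell(lat)
        log = simulate_population(grid, GrowthParams(), seed=5,
                                  target_size=60)
        assert grid.n_cells == 60
        assert grid.u.max() <= 2
        assert grid.is_connected()
        n_div = sum(1 for ev in log if ev.kind == "divide")
        assert n_div == 59

    def test_deterministic_replayable_log(self, tmp_path):
        lat = build_hex_lattice(15, 15)
        g1 = PopulationGrid.single_cell(lat)
        g2 = PopulationGrid.single_cell(lat)
        log1 = simulate_population(g1, GrowthParams(), seed=9,
                                   target_size=30)
        log2 = simulate_population(g2, GrowthParams(), seed=9,
                                   target_size=30)
        assert log1 == log2
        path = tmp_path / "events.jsonl"
        log1.write(path)
        assert EventLog.read(path) == log1
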