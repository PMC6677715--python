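"""Inner-outer coupling: division splits, event application, replay."""

import numpy as np
import pytest

from stochtissue import (
    EventLog,
    GrowthParams,
    PathwayParams,
    PopulationGrid,
    TissueState,
    apply_event,
    build_hex_lattice,
    divide_counts,
    run_coupled,
    simulate_population,
)
from stochtissue.dlcm import Event
from stochtissue.rdme import cell_mesh_fixture, single_voxel_mesh


@pytest.fixture
def small_mesh():
    return cell_mesh_fixture(12, omega=400.0)


class TestDivideCounts:
    def test_zero_parent(self, small_mesh, rng):
        parent = np.zeros((small_mesh.n_voxels, 3), dtype=np.int64)
        d1, d2 = divide_counts(parent, small_mesh.volumes, rng)
        assert not d1.any() and not d2.any()

    def test_exact_conservation_every_replicate(self, small_mesh, rng):
        parent = rng.integers(0, 50, (small_mesh.n_voxels, 3))
        for _ in range(50):
            d1, d2 = divide_counts(parent, small_mesh.volumes, rng)
            assert np.array_equal(d1.sum(0) + d2.sum(0), parent.sum(0))
            assert np.all(d1 >= 0) and np.all(d2 >= 0)

    def test_binomial_split_mean(self, small_mesh, rng):
        """Each molecule goes to daughter 1 with probability 1/2: over
        1000 splits of N = 100 the mean is within 3 standard errors of
        50 (sd = 5 per split)."""
        parent = np.zeros((small_mesh.n_voxels, 3), dtype=np.int64)
        parent[0, 0] = 100
        means = [divide_counts(parent, small_mesh.volumes, rng)[0].sum()
                 for _ in range(1000)]
        se = 5.0 / np.sqrt(1000)
        assert abs(np.mean(means) - 50.0) < 3.0 * se

    def test_reporter_not_split_option(self, small_mesh, rng):
        parent = np.zeros((small_mesh.n_voxels, 3), dtype=np.int64)
        parent[:, 2] = 7
        d1, d2 = divide_counts(parent, small_mesh.volumes, rng,
                               split_reporter=False)
        assert d1[:, 2].sum() == 0 and d2[:, 2].sum() == 0


def _two_cell_state(mesh, params=None):
    lat = build_hex_lattice(6, 6)
    grid = PopulationGrid(lat)
    grid.add_cell(14)
    grid.add_cell(15)
    return TissueState.from_grid(grid, mesh, params or PathwayParams())


class TestApplyEvent:
    def test_move_and_move_back(self, small_mesh, rng):
        st = _two_cell_state(small_mesh)
        st.states[0][:, 1] = 3
        before_u = st.grid.u.copy()
        before_tot = st.totals().copy()
        apply_event(st, Event(0.1, "move", 14, 13, 0), rng)
        apply_event(st, Event(0.2, "move", 13, 14, 0), rng)
        assert np.array_equal(st.grid.u, before_u)
        assert np.array_equal(st.totals(), before_tot)

    def test_divide_conserves_totals_and_adds_cell(self, small_mesh, rng):
        st = _two_cell_state(small_mesh)
        st.states[0][:, 0] = 5
        total_before = st.totals().sum(axis=0)
        apply_event(st, Event(0.1, "divide", 14, -1, 0, new_id=2), rng)
        assert st.grid.n_cells == 3
        assert np.array_equal(st.totals().sum(axis=0), total_before)
        assert st.grid.u[14] == 2

    def test_graph_matches_fresh_rebuild(self, small_mesh, rng):
        st = _two_cell_state(small_mesh)
        apply_event(st, Event(0.1, "move", 15, 16, 1), rng)
        fresh = TissueState(grid=st.grid, mesh=st.mesh,
                            states=st.states, params=st.params,
                            protrusion=st.protrusion)
        assert (st.graph.junctional != fresh.graph.junctional).nnz == 0
        assert (st.graph.protrusional != fresh.graph.protrusional).nnz == 0

    def test_illegal_event_rejected(self, small_mesh, rng):
        st = _two_cell_state(small_mesh)
        with pytest.raises(ValueError):
            apply_event(st, Event(0.1, "move", 14, 99, 77), rng)
        with pytest.raises(ValueError):
            apply_event(st, Event(0.1, "jump", 14, 13, 0), rng)


class TestRunCoupled:
    def test_one_way_replay_bit_reproducible(self):
        """Same seed and event log give bit-identical trajectories."""
        lat = build_hex_lattice(12, 12)
        grid = PopulationGrid.single_cell(lat)
        log = simulate_population(grid, GrowthParams(), seed=3,
                                  target_size=8)
        p = PathwayParams()
        mesh = cell_mesh_fixture(12, p.omega)

        def one(seed):
            g = PopulationGrid.single_cell(lat)
            st = TissueState.from_grid(g, mesh, p)
            return run_coupled(st, EventLog(log), t_end=1.0, seed=seed,
                               output_times=np.array([0.5, 1.0]))

        s1, s2 = one(11), one(11)
        for a, b in zip(s1, s2):
            assert a["cell_ids"] == b["cell_ids"]
            assert np.array_equal(a["totals"], b["totals"])
        s3 = one(12)
        assert not all(np.array_equal(a["totals"], b["totals"])
                       for a, b in zip(s1, s3))

    def test_moves_and_rebuilds_never_inject_molecules(self):
        """With every reaction channel silent (zero state, zero
        production) a replay full of moves conserves the all-zero
        totals: moves and graph rebuilds alone never create
        molecules."""
        lat = build_hex_lattice(12, 12)
        g = PopulationGrid(lat)
        for vox in (65, 66, 77):
            g.add_cell(vox)
        log = EventLog([Event(0.2, "move", 66, 54, 1),
                        Event(0.4, "move", 54, 66, 1)])
        p = PathwayParams(beta_n=0, beta_d=0, beta_r=0)
        mesh = cell_mesh_fixture(12, p.omega)
        st = TissueState.from_grid(g, mesh, p)
        snaps = run_coupled(st, log, t_end=0.5, seed=4,
                            output_times=np.array([0.5]))
        assert snaps[-1]["totals"].sum() == 0

    def test_single_cell_single_voxel_reduces_to_well_stirred(self):
        """With an empty event log and a one-voxel mesh the coupled
        driver is distributionally the plain chunked SSA (KS test on the
        Notch marginal)."""
        from scipy.stats import ks_2samp

        from stochtissue import build_contact_graph, ssa_population

        p = PathwayParams(beta_n=2.0, beta_d=2.0, beta_r=50.0, k_rs=1.0,
                          omega=20.0, dtau_min=2.0, dtau_max=2.0)
        mesh = single_voxel_mesh(p.omega)
        lat1 = build_hex_lattice(1, 1)
        g = build_contact_graph(lat1)
        reps = 150
        a = np.empty(reps)
        b = np.empty(reps)
        for k in range(reps):
            grid = PopulationGrid.single_cell(lat1)
            st = TissueState.from_grid(grid, mesh, p)
            snaps = run_coupled(st, EventLog(), t_end=2.0, seed=1000 + k)
            a[k] = snaps[-1]["totals"][0, 0]
            _, traj = ssa_population(np.zeros((1, 3), np.int64), g, p,
                                     2.0, seed=5000 + k)
            b[k] = traj[-1, 0, 0]
        assert ks_2samp(a, b).pvalue > 0.01

    def test_unsorted_log_rejected(self, small_mesh):
        st = _two_cell_state(small_mesh)
        log = EventLog([Event(1.0, "move", 14, 13, 0),
                        Event(0.5, "move", 13, 14, 0)])
        with pytest.raises(ValueError):
            run_coupled(st, log, t_end=2.0)

    def test_t_end_before_current_time_rejected(self, small_mesh):
        st = _two_cell_state(small_mesh)
        st.time = 5.0
        with pytest.raises(ValueError):
            run_coupled(st, EventLog(), t_end=1.0)

    def test_live_two_way_mode_grows(self, small_mesh):
        lat = build_hex_lattice(10, 10)
        grid = PopulationGrid.single_cell(lat)
        p = PathwayParams(beta_n=0, beta_d=0, beta_r=0,
                          dtau_min=0.25, dtau_max=0.25)
        st = TissueState.from_grid(grid, small_mesh, p)
        snaps = run_coupled(st, None, t_end=3.0, seed=2,
                            growth=GrowthParams(target_size=20))
        assert st.grid.n_cells > 1
        assert st.grid.u.max() <= 2
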