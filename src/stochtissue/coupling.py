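"""Inner-outer driver coupling single-cell reaction-diffusion dynamics to
the population layer.

Between population events every cell's spatial-stochastic state advances
independently in frozen-signal time chunks: per-cell species totals are
aggregated into cell-to-cell signals, the chunk length ``dtau`` follows
the adaptive 5% rule on the population concentration vector, and each
cell is advanced to ``min(t + dtau, next event time)``.  Population
events (moves and divisions) are either replayed one-way from a
pre-recorded :class:`~stochtissue.dlcm.EventLog` or sampled live from the
DLCM rates (two-way hook; in the shipped experiments the growth process
does not depend on molecular state).

A dividing cell shares its molecules binomially between the daughters
(each molecule independently with probability 1/2), the daughter totals
being re-distributed over each daughter's mesh proportionally to voxel
volume; moves carry the full internal state unchanged.  After every
event the contact graph is rebuilt from the new positions.  Chunk/event
time ties are processed event first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import advance_cell_direct
from .contacts import (ContactGraph, Lattice, ProtrusionSpec,
                       build_contact_graph, lattice_from_positions)
from .dlcm import (Event, EventLog, GrowthParams, PopulationGrid,
                   movement_rates, nutrient_field, proliferation_rates,
                   solve_pressure)
from .params import PathwayParams
from .pathway import adaptive_chunk, ndr_rhs
from .rdme import CellMesh, advance_rdme_direct, cell_totals, nsm

__all__ = ["TissueState", "divide_counts", "apply_event", "run_coupled"]


@dataclass
class TissueState:
    """The full multilevel state: occupancy grid, per-cell molecular
    states (one ``(n_voxels, 3)`` count array per cell id, all sharing
    the geometry of ``mesh``), the current contact graph and time."""

    grid: PopulationGrid
    mesh: CellMesh
    states: dict[int, np.ndarray]
    params: PathwayParams
    protrusion: ProtrusionSpec = field(default_factory=ProtrusionSpec)
    graph: ContactGraph | None = None
    cell_ids: list[int] = field(default_factory=list)
    time: float = 0.0

    def __post_init__(self) -> None:
        if set(self.states) != set(self.grid.cell_voxel):
            raise ValueError("cell ids in grid and state table must coincide")
        if self.graph is None:
            self.rebuild_graph()

    @classmethod
    def from_grid(
        cls,
        grid: PopulationGrid,
        mesh: CellMesh,
        params: PathwayParams,
        protrusion: ProtrusionSpec | None = None,
        initial_counts: dict[int, np.ndarray] | None = None,
    ) -> "TissueState":
        states = {}
        for cid in grid.cell_voxel:
            if initial_counts and cid in initial_counts:
                states[cid] = np.array(initial_counts[cid], dtype=np.int64)
            else:
                states[cid] = np.zeros((mesh.n_voxels, 3), dtype=np.int64)
        return cls(grid=grid, mesh=mesh, states=states, params=params,
                   protrusion=protrusion or ProtrusionSpec())

    def rebuild_graph(self) -> None:
        """Recompute the contact graph from the current positions.

        Cell positions are their voxel centers; the two cells of a
        doubly occupied voxel share a position and count as junctional
        contacts of each other (center distance 0 <= 2)."""
        self.cell_ids = sorted(self.states)
        pos = np.array([
            self.grid.lattice.positions[self.grid.cell_voxel[cid]]
            for cid in self.cell_ids
        ])
        cell_lattice = lattice_from_positions(pos.reshape(-1, 2))
        self.graph = build_contact_graph(
            cell_lattice, self.protrusion,
            (self.params.w_a, self.params.q_a, self.params.w_b, self.params.q_b),
        )

    def totals(self) -> np.ndarray:
        """Per-cell species totals, rows ordered like ``cell_ids``."""
        return np.array([cell_totals(self.states[cid]) for cid in self.cell_ids])


def divide_counts(
    parent: np.ndarray,
    volumes: np.ndarray,
    rng: np.random.Generator,
    split_reporter: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Random molecular partition at division.

    Every molecule of every species is assigned independently to either
    daughter with probability 1/2 (a binomial split of the per-species
    cell totals); each daughter's share is then placed on its own mesh
    multinomially with voxel-volume weights.  Totals are conserved
    exactly.  With ``split_reporter=False`` the reporter is not split:
    both daughters restart with zero reporter.
    """
    parent = np.asarray(parent, dtype=np.int64)
    tot = parent.sum(axis=0)
    nvox = parent.shape[0]
    w = np.asarray(volumes, dtype=float)
    w = w / w.sum()
    d1 = np.zeros((nvox, 3), dtype=np.int64)
    d2 = np.zeros((nvox, 3), dtype=np.int64)
    for spc in range(3):
        if spc == 2 and not split_reporter:
            continue
        n1 = rng.binomial(tot[spc], 0.5)
        n2 = tot[spc] - n1
        d1[:, spc] = rng.multinomial(n1, w)
        d2[:, spc] = rng.multinomial(n2, w)
    return d1, d2


def apply_event(
    state: TissueState,
    event: Event,
    rng: np.random.Generator,
    split_reporter: bool = True,
) -> None:
    """Execute one population event on the tissue state (in place).

    A move carries the cell's entire internal state with it; a division
    replaces the parent by two daughters (the parent id is reused for
    the first daughter) via :func:`divide_counts`.  The derived sets and
    the contact graph are recomputed."""
    if event.kind == "move":
        state.grid.move_cell(event.cell_id, event.dest)
    elif event.kind == "divide":
        new_id = event.new_id if event.new_id >= 0 else None
        new_id = state.grid.divide_cell(event.cell_id, new_id)
        d1, d2 = divide_counts(state.states[event.cell_id],
                               state.mesh.volumes, rng, split_reporter)
        state.states[event.cell_id] = d1
        state.states[new_id] = d2
    else:
        raise ValueError(f"unknown event kind {event.kind!r}")
    state.time = max(state.time, event.time)
    state.rebuild_graph()


def _signals(state: TissueState) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    from .contacts import aggregate_signals

    totals = state.totals()
    return aggregate_signals(totals[:, 0], totals[:, 1], state.graph), totals


def _advance_all(
    state: TissueState,
    d_in: np.ndarray, d_out: np.ndarray, n_in: np.ndarray,
    t0: float, t1: float,
    rng: np.random.Generator,
    method: str,
) -> None:
    p = state.params
    for k, cid in enumerate(state.cell_ids):
        seed = int(rng.integers(0, 2**31 - 1))
        cell = state.states[cid]
        if method == "nsm":
            state.states[cid] = nsm(
                state.mesh, cell, p,
                signals=(d_in[k], d_out[k], n_in[k]),
                t_end=t1 - t0, seed=np.random.default_rng(seed),
            )
        elif state.mesh.n_voxels == 1:
            advance_cell_direct(
                cell[0], d_in[k], d_out[k], n_in[k],
                p.beta_n, p.beta_d, p.beta_r, p.k_t, p.k_c, p.k_rs,
                p.m, p.s, p.omega, t0, t1, seed,
            )
        else:
            advance_rdme_direct(state.mesh, cell, p,
                                (d_in[k], d_out[k], n_in[k]), t0, t1, seed)


def run_coupled(
    state: TissueState,
    eventlog: EventLog | None,
    t_end: float,
    seed: int | np.random.Generator = 0,
    output_times: np.ndarray | None = None,
    growth: GrowthParams | None = None,
    method: str = "direct",
    split_reporter: bool = True,
) -> list[dict]:
    """Advance the tissue to ``t_end``, replaying a recorded event log
    (one-way mode) or sampling population events live (two-way mode,
    ``growth`` given).

    Returns one snapshot dict per output time with keys ``time``,
    ``cell_ids``, ``totals`` (per-cell species totals) and ``voxels``.
    Reproducible bit-for-bit for a fixed seed and event log.
    """
    if t_end < state.time:
        raise ValueError("t_end precedes current time")
    if eventlog is not None and growth is not None:
        raise ValueError("pass either an event log or growth parameters")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if output_times is None:
        output_times = np.array([t_end])
    out_times = np.asarray(output_times, dtype=float)
    if np.any(np.diff(out_times) < 0):
        raise ValueError("output times must be sorted")
    pending = list(eventlog) if eventlog is not None else []
    if any(e2.time < e1.time for e1, e2 in zip(pending, pending[1:])):
        raise ValueError("event log times are not sorted")
    pending = [e for e in pending if e.time >= state.time]

    snapshots: list[dict] = []

    def record(t: float) -> None:
        snapshots.append({
            "time": t,
            "cell_ids": list(state.cell_ids),
            "totals": state.totals(),
            "voxels": [state.grid.cell_voxel[c] for c in state.cell_ids],
        })

    def next_live_event() -> Event | None:
        assert growth is not None
        p = solve_pressure(state.grid)
        moves = movement_rates(state.grid, p, growth)
        c = nutrient_field(state.grid, growth)
        births = (proliferation_rates(state.grid, c, growth)
                  if state.grid.n_cells < growth.target_size else [])
        rates = np.array([r for _, _, r in moves] + [r for _, r in births])
        total = rates.sum()
        if total <= 0.0:
            return None
        dt = rng.exponential(1.0 / total)
        k = int(rng.choice(len(rates), p=rates / total))
        if k < len(moves):
            src, dst, _ = moves[k]
            cid = int(rng.choice(state.grid.cells[src]))
            return Event(state.time + dt, "move", src, dst, cid)
        vox, _ = births[k - len(moves)]
        return Event(state.time + dt, "divide", vox, -1,
                     state.grid.cells[vox][0])

    live_event = next_live_event() if growth is not None else None

    i_out = 0
    while i_out < len(out_times) and out_times[i_out] <= state.time:
        record(out_times[i_out])
        i_out += 1

    while state.time < t_end:
        (d_in, d_out, n_in), totals = _signals(state)
        conc = totals / state.params.omega
        sig_conc = np.stack([d_in, d_out, n_in], axis=-1) / state.params.omega
        f_x = ndr_rhs(conc, sig_conc, state.params)
        dtau = adaptive_chunk(conc, f_x, state.params)
        t_event = np.inf
        if pending:
            t_event = pending[0].time
        elif live_event is not None:
            t_event = live_event.time
        t_next_out = out_times[i_out] if i_out < len(out_times) else np.inf
        t1 = min(state.time + dtau, t_event, t_next_out, t_end)
        if t1 > state.time:
            _advance_all(state, d_in, d_out, n_in, state.time, t1, rng, method)
            state.time = t1
        # ties (event time == chunk boundary) are processed event first
        if pending and pending[0].time <= state.time:
            apply_event(state, pending.pop(0), rng, split_reporter)
        elif live_event is not None and live_event.time <= state.time:
            apply_event(state, live_event, rng, split_reporter)
            live_event = next_live_event()
        while i_out < len(out_times) and out_times[i_out] <= state.time:
            record(out_times[i_out])
            i_out += 1
    while i_out < len(out_times):
        record(out_times[i_out])
        i_out += 1
    return snapshots
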