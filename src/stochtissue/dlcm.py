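"""On-lattice cell-population mechanics (discrete Laplacian cell
mechanics, DLCM).

Cells live in lattice voxels with occupancy ``u_i in {0, 1, 2}``.  Voxels
above unit occupancy act as unit sources of a dimensionless cellular
pressure, spread by the lattice Laplacian with zero Dirichlet data on the
discrete boundary (the empty voxels edge-adjacent to the population)::

    -L p = s(u)  on  Omega_h = {i : u_i > 0},   s(u) = 1{u = 2}
       p = 0     on  dOmega_h

The edge current ``I_ij = (e_ij/d_ij)(p_i - p_j)`` converts into the rate
of the event that one cell moves from voxel i to voxel j,
``R_ij = D_move * max(0, I_ij)``, admissible only into voxels holding
strictly fewer cells.  Proliferation is nutrient limited: a quasi-static
nutrient field is fed at the population boundary, diffuses through the
population and is consumed linearly by the cells; cells in singly
occupied voxels with nutrient above a threshold divide at rate ``mu``.
The whole population advances by Gillespie's direct method, one
move/divide event at a time, and every event is recorded in a replayable
log.

Uniform lattices (hexagonal or square) use ``e_ij/d_ij = 1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .contacts import Lattice, build_hex_lattice

__all__ = [
    "PopulationGrid",
    "GrowthParams",
    "Event",
    "EventLog",
    "solve_pressure",
    "boundary_outflux",
    "movement_rates",
    "nutrient_field",
    "proliferation_rates",
    "simulate_population",
]


@dataclass(frozen=True)
class GrowthParams:
    """Population-layer parameters.

    ``kappa``: nutrient consumption per cell; ``mu``: division rate of a
    nutrient-sufficient cell; ``c_thr``: nutrient threshold for division;
    ``c_b``: boundary nutrient level; ``d_move``: conversion factor from
    pressure current to movement rate; ``target_size``: population size at
    which a growth run stops.

    ``prevent_detachment``: the conversion factor may depend on the type
    of movement; with this flag (default) it is zero for the moves that
    would fragment the population into disconnected pieces, keeping the
    growing tissue edge-connected (a minimal stand-in for cell-cell
    adhesion).  Set to False for the unconstrained pressure-driven rates.
    """

    kappa: float = 0.02
    mu: float = 1.0
    c_thr: float = 0.5
    c_b: float = 1.0
    d_move: float = 1.0
    target_size: int = 1000
    prevent_detachment: bool = True

    def __post_init__(self) -> None:
        for name in ("kappa", "mu", "c_thr", "c_b", "d_move"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.target_size < 1:
            raise ValueError("target_size must be >= 1")


@dataclass
class Event:
    """One population event: a cell move or a division."""

    time: float
    kind: str            # "move" | "divide"
    source: int          # voxel index
    dest: int            # voxel index (move) or -1 (divide)
    cell_id: int
    new_id: int = -1     # daughter id (divide only)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, line: str) -> "Event":
        return cls(**json.loads(line))


class EventLog(list):
    """Time-ordered list of :class:`Event`, serializable as JSON lines."""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for ev in self:
                fh.write(ev.to_json() + "\n")

    @classmethod
    def read(cls, path) -> "EventLog":
        log = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    log.append(Event.from_json(line))
        times = [ev.time for ev in log]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event log times are not sorted")
        return log


class PopulationGrid:
    """Occupancy grid over a lattice: ``u_i in {0, 1, 2}`` cells per
    voxel plus the cell identities in each voxel."""

    def __init__(self, lattice: Lattice):
        self.lattice = lattice
        n = lattice.n_cells  # lattice sites = population voxels
        self.u = np.zeros(n, dtype=np.int64)
        self.cells: list[list[int]] = [[] for _ in range(n)]
        self.cell_voxel: dict[int, int] = {}
        self.next_cell_id = 0

    @classmethod
    def single_cell(cls, lattice: Lattice, voxel: int | None = None
                    ) -> "PopulationGrid":
        grid = cls(lattice)
        if voxel is None:
            # most central lattice site
            pos = lattice.positions
            voxel = int(np.argmin(((pos - pos.mean(axis=0)) ** 2).sum(axis=1)))
        grid.add_cell(voxel)
        return grid

    @classmethod
    def from_occupancy(cls, lattice: Lattice, u) -> "PopulationGrid":
        grid = cls(lattice)
        for i, k in enumerate(np.asarray(u, dtype=int)):
            for _ in range(k):
                grid.add_cell(i)
        return grid

    # -- mutation ----------------------------------------------------

    def add_cell(self, voxel: int, cell_id: int | None = None) -> int:
        if self.u[voxel] >= 2:
            raise ValueError(f"voxel {voxel} is at carrying capacity")
        if cell_id is None:
            cell_id = self.next_cell_id
        elif cell_id in self.cell_voxel:
            raise ValueError(f"cell id {cell_id} already present")
        self.next_cell_id = max(self.next_cell_id, cell_id + 1)
        self.u[voxel] += 1
        self.cells[voxel].append(cell_id)
        self.cell_voxel[cell_id] = voxel
        return cell_id

    def move_cell(self, cell_id: int, dest: int) -> None:
        src = self.cell_voxel.get(cell_id)
        if src is None:
            raise ValueError(f"unknown cell id {cell_id}")
        if self.u[dest] >= self.u[src]:
            raise ValueError("move destination must hold fewer cells")
        self.cells[src].remove(cell_id)
        self.u[src] -= 1
        self.cells[dest].append(cell_id)
        self.u[dest] += 1
        self.cell_voxel[cell_id] = dest

    def divide_cell(self, cell_id: int, new_id: int | None = None) -> int:
        """Division in place: the voxel gains the daughter (u -> 2)."""
        voxel = self.cell_voxel.get(cell_id)
        if voxel is None:
            raise ValueError(f"unknown cell id {cell_id}")
        if self.u[voxel] != 1:
            raise ValueError("division requires a singly occupied voxel")
        return self.add_cell(voxel, new_id)

    # -- derived sets ------------------------------------------------

    @property
    def n_cells(self) -> int:
        return int(self.u.sum())

    @property
    def occupied(self) -> np.ndarray:
        """Omega_h: indices of populated voxels."""
        return np.flatnonzero(self.u > 0)

    @property
    def boundary(self) -> np.ndarray:
        """dOmega_h: empty voxels sharing an edge with the population."""
        adj = self.lattice.adjacency
        touched = adj @ (self.u > 0)
        return np.flatnonzero((self.u == 0) & (touched > 0))

    def is_connected(self) -> bool:
        occ = self.occupied
        if len(occ) <= 1:
            return True
        sub = self.lattice.adjacency[np.ix_(occ, occ)]
        ncomp, _ = sp.csgraph.connected_components(sub, directed=False)
        return ncomp == 1

    def snapshot_rows(self):
        """(voxel id, x, y, u, cell ids) rows for occupied voxels."""
        return [
            (int(i), float(self.lattice.positions[i, 0]),
             float(self.lattice.positions[i, 1]), int(self.u[i]),
             list(self.cells[i]))
            for i in self.occupied
        ]


def _lattice_degree(lattice: Lattice) -> np.ndarray:
    return np.asarray(lattice.adjacency.sum(axis=1)).ravel()


def _interior_solve(grid: PopulationGrid, rhs_interior: np.ndarray,
                    dirichlet_value: float) -> np.ndarray:
    """Solve ``-L x = rhs`` on the occupied set with constant Dirichlet
    data on the discrete boundary; returns x over all voxels (boundary
    voxels carry the Dirichlet value, other empties 0)."""
    occ = grid.occupied
    if len(occ) == 0:
        raise ValueError("population is empty")
    bnd = grid.boundary
    if len(bnd) == 0:
        raise ValueError(
            "population has no discrete boundary (lattice fully occupied)")
    adj = grid.lattice.adjacency
    deg = _lattice_degree(grid.lattice)[occ].astype(float)
    A = sp.diags(deg) - adj[np.ix_(occ, occ)].astype(float)
    b = np.asarray(rhs_interior, dtype=float).copy()
    if dirichlet_value != 0.0:
        bmask = np.zeros(grid.lattice.n_cells)
        bmask[bnd] = dirichlet_value
        b = b + adj[occ] @ bmask
    x = np.zeros(grid.lattice.n_cells)
    x[occ] = spsolve(A.tocsc(), b)
    x[bnd] = dirichlet_value
    return x


def solve_pressure(grid: PopulationGrid) -> np.ndarray:
    """Cellular pressure: ``-L p = 1{u = 2}`` on the population, ``p = 0``
    on the discrete boundary.  Returns p over all voxels (zero outside
    the population).  Non-negative by the maximum principle; identically
    zero when no voxel is doubly occupied."""
    occ = grid.occupied
    s = (grid.u[occ] == 2).astype(float)
    if not s.any():
        return np.zeros(grid.lattice.n_cells)
    return _interior_solve(grid, s, 0.0)


def boundary_outflux(grid: PopulationGrid, p: np.ndarray) -> float:
    """Sum of pressure currents over edges into the discrete boundary
    (equals the total source by the discrete divergence theorem)."""
    occ = grid.occupied
    bnd_set = set(grid.boundary.tolist())
    total = 0.0
    for i in occ:
        for j in grid.lattice.neighbors(int(i)):
            if int(j) in bnd_set:
                total += p[i] - 0.0
    return total


def _articulation_voxels(grid: PopulationGrid) -> set[int]:
    """Articulation points of the occupied-voxel graph (voxels whose
    removal disconnects the population), by iterative Tarjan DFS."""
    occ = grid.occupied
    occ_set = set(occ.tolist())
    visited: dict[int, int] = {}
    low: dict[int, int] = {}
    parent: dict[int, int | None] = {}
    arts: set[int] = set()
    counter = 0
    for root in occ:
        root = int(root)
        if root in visited:
            continue
        stack = [(root, iter([int(j) for j in grid.lattice.neighbors(root)
                              if int(j) in occ_set]))]
        parent[root] = None
        visited[root] = low[root] = counter
        counter += 1
        root_children = 0
        while stack:
            v, it = stack[-1]
            advanced = False
            for w in it:
                if w not in visited:
                    parent[w] = v
                    visited[w] = low[w] = counter
                    counter += 1
                    if v == root:
                        root_children += 1
                    stack.append(
                        (w, iter([int(j) for j in grid.lattice.neighbors(w)
                                  if int(j) in occ_set])))
                    advanced = True
                    break
                elif w != parent[v]:
                    low[v] = min(low[v], visited[w])
            if not advanced:
                stack.pop()
                pv = parent[v]
                if pv is not None:
                    low[pv] = min(low[pv], low[v])
                    if pv != root and low[v] >= visited[pv]:
                        arts.add(pv)
        if root_children > 1:
            arts.add(root)
    return arts


def movement_rates(
    grid: PopulationGrid, p: np.ndarray, params: GrowthParams
) -> list[tuple[int, int, float]]:
    """Candidate moves ``(source voxel, dest voxel, rate)``.

    For each edge with ``u_i > u_j``: ``rate = d_move * max(0,
    (e_ij/d_ij)(p_i - p_j))`` (only downhill pressure currents convert
    into movements; equal occupancy admits no move).  The moving cell is
    chosen uniformly from the source voxel when the event fires.

    With ``params.prevent_detachment`` (default) the conversion factor is
    zero for moves that would fragment the population: a sole occupant
    (``u_i = 1``) may not leave an articulation voxel, and its
    destination must touch the population through some voxel other than
    the one being vacated.  Moves from doubly occupied voxels can never
    disconnect the population and are unrestricted.
    """
    arts: set[int] | None = None
    occ_mask = grid.u > 0
    out = []
    for i in grid.occupied:
        i = int(i)
        for j in grid.lattice.neighbors(i):
            j = int(j)
            if grid.u[i] <= grid.u[j]:
                continue
            rate = params.d_move * (p[i] - p[j])
            if rate <= 0.0:
                continue
            if params.prevent_detachment and grid.u[i] == 1:
                # destination must keep contact with the rest
                if not any(occ_mask[int(k)] and int(k) != i
                           for k in grid.lattice.neighbors(j)):
                    continue
                if arts is None:
                    arts = _articulation_voxels(grid)
                if i in arts:
                    continue
            out.append((i, j, float(rate)))
    return out


def nutrient_field(grid: PopulationGrid, params: GrowthParams) -> np.ndarray:
    """Quasi-static nutrient concentration: fed at level ``c_b`` on the
    discrete boundary, spread by the lattice Laplacian and consumed at
    rate ``kappa`` per cell (``-L c = -kappa * u`` on the population),
    clamped at zero.  Empty voxels away from the population are reported
    at ``c_b``."""
    c = _interior_solve(grid, -params.kappa * grid.u[grid.occupied],
                        params.c_b)
    far = (grid.u == 0)
    far[grid.boundary] = False
    c[far] = params.c_b
    return np.maximum(c, 0.0)


def proliferation_rates(
    grid: PopulationGrid, c: np.ndarray, params: GrowthParams
) -> list[tuple[int, float]]:
    """Per-voxel division candidates ``(voxel, rate)``: rate ``mu`` for
    the cell of each singly occupied voxel with ``c >= c_thr`` (voxels at
    carrying capacity do not divide)."""
    out = []
    for i in grid.occupied:
        i = int(i)
        if grid.u[i] == 1 and c[i] >= params.c_thr and params.mu > 0:
            out.append((i, params.mu))
    return out


def simulate_population(
    grid: PopulationGrid,
    params: GrowthParams,
    t_end: float = np.inf,
    seed: int | np.random.Generator = 0,
    target_size: int | None = None,
) -> EventLog:
    """Event-driven growth/relaxation of the population by Gillespie's
    direct method.

    After every executed event the pressure and nutrient systems are
    re-solved and all rates recomputed.  The run stops at the configured
    target population size, at ``t_end``, or at an absorbing equilibrium
    (total rate zero).  Mutates ``grid`` in place and returns the
    :class:`EventLog` of all executed events.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if target_size is None:
        target_size = params.target_size
    log = EventLog()
    t = 0.0
    while grid.n_cells < target_size and t < t_end:
        p = solve_pressure(grid)
        moves = movement_rates(grid, p, params)
        c = nutrient_field(grid, params)
        births = proliferation_rates(grid, c, params)
        rates = np.array([r for _, _, r in moves] + [r for _, r in births])
        total = rates.sum()
        if total <= 0.0:
            break  # absorbing equilibrium
        t += rng.exponential(1.0 / total)
        if t >= t_end:
            break
        k = int(rng.choice(len(rates), p=rates / total))
        if k < len(moves):
            src, dst, _ = moves[k]
            cell_id = int(rng.choice(grid.cells[src]))
            grid.move_cell(cell_id, dst)
            log.append(Event(t, "move", src, dst, cell_id))
        else:
            vox, _ = births[k - len(moves)]
            parent = grid.cells[vox][0]
            new_id = grid.divide_cell(parent)
            log.append(Event(t, "divide", vox, -1, parent, new_id))
    return log
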