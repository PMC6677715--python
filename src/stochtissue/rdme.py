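"""Spatial-stochastic single-cell layer: unstructured mesh + NSM sampler.

A single cell is discretized by a triangulated disc (cytoplasm with a
concentric, purely geometric nucleus region) whose *dual mesh* supplies
the computational compartments: one voxel per mesh node, with the voxel
volume given by the lumped finite-element mass and the edge coupling
``e_ij/d_ij`` by the P1 stiffness (cotangent) weights.  Diffusion is a
set of first-order jump reactions with per-molecule rate

    q_ij = gamma * (e_ij / d_ij) / V_i

which is the finite-volume/FEM-consistent discretization of the Laplacian
whose stationary distribution places molecules proportionally to voxel
volume.  All pathway reactions are active in every voxel with the voxel
volume replacing the system volume in the volume scalings (see
``_kernels`` for the channel set).

The exact sampler is the Next Subvolume Method: per-voxel next-event
times are kept in a priority queue; each event picks diffusion versus
reaction proportionally to the summed propensities within the chosen
voxel, executes it, and refreshes only the affected voxels.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import Delaunay

from ._kernels import advance_multivoxel_direct
from .params import PathwayParams

__all__ = [
    "CellMesh",
    "cell_mesh_fixture",
    "diffusion_jump_rates",
    "nsm",
    "advance_rdme_direct",
    "cell_totals",
]


@dataclass(frozen=True)
class CellMesh:
    """Dual-mesh discretization of one cell.

    ``volumes`` sum to the system volume ``omega``; ``edges`` is an
    ``(n_edges, 2)`` int array of unique undirected mesh edges with
    geometric ratios ``e_over_d``; ``centroids`` are the node coordinates
    (used for division partitioning and plotting).
    """

    centroids: np.ndarray      # (nvox, 2)
    volumes: np.ndarray        # (nvox,)
    edges: np.ndarray          # (n_edges, 2) int
    e_over_d: np.ndarray       # (n_edges,)
    omega: float

    @property
    def n_voxels(self) -> int:
        return self.volumes.shape[0]

    def is_connected(self) -> bool:
        g = self.coupling_matrix()
        n, _ = sp.csgraph.connected_components(g, directed=False)
        return n == 1

    def coupling_matrix(self) -> sp.csr_matrix:
        """Symmetric matrix of the geometric ratios e_ij/d_ij."""
        n = self.n_voxels
        if len(self.edges) == 0:
            return sp.csr_matrix((n, n))
        i, j = self.edges.T
        m = sp.coo_matrix((self.e_over_d, (i, j)), shape=(n, n))
        return (m + m.T).tocsr()

    def to_tables(self):
        """(voxel_table, edge_table) as lists of tuples for text export:
        (id, x, y, volume) and (i, j, e_over_d)."""
        vox = [(k, float(x), float(y), float(v))
               for k, ((x, y), v) in enumerate(zip(self.centroids, self.volumes))]
        edg = [(int(i), int(j), float(w))
               for (i, j), w in zip(self.edges, self.e_over_d)]
        return vox, edg


def single_voxel_mesh(omega: float) -> CellMesh:
    """Degenerate one-voxel mesh: the well-stirred cell."""
    return CellMesh(
        centroids=np.zeros((1, 2)),
        volumes=np.array([float(omega)]),
        edges=np.empty((0, 2), dtype=np.int64),
        e_over_d=np.empty(0),
        omega=float(omega),
    )


def _disc_points(n_target: int, nucleus_radius: float) -> np.ndarray:
    """Deterministic point set on the unit disc: a center node plus
    concentric rings, one of which traces the nucleus boundary."""
    # ring count chosen so 1 + sum(round(2 pi k)) ~ n_target
    n_rings = max(1, int(round(np.sqrt(n_target / np.pi) - 0.4)))
    pts = [np.zeros((1, 2))]
    radii = np.linspace(0.0, 1.0, n_rings + 1)[1:]
    # snap the ring closest to the nucleus boundary onto it
    k = int(np.argmin(np.abs(radii - nucleus_radius)))
    radii[k] = nucleus_radius
    for ring, r in enumerate(radii):
        m = max(3, int(round(2.0 * np.pi * r * n_rings)))
        # stagger successive rings so triangles stay well shaped
        phase = 0.5 * (ring % 2) * 2.0 * np.pi / m
        ang = phase + 2.0 * np.pi * np.arange(m) / m
        pts.append(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
    return np.vstack(pts)


def cell_mesh_fixture(
    n_voxels_target: int = 40,
    omega: float = 400.0,
    nucleus_radius: float = 0.4,
) -> CellMesh:
    """Deterministic single-cell mesh: triangulated disc, dual-mesh voxels.

    The triangulation is a fixed function of the target voxel count, so
    repeated calls give identical meshes.  Voxel volumes are the lumped
    P1 mass (one third of the adjacent triangle areas), rescaled so they
    sum to ``omega`` exactly; edge ratios are the P1 stiffness cotangent
    weights (non-negative on a Delaunay triangulation).
    """
    if n_voxels_target < 1:
        raise ValueError("n_voxels_target must be >= 1")
    if omega <= 0:
        raise ValueError("omega must be positive")
    if n_voxels_target == 1:
        return single_voxel_mesh(omega)
    pts = _disc_points(n_voxels_target, nucleus_radius)
    tri = Delaunay(pts)
    n = pts.shape[0]
    lumped = np.zeros(n)
    wsum: dict[tuple[int, int], float] = {}
    for simplex in tri.simplices:
        p = pts[simplex]
        # signed doubled area and cotangent weights of the P1 stiffness
        v0, v1, v2 = p
        e01, e02 = v1 - v0, v2 - v0
        area2 = abs(e01[0] * e02[1] - e01[1] * e02[0])
        if area2 <= 0:
            continue
        area = 0.5 * area2
        lumped[simplex] += area / 3.0
        for a in range(3):
            b, c = (a + 1) % 3, (a + 2) % 3
            # edge (b, c) opposite vertex a: weight = cot(angle at a) / 2
            e1 = p[b] - p[a]
            e2 = p[c] - p[a]
            cot = float(np.dot(e1, e2)) / area2
            key = (min(simplex[b], simplex[c]), max(simplex[b], simplex[c]))
            wsum[key] = wsum.get(key, 0.0) + 0.5 * cot
    edges = np.array(sorted(wsum), dtype=np.int64)
    e_over_d = np.array([max(0.0, wsum[tuple(e)]) for e in edges])
    keep = e_over_d > 1e-12
    edges, e_over_d = edges[keep], e_over_d[keep]
    volumes = lumped * (omega / lumped.sum())
    mesh = CellMesh(centroids=pts, volumes=volumes, edges=edges,
                    e_over_d=e_over_d, omega=float(omega))
    if not mesh.is_connected():
        raise RuntimeError("generated mesh is not connected")
    return mesh


def diffusion_jump_rates(mesh: CellMesh, gamma: float) -> sp.csr_matrix:
    """Per-molecule jump-rate matrix: off-diagonal ``q_ij = gamma *
    (e_ij/d_ij) / V_i``, diagonal set to minus the row sum (rows sum to
    zero).  The default diffusion constant of the running model is
    ``gamma = 1/omega`` for all three species."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    n = mesh.n_voxels
    coup = mesh.coupling_matrix().tocoo()
    rates = gamma * coup.data / mesh.volumes[coo_row := coup.row]
    q = sp.coo_matrix((rates, (coo_row, coup.col)), shape=(n, n)).tocsr()
    q = q - sp.diags(np.asarray(q.sum(axis=1)).ravel())
    return q.tocsr()


def _offdiag_csr(q: sp.csr_matrix) -> sp.csr_matrix:
    q = q.copy().tolil()
    q.setdiag(0.0)
    return q.tocsr()


def cell_totals(state: np.ndarray) -> np.ndarray:
    """Whole-cell species totals ``(N, D, R)`` of a per-voxel state."""
    state = np.asarray(state)
    if state.ndim != 2 or state.shape[1] != 3:
        raise ValueError("state must have shape (n_voxels, 3)")
    return state.sum(axis=0)


def _voxel_propensities(
    counts_v: np.ndarray, volume: float, signals: np.ndarray,
    params: PathwayParams,
) -> np.ndarray:
    """The nine reaction propensities of one voxel (volume ``V_v`` in
    place of the system volume; local Hill concentrations; per-cell
    signals at the whole-cell volume)."""
    N, D, R = (float(c) for c in counts_v)
    d_in, d_out, n_in = (float(x) for x in signals)
    V = float(volume)
    om = params.omega
    r1 = 1.0 / (1.0 + (R / V) ** params.m)
    x = ((d_out / om) * (N / V)) ** params.s
    r2 = x / (params.k_rs + x)
    return np.array([
        params.beta_n * V,
        params.beta_d * V * r1,
        params.beta_r * V * r2,
        N * d_in / (params.k_t * om),
        D * n_in / (params.k_t * om),
        N * D / (params.k_c * V),
        N,
        D,
        R,
    ])


_STOICH = np.array([
    [+1, 0, 0], [0, +1, 0], [0, 0, +1],
    [-1, 0, 0], [0, -1, 0], [-1, -1, 0],
    [-1, 0, 0], [0, -1, 0], [0, 0, -1],
], dtype=np.int64)


def nsm(
    mesh: CellMesh,
    initial: np.ndarray,
    params: PathwayParams,
    signals: np.ndarray = (0.0, 0.0, 0.0),
    t_end: float = 1.0,
    seed: int | np.random.Generator = 0,
    gamma: float | None = None,
    reactions_enabled: bool = True,
) -> np.ndarray:
    """Next Subvolume Method: exact SSA of the reaction-diffusion process
    of one cell over ``[0, t_end)`` with frozen signals.

    ``initial`` has shape ``(n_voxels, 3)``; ``signals`` is the frozen
    ``(d_in, d_out, n_in)`` triple in count units.  ``gamma`` defaults to
    ``1/omega``.  Waiting times are redrawn (not rescaled) for affected
    voxels after each event, which is statistically exact for the
    memoryless exponential clocks; equal event times break ties by voxel
    index.  Returns the final state (a new array).
    """
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    state = np.array(initial, dtype=np.int64, copy=True)
    if state.shape != (mesh.n_voxels, 3):
        raise ValueError(f"initial must have shape ({mesh.n_voxels}, 3)")
    if np.any(state < 0):
        raise ValueError("counts must be non-negative")
    signals = np.asarray(signals, dtype=float)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if gamma is None:
        gamma = 1.0 / params.omega
    q = _offdiag_csr(diffusion_jump_rates(mesh, gamma))
    nvox = mesh.n_voxels

    def voxel_rates(v: int):
        if reactions_enabled:
            a = _voxel_propensities(state[v], mesh.volumes[v], signals, params)
        else:
            a = np.zeros(9)
        row = slice(q.indptr[v], q.indptr[v + 1])
        jump_per_molecule = q.data[row].sum()
        diff = float(state[v].sum()) * jump_per_molecule
        return a, diff

    # priority queue of (next_time, voxel, generation); stale entries
    # are skipped via the generation counter
    gen = np.zeros(nvox, dtype=np.int64)
    heap: list[tuple[float, int, int]] = []

    def push(v: int, now: float):
        a, diff = voxel_rates(v)
        tot = a.sum() + diff
        if not np.isfinite(tot):
            raise FloatingPointError("non-finite propensity")
        t_next = now + rng.exponential(1.0 / tot) if tot > 0 else np.inf
        gen[v] += 1
        heapq.heappush(heap, (t_next, v, gen[v]))

    for v in range(nvox):
        push(v, 0.0)
    while heap:
        t_ev, v, g = heapq.heappop(heap)
        if g != gen[v]:
            continue
        if t_ev >= t_end or not np.isfinite(t_ev):
            break
        a, diff = voxel_rates(v)
        tot = a.sum() + diff
        u = rng.uniform() * tot
        touched = [v]
        if u < a.sum():
            ch = int(np.searchsorted(np.cumsum(a), u, side="right"))
            ch = min(ch, 8)
            state[v] += _STOICH[ch]
        else:
            u -= a.sum()
            row = slice(q.indptr[v], q.indptr[v + 1])
            rates = q.data[row]
            targets = q.indices[row]
            jump_per_molecule = rates.sum()
            # species block (N, D, R), then edge within the block
            edges_cum = np.cumsum(rates)
            sp_idx = None
            for spc in range(3):
                block = state[v, spc] * jump_per_molecule
                if u < block:
                    sp_idx = spc
                    break
                u -= block
            if sp_idx is None:
                sp_idx = 2  # round-off tail
            k = int(np.searchsorted(edges_cum * state[v, sp_idx], u,
                                    side="right"))
            k = min(k, len(targets) - 1)
            w = int(targets[k])
            state[v, sp_idx] -= 1
            state[w, sp_idx] += 1
            touched.append(w)
        for vv in touched:
            push(vv, t_ev)
    return state


def advance_rdme_direct(
    mesh: CellMesh,
    state: np.ndarray,
    params: PathwayParams,
    signals: np.ndarray,
    t0: float,
    t1: float,
    seed: int,
    gamma: float | None = None,
) -> int:
    """Direct-method reference/performance path over the same voxelized
    propensity set as :func:`nsm` (JIT compiled; modifies ``state`` in
    place).  Distributional equivalence with the NSM is a tested
    invariant."""
    if gamma is None:
        gamma = 1.0 / params.omega
    q = _offdiag_csr(diffusion_jump_rates(mesh, gamma))
    d_in, d_out, n_in = (float(x) for x in np.asarray(signals, dtype=float))
    return advance_multivoxel_direct(
        state, mesh.volumes,
        q.indptr, q.indices, q.data,
        d_in, d_out, n_in,
        params.beta_n, params.beta_d, params.beta_r,
        params.k_t, params.k_c, params.k_rs,
        params.m, params.s, params.omega,
        t0, t1, seed,
    )
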