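"""Lattice geometry and the cell-to-cell signaling graph.

Cells sit on a regular lattice (hexagonal packing by default, unit cell
radius, neighbor center distance 2).  Two kinds of contacts carry signal:

* junctional -- direct membrane contact with the <= 6 lattice neighbors
  at center distance 2 (superscript (a) in the signaling sums);
* protrusional -- contacts mediated by cellular protrusions reaching
  beyond nearest neighbors, parameterized by a length ``l`` (cell radii),
  a set of directions ``theta`` and an angular width ``dtheta``
  (superscript (b)).

A contact ``j in P(i)`` requires *mutual reach*: the protrusion sectors of
both cells must cover the partner's direction.  With ``dtheta = 2*pi`` the
reach is isotropic and directions are ignored.

Signals are aggregated as weighted sums over the two contact sets::

    d_in  = w_a * sum_{J(i)} D_j + w_b * sum_{P(i)} D_j
    d_out = q_a * sum_{J(i)} D_j + q_b * sum_{P(i)} D_j
    n_in  = w_a * sum_{J(i)} N_j + w_b * sum_{P(i)} N_j
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

__all__ = [
    "Lattice",
    "ProtrusionSpec",
    "ContactGraph",
    "build_hex_lattice",
    "build_square_lattice",
    "lattice_from_positions",
    "protrusional_contacts",
    "build_contact_graph",
    "aggregate_signals",
]

# center distance of touching unit-radius cells
_JUNCTIONAL_DIST = 2.0
_TOL = 1e-9


@dataclass(frozen=True)
class Lattice:
    """Cell positions plus junctional adjacency.

    Positions are in units of the cell radius; touching cells are at
    center distance 2.  ``adjacency`` is a symmetric boolean CSR matrix.
    """

    positions: np.ndarray  # (n, 2)
    adjacency: sp.csr_matrix  # junctional neighbors (distance 2)
    periodic: bool = False
    box: tuple[float, float] | None = None  # periodic box lengths (Lx, Ly)

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return self.adjacency.indices[
            self.adjacency.indptr[i] : self.adjacency.indptr[i + 1]
        ]

    def displacement(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """Displacement vectors from cells ``i`` to cells ``j`` (minimal image
        if periodic)."""
        d = self.positions[j] - self.positions[i]
        if self.periodic:
            assert self.box is not None
            box = np.asarray(self.box)
            d = d - box * np.round(d / box)
        return d


@dataclass(frozen=True)
class ProtrusionSpec:
    """Protrusion geometry: length ``l`` (cell radii), directions ``theta``
    (radians) and angular width ``dtheta``.

    ``dtheta = 2*pi`` means isotropic protrusions (directions ignored).
    """

    length: float = 3.5
    directions: tuple[float, ...] = (0.0,)
    width: float = 2.0 * np.pi

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("protrusion length must be >= 0")
        if not 0.0 <= self.width <= 2.0 * np.pi + _TOL:
            raise ValueError("angular width must lie in [0, 2*pi]")

    @property
    def isotropic(self) -> bool:
        return self.width >= 2.0 * np.pi - _TOL


@dataclass
class ContactGraph:
    """Junctional and protrusional contact sets plus the signal weights in
    force.  ``junctional`` and ``protrusional`` are symmetric boolean CSR
    matrices with disjoint sparsity patterns and empty diagonals."""

    junctional: sp.csr_matrix
    protrusional: sp.csr_matrix
    w_a: float = 1.0
    w_b: float = 1.0
    q_a: float = 1.0
    q_b: float = 1.0

    @property
    def n_cells(self) -> int:
        return self.junctional.shape[0]

    def junctional_set(self, i: int) -> set[int]:
        m = self.junctional
        return set(m.indices[m.indptr[i] : m.indptr[i + 1]].tolist())

    def protrusional_set(self, i: int) -> set[int]:
        m = self.protrusional
        return set(m.indices[m.indptr[i] : m.indptr[i + 1]].tolist())

    def to_edge_list(self):
        """Edge list as (i, j, type) rows with i < j, type in
        {'junctional', 'protrusional'}."""
        rows = []
        for name, m in (("junctional", self.junctional),
                        ("protrusional", self.protrusional)):
            coo = sp.triu(m, k=1).tocoo()
            rows.extend((int(i), int(j), name) for i, j in zip(coo.row, coo.col))
        rows.sort()
        return rows


def _adjacency_from_positions(
    positions: np.ndarray, periodic: bool, box: tuple[float, float] | None
) -> sp.csr_matrix:
    n = positions.shape[0]
    if n == 1:
        return sp.csr_matrix((1, 1), dtype=bool)
    r = _JUNCTIONAL_DIST + _TOL
    if periodic:
        assert box is not None
        pairs = set()
        tree = cKDTree(positions)
        # tile the 8 periodic images; map pairs back to base indices
        shifts = [(sx, sy) for sx in (-1, 0, 1) for sy in (-1, 0, 1)]
        for sx, sy in shifts:
            if sx == 0 and sy == 0:
                continue
            shifted = positions + np.array([sx * box[0], sy * box[1]])
            t2 = cKDTree(shifted)
            for i, js in enumerate(tree.query_ball_tree(t2, r)):
                for j in js:
                    if i != j:
                        pairs.add((min(i, j), max(i, j)))
        for i, j in tree.query_pairs(r):
            pairs.add((min(i, j), max(i, j)))
        if not pairs:
            return sp.csr_matrix((n, n), dtype=bool)
        ii, jj = np.array(sorted(pairs)).T
    else:
        tree = cKDTree(positions)
        pairs = tree.query_pairs(r, output_type="ndarray")
        if len(pairs) == 0:
            return sp.csr_matrix((n, n), dtype=bool)
        ii, jj = pairs.T
    data = np.ones(len(ii), dtype=bool)
    adj = sp.coo_matrix((data, (ii, jj)), shape=(n, n))
    adj = adj + adj.T
    return adj.tocsr()


def build_hex_lattice(nx: int, ny: int, periodic: bool = False) -> Lattice:
    """Hexagonally packed lattice of ``nx * ny`` cells, unit cell radius.

    Rows are offset so that touching neighbors are at center distance 2;
    interior cells have exactly 6 junctional neighbors.  Periodic wrapping
    requires an even number of rows.
    """
    if nx < 1 or ny < 1:
        raise ValueError("lattice dimensions must be >= 1")
    if periodic and ny % 2 != 0:
        raise ValueError("periodic hexagonal lattice requires even ny")
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="xy")
    x = 2.0 * ix + (iy % 2)  # odd rows shifted half a spacing
    y = np.sqrt(3.0) * iy
    positions = np.column_stack([x.ravel(), y.ravel()]).astype(float)
    box = (2.0 * nx, np.sqrt(3.0) * ny) if periodic else None
    adj = _adjacency_from_positions(positions, periodic, box)
    return Lattice(positions=positions, adjacency=adj, periodic=periodic, box=box)


def build_square_lattice(nx: int, ny: int, periodic: bool = False) -> Lattice:
    """Square lattice with spacing 2 (4 junctional neighbors in the
    interior); ``ny = 1`` gives a 1-D chain."""
    if nx < 1 or ny < 1:
        raise ValueError("lattice dimensions must be >= 1")
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="xy")
    positions = np.column_stack([2.0 * ix.ravel(), 2.0 * iy.ravel()]).astype(float)
    box = (2.0 * nx, 2.0 * ny) if periodic else None
    adj = _adjacency_from_positions(positions, periodic, box)
    return Lattice(positions=positions, adjacency=adj, periodic=periodic, box=box)


def lattice_from_positions(positions: np.ndarray) -> Lattice:
    """Lattice from explicit cell-center coordinates (non-periodic)."""
    positions = np.asarray(positions, dtype=float)
    adj = _adjacency_from_positions(positions, False, None)
    return Lattice(positions=positions, adjacency=adj)


def _angle_within(phi: np.ndarray, spec: ProtrusionSpec) -> np.ndarray:
    """Whether direction angles ``phi`` fall inside any protrusion sector
    (closed at the sector edges)."""
    if spec.isotropic:
        return np.ones_like(phi, dtype=bool)
    ok = np.zeros_like(phi, dtype=bool)
    half = spec.width / 2.0
    for theta in spec.directions:
        d = np.angle(np.exp(1j * (phi - theta)))  # wrap to (-pi, pi]
        ok |= np.abs(d) <= half + _TOL
    return ok


def protrusional_contacts(lattice: Lattice, spec: ProtrusionSpec) -> sp.csr_matrix:
    """Protrusional contact matrix P under the mutual-reach rule.

    ``j in P(i)`` iff center distance lies in ``(2, l]``, the direction
    i -> j is inside a protrusion sector of i, and the direction j -> i is
    inside a sector of j.  Junctional neighbors (distance 2) are excluded.
    Symmetric by construction.
    """
    n = lattice.n_cells
    if spec.length <= _JUNCTIONAL_DIST or n < 2:
        return sp.csr_matrix((n, n), dtype=bool)
    r = spec.length + _TOL
    if lattice.periodic:
        assert lattice.box is not None
        pairs = set()
        tree = cKDTree(lattice.positions)
        for sx in (-1, 0, 1):
            for sy in (-1, 0, 1):
                if sx == 0 and sy == 0:
                    continue
                shifted = lattice.positions + np.array(
                    [sx * lattice.box[0], sy * lattice.box[1]]
                )
                t2 = cKDTree(shifted)
                for i, js in enumerate(tree.query_ball_tree(t2, r)):
                    for j in js:
                        if i != j:
                            pairs.add((min(i, j), max(i, j)))
        for i, j in tree.query_pairs(r):
            pairs.add((min(i, j), max(i, j)))
        pairs = np.array(sorted(pairs)) if pairs else np.empty((0, 2), int)
    else:
        tree = cKDTree(lattice.positions)
        pairs = tree.query_pairs(r, output_type="ndarray")
    if len(pairs) == 0:
        return sp.csr_matrix((n, n), dtype=bool)
    ii, jj = pairs[:, 0], pairs[:, 1]
    disp = lattice.displacement(ii, jj)
    dist = np.hypot(disp[:, 0], disp[:, 1])
    in_range = (dist > _JUNCTIONAL_DIST + _TOL) & (dist <= spec.length + _TOL)
    phi_ij = np.arctan2(disp[:, 1], disp[:, 0])
    phi_ji = np.angle(np.exp(1j * (phi_ij + np.pi)))
    mutual = _angle_within(phi_ij, spec) & _angle_within(phi_ji, spec)
    keep = in_range & mutual
    ii, jj = ii[keep], jj[keep]
    data = np.ones(len(ii), dtype=bool)
    m = sp.coo_matrix((data, (ii, jj)), shape=(n, n))
    m = m + m.T
    return m.tocsr()


def build_contact_graph(
    lattice: Lattice,
    spec: ProtrusionSpec | None = None,
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
) -> ContactGraph:
    """Contact graph with weights ``(w_a, q_a, w_b, q_b)``."""
    w_a, q_a, w_b, q_b = weights
    if min(w_a, q_a, w_b, q_b) < 0:
        raise ValueError("signal weights must be non-negative")
    spec = spec if spec is not None else ProtrusionSpec()
    prot = protrusional_contacts(lattice, spec)
    return ContactGraph(
        junctional=lattice.adjacency.tocsr(),
        protrusional=prot,
        w_a=w_a, w_b=w_b, q_a=q_a, q_b=q_b,
    )


def aggregate_signals(
    notch: np.ndarray, delta: np.ndarray, graph: ContactGraph
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell weighted signal sums ``(d_in, d_out, n_in)``.

    ``notch`` and ``delta`` are per-cell values (counts or concentrations;
    the output is in the caller's units).  Linear in the values; zero for a
    cell with no contacts.
    """
    notch = np.asarray(notch, dtype=float)
    delta = np.asarray(delta, dtype=float)
    n = graph.n_cells
    if notch.shape != (n,) or delta.shape != (n,):
        raise ValueError(
            f"value vectors must have shape ({n},), got {notch.shape}/{delta.shape}"
        )
    J = graph.junctional.astype(float)
    P = graph.protrusional.astype(float)
    d_a, d_b = J @ delta, P @ delta
    n_a, n_b = J @ notch, P @ notch
    d_in = graph.w_a * d_a + graph.w_b * d_b
    d_out = graph.q_a * d_a + graph.q_b * d_b
    n_in = graph.w_a * n_a + graph.w_b * n_b
    return d_in, d_out, n_in
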