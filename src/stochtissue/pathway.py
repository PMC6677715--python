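"""The Notch-Delta-Reporter signaling model of a single cell.

Three forms of the same lateral-inhibition-with-protrusions pathway:

* :func:`ndr_rhs` -- the deterministic ODE right-hand side.  Notch ``n``
  is consumed by trans-interaction with incoming Delta, by cis-inhibition
  with the cell's own Delta, and by linear decay; Delta ``d`` is produced
  under Hill repression by the reporter and consumed symmetrically; the
  reporter ``r`` is produced under Hill activation by the product of
  outgoing Delta and Notch.
* :func:`ndr_propensities` -- the stochastic transition rates obtained by
  reading concentrations as molecule counts ``(N, D, R)`` at a system
  volume ``Omega``.
* :func:`collier_rhs` -- the classical two-species juxtacrine
  lateral-inhibition model (Collier et al. 1996) kept as a reference:
  ``n' = f(<d>) - n``, ``d' = const * (g(n) - d)`` with caller-supplied
  monotone ``f`` (increasing) and ``g`` (decreasing).

:func:`ssa_population` advances a static population of well-stirred cells
by Gillespie's direct method in frozen-signal time chunks: cell-to-cell
signals are recomputed at chunk boundaries and held constant in between,
with the chunk length chosen adaptively so that a forward Euler step of
the ODE would change the state norm by ``chunk_safety`` (5% by default).
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from ._kernels import advance_cell_direct
from .contacts import ContactGraph, aggregate_signals
from .params import PathwayParams

__all__ = [
    "ndr_rhs",
    "collier_rhs",
    "ndr_propensities",
    "adaptive_chunk",
    "ssa_population",
    "random_initial_counts",
    "isolated_fixed_point",
    "PROPENSITY_CHANNELS",
]

#: Stoichiometry (dN, dD, dR) of the nine reaction channels, in the fixed
#: order returned by :func:`ndr_propensities`.
PROPENSITY_CHANNELS: tuple[tuple[int, int, int], ...] = (
    (+1, 0, 0),   # 0: Notch production, beta_n * Omega
    (0, +1, 0),   # 1: Delta production, beta_d * Omega * r1 (reporter repression)
    (0, 0, +1),   # 2: Reporter production, beta_r * Omega * r2 (Delta-Notch activation)
    (-1, 0, 0),   # 3: trans-degradation of Notch by incoming Delta
    (0, -1, 0),   # 4: trans-degradation of Delta by incoming Notch
    (-1, -1, 0),  # 5: cis pair annihilation N + D -> 0
    (-1, 0, 0),   # 6: Notch decay
    (0, -1, 0),   # 7: Delta decay
    (0, 0, -1),   # 8: Reporter decay
)


def _check_nonneg(name: str, arr: np.ndarray) -> None:
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")


def ndr_rhs(
    state: np.ndarray, signals: np.ndarray, params: PathwayParams
) -> np.ndarray:
    """ODE right-hand side ``(n', d', r')`` per cell.

    Parameters
    ----------
    state : array, shape (..., 3)
        Concentrations ``(n, d, r)`` per cell.
    signals : array, shape (..., 3)
        Precomputed weighted signals ``(d_in, d_out, n_in)`` per cell, in
        concentration units.
    """
    state = np.asarray(state, dtype=float)
    signals = np.asarray(signals, dtype=float)
    if state.shape != signals.shape or state.shape[-1] != 3:
        raise ValueError("state and signals must both have shape (..., 3)")
    _check_nonneg("state", state)
    _check_nonneg("signals", signals)
    n, d, r = state[..., 0], state[..., 1], state[..., 2]
    d_in, d_out, n_in = signals[..., 0], signals[..., 1], signals[..., 2]
    cis = d * n / params.k_c
    dn = params.beta_n - d_in * n / params.k_t - cis - n
    x = (d_out * n) ** params.s
    dd = params.beta_d / (1.0 + r**params.m) - d * n_in / params.k_t - cis - d
    dr = params.beta_r * x / (params.k_rs + x) - r
    return np.stack([dn, dd, dr], axis=-1)


def collier_rhs(
    state: np.ndarray,
    neighbor_mean_d: np.ndarray,
    f: Callable[[np.ndarray], np.ndarray] | None = None,
    g: Callable[[np.ndarray], np.ndarray] | None = None,
    const: float = 1.0,
) -> np.ndarray:
    """Classical juxtacrine lateral-inhibition right-hand side.

    ``state`` has shape ``(..., 2)`` holding ``(n, d)``;
    ``neighbor_mean_d`` is the Delta level averaged over each cell's
    junctional neighbors.  ``f`` must be monotone increasing (Notch
    activation by neighbor Delta) and ``g`` monotone decreasing (Delta
    repression by own Notch); the defaults are the Hill forms
    ``f(x) = x^2/(0.01 + x^2)`` and ``g(x) = 1/(1 + 100 x^2)``.
    """
    if f is None:
        f = lambda x: x**2 / (0.01 + x**2)
    if g is None:
        g = lambda x: 1.0 / (1.0 + 100.0 * x**2)
    state = np.asarray(state, dtype=float)
    n, d = state[..., 0], state[..., 1]
    dn = f(np.asarray(neighbor_mean_d, dtype=float)) - n
    dd = const * (g(n) - d)
    return np.stack([dn, dd], axis=-1)


def ndr_propensities(
    counts: np.ndarray, signals: np.ndarray, params: PathwayParams
) -> np.ndarray:
    """The nine stochastic transition rates of one well-stirred cell.

    ``counts`` is ``(N, D, R)`` (molecule numbers); ``signals`` is
    ``(D_in, D_out, N_in)`` in count units (weighted sums of neighbor
    counts).  The channel order and stoichiometry are given by
    :data:`PROPENSITY_CHANNELS`; the regulatory factors are

        r1 = 1 / (1 + (R/Omega)^m)
        r2 = (D_out * N / Omega^2)^s / (k_rs + (D_out * N / Omega^2)^s)
    """
    counts = np.asarray(counts, dtype=float)
    signals = np.asarray(signals, dtype=float)
    if counts.shape != (3,) or signals.shape != (3,):
        raise ValueError("counts and signals must have shape (3,)")
    _check_nonneg("counts", counts)
    _check_nonneg("signals", signals)
    N, D, R = counts
    d_in, d_out, n_in = signals
    om = params.omega
    r1 = 1.0 / (1.0 + (R / om) ** params.m)
    x = (d_out * N / om**2) ** params.s
    r2 = x / (params.k_rs + x)
    return np.array([
        params.beta_n * om,
        params.beta_d * om * r1,
        params.beta_r * om * r2,
        N * d_in / (params.k_t * om),
        D * n_in / (params.k_t * om),
        N * D / (params.k_c * om),
        N,
        D,
        R,
    ])


def adaptive_chunk(
    x: np.ndarray, f_x: np.ndarray, params: PathwayParams
) -> float:
    """Adaptive frozen-signal chunk length.

    ``dtau = chunk_safety * ||x|| / ||f(x)||`` with the Euclidean norm
    over the concatenated concentration vector of the whole population,
    i.e. the largest forward Euler step of the ODE that changes the state
    norm by the safety fraction.  Clamped to ``[dtau_min, dtau_max]``;
    at equilibrium (``f(x) = 0``) the chunk is ``dtau_max``, and for a
    zero state with non-zero drift it is ``dtau_min``.
    """
    nx = float(np.linalg.norm(np.ravel(x)))
    nf = float(np.linalg.norm(np.ravel(f_x)))
    if nf == 0.0:
        return params.dtau_max
    if nx == 0.0:
        return params.dtau_min
    return float(np.clip(params.chunk_safety * nx / nf, params.dtau_min,
                         params.dtau_max))


def random_initial_counts(
    n_cells: int, params: PathwayParams, rng: np.random.Generator
) -> np.ndarray:
    """Random initial molecular state: per cell and species, ``N`` and
    ``D`` are Poisson with mean ``Omega * u``, ``u ~ Uniform(0, 1)`` drawn
    independently, and ``R = 0``.  Spans low-to-high starting levels
    without biasing toward a particular patterned state."""
    u = rng.uniform(size=(n_cells, 2))
    counts = np.zeros((n_cells, 3), dtype=np.int64)
    counts[:, :2] = rng.poisson(params.omega * u)
    return counts


def isolated_fixed_point(
    params: PathwayParams, x0: tuple[float, float, float] = (1.0, 1.0, 0.0)
) -> np.ndarray:
    """Deterministic fixed point of an isolated cell (all signals zero):
    the ODE is integrated to near-stationarity and the result polished by
    a root find."""
    from scipy.integrate import solve_ivp
    from scipy.optimize import fsolve

    zero_sig = np.zeros(3)

    def fun(x):
        return ndr_rhs(np.abs(x), zero_sig, params)

    tr = solve_ivp(lambda t, y: fun(y), (0.0, 200.0), np.asarray(x0, float),
                   rtol=1e-10, atol=1e-12)
    sol = fsolve(fun, tr.y[:, -1], xtol=1e-13)
    return np.abs(np.asarray(sol))


def _chunk_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def ssa_population(
    initial: np.ndarray,
    graph: ContactGraph,
    params: PathwayParams,
    t_end: float,
    seed: int | np.random.Generator = 0,
    output_times: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Chunked Gillespie simulation of a static population of well-stirred
    cells.

    Repeatedly (i) aggregates every cell's signals from the current
    counts, (ii) picks a chunk ``dtau`` via :func:`adaptive_chunk` on the
    population concentration vector, and (iii) advances every cell
    independently by the direct method over ``[t, t + dtau)`` with the
    signals frozen.  Reproducible for a fixed seed.

    Returns ``(times, trajectory)`` with ``trajectory`` of shape
    ``(len(times), n_cells, 3)`` holding ``(N, D, R)`` counts.
    """
    if t_end < 0:
        raise ValueError("t_end must be non-negative")
    counts = np.array(initial, dtype=np.int64, copy=True)
    if counts.ndim != 2 or counts.shape[1] != 3:
        raise ValueError("initial must have shape (n_cells, 3)")
    if np.any(counts < 0):
        raise ValueError("initial counts must be non-negative")
    n_cells = counts.shape[0]
    if graph.n_cells != n_cells:
        raise ValueError("contact graph size does not match initial state")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if output_times is None:
        output_times = np.array([t_end])
    out_times = np.asarray(output_times, dtype=float)
    if np.any(np.diff(out_times) < 0) or np.any(out_times < 0):
        raise ValueError("output times must be sorted and non-negative")
    traj = np.zeros((len(out_times), n_cells, 3), dtype=np.int64)
    t = 0.0
    i_out = 0
    while i_out < len(out_times) and out_times[i_out] <= t:
        traj[i_out] = counts
        i_out += 1
    while t < t_end and i_out < len(out_times):
        d_in, d_out, n_in = aggregate_signals(counts[:, 0], counts[:, 1], graph)
        conc = counts / params.omega
        sig_conc = np.stack([d_in, d_out, n_in], axis=-1) / params.omega
        f_x = ndr_rhs(conc, sig_conc, params)
        if not np.all(np.isfinite(f_x)):
            raise FloatingPointError("non-finite drift encountered")
        dtau = adaptive_chunk(conc, f_x, params)
        t1 = min(t + dtau, out_times[i_out], t_end)
        for c in range(n_cells):
            advance_cell_direct(
                counts[c], d_in[c], d_out[c], n_in[c],
                params.beta_n, params.beta_d, params.beta_r,
                params.k_t, params.k_c, params.k_rs,
                params.m, params.s, params.omega,
                t, t1, _chunk_seed(rng),
            )
        t = t1
        while i_out < len(out_times) and out_times[i_out] <= t:
            traj[i_out] = counts
            i_out += 1
    while i_out < len(out_times):
        traj[i_out] = counts
        i_out += 1
    return out_times, traj
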