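"""Numba inner kernels for the stochastic simulation loops.

The direct-method kernels below are the hot paths: a pattern run executes
on the order of 1e9 reaction events, so the per-event work is JIT
compiled.  Channel ordering is fixed (and mirrored by
``pathway.ndr_propensities``) so trajectories are reproducible for a
fixed seed:

    0  0 -> N        rate beta_n * V
    1  0 -> D        rate beta_d * V / (1 + (R/V)^m)
    2  0 -> R        rate beta_r * V * hill_s((D_out/Omega) * (N/V))
    3  N -> 0        rate N * D_in / (k_t * Omega)
    4  D -> 0        rate D * N_in / (k_t * Omega)
    5  N + D -> 0    rate N * D / (k_c * V)
    6  N -> 0        rate N
    7  D -> 0        rate D
    8  R -> 0        rate R

For the well-stirred (single compartment) case V = Omega.  In the
multivoxel case production scales with the voxel volume V_i, the
bimolecular channel with 1/V_i, the regulatory Hill factors read the
local voxel concentration, and the frozen cell-to-cell signals enter as
whole-cell quantities divided by the whole-cell volume Omega (signals
are per-cell, not per-voxel, quantities).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["advance_cell_direct", "advance_multivoxel_direct"]


_U64_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)
_SPLITMIX_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_XSS_MULT = np.uint64(0x2545F4914F6CDD1D)
_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _seed_state(seed):
    # splitmix64 scramble so that consecutive seeds give unrelated streams
    z = (np.uint64(seed) + _SPLITMIX_GAMMA) & _U64_MASK
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _U64_MASK
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _U64_MASK
    z = z ^ (z >> np.uint64(31))
    if z == np.uint64(0):
        z = _SPLITMIX_GAMMA
    return z


@njit(cache=True, inline="always")
def _xorshift_next(x):
    # xorshift64* step; returns (new_state, uniform in [0, 1))
    x ^= x >> np.uint64(12)
    x = (x ^ (x << np.uint64(25))) & _U64_MASK
    x ^= x >> np.uint64(27)
    u = float(((x * _XSS_MULT) & _U64_MASK) >> np.uint64(11)) * _INV_2_53
    return x, u


@njit(cache=True, inline="always")
def _ipow(x, k):
    """x**k for small positive integer k without libm pow."""
    r = x
    for _ in range(k - 1):
        r *= x
    return r


@njit(cache=True, inline="always")
def _hill_r1(R_over_omega, m):
    return 1.0 / (1.0 + _ipow(R_over_omega, m))


@njit(cache=True, inline="always")
def _hill_r2(x, s, k_rs):
    xs = _ipow(x, s)
    return xs / (k_rs + xs)


@njit(cache=True)
def advance_cell_direct(
    counts,       # int64[3] (N, D, R), modified in place
    d_in, d_out, n_in,   # frozen signals, count units
    beta_n, beta_d, beta_r,
    k_t, k_c, k_rs, m, s, omega,
    t0, t1, seed,
):
    """Advance one well-stirred cell by Gillespie's direct method over
    [t0, t1) with frozen signals.  Returns the number of events fired.

    The categorical selection scans channels in the order
    R-production, R-decay, D-production, N-production, trans-N, trans-D,
    cis pair, N-decay, D-decay (most frequent channels first in the
    patterned regime); the order is fixed so a trajectory is reproducible
    for a fixed seed.
    """
    state = _seed_state(seed)
    N = float(counts[0])
    D = float(counts[1])
    R = float(counts[2])
    ktO = k_t * omega
    kcO = k_c * omega
    om2 = omega * omega
    a0 = beta_n * omega
    bdo = beta_d * omega
    bro = beta_r * omega
    # propensities depending only on R or N are cached; the running total
    # S excludes the R-decay channel and is updated incrementally (with a
    # periodic full resync against float drift)
    a1 = bdo * _hill_r1(R / omega, m)
    a2 = bro * _hill_r2(d_out * N / om2, s, k_rs)
    c3 = d_in / ktO
    c4 = n_in / ktO
    a3 = N * c3
    a4 = D * c4
    a5 = N * D / kcO
    S = a0 + a1 + a2 + a3 + a4 + a5 + N + D
    t = t0
    n_events = 0
    while True:
        a_tot = S + R
        if a_tot <= 0.0:
            break
        state, u = _xorshift_next(state)
        t -= np.log(1.0 - u) / a_tot
        if t >= t1:
            break
        state, u = _xorshift_next(state)
        u *= a_tot
        if u < a2 + R:
            # reporter churn fast path: only a1 depends on R
            if u < a2:
                R += 1.0
            else:
                R -= 1.0
            a1new = bdo * _hill_r1(R / omega, m)
            S += a1new - a1
            a1 = a1new
        else:
            u -= a2 + R
            if u < a1:
                D += 1.0
            elif u < a1 + a0:
                N += 1.0
                a2 = bro * _hill_r2(d_out * N / om2, s, k_rs)
            elif u < a1 + a0 + a3:
                N -= 1.0
                a2 = bro * _hill_r2(d_out * N / om2, s, k_rs)
            elif u < a1 + a0 + a3 + a4:
                D -= 1.0
            elif u < a1 + a0 + a3 + a4 + a5:
                N -= 1.0
                D -= 1.0
                a2 = bro * _hill_r2(d_out * N / om2, s, k_rs)
            elif u < a1 + a0 + a3 + a4 + a5 + N:
                N -= 1.0
            else:
                # tail: D decay (round-off lands here harmlessly when D > 0)
                if D > 0.0:
                    D -= 1.0
            a3 = N * c3
            a4 = D * c4
            a5 = N * D / kcO
            S = a0 + a1 + a2 + a3 + a4 + a5 + N + D
        n_events += 1
        if n_events & 0xFFFF == 0:
            S = a0 + a1 + a2 + a3 + a4 + a5 + N + D
    counts[0] = np.int64(N)
    counts[1] = np.int64(D)
    counts[2] = np.int64(R)
    return n_events


@njit(cache=True)
def advance_multivoxel_direct(
    counts,        # int64[nvox, 3], modified in place
    volumes,       # float64[nvox]
    jump_indptr, jump_indices, jump_rates,  # CSR of per-molecule jump rates i->j
    d_in, d_out, n_in,
    beta_n, beta_d, beta_r,
    k_t, k_c, k_rs, m, s, omega,
    t0, t1, seed,
):
    """Advance one spatially resolved cell (reaction-diffusion) by the
    direct method over [t0, t1) with frozen signals.

    Per-molecule diffusion jump rates are supplied in CSR form; the rate
    of the jump channel i->j is ``counts[i, sp] * jump_rates[k]``.
    Regulatory Hill factors use the *local* voxel concentration of the
    cell's own species (``R_v / V_v``, ``N_v / V_v``) and the whole-cell
    concentration of the frozen signals (``d_out / omega``); the
    signal-mediated degradations use the whole-cell volume.  With a
    single voxel this reduces exactly to the well-stirred channel set.
    Returns the number of events fired.
    """
    np.random.seed(seed)
    nvox = counts.shape[0]
    ktO = k_t * omega
    d_out_conc = d_out / omega
    t = t0
    n_events = 0
    while True:
        a_tot = 0.0
        for v in range(nvox):
            Nv = counts[v, 0]
            Dv = counts[v, 1]
            Rv = counts[v, 2]
            Vv = volumes[v]
            r1 = _hill_r1(Rv / Vv, m)
            r2 = _hill_r2(d_out_conc * Nv / Vv, s, k_rs)
            a_tot += (beta_n + beta_d * r1 + beta_r * r2) * Vv
            a_tot += Nv * d_in / ktO + Dv * n_in / ktO
            a_tot += Nv * Dv / (k_c * Vv)
            a_tot += Nv + Dv + Rv
            # diffusion out of v (all three species share the geometry)
            row_rate = 0.0
            for k in range(jump_indptr[v], jump_indptr[v + 1]):
                row_rate += jump_rates[k]
            a_tot += (Nv + Dv + Rv) * row_rate
        if a_tot <= 0.0:
            break
        t += -np.log(np.random.random()) / a_tot
        if t >= t1:
            break
        u = np.random.random() * a_tot
        acc = 0.0
        done = False
        for v in range(nvox):
            Nv = counts[v, 0]
            Dv = counts[v, 1]
            Rv = counts[v, 2]
            Vv = volumes[v]
            a0 = beta_n * Vv
            a1 = beta_d * _hill_r1(Rv / Vv, m) * Vv
            a2 = beta_r * _hill_r2(d_out_conc * Nv / Vv, s, k_rs) * Vv
            a3 = Nv * d_in / ktO
            a4 = Dv * n_in / ktO
            a5 = Nv * Dv / (k_c * Vv)
            local = a0 + a1 + a2 + a3 + a4 + a5 + Nv + Dv + Rv
            row_rate = 0.0
            for k in range(jump_indptr[v], jump_indptr[v + 1]):
                row_rate += jump_rates[k]
            local += (Nv + Dv + Rv) * row_rate
            if u >= acc + local:
                acc += local
                continue
            u -= acc
            # reaction channels in the fixed order, then diffusion
            if u < a0:
                counts[v, 0] += 1
            elif u < a0 + a1:
                counts[v, 1] += 1
            elif u < a0 + a1 + a2:
                counts[v, 2] += 1
            elif u < a0 + a1 + a2 + a3:
                counts[v, 0] -= 1
            elif u < a0 + a1 + a2 + a3 + a4:
                counts[v, 1] -= 1
            elif u < a0 + a1 + a2 + a3 + a4 + a5:
                counts[v, 0] -= 1
                counts[v, 1] -= 1
            elif u < a0 + a1 + a2 + a3 + a4 + a5 + Nv:
                counts[v, 0] -= 1
            elif u < a0 + a1 + a2 + a3 + a4 + a5 + Nv + Dv:
                counts[v, 1] -= 1
            elif u < a0 + a1 + a2 + a3 + a4 + a5 + Nv + Dv + Rv:
                counts[v, 2] -= 1
            else:
                u -= a0 + a1 + a2 + a3 + a4 + a5 + Nv + Dv + Rv
                # diffusion: species blocks N, D, R over the CSR row
                for sp in range(3):
                    csp = counts[v, sp]
                    found = False
                    for k in range(jump_indptr[v], jump_indptr[v + 1]):
                        ch = csp * jump_rates[k]
                        if u < ch:
                            counts[v, sp] -= 1
                            counts[jump_indices[k], sp] += 1
                            found = True
                            break
                        u -= ch
                    if found:
                        break
            done = True
            break
        # round-off at the categorical tail (u beyond the accumulated
        # total, probability ~ machine eps) is treated as a null event
        n_events += 1
    return n_events
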