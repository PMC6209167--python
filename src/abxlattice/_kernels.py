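"""Jitted sweep kernel for the lattice simulation.

Site codes (also the on-disk snapshot codes):
  0           vacant
  1 .. n      species-1 strain carrying the (k-1)-th production rate in
              ``allowed_a`` (with allowed_a[0] == 0, code 1 is the
              non-producer N)
  100         species-2 sensitive (S)
  101         species-2 resistant (R)

One sweep = one time step ``dt``: every site is visited once in a fresh
uniform random permutation (Fisher-Yates fused with the visit loop).  At
an occupied site the cell attempts reproduction with probability
``max(0, r_i) * dt`` into a uniformly chosen Moore neighbour (placed only
if that site is vacant, mutated with probability ``u``), and
independently dies with probability ``v * dt``.  Both events are resolved
from a single uniform draw by exact joint sampling (U < pq: both;
U < p: birth only; U < p + q - pq: death only).  Updates are applied
immediately (asynchronous semantics), so a newborn on a not-yet-visited
site is itself visited later in the same sweep.

Performance notes (this is the package's hot loop):
  - three independent xorshift64* streams (shuffle / event / placement)
    keep the serial RNG dependency chains short; the event stream is
    advanced for every visited site, occupied or not, so the hot path
    has a single data-dependent branch;
  - that branch compares the raw 64-bit event draw against a per-code
    upper bound on all event probabilities (0 for vacant sites), so the
    ~97% "nothing happens" path touches no rate tables and performs no
    float conversion; the rare path re-checks exact thresholds;
  - the 9-site antibiotic neighbourhood production sum is maintained
    incrementally in ``afield`` (updated on each producer birth/death).
    For integer production rates the float32 field is exact; callers can
    rebuild it from scratch via ``abxlattice.lattice.antibiotic_field``.
"""
from __future__ import annotations

import numpy as np
from numba import float64, int64, njit, uint64

CODE_VACANT = 0
CODE_S = 100
CODE_R = 101
N_CODES = 102

_M = np.uint64(2685821657736338717)  # xorshift64* output multiplier
_INV53 = 1.1102230246251565e-16  # 2**-53


@njit(inline="always", cache=True)
def _step(s):
    s ^= s >> uint64(12)
    s ^= s << uint64(25)
    s ^= s >> uint64(27)
    return s


@njit(cache=True)
def run_sweeps(g, afield, perm, state, xp, xm, arate,
               t_both, t_birth, t_dall, bound_u,
               r2, inv9b, q, dt, u, n_strains, sr_mut, global_disp,
               n_sweeps):
    """Advance the flattened lattice ``g`` by ``n_sweeps`` steps in place.

    ``t_both``/``t_birth``/``t_dall`` are per-code joint-draw thresholds
    (see :func:`birth_thresholds`); ``bound_u`` is the per-code uint64
    bound on the raw event draw (see :func:`event_bounds`).  ``state``
    holds the three RNG stream states and is updated in place;
    ``xp``/``xm`` are the +1/-1 torus wrap tables.
    """
    L = int64(xp.shape[0])
    n = L * L
    s1 = state[0]
    s2 = state[1]
    s3 = state[2]
    for _ in range(n_sweeps):
        for i in range(n - 1, -1, -1):
            if i > 0:
                s1 = _step(s1)
                j = int64((((s1 * _M) >> uint64(32)) * uint64(i + 1))
                          >> uint64(32))
                tmp = perm[i]
                perm[i] = perm[j]
                perm[j] = tmp
            site = int64(perm[i])
            code = g[site]
            s2 = _step(s2)
            draw_u = s2 * _M
            if draw_u >= bound_u[code]:
                continue
            draw = float64(draw_u >> uint64(11)) * _INV53
            if code == CODE_S:
                r = r2 - float64(afield[site]) * inv9b
                p = r * dt if r > 0.0 else 0.0
                tb = p
                tboth = p * q
                tdall = p + q - p * q
            else:
                tb = t_birth[code]
                tboth = t_both[code]
                tdall = t_dall[code]
            if draw >= tdall:
                continue
            x = site // L
            y = site - x * L
            if draw < tb:
                # birth attempt into a uniformly chosen target site
                s3 = _step(s3)
                if global_disp:
                    t = int64((((s3 * _M) >> uint64(32)) * uint64(n))
                              >> uint64(32))
                else:
                    d = int64((s3 * _M) >> uint64(61))
                    if d < 3:
                        tx = int64(xm[x])
                    elif d < 5:
                        tx = x
                    else:
                        tx = int64(xp[x])
                    if d == 0 or d == 3 or d == 5:
                        ty = int64(xm[y])
                    elif d == 1 or d == 6:
                        ty = y
                    else:
                        ty = int64(xp[y])
                    t = tx * L + ty
                if g[t] == CODE_VACANT:
                    off = code
                    if u > 0.0:
                        s3 = _step(s3)
                        if float64((s3 * _M) >> uint64(11)) * _INV53 < u:
                            if code < CODE_S:
                                if n_strains > 1:
                                    # uniform over strains excluding parent
                                    s3 = _step(s3)
                                    k = int64((((s3 * _M) >> uint64(32))
                                               * uint64(n_strains - 1))
                                              >> uint64(32)) + 1
                                    if k >= code:
                                        k += 1
                                    off = np.int8(k)
                            elif sr_mut:
                                off = (np.int8(CODE_R)
                                       if code == np.int8(CODE_S)
                                       else np.int8(CODE_S))
                    g[t] = off
                    av = arate[off]
                    if av > 0.0:
                        txx = t // L
                        tyy = t - txx * L
                        for ddx in range(-1, 2):
                            xx = txx + ddx
                            if xx < 0:
                                xx += L
                            elif xx >= L:
                                xx -= L
                            ro = xx * L
                            for ddy in range(-1, 2):
                                yy = tyy + ddy
                                if yy < 0:
                                    yy += L
                                elif yy >= L:
                                    yy -= L
                                afield[ro + yy] += av
                if draw >= tboth:
                    continue
            # death of the focal cell
            g[site] = CODE_VACANT
            av = arate[code]
            if av > 0.0:
                for ddx in range(-1, 2):
                    xx = x + ddx
                    if xx < 0:
                        xx += L
                    elif xx >= L:
                        xx -= L
                    ro = xx * L
                    for ddy in range(-1, 2):
                        yy = y + ddy
                        if yy < 0:
                            yy += L
                        elif yy >= L:
                            yy -= L
                        afield[ro + yy] -= av
    state[0] = s1
    state[1] = s2
    state[2] = s3


def birth_thresholds(rates: np.ndarray, v: float, dt: float):
    """Joint-draw thresholds from per-code growth rates.

    Returns ``(t_both, t_birth, t_dall)`` where, for birth probability
    ``p = max(0, r) * dt`` and death probability ``q = v * dt``, a single
    uniform draw U resolves both independent events: U < pq -> both,
    U < p -> birth only, U < p + q - pq -> death only.
    """
    p = np.clip(rates, 0.0, None) * dt
    q = v * dt
    return p * q, p, p + q - p * q


def event_bounds(t_dall: np.ndarray, r2: float, v: float, dt: float) -> np.ndarray:
    """Per-code uint64 bound on the raw event draw.

    Vacant sites get bound 0; S cells a bound covering their maximal
    birth probability ``r2 * dt``.  Bounds are inflated by one part in
    1e9 so the uint64 fast-path test is a strict superset of the exact
    float comparison re-done on the rare path.
    """
    q = v * dt
    p_s = r2 * dt
    bounds = t_dall.copy()
    bounds[CODE_S] = p_s + q - p_s * q
    bounds[CODE_VACANT] = 0.0
    scaled = np.minimum(bounds * (1.0 + 1e-9), 1.0) * 2.0**64
    return np.minimum(scaled, 2.0**64 - 2**11).astype(np.uint64)
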