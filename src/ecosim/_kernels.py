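"""Numba-compiled Euler-Maruyama inner loops.

The kernels consume the packed parameter vector produced by
``Parameters.pack()`` (see index map below) and mirror the pure-NumPy rate
laws in :mod:`ecosim.network`; the test suite asserts the two routes agree.

Packed parameter indices::

    0 k1   1 k2    2 cmax   3 k3_eff  4 alpha1  5 alpha2  6 k4    7 k5
    8 k6_eff  9 omega1  10 k7  11 k7b  12 n1  13 k8  14 k9_eff  15 omega2
    16 k10  17 k10b  18 n2  19 k11  20 k12  21 k13  22 k14  23 k15  24 k16
    25 d  26 noise_scale
"""

import numpy as np
from numba import njit

# Sparse stoichiometry: parallel arrays of (species, reaction, coefficient)
# for the 21 nonzero entries, kept in sync with network.STOICHIOMETRY by a
# unit test.
_NZ_SPECIES = np.array(
    [0, 1, 0, 1, 2, 3, 3, 5, 6, 6, 7, 2, 4, 8, 2, 3, 4, 5, 7, 8, 1],
    dtype=np.int64,
)
_NZ_REACTION = np.array(
    [0, 1, 2, 3, 4, 5, 6, 6, 7, 8, 8, 9, 9, 10, 11, 12, 13, 14, 15, 16, 17],
    dtype=np.int64,
)
_NZ_COEF = np.array(
    [1, 1, -1, -1, 1, 1, -2, 1, 1, -1, 1, -2, 1, 1, -1, -1, -1, -1, -1, -1, -1],
    dtype=np.float64,
)
_N_NZ = _NZ_SPECIES.shape[0]

OK = 0
NONFINITE = 1


@njit(cache=True)
def _fill_propensities(y, p, a):
    logistic = 1.0 - (y[0] + y[1]) / p[2]
    if logistic < 0.0:
        logistic = 0.0
    a[0] = p[0] * y[0] * logistic
    a[1] = p[1] * y[1] * logistic
    a[2] = p[3] * y[0] / (1.0 + p[4] * y[7])
    a[3] = p[3] * y[1] / (1.0 + p[5] * y[8])
    a[4] = p[6] * y[0]
    a[5] = p[7] * y[1]
    a[6] = p[8] * y[3] * y[3] / p[9]
    x = y[5] / p[9]
    if x > 0.0:
        if p[12] == 1.0:
            a[7] = p[9] * p[10] * x / (p[11] + x)
        else:
            xn = x ** p[12]
            a[7] = p[9] * p[10] * xn / (p[11] ** p[12] + xn)
    else:
        a[7] = 0.0
    a[8] = p[13] * y[6]
    a[9] = p[14] * y[2] * y[2] / p[15]
    z = y[4] / p[15]
    if z > 0.0:
        if p[18] == 1.0:
            a[10] = p[15] * p[16] * z / (p[17] + z)
        else:
            zn = z ** p[18]
            a[10] = p[15] * p[16] * zn / (p[17] ** p[18] + zn)
    else:
        a[10] = 0.0
    a[11] = p[19] * y[2]
    a[12] = p[20] * y[3]
    a[13] = p[21] * y[4]
    a[14] = p[22] * y[5]
    a[15] = p[23] * y[7]
    a[16] = p[24] * y[8]
    a[17] = p[25] * y[1]


@njit(cache=True)
def _advance(y, p, dt, sqdt, eps, a, dy, xi):
    """One Euler-Maruyama step in place; returns nothing."""
    _fill_propensities(y, p, a)
    for i in range(9):
        dy[i] = 0.0
    if eps > 0.0:
        for j in range(18):
            xi[j] = np.random.standard_normal()
        for k in range(_N_NZ):
            i = _NZ_SPECIES[k]
            j = _NZ_REACTION[k]
            aj = a[j]
            dy[i] += _NZ_COEF[k] * (aj * dt + eps * np.sqrt(aj) * sqdt * xi[j])
    else:
        for k in range(_N_NZ):
            dy[_NZ_SPECIES[k]] += _NZ_COEF[k] * a[_NZ_REACTION[k]] * dt
    for i in range(9):
        y[i] += dy[i]
        if y[i] < 0.0:
            y[i] = 0.0


@njit(cache=True)
def integrate(y0, p, dt, n_steps, record_every, ext_thresh, seed, record):
    """Integrate and record every ``record_every`` steps into ``record``.

    ``record`` must be preallocated with shape (n_steps//record_every + 1, 9)
    and n_steps must be a multiple of record_every.  Returns
    ``(status, bad_step, tz1, tz2)`` where tz1/tz2 are the first steps at
    which c1/c2 absorbed to zero (-1 if never).
    """
    np.random.seed(seed)
    y = y0.copy()
    a = np.empty(18)
    dy = np.empty(9)
    xi = np.empty(18)
    eps = p[26]
    sqdt = np.sqrt(dt)
    record[0] = y
    tz1 = -1
    tz2 = -1
    ri = 1
    for s in range(1, n_steps + 1):
        _advance(y, p, dt, sqdt, eps, a, dy, xi)
        if y[0] < ext_thresh:
            y[0] = 0.0
            if tz1 < 0:
                tz1 = s
        if y[1] < ext_thresh:
            y[1] = 0.0
            if tz2 < 0:
                tz2 = s
        if s % record_every == 0:
            for i in range(9):
                if not np.isfinite(y[i]):
                    return NONFINITE, s, tz1, tz2
            record[ri] = y
            ri += 1
    return OK, -1, tz1, tz2


@njit(cache=True)
def final_state(y0, p, dt, n_steps, ext_thresh, seed, y_out):
    """Integrate without recording; exit early once both populations absorb.

    Populations cannot recover from zero (every producing channel carries a
    factor of the population itself), so extinction of both is absorbing and
    the early exit is exact for survival queries.  Returns
    ``(status, bad_step, tz1, tz2)``.
    """
    np.random.seed(seed)
    y = y0.copy()
    a = np.empty(18)
    dy = np.empty(9)
    xi = np.empty(18)
    eps = p[26]
    sqdt = np.sqrt(dt)
    tz1 = -1
    tz2 = -1
    for s in range(1, n_steps + 1):
        _advance(y, p, dt, sqdt, eps, a, dy, xi)
        if y[0] < ext_thresh:
            y[0] = 0.0
            if tz1 < 0:
                tz1 = s
        if y[1] < ext_thresh:
            y[1] = 0.0
            if tz2 < 0:
                tz2 = s
        if tz1 >= 0 and tz2 >= 0:
            break
        if s % 1000 == 0:
            for i in range(9):
                if not np.isfinite(y[i]):
                    y_out[:] = y
                    return NONFINITE, s, tz1, tz2
    y_out[:] = y
    for i in range(9):
        if not np.isfinite(y[i]):
            return NONFINITE, n_steps, tz1, tz2
    return OK, -1, tz1, tz2
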