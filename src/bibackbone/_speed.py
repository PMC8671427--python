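"""Hot numerical loops, JIT-compiled with numba when available.

Two operations dominate runtime at simulation scale (hundreds of agents,
thousands of artifacts): curveball trading for fixed-degree-sequence
sampling, and the per-pair Poisson-binomial upper tail for SDSM p-values.
Both have identical pure-NumPy implementations used when numba is absent;
the two variants need not produce identical random streams, only valid ones.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - import-time dispatch
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def _curveball_trades_nb(B, n_trades, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    m, n = B.shape
    only_a = np.empty(n, np.int64)
    only_b = np.empty(n, np.int64)
    pool = np.empty(n, np.int64)
    for _ in range(n_trades):
        a = np.random.randint(0, m)
        b = np.random.randint(0, m - 1)
        if b >= a:
            b += 1
        la = 0
        lb = 0
        for k in range(n):
            ba = B[a, k]
            bb = B[b, k]
            if ba == 1 and bb == 0:
                only_a[la] = k
                la += 1
            elif ba == 0 and bb == 1:
                only_b[lb] = k
                lb += 1
        if la == 0 or lb == 0:
            continue
        tot = la + lb
        for t in range(la):
            pool[t] = only_a[t]
        for t in range(lb):
            pool[la + t] = only_b[t]
        for t in range(la):  # partial Fisher-Yates: first la entries go to row a
            j = t + np.random.randint(0, tot - t)
            tmp = pool[t]
            pool[t] = pool[j]
            pool[j] = tmp
        for t in range(tot):
            k = pool[t]
            if t < la:
                B[a, k] = 1
                B[b, k] = 0
            else:
                B[a, k] = 0
                B[b, k] = 1
    return B


def _curveball_trades_np(B, n_trades, seed):
    rs = np.random.RandomState(seed)
    m, n = B.shape
    for _ in range(n_trades):
        a = rs.randint(0, m)
        b = rs.randint(0, m - 1)
        if b >= a:
            b += 1
        ra, rb = B[a], B[b]
        only_a = np.nonzero((ra == 1) & (rb == 0))[0]
        only_b = np.nonzero((ra == 0) & (rb == 1))[0]
        la, lb = only_a.size, only_b.size
        if la == 0 or lb == 0:
            continue
        pool = np.concatenate((only_a, only_b))
        rs.shuffle(pool)
        B[a, pool] = 0
        B[b, pool] = 0
        B[a, pool[:la]] = 1
        B[b, pool[la:]] = 1
    return B


@njit(cache=False)
def _pb_upper_tail_pairs_nb(P, W):  # pragma: no cover - jitted
    m, n = P.shape
    out = np.ones((m, m))
    buf = np.empty(n + 2)
    for i in range(m):
        for j in range(i + 1, m):
            w = W[i, j]
            if w <= 0:
                p = 1.0
            else:
                # Pr(X >= w) = 1 - Pr(X <= w-1); the truncated convolution
                # keeping entries 0..w-1 is exact for the lower cdf because
                # each step is lower triangular.
                L = w
                for t in range(L):
                    buf[t] = 0.0
                buf[0] = 1.0
                reach = 0  # highest support index populated so far
                for k in range(n):
                    pk = P[i, k] * P[j, k]
                    if pk == 0.0:
                        continue
                    hi = reach + 1
                    if hi > L - 1:
                        hi = L - 1
                    for t in range(hi, 0, -1):
                        buf[t] = buf[t] * (1.0 - pk) + buf[t - 1] * pk
                    buf[0] *= 1.0 - pk
                    reach += 1
                cdf = 0.0
                for t in range(L):
                    cdf += buf[t]
                p = 1.0 - cdf
                if p < 0.0:
                    p = 0.0
            out[i, j] = p
            out[j, i] = p
    return out


def _pb_upper_tail_pairs_np(P, W):
    from .null_models import poisson_binomial_pmf

    m, n = P.shape
    out = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            w = int(W[i, j])
            if w <= 0:
                p = 1.0
            else:
                pmf = poisson_binomial_pmf(P[i] * P[j])
                p = float(pmf[w:].sum())
            out[i, j] = out[j, i] = p
    return out


if HAVE_NUMBA:
    curveball_trades = _curveball_trades_nb
    pb_upper_tail_pairs = _pb_upper_tail_pairs_nb
else:
    curveball_trades = _curveball_trades_np
    pb_upper_tail_pairs = _pb_upper_tail_pairs_np
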