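"""Numba-accelerated inner kernels with pure-numpy fallbacks.

The adaptive controller evaluates every module twice per attempted step
and reduces a relative error over the full grid; these few functions
dominate the run time of gridded models.  Semantics are identical to the
numpy paths (which remain the reference implementations in tests).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True, fastmath=False)
def max_rel_error(d1: np.ndarray, d2: np.ndarray, floor: float) -> float:
    """max over scored entries of |d1-d2|/|d2| (inf if d2 lost a delta).

    Entries with |d2| <= floor and |d1-d2| <= floor are negligible;
    |d2| <= floor with a significant difference forces a decrease (inf).
    Returns the linear ratio (not log10); 0.0 when nothing is scored.
    """
    worst = 0.0
    for i in range(d1.shape[0]):
        mag = abs(d2[i])
        diff = abs(d1[i] - d2[i])
        if mag > floor:
            r = diff / mag
            if r > worst:
                worst = r
        elif diff > floor:
            return math.inf
    return worst


@njit(cache=True, fastmath=False)
def stencil_rhs(c: np.ndarray, wl: np.ndarray, wr: np.ndarray,
                wu: np.ndarray, wd: np.ndarray, coef: float,
                out: np.ndarray) -> None:
    """Restricted five-point stencil with cached face weights (in-place)."""
    n, m = c.shape
    for i in range(n):
        for j in range(m):
            acc = 0.0
            if j + 1 < m:
                acc += wr[i, j] * (c[i, j + 1] - c[i, j])
            if j > 0:
                acc -= wl[i, j - 1] * (c[i, j] - c[i, j - 1])
            if i + 1 < n:
                acc += wd[i, j] * (c[i + 1, j] - c[i, j])
            if i > 0:
                acc -= wu[i - 1, j] * (c[i, j] - c[i - 1, j])
            out[i, j] = coef * acc


@njit(cache=True, fastmath=False)
def total_error_rel(d_full: np.ndarray, d_scaf: np.ndarray, y: np.ndarray,
                    floor: float) -> float:
    """max |d_full - d_scaf| / |y + d_scaf| over significant entries."""
    worst = 0.0
    for i in range(y.shape[0]):
        diff = abs(d_full[i] - d_scaf[i])
        denom = abs(y[i] + d_scaf[i])
        if diff <= floor and denom <= floor:
            continue
        if denom <= 0.0:
            if diff > 0.0:
                return math.inf
            continue
        r = diff / denom
        if r > worst:
            worst = r
    return worst
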