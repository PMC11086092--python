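"""Pair-counting kernels for the O(N^2) estimators.

Approximate entropy and the correlation integral both count pairs of
(embedded) points closer than a tolerance.  The counts are computed by
exact enumeration of every admissible pair; numba compiles the loops
when it is available and a vectorised numpy path produces identical
counts otherwise.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every feature test
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _apen_phis_py(x: np.ndarray, m: int, r: float) -> tuple[float, float]:
    n = len(x)
    nm = n - m + 1   # number of m-length templates
    nm1 = n - m      # number of (m+1)-length templates
    # self-matches included: start counts at 1
    cm = np.ones(nm, dtype=np.int64)
    cm1 = np.ones(nm1, dtype=np.int64)
    # chebyshev distance built incrementally one coordinate at a time
    d = np.zeros((nm, nm))
    for k in range(m):
        xk = x[k : k + nm]
        np.maximum(d, np.abs(xk[:, None] - xk[None, :]), out=d)
    close = d <= r
    np.fill_diagonal(close, False)
    cm += close.sum(axis=1)
    xk = x[m : m + nm1]
    d1 = np.maximum(d[:nm1, :nm1], np.abs(xk[:, None] - xk[None, :]))
    close1 = d1 <= r
    np.fill_diagonal(close1, False)
    cm1 += close1.sum(axis=1)
    phi_m = float(np.mean(np.log(cm / nm)))
    phi_m1 = float(np.mean(np.log(cm1 / nm1)))
    return phi_m, phi_m1


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _apen_phis_nb(x, m, r):  # pragma: no cover - numba path
        n = len(x)
        nm = n - m + 1
        nm1 = n - m
        cm = np.ones(nm, dtype=np.int64)
        cm1 = np.ones(nm1, dtype=np.int64)
        for i in range(nm):
            for j in range(i + 1, nm):
                d = 0.0
                for k in range(m):
                    a = abs(x[i + k] - x[j + k])
                    if a > d:
                        d = a
                if d <= r:
                    cm[i] += 1
                    cm[j] += 1
                    if j < nm1:  # i < j implies i < nm1 too
                        a = abs(x[i + m] - x[j + m])
                        if a > d:
                            d = a
                        if d <= r:
                            cm1[i] += 1
                            cm1[j] += 1
        phi_m = np.mean(np.log(cm / nm))
        phi_m1 = np.mean(np.log(cm1 / nm1))
        return phi_m, phi_m1

    @numba.njit(cache=True)
    def _corr_counts_nb(states, edges_sq, theiler):  # pragma: no cover - numba path
        m, dim = states.shape
        nr = len(edges_sq)
        hist = np.zeros(nr + 1, dtype=np.int64)
        for i in range(m):
            for j in range(i + theiler + 1, m):
                s = 0.0
                for k in range(dim):
                    diff = states[i, k] - states[j, k]
                    s += diff * diff
                # first edge with edges_sq >= s (binary search)
                lo, hi = 0, nr
                while lo < hi:
                    mid = (lo + hi) // 2
                    if edges_sq[mid] < s:
                        lo = mid + 1
                    else:
                        hi = mid
                hist[lo] += 1
        counts = np.zeros(nr, dtype=np.int64)
        acc = 0
        for k in range(nr):
            acc += hist[k]
            counts[k] = acc
        return counts


def _best_region_py(slopes: np.ndarray, rel_tol: float, min_points: int):
    n1 = len(slopes)
    best_i, best_j, best_len, best_var = -1, -1, 0, np.inf
    for i in range(n1):
        for j in range(i + min_points - 1, n1 + 1):
            s = slopes[i:j]
            mu = s.mean()
            if mu == 0.0:
                continue
            dev = np.max(np.abs(s - mu)) / abs(mu)
            if dev <= rel_tol:
                length = j - i + 1
                if length > best_len or (length == best_len and dev < best_var):
                    best_i, best_j, best_len, best_var = i, j, length, dev
    return best_i, best_j


if _HAVE_NUMBA:

    @numba.njit(cache=True)
    def _best_region_nb(slopes, rel_tol, min_points):  # pragma: no cover - numba path
        n1 = len(slopes)
        best_i, best_j, best_len = -1, -1, 0
        best_var = 1e300
        for i in range(n1):
            for j in range(i + min_points - 1, n1 + 1):
                mu = 0.0
                for k in range(i, j):
                    mu += slopes[k]
                mu /= j - i
                if mu == 0.0:
                    continue
                dev = 0.0
                for k in range(i, j):
                    a = abs(slopes[k] - mu)
                    if a > dev:
                        dev = a
                dev /= abs(mu)
                if dev <= rel_tol:
                    length = j - i + 1
                    if length > best_len or (length == best_len and dev < best_var):
                        best_i, best_j, best_len, best_var = i, j, length, dev
        return best_i, best_j


def best_region(slopes: np.ndarray, rel_tol: float, min_points: int) -> tuple[int, int]:
    """Longest slope window [i, j-1] (slope indices) with relative
    deviation from its mean below rel_tol; (-1, -1) when none exists."""
    slopes = np.ascontiguousarray(slopes, dtype=np.float64)
    if _HAVE_NUMBA:
        i, j = _best_region_nb(slopes, rel_tol, int(min_points))
        return int(i), int(j)
    return _best_region_py(slopes, rel_tol, min_points)


def apen_phis(x: np.ndarray, m: int, r: float) -> tuple[float, float]:
    """phi(m) and phi(m+1) for approximate entropy, self-matches included."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    if _HAVE_NUMBA:
        phi_m, phi_m1 = _apen_phis_nb(x, m, r)
        return float(phi_m), float(phi_m1)
    return _apen_phis_py(x, m, r)


def correlation_counts(states: np.ndarray, edges: np.ndarray, theiler: int) -> np.ndarray:
    """Number of state pairs (i, j), j - i > theiler, with ||xi-xj|| <= edge.

    Returns one cumulative count per entry of ``edges`` (ascending radii).
    """
    states = np.ascontiguousarray(states, dtype=np.float64)
    edges = np.asarray(edges, dtype=np.float64)
    edges_sq = edges * edges
    if _HAVE_NUMBA:
        return _corr_counts_nb(states, edges_sq, int(theiler))
    m = states.shape[0]
    counts = np.zeros(len(edges), dtype=np.int64)
    for i in range(m - theiler - 1):
        diff = states[i + theiler + 1 :] - states[i]
        dist_sq = np.einsum("ij,ij->i", diff, diff)
        for k, e in enumerate(edges_sq):
            counts[k] += int((dist_sq <= e).sum())
    return counts
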