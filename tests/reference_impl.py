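"""Naive brute-force reference implementations for oracle tests.

Each function evaluates its defining formula by direct enumeration
(plain Python loops, no shared code with the package internals) so the
optimised estimators can be checked against them at small N.
"""

import math

import numpy as np


def naive_correlation_sum(states: np.ndarray, radii, theiler: int) -> np.ndarray:
    """Fraction of state pairs (|i-j| > theiler) with ||xi - xj|| <= r."""
    m = len(states)
    out = []
    for r in radii:
        count = 0
        total = 0
        for i in range(m):
            for j in range(i + 1, m):
                if j - i <= theiler:
                    continue
                total += 1
                d = math.sqrt(sum((states[i, k] - states[j, k]) ** 2
                                  for k in range(states.shape[1])))
                if d <= r:
                    count += 1
        out.append(count / total)
    return np.array(out)


def naive_higuchi_lengths(x: np.ndarray, k: int) -> np.ndarray:
    """Curve lengths L_m(k), m = 1..k, by direct evaluation."""
    n = len(x)
    out = []
    for m in range(1, k + 1):
        a = (n - m) / k
        na = math.floor(a)
        s = 0.0
        for i in range(1, na + 1):
            s += abs(x[m - 1 + i * k] - x[m - 1 + (i - 1) * k])
        out.append((n - 1) / (a * k) * s / k)
    return np.array(out)


def naive_rs(x: np.ndarray, sizes) -> np.ndarray:
    """Mean rescaled range over non-overlapping segments of each size."""
    out = []
    for n in sizes:
        ratios = []
        for start in range(0, (len(x) // n) * n, n):
            seg = x[start : start + n]
            mean = sum(seg) / n
            dev = [v - mean for v in seg]
            cum, y = 0.0, []
            for d in dev:
                cum += d
                y.append(cum)
            r = max(y) - min(y)
            sd = math.sqrt(sum(d * d for d in dev) / (n - 1))
            if sd > 0:
                ratios.append(r / sd)
        out.append(sum(ratios) / len(ratios))
    return np.array(out)


def naive_dfa_fluctuation(x: np.ndarray, scales) -> np.ndarray:
    """RMS deviation from per-segment linear trends of the cumulative sum."""
    mean = sum(x) / len(x)
    y = []
    cum = 0.0
    for v in x:
        cum += v - mean
        y.append(cum)
    y = np.array(y)
    out = []
    for s in scales:
        n_seg = len(y) // s
        sq = []
        for seg_i in range(n_seg):
            seg = y[seg_i * s : (seg_i + 1) * s]
            t = np.arange(s, dtype=float)
            slope, intercept = np.polyfit(t, seg, 1)
            resid = seg - (slope * t + intercept)
            sq.extend(resid**2)
        out.append(math.sqrt(sum(sq) / len(sq)))
    return np.array(out)
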