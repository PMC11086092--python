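"""Log-log slope fitting with automatic scaling-region selection.

Scale-invariant estimators (correlation dimension, Lyapunov divergence,
R/S, DFA, Higuchi) all end in "the slope of the best linear
approximation" of a log-log curve.  Where the linear range is not the
whole curve (D2, LLE), the scaling region is selected automatically as
the longest contiguous sub-range whose point-to-point slopes stay within
a relative tolerance of their mean — manual region picking would not be
reproducible.
"""

from __future__ import annotations

import numpy as np


def fit_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y against x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x - x.mean()
    return float(np.dot(xm, y - y.mean()) / np.dot(xm, xm))


def select_scaling_region(
    x: np.ndarray,
    y: np.ndarray,
    rel_tol: float = 0.15,
    min_points: int = 4,
) -> tuple[int, int, bool]:
    """Longest contiguous index range [i, j] with stable local slope.

    Local slopes s_k = (y[k+1]-y[k])/(x[k+1]-x[k]) inside the candidate
    range must all satisfy |s_k - mean(s)| <= rel_tol * |mean(s)|.

    Returns (start, stop_inclusive, found).  When no range of at least
    ``min_points`` qualifies the whole curve is returned with
    ``found=False`` (callers flag the fit as unreliable).
    """
    from eegcomplexity._kernels import best_region

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two points to fit a slope")
    if n <= min_points:
        return 0, n - 1, False
    slopes = np.diff(y) / np.diff(x)
    i, j = best_region(slopes, rel_tol, min_points)
    if i < 0:
        return 0, n - 1, False
    return i, j, True


def slope_in_scaling_region(
    x: np.ndarray,
    y: np.ndarray,
    rel_tol: float = 0.15,
    min_points: int = 4,
) -> tuple[float, bool]:
    """Slope fitted over the automatically selected scaling region."""
    i, j, found = select_scaling_region(x, y, rel_tol=rel_tol, min_points=min_points)
    return fit_slope(x[i : j + 1], y[i : j + 1]), found
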