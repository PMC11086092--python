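"""Ten non-linear descriptors of a band-limited EEG window.

Attractor-based estimators (correlation dimension, largest Lyapunov
exponent) operate on a time-delay embedding x_i = [x(i), x(i+tau), ...,
x(i+(m-1)tau)] with M = N - (m-1)*tau states; the embedding delay tau
comes from the first local minimum of the auto mutual information and
the dimension m from the false-nearest-neighbour criterion.  The
remaining descriptors (approximate entropy, Hurst exponent via rescaled
range, DFA exponent, Higuchi and Katz fractal dimensions, energy,
Shannon and log-energy entropies) are computed directly on the series.

All estimators are pure functions of their inputs; neighbour searches
exclude temporally adjacent states through a Theiler window of m*tau
samples to suppress autocorrelation bias.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from eegcomplexity._fitting import fit_slope, slope_in_scaling_region
from eegcomplexity._kernels import apen_phis, correlation_counts
from eegcomplexity.errors import DegenerateSeriesError, ParameterError

__all__ = [
    "FEATURE_NAMES", "EmbeddingParams", "Attractor", "FeatureVector",
    "estimate_delay", "estimate_dimension", "embed",
    "correlation_sum", "correlation_dimension", "largest_lyapunov",
    "approximate_entropy", "rs_curve", "hurst_rs", "dfa_fluctuation", "dfa",
    "higuchi_curve_length", "higuchi_fd", "katz_fd", "energy",
    "shannon_entropy", "log_energy_entropy", "extract_all",
]

#: canonical feature order used across tables and classifiers
FEATURE_NAMES = ["D2", "LLE", "ApEn", "H", "DFA", "FDh", "FDk", "EN", "ETs", "ETL"]

#: energies below this are treated as silence in the entropy sums
ENERGY_EPS = 1e-12


class UnreliableResultWarning(UserWarning):
    """The estimate was produced but its scaling fit is questionable."""


@dataclass(frozen=True)
class EmbeddingParams:
    """Time-delay embedding parameters: delay in samples and dimension."""

    tau: int
    m: int

    def __post_init__(self) -> None:
        if self.tau < 1 or self.m < 1:
            raise ParameterError(f"require tau >= 1 and m >= 1, got tau={self.tau}, m={self.m}")


@dataclass(frozen=True)
class Attractor:
    """Delay-embedded state matrix: row i is [x(i), x(i+tau), ..., x(i+(m-1)tau)]."""

    states: np.ndarray
    n_source: int
    params: EmbeddingParams

    @property
    def n_states(self) -> int:
        return self.states.shape[0]

    @property
    def theiler(self) -> int:
        """Default Theiler exclusion window m*tau for neighbour searches."""
        return self.params.m * self.params.tau


def _as_series(x, min_len: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64).ravel()
    if len(x) < min_len:
        raise ParameterError(f"series of length {len(x)} is too short (need >= {min_len})")
    if not np.all(np.isfinite(x)):
        raise ParameterError("series contains non-finite values")
    return x


# ---------------------------------------------------------------------------
# embedding parameter selection
# ---------------------------------------------------------------------------

def _auto_mutual_information(bx: np.ndarray, lag: int, bins: int) -> float:
    """Mutual information between x(t) and x(t+lag) from pre-binned data."""
    a, b = bx[:-lag], bx[lag:]
    joint = np.bincount(a * bins + b, minlength=bins * bins).astype(float)
    joint /= joint.sum()
    pa = joint.reshape(bins, bins).sum(axis=1)
    pb = joint.reshape(bins, bins).sum(axis=0)
    nz = joint > 0
    outer = np.outer(pa, pb).ravel()
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def estimate_delay(series, max_lag: int | None = None, bins: int = 16) -> int:
    """Embedding delay: first local minimum of the auto mutual information.

    Falls back to the first zero crossing of the autocorrelation when the
    AMI curve has no local minimum within the scanned range; the result
    is capped at N/10.
    """
    x = _as_series(series, min_len=64)
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("constant series has no delay structure")
    n = len(x)
    cap = max(2, n // 10) if max_lag is None else int(max_lag)

    edges = np.linspace(x.min(), x.max(), bins + 1)
    bx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, bins - 1)
    ami_prev = np.inf
    ami_here = _auto_mutual_information(bx, 1, bins)
    # a genuine dip must undercut both neighbours by more than the
    # histogram estimator's numerical wiggle (periodic signals produce
    # flat AMI plateaus that would otherwise trigger spurious minima)
    tol = 1e-3 * ami_here
    for lag in range(1, cap):
        ami_next = _auto_mutual_information(bx, lag + 1, bins)
        if ami_here < ami_prev - tol and ami_here < ami_next - tol:
            return lag
        ami_prev, ami_here = ami_here, ami_next

    # fallback: first zero crossing of the autocorrelation (the lag on
    # whichever side of the crossing sits closer to zero)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :]
    acf = acf / acf[0]
    below = np.nonzero(acf[1 : cap + 1] <= 0)[0]
    if len(below):
        lag = int(below[0]) + 1
        if lag > 1 and abs(acf[lag - 1]) < abs(acf[lag]):
            lag -= 1
        return lag
    return cap


def estimate_dimension(
    series,
    tau: int,
    m_max: int = 10,
    rtol: float = 15.0,
    atol: float = 2.0,
    fnn_threshold: float = 0.01,
    max_refs: int = 128,
) -> int:
    """Embedding dimension: smallest m with a false-nearest-neighbour
    fraction below ``fnn_threshold``.

    A neighbour is false when the added coordinate stretches it by more
    than the distance ratio ``rtol``, or when the stretched distance
    exceeds ``atol`` times the series SD — the second (loneliness)
    criterion keeps pure noise from spuriously "settling" at moderate m,
    where nearest-neighbour distances are already so large that the
    ratio test cannot fire.

    Returns ``m_max`` with an :class:`UnreliableResultWarning` when the
    criterion is never met (typical for noise-dominated series).
    """
    x = _as_series(series, min_len=64)
    if tau < 1:
        raise ParameterError(f"tau must be >= 1, got {tau}")
    if len(x) < (m_max - 1) * tau + 2:
        raise ParameterError(
            f"series of length {len(x)} too short for m up to {m_max} at tau={tau}"
        )
    n = len(x)
    prev_frac = np.inf
    for m in range(1, m_max):
        n_valid = n - m * tau  # states whose (m+1)-th coordinate exists
        if n_valid < 20:
            break
        emb = np.column_stack([x[k * tau : k * tau + n_valid] for k in range(m)])
        step = max(1, math.ceil(n_valid / max_refs))
        refs = np.arange(0, n_valid, step)
        d = cdist(emb[refs], emb)
        # Theiler exclusion around each reference index
        d[np.abs(refs[:, None] - np.arange(n_valid)[None, :]) <= tau] = np.inf
        j_nn = np.argmin(d, axis=1)
        d0 = d[np.arange(len(refs)), j_nn]
        ok = np.isfinite(d0)
        if ok.sum() < 10:
            continue
        new_coord = np.abs(x[refs[ok] + m * tau] - x[j_nn[ok] + m * tau])
        # zero-distance neighbours (exactly repeated states) are false only
        # if the next coordinate separates them beyond numerical noise
        thresh = np.maximum(rtol * d0[ok], 1e-9 * (np.ptp(x) or 1.0))
        stretched = np.sqrt(d0[ok] ** 2 + new_coord**2)
        false = (new_coord > thresh) | (stretched > atol * x.std())
        frac = float(np.mean(false))
        if frac < fnn_threshold:
            return m
        # stochastic series plateau far above the threshold; once the
        # fraction stops improving there is nothing left to gain
        if frac >= prev_frac and frac > 5 * fnn_threshold:
            break
        prev_frac = frac
    warnings.warn(
        f"false-nearest-neighbour fraction never fell below {fnn_threshold}; "
        f"returning the cap m={m_max}",
        UnreliableResultWarning,
        stacklevel=2,
    )
    return m_max


def embed(series, params: EmbeddingParams) -> Attractor:
    """Delay-embed a series into M = N - (m-1)*tau state vectors."""
    x = _as_series(series)
    n = len(x)
    m, tau = params.m, params.tau
    n_states = n - (m - 1) * tau
    if n_states < 1:
        raise ParameterError(
            f"embedding with m={m}, tau={tau} needs N > (m-1)*tau; got N={n} (M={n_states})"
        )
    states = np.column_stack([x[k * tau : k * tau + n_states] for k in range(m)])
    return Attractor(states=states, n_source=n, params=params)


# ---------------------------------------------------------------------------
# attractor-based estimators
# ---------------------------------------------------------------------------

def correlation_sum(att: Attractor, radii, theiler: int | None = None) -> np.ndarray:
    """Correlation integral C(r): fraction of admissible state pairs with
    ||xi - xj|| <= r, pairs with |i - j| <= theiler excluded."""
    radii = np.asarray(radii, dtype=np.float64)
    if np.any(np.diff(radii) < 0):
        raise ParameterError("radii must be non-decreasing")
    w = att.theiler if theiler is None else int(theiler)
    m = att.n_states
    k = m - w - 1
    if k < 1:
        raise ParameterError("Theiler window leaves no admissible state pairs")
    n_pairs = k * (k + 1) // 2
    counts = correlation_counts(att.states, radii, w)
    return counts / n_pairs


def _subsample(att: Attractor, max_states: int) -> tuple[np.ndarray, int]:
    """Deterministic strided subsample; rescales the Theiler window to match."""
    m = att.n_states
    if m <= max_states:
        return att.states, att.theiler
    stride = math.ceil(m / max_states)
    return att.states[::stride], math.ceil(att.theiler / stride)


def correlation_dimension(
    att: Attractor,
    n_radii: int = 20,
    percentiles: tuple[float, float] = (0.2, 15.0),
    rel_tol: float = 0.15,
    max_states: int = 1024,
) -> float:
    """Grassberger-Procaccia correlation dimension.

    C(r) is evaluated on a log-spaced radius grid spanning the 0.2th to
    15th percentile of the pairwise state distances and D2 is the slope
    of log C vs log r over the automatically selected scaling region
    (the longest sub-range whose local slopes vary by less than
    ``rel_tol``).  D2 is defined in the r -> 0 limit, so the grid leans
    deliberately toward small radii: at mid-range radii C(r) already
    saturates toward the attractor's macroscopic extent and the slope is
    biased low.  Attractors beyond ``max_states`` states are strided
    down deterministically before pair counting.
    """
    if att.n_states < 100:
        raise ParameterError(f"need at least 100 states for D2, got {att.n_states}")
    states, w = _subsample(att, max_states)
    # the radius grid only needs approximate distance percentiles: estimate
    # them from a strided state subsample to avoid an O(M^2) sort
    probe = states[:: max(1, math.ceil(len(states) / 256))]
    dists = pdist(probe)
    d_lo, d_hi = np.percentile(dists, percentiles)
    if d_hi == 0:
        raise DegenerateSeriesError("all attractor states coincide")
    if d_lo <= 0:
        d_lo = dists[dists > 0].min()
    radii = np.geomspace(d_lo, d_hi, n_radii)
    sub = Attractor(states=states, n_source=att.n_source, params=att.params)
    c = correlation_sum(sub, radii, theiler=w)
    keep = c > 0
    if keep.sum() < 3:
        raise DegenerateSeriesError("correlation sum vanishes on the radius grid")
    slope, found = slope_in_scaling_region(np.log(radii[keep]), np.log(c[keep]), rel_tol=rel_tol)
    if not found:
        warnings.warn(
            "no stable scaling region in log C(r); slope fitted over the full grid",
            UnreliableResultWarning,
            stacklevel=2,
        )
    return slope


def largest_lyapunov(
    att: Attractor,
    ts: float,
    kmax: int | None = None,
    max_refs: int = 256,
    rel_tol: float = 0.15,
) -> float:
    """Largest Lyapunov exponent per second, Rosenstein-style.

    Each reference state is paired with its nearest neighbour outside the
    Theiler window; the mean log divergence curve over k follow-up steps
    is fitted over its automatically selected linear region and the slope
    is divided by the sampling period ``ts``.
    """
    if ts <= 0:
        raise ParameterError("sampling period ts must be positive")
    m = att.n_states
    if m < 200:
        raise ParameterError(f"need at least 200 states for the LLE, got {m}")
    if kmax is None:
        kmax = min(40, m // 10)
    w = att.theiler
    n_valid = m - kmax
    if n_valid - w - 1 < 10:
        raise ParameterError("too few valid neighbour pairs for divergence tracking")
    states = att.states
    step = max(1, math.ceil(n_valid / max_refs))
    refs = np.arange(0, n_valid, step)
    d = cdist(states[refs], states[:n_valid])
    d[np.abs(refs[:, None] - np.arange(n_valid)[None, :]) <= w] = np.inf
    d[d == 0] = np.inf
    j_nn = np.argmin(d, axis=1)
    d0 = d[np.arange(len(refs)), j_nn]
    ok = np.isfinite(d0)
    if ok.sum() < 10:
        raise ParameterError("too few valid neighbour pairs for divergence tracking")
    refs, j_nn = refs[ok], j_nn[ok]

    steps_idx = np.arange(kmax + 1)
    diff = states[refs[:, None] + steps_idx] - states[j_nn[:, None] + steps_idx]
    dk = np.sqrt(np.einsum("rkm,rkm->rk", diff, diff))
    with np.errstate(divide="ignore"):
        logs = np.where(dk > 0, np.log(np.where(dk > 0, dk, 1.0)), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        curve = np.nanmean(logs, axis=0)
    good = np.isfinite(curve)
    steps = np.arange(kmax + 1, dtype=float)
    slope, found = slope_in_scaling_region(steps[good], curve[good], rel_tol=rel_tol)
    if not found:
        warnings.warn(
            "no stable linear region in the divergence curve; slope fitted over the full curve",
            UnreliableResultWarning,
            stacklevel=2,
        )
    return slope / ts


# ---------------------------------------------------------------------------
# series-based estimators
# ---------------------------------------------------------------------------

def approximate_entropy(series, m: int = 2, r_frac: float = 0.2) -> float:
    """ApEn(m, r) with r = r_frac * SD(series) and self-matches included.

    A zero-variance series is perfectly regular and returns 0 by
    convention.  Because r scales with the SD the statistic is invariant
    to amplitude scaling.
    """
    x = _as_series(series, min_len=100)
    if m < 1:
        raise ParameterError("template length m must be >= 1")
    sd = float(np.std(x))
    if sd == 0:
        return 0.0
    phi_m, phi_m1 = apen_phis(x, m, r_frac * sd)
    return phi_m - phi_m1


def rs_curve(series, segment_sizes) -> np.ndarray:
    """Mean rescaled range R(n)/SD(n) over non-overlapping segments."""
    x = _as_series(series)
    out = np.empty(len(segment_sizes))
    for i, n in enumerate(segment_sizes):
        n = int(n)
        n_seg = len(x) // n
        if n_seg < 1:
            raise ParameterError(f"segment size {n} exceeds series length {len(x)}")
        segs = x[: n_seg * n].reshape(n_seg, n)
        dev = segs - segs.mean(axis=1, keepdims=True)
        y = np.cumsum(dev, axis=1)
        r = y.max(axis=1) - y.min(axis=1)
        s = segs.std(axis=1, ddof=1)
        ok = s > 0
        if not np.any(ok):
            raise DegenerateSeriesError(f"all segments of size {n} are constant")
        out[i] = np.mean(r[ok] / s[ok])
    return out


def hurst_rs(series, min_size: int = 16) -> float:
    """Hurst exponent: slope of log R/S over dyadic segment sizes 16..N/2,
    clipped to [0, 1] with a warning when the raw slope falls outside."""
    x = _as_series(series, min_len=256)
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("R/SD is undefined for a constant series")
    sizes = []
    n = min_size
    while n <= len(x) // 2:
        sizes.append(n)
        n *= 2
    rs = rs_curve(x, sizes)
    h = fit_slope(np.log(sizes), np.log(rs))
    if not 0.0 <= h <= 1.0:
        warnings.warn(
            f"R/S slope {h:.3f} outside [0, 1]; clipped", UnreliableResultWarning, stacklevel=2
        )
        h = float(np.clip(h, 0.0, 1.0))
    return h


def dfa_fluctuation(series, scales) -> np.ndarray:
    """DFA fluctuation F(m): RMS deviation of the cumulative deviation
    series from per-segment linear (order-1) trends."""
    x = _as_series(series)
    y = np.cumsum(x - x.mean())
    out = np.empty(len(scales))
    for i, s in enumerate(scales):
        s = int(s)
        if s < 4:
            raise ParameterError("DFA segment size must be >= 4")
        n_seg = len(y) // s
        if n_seg < 1:
            raise ParameterError(f"scale {s} exceeds series length {len(y)}")
        segs = y[: n_seg * s].reshape(n_seg, s)
        t = np.arange(s, dtype=float)
        tc = t - t.mean()
        denom = np.dot(tc, tc)
        slope = segs @ tc / denom
        resid = segs - segs.mean(axis=1, keepdims=True) - slope[:, None] * tc[None, :]
        out[i] = np.sqrt(np.mean(resid**2))
    return out


def dfa(series, n_scales: int = 16) -> float:
    """DFA scaling exponent: log-log slope of F(m) over log-spaced m in [4, N/4]."""
    x = _as_series(series, min_len=256)
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("DFA is undefined for a constant series")
    scales = np.unique(np.geomspace(4, len(x) // 4, n_scales).astype(int))
    f = dfa_fluctuation(x, scales)
    keep = f > 0
    if keep.sum() < 3:
        raise DegenerateSeriesError("DFA fluctuation vanishes at almost every scale")
    return fit_slope(np.log(scales[keep]), np.log(f[keep]))


def higuchi_curve_length(series, k: int) -> np.ndarray:
    """Higuchi curve lengths L_m(k) for m = 1..k (1-based series offsets)."""
    x = _as_series(series)
    n = len(x)
    out = np.empty(k)
    for m in range(1, k + 1):
        a = (n - m) / k
        na = int(a)
        if na < 1:
            raise ParameterError(f"series too short for Higuchi k={k}")
        idx = m - 1 + np.arange(na + 1) * k
        out[m - 1] = (n - 1) / (a * k) * np.sum(np.abs(np.diff(x[idx]))) / k
    return out


def higuchi_fd(series, kmax: int = 8) -> float:
    """Higuchi fractal dimension: slope of ln L(k) vs ln(1/k), k = 1..kmax."""
    if kmax < 2:
        raise ParameterError("kmax must be >= 2")
    x = _as_series(series, min_len=10 * kmax)
    lk = np.empty(kmax)
    for k in range(1, kmax + 1):
        lk[k - 1] = np.mean(higuchi_curve_length(x, k))
    if np.any(lk <= 0):
        raise DegenerateSeriesError("zero curve length (constant series?)")
    ks = np.arange(1, kmax + 1, dtype=float)
    return fit_slope(np.log(1.0 / ks), np.log(lk))


def katz_fd(series) -> float:
    """Katz fractal dimension on (index, value) pairs with unit index step."""
    x = _as_series(series, min_len=3)
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("Katz FD is undefined for a constant series")
    n = len(x)
    steps = np.sqrt(1.0 + np.diff(x) ** 2)
    total = steps.sum()
    mean_step = total / (n - 1)
    i = np.arange(1, n, dtype=float)
    d = np.sqrt(i**2 + (x[1:] - x[0]) ** 2).max()
    if d == 0 or total == 0:
        raise DegenerateSeriesError("degenerate waveform extent for Katz FD")
    return float(np.log(total / mean_step) / np.log(d / mean_step))


def energy(series) -> float:
    """Signal energy: sum of squared amplitudes."""
    x = _as_series(series, min_len=1)
    return float(np.sum(x**2))


def shannon_entropy(series) -> float:
    """Shannon-type spectral entropy -sum |x|^2 log |x|^2 (natural log);
    samples with |x|^2 below ENERGY_EPS contribute zero."""
    x = _as_series(series, min_len=1)
    p = x**2
    p = p[p >= ENERGY_EPS]
    return float(-np.sum(p * np.log(p)))


def log_energy_entropy(series) -> float:
    """Log-energy entropy -sum log |x|^2 (natural log), with |x|^2 floored
    at ENERGY_EPS; the printed sign convention is kept even though it is
    nonstandard - the statistic is discriminative, not a calibrated entropy."""
    x = _as_series(series, min_len=1)
    p = np.maximum(x**2, ENERGY_EPS)
    return float(-np.sum(np.log(p)))


# ---------------------------------------------------------------------------
# combined extraction
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """The ten features of one (subject, channel, band, window) series.

    Estimators that cannot run on the input (constant signal, attractor
    too short...) leave NaN and record the reason in ``status`` rather
    than aborting the window.
    """

    values: dict[str, float] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([self.values[name] for name in FEATURE_NAMES])

    def ok(self, name: str) -> bool:
        return self.status[name] == "ok"


def _attempt(fv: FeatureVector, name: str, fn) -> None:
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", UnreliableResultWarning)
        try:
            fv.values[name] = float(fn())
            unreliable = [w for w in caught if issubclass(w.category, UnreliableResultWarning)]
            fv.status[name] = f"unreliable: {unreliable[0].message}" if unreliable else "ok"
        except (ParameterError, DegenerateSeriesError) as exc:
            fv.values[name] = float("nan")
            fv.status[name] = f"degenerate: {exc}"


def extract_all(
    series,
    fs: float,
    kmax: int = 8,
    apen_m: int = 2,
    apen_r_frac: float = 0.2,
    m_cap: int = 6,
) -> FeatureVector:
    """Compute the full 10-feature vector for one band-limited window.

    Delay and dimension are estimated once per series; attractor-based
    features whose preconditions fail are flagged, never silently dropped.
    The default embedding-dimension cap follows the Eckmann-Ruelle data
    requirement m <= 2*log10(N) (~6 for 1280-sample windows): estimating
    D2 beyond it from a single window is meaningless and stochastic
    band series would otherwise always saturate a higher cap.
    """
    x = _as_series(series, min_len=2)
    if fs <= 0:
        raise ParameterError("sampling rate must be positive")
    fv = FeatureVector()

    att = None
    embed_err: str | None = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UnreliableResultWarning)
            tau = estimate_delay(x)
            m = estimate_dimension(x, tau, m_max=m_cap)
        att = embed(x, EmbeddingParams(tau=tau, m=m))
    except (ParameterError, DegenerateSeriesError) as exc:
        embed_err = str(exc)

    if att is not None:
        _attempt(fv, "D2", lambda: correlation_dimension(att))
        _attempt(fv, "LLE", lambda: largest_lyapunov(att, ts=1.0 / fs))
    else:
        for name in ("D2", "LLE"):
            fv.values[name] = float("nan")
            fv.status[name] = f"degenerate: embedding failed ({embed_err})"

    _attempt(fv, "ApEn", lambda: approximate_entropy(x, m=apen_m, r_frac=apen_r_frac))
    _attempt(fv, "H", lambda: hurst_rs(x))
    _attempt(fv, "DFA", lambda: dfa(x))
    _attempt(fv, "FDh", lambda: higuchi_fd(x, kmax=kmax))
    _attempt(fv, "FDk", lambda: katz_fd(x))
    _attempt(fv, "EN", lambda: energy(x))
    _attempt(fv, "ETs", lambda: shannon_entropy(x))
    _attempt(fv, "ETL", lambda: log_energy_entropy(x))
    return fv
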