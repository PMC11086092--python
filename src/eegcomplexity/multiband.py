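"""Five-band EEG decomposition with a biorthogonal-3.5 wavelet filter bank.

A 5-level critically decimated octave filter bank at fs = 256 Hz maps
the detail/approximation branches onto the canonical EEG sub-bands:

    gamma <- D2 (32-64 Hz; content above 45 Hz is removed upstream)
    beta  <- D3 (16-32 Hz)
    alpha <- D4 (8-16 Hz)
    theta <- D5 (4-8 Hz)
    delta <- A5 (0-4 Hz; the 0.1 Hz high-pass removes DC upstream)

Features are computed on single-branch *reconstructions*, not on the
decimated coefficients: at level 5 a 1280-sample window leaves only ~40
coefficients, far too short for attractor-based estimators, and
reconstruction keeps all bands length-comparable.  D1 (64-128 Hz) is
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from eegcomplexity.errors import ParameterError
from eegcomplexity.preprocess import WindowSet

__all__ = [
    "BANDS", "BAND_NAMES", "WaveletPyramid", "SubbandWindowSet",
    "dwt_decompose", "reconstruct_branch", "reconstruct_subband",
    "band_project", "decompose_to_subbands",
]

#: band -> (f_lo, f_hi, branch index into the level-5 wavedec coefficient list
#: [A5, D5, D4, D3, D2, D1]); nominal edges follow the octave convention at 256 Hz
BANDS: dict[str, tuple[float, float, int]] = {
    "delta": (0.1, 4.0, 0),
    "theta": (4.0, 8.0, 1),
    "alpha": (8.0, 16.0, 2),
    "beta": (16.0, 32.0, 3),
    "gamma": (32.0, 45.0, 4),
}

BAND_NAMES = list(BANDS)

#: sampling rate the band <-> level mapping is valid for
BANDMAP_FS = 256.0

DEFAULT_WAVELET = "bior3.5"
DEFAULT_MODE = "symmetric"


@dataclass(frozen=True)
class WaveletPyramid:
    """Coefficients of a multi-level DWT: [A_L, D_L, D_{L-1}, ..., D_1]."""

    coeffs: list[np.ndarray]
    wavelet: str
    mode: str
    n: int  # original series length

    @property
    def levels(self) -> int:
        return len(self.coeffs) - 1


@dataclass(frozen=True)
class SubbandWindowSet:
    """Per window and channel, the five reconstructed sub-band series.

    ``data`` has shape (n_windows, n_channels, n_bands, window_len) with
    bands ordered as :data:`BAND_NAMES`.
    """

    data: np.ndarray
    fs: float
    channels: list[str]
    bands: tuple[str, ...] = tuple(BAND_NAMES)

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    def series(self, window: int, channel: int, band: str) -> np.ndarray:
        return self.data[window, channel, self.bands.index(band)]


def dwt_decompose(
    series,
    wavelet: str = DEFAULT_WAVELET,
    levels: int = 5,
    mode: str = DEFAULT_MODE,
) -> WaveletPyramid:
    """Decompose a series into a ``levels``-deep wavelet pyramid."""
    x = np.asarray(series, dtype=np.float64).ravel()
    if len(x) < 2**levels:
        raise ParameterError(
            f"series of length {len(x)} too short for a {levels}-level DWT "
            f"(minimum {2**levels} samples)"
        )
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode=mode)
    return WaveletPyramid(coeffs=coeffs, wavelet=wavelet, mode=mode, n=len(x))


def reconstruct_branch(pyramid: WaveletPyramid, branch: int) -> np.ndarray:
    """Inverse transform of a single branch (0 = A_L, 1 = D_L, ... last = D_1)."""
    if not 0 <= branch < len(pyramid.coeffs):
        raise ParameterError(f"branch {branch} outside pyramid with {len(pyramid.coeffs)} branches")
    coeffs = [c if i == branch else np.zeros_like(c) for i, c in enumerate(pyramid.coeffs)]
    out = pywt.waverec(coeffs, pyramid.wavelet, mode=pyramid.mode)
    return out[: pyramid.n]


def reconstruct_subband(pyramid: WaveletPyramid, band: str) -> np.ndarray:
    """Band-limited series carried by one named sub-band branch."""
    if band not in BANDS:
        raise ParameterError(f"unknown band {band!r}; expected one of {BAND_NAMES}")
    if pyramid.levels != 5:
        raise ParameterError("the band <-> branch mapping requires a 5-level pyramid")
    return reconstruct_branch(pyramid, BANDS[band][2])


def band_project(
    series,
    band: str,
    fs: float = BANDMAP_FS,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_MODE,
) -> np.ndarray:
    """Project a full-length series onto one sub-band branch.

    This is the idempotent single-branch operator the analysis applies
    per window; the synthetic generator uses it to build components that
    stay exactly inside one band of the filter bank.
    """
    if fs != BANDMAP_FS:
        raise ParameterError(f"band mapping is defined at fs={BANDMAP_FS:g} Hz, got {fs:g}")
    return reconstruct_subband(dwt_decompose(series, wavelet=wavelet, mode=mode), band)


def decompose_to_subbands(
    windows: WindowSet,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_MODE,
) -> SubbandWindowSet:
    """Decompose every window and channel into the five sub-band series."""
    if windows.fs != BANDMAP_FS:
        raise ParameterError(
            f"band <-> level mapping is specific to fs={BANDMAP_FS:g} Hz; "
            f"got fs={windows.fs:g} (resample first)"
        )
    n_win, n_ch, wlen = windows.windows.shape
    out = np.empty((n_win, n_ch, len(BANDS), wlen))
    for w in range(n_win):
        for c in range(n_ch):
            pyr = dwt_decompose(windows.windows[w, c], wavelet=wavelet, mode=mode)
            for b, band in enumerate(BAND_NAMES):
                out[w, c, b] = reconstruct_subband(pyr, band)
    if not np.all(np.isfinite(out)):
        raise ParameterError("non-finite values in sub-band reconstructions")
    return SubbandWindowSet(data=out, fs=windows.fs, channels=list(windows.channels))
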