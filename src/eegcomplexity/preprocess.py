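"""Recording I/O and the automatable preprocessing chain.

Order of operations mirrors a conventional resting-state workflow:
optional re-referencing, zero-phase band-pass (0.1-45 Hz), polyphase
downsampling to 256 Hz, DC removal, first-minute selection and
contiguous 5 s windowing.  Manual steps (bad-channel interpolation, ICA
artifact rejection) are out of scope; the loader instead hard-fails on
non-finite data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal

from eegcomplexity.errors import ParameterError, RecordingIOError

__all__ = [
    "EEGRecording", "WindowSet", "load_recording", "save_recording",
    "bandpass_dc", "resample_to", "select_first_minute", "window", "rereference",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EEGRecording:
    """One subject's multichannel recording (channels x samples, µV)."""

    data: np.ndarray
    fs: float
    channels: list[str]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2:
            raise ParameterError(f"expected a channels x samples matrix, got shape {data.shape}")
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channels) != data.shape[0]:
            raise ParameterError(
                f"{len(self.channels)} channel labels for {data.shape[0]} data rows"
            )
        object.__setattr__(self, "data", data)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def ts(self) -> float:
        """Sampling period in seconds."""
        return 1.0 / self.fs

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class WindowSet:
    """Contiguous non-overlapping windows: (n_windows, n_channels, window_len)."""

    windows: np.ndarray
    fs: float
    channels: list[str]
    duration: float  # seconds per window

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def window_len(self) -> int:
        return self.windows.shape[2]


def _check_finite(data: np.ndarray, channels: list[str], path) -> None:
    bad = ~np.all(np.isfinite(data), axis=1)
    if np.any(bad):
        names = [channels[i] for i in np.nonzero(bad)[0]]
        raise RecordingIOError(f"non-finite samples in {path} on channel(s) {', '.join(names)}")


def load_recording(path, fmt: str | None = None, fs: float | None = None) -> EEGRecording:
    """Load an EDF or plain-matrix recording.

    Matrix formats (``.npy`` binary, or delimited ``.tsv``/``.csv``/
    ``.txt`` with one row per channel) take the sampling rate and
    channel labels from a JSON sidecar ``<stem>.json`` (keys ``fs`` and
    ``channels``) or from the ``fs`` argument.
    """
    path = Path(path)
    if not path.exists():
        raise RecordingIOError(f"no such recording: {path}")
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if fmt == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise RecordingIOError("reading EDF requires the optional mne dependency") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> µV
        rec_fs = float(raw.info["sfreq"])
        channels = list(raw.ch_names)
    elif fmt == "matrix":
        sidecar = path.with_suffix(".json")
        meta = {}
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        rec_fs = float(meta.get("fs", fs) or 0.0)
        if rec_fs <= 0:
            raise RecordingIOError(f"no sampling rate for {path}: supply a sidecar or fs=")
        if path.suffix == ".npy":
            data = np.load(path)
        else:
            delim = "," if path.suffix == ".csv" else None
            data = np.loadtxt(path, delimiter=delim, ndmin=2)
        channels = list(meta.get("channels") or [f"ch{i + 1:02d}" for i in range(data.shape[0])])
    else:
        raise ParameterError(f"unknown recording format {fmt!r}")
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise RecordingIOError(f"{path}: expected a channels x samples matrix, got {data.shape}")
    _check_finite(data, channels, path)
    return EEGRecording(data=data, fs=rec_fs, channels=channels)


def save_recording(rec: EEGRecording, path) -> Path:
    """Write a recording as a matrix file plus JSON sidecar (.npy or .tsv)."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, rec.data)
    elif path.suffix in {".tsv", ".txt"}:
        np.savetxt(path, rec.data, delimiter="\t")
    elif path.suffix == ".csv":
        np.savetxt(path, rec.data, delimiter=",")
    else:
        raise ParameterError(f"unsupported output format {path.suffix!r}")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"fs": rec.fs, "channels": rec.channels}))
    return path


def bandpass_dc(rec: EEGRecording, lo: float = 0.1, hi: float = 45.0, order: int = 4) -> EEGRecording:
    """Zero-phase band-pass plus explicit DC removal.

    The high-pass side is an ``order``-4 Butterworth at ``lo``.  The
    low-pass side is a Chebyshev-II section designed for a flat passband
    up to ``hi`` with its stopband a ~11% step above (a 45 Hz corner
    rejects 50 Hz mains): a plain low-order Butterworth at ``hi`` would
    leave most of a 50 Hz tone standing.  Both are applied
    forward-backward, so non-linear features see no phase distortion.
    """
    if hi >= rec.fs / 2:
        raise ParameterError(f"high cutoff {hi} Hz >= Nyquist {rec.fs / 2} Hz")
    if not 0 < lo < hi:
        raise ParameterError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    hp = signal.butter(order, lo, btype="highpass", fs=rec.fs, output="sos")
    n_lp, wn = signal.cheb2ord(hi, min(hi * 10 / 9, 0.99 * rec.fs / 2), 0.5, 15, fs=rec.fs)
    lp = signal.cheby2(n_lp, 15, wn, btype="lowpass", fs=rec.fs, output="sos")
    # generous padding keeps the 0.1 Hz corner's edge transients out
    padlen = min(rec.n_samples - 1, 2048)
    data = signal.sosfiltfilt(hp, rec.data, axis=1, padlen=padlen)
    data = signal.sosfiltfilt(lp, data, axis=1, padlen=padlen)
    data = data - data.mean(axis=1, keepdims=True)
    return replace(rec, data=data)


def resample_to(rec: EEGRecording, target_fs: float = 256.0) -> EEGRecording:
    """Anti-aliased polyphase downsampling (upsampling is not supported)."""
    if target_fs > rec.fs:
        raise ParameterError(f"upsampling {rec.fs} -> {target_fs} Hz is not supported")
    if target_fs == rec.fs:
        return rec
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return EEGRecording(data=data, fs=target_fs, channels=list(rec.channels))


def select_first_minute(rec: EEGRecording, seconds: float = 60.0) -> EEGRecording:
    """Keep the first ``seconds`` of the recording."""
    n = int(round(seconds * rec.fs))
    if rec.n_samples < n:
        raise ParameterError(
            f"recording provides {rec.duration:.2f} s, need {seconds:g} s"
        )
    return replace(rec, data=rec.data[:, :n])


def window(rec: EEGRecording, duration: float = 5.0) -> WindowSet:
    """Split into contiguous non-overlapping windows; the trailing
    remainder shorter than one window is discarded with a logged notice."""
    if duration <= 0:
        raise ParameterError("window duration must be positive")
    wlen = int(round(duration * rec.fs))
    n_win = rec.n_samples // wlen
    if n_win < 1:
        raise ParameterError(
            f"recording of {rec.n_samples} samples shorter than one {wlen}-sample window"
        )
    rem = rec.n_samples - n_win * wlen
    if rem:
        log.info("discarding %d trailing samples (< one %g s window)", rem, duration)
    wins = rec.data[:, : n_win * wlen].reshape(rec.n_channels, n_win, wlen).transpose(1, 0, 2)
    return WindowSet(windows=np.ascontiguousarray(wins), fs=rec.fs,
                     channels=list(rec.channels), duration=duration)


def rereference(rec: EEGRecording, reference_channels=None) -> EEGRecording:
    """Subtract the mean of the named reference channels (e.g., linked
    mastoids).  A no-op when no reference is given, as for synthetic data
    that carries no montage."""
    if not reference_channels:
        return rec
    missing = [c for c in reference_channels if c not in rec.channels]
    if missing:
        raise ParameterError(f"reference channel(s) not in recording: {', '.join(missing)}")
    idx = [rec.channels.index(c) for c in reference_channels]
    ref = rec.data[idx].mean(axis=0, keepdims=True)
    return replace(rec, data=rec.data - ref)
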