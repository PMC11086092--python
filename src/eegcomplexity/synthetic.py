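"""Synthetic two-group EEG cohorts with controlled spectral and
non-linear structure.

Each channel is a sum of five band components, one per EEG sub-band.  A
component mixes a narrow-band oscillation (randomised-phase sinusoid
with frequency drift and slow amplitude modulation) with fractional
Gaussian noise projected onto the corresponding wavelet branch, so the
component sits exactly inside one branch of the analysis filter bank
and injected group effects stay local to their (channel, band) cell.

Three effect families shift a generator parameter for the second group:

``hurst``
    adds to the Hurst exponent of the component's fGn source.  Note the
    downstream band-wise Hurst *estimator* cannot see long-range
    dependence inside a narrow band (it lives below the band), so this
    effect expresses itself through the within-band spectral footprint,
    chiefly the band's energy share.
``energy``
    multiplies the component amplitude by (1 + magnitude).
``irregularity``
    adds to the stochastic fraction of the component's variance.

This module defines the test-bed for the pipeline, not a biophysical
claim: there is no volume conduction, no artifacts, no montage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from eegcomplexity.errors import ParameterError
from eegcomplexity.multiband import BAND_NAMES, BANDS, BANDMAP_FS, band_project
from eegcomplexity.preprocess import EEGRecording, save_recording

__all__ = [
    "CohortConfig", "EffectSpec", "SubjectRecord",
    "gen_fgn", "gen_chaotic", "gen_band_oscillation", "gen_cohort",
    "write_cohort", "load_cohort",
]

log = logging.getLogger(__name__)

#: default per-band component amplitudes (µV-ish 1/f profile with an alpha peak)
DEFAULT_BAND_AMPLITUDE = {
    "delta": 4.0,
    "theta": 2.5,
    "alpha": 3.0,
    "beta": 1.5,
    "gamma": 0.8,
}

#: default Hurst exponent of every band's fGn source: 0.5 is the neutral
#: null (flat spectrum within each band); effects inject persistence
DEFAULT_HURST = 0.5

#: default stochastic fraction of a band component's variance (1:1 mixing)
DEFAULT_NOISE_FRACTION = 0.5

#: broadband sensor noise amplitude relative to the summed component RMS
SENSOR_NOISE_FRACTION = 0.05

EFFECT_FAMILIES = ("hurst", "energy", "irregularity")


@dataclass(frozen=True)
class EffectSpec:
    """One injected group difference at a (channel, band) cell."""

    channel: int
    band: str
    family: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise ParameterError(f"unknown band {self.band!r}; expected one of {BAND_NAMES}")
        if self.family not in EFFECT_FAMILIES:
            raise ParameterError(
                f"unknown effect family {self.family!r}; expected one of {EFFECT_FAMILIES}"
            )
        if self.channel < 0:
            raise ParameterError("channel index must be non-negative")


@dataclass(frozen=True)
class SubjectRecord:
    """Subject id, group label and a pseudo-PSQI global score (0-21);
    scores <= 5 mark good sleepers, > 5 poor sleepers."""

    subject: str
    group: str
    psqi: int

    def __post_init__(self) -> None:
        if not 0 <= self.psqi <= 21:
            raise ParameterError(f"PSQI global score must be in 0..21, got {self.psqi}")


@dataclass(frozen=True)
class CohortConfig:
    """Study design of one synthetic two-group cohort.

    ``effect_spec`` entries shift group 2's generator parameter at the
    named (channel, band) cell; group 1 is always the reference.  The
    first group is generated as good sleepers (pseudo-PSQI 0-5), the
    second as poor sleepers (6-15); only the > 5 cutoff is functionally
    meaningful.
    """

    n_per_group: tuple[int, int] = (11, 25)
    n_channels: int = 32
    fs: float = 256.0
    duration: float = 60.0
    effect_spec: tuple[EffectSpec, ...] = ()
    seed: int = 0
    group_labels: tuple[str, str] = ("YG", "OB")
    band_amplitude: dict = field(default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDE))
    hurst: float = DEFAULT_HURST
    noise_fraction: float = DEFAULT_NOISE_FRACTION

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 2 or min(self.n_per_group) < 1:
            raise ParameterError("n_per_group must be a pair of positive integers")
        if self.n_channels < 1 or self.fs <= 0 or self.duration <= 0:
            raise ParameterError("n_channels, fs and duration must be positive")
        if self.group_labels[0] == self.group_labels[1]:
            raise ParameterError("group labels must differ")
        effects = tuple(
            e if isinstance(e, EffectSpec) else EffectSpec(*e) for e in self.effect_spec
        )
        for e in effects:
            if e.channel >= self.n_channels:
                raise ParameterError(
                    f"effect channel {e.channel} outside 0..{self.n_channels - 1}"
                )
        object.__setattr__(self, "effect_spec", effects)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


# ---------------------------------------------------------------------------
# primitive generators
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gen_fgn(hurst: float, n: int, seed=None) -> np.ndarray:
    """Fractional Gaussian noise by exact circulant embedding.

    The Davies-Harte construction embeds the length-n fGn covariance in
    a circulant matrix whose eigenvalues are obtained by FFT; for fGn
    they are non-negative for every 0 < H < 1, so the synthesis is exact.
    Should rounding ever produce a negative eigenvalue, an approximate
    spectral synthesis is used instead with a logged warning.
    """
    if not 0.0 < hurst < 1.0:
        raise ParameterError(f"Hurst exponent must lie in (0, 1), got {hurst}")
    if n < 2:
        raise ParameterError(f"need n >= 2 samples, got {n}")
    rng = _rng(seed)
    k = np.arange(n + 1, dtype=np.float64)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))
    circ = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(circ).real
    m = len(circ)
    if lam.min() < -1e-9:
        log.warning(
            "circulant embedding not positive semi-definite (min eigenvalue %.3g); "
            "falling back to approximate spectral synthesis", lam.min()
        )
        return _fgn_spectral(hurst, n, rng)
    lam = np.clip(lam, 0.0, None)
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    w = np.fft.ifft(np.sqrt(lam) * z).real * np.sqrt(m)
    return w[:n]


def _fgn_spectral(hurst: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Approximate fGn: shape white Gaussian noise by |f|^(1/2 - H) in
    the frequency domain (periodic approximation of the fGn spectrum)."""
    freqs = np.fft.rfftfreq(n)
    amp = np.empty_like(freqs)
    amp[0] = 0.0
    amp[1:] = freqs[1:] ** (0.5 - hurst)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def gen_chaotic(system: str, params: dict | None = None, n: int = 1000,
                seed=None, transient: int = 1000) -> np.ndarray:
    """Deterministic chaotic series: logistic-map orbit or Lorenz x-coordinate.

    ``params`` accepts r/x0 for the logistic map (defaults r=4, x0 drawn
    from the seed) and sigma/rho/beta/dt for Lorenz (classic 10, 28, 8/3
    at dt=0.05).  The first ``transient`` steps are discarded.
    """
    if n < 100:
        raise ParameterError(f"need n >= 100, got {n}")
    params = dict(params or {})
    rng = _rng(seed)
    if system == "logistic":
        r = float(params.get("r", 4.0))
        if not 0.0 < r <= 4.0:
            raise ParameterError(f"logistic parameter r must lie in (0, 4], got {r}")
        x0 = params.get("x0")
        x = float(rng.uniform(0.01, 0.99)) if x0 is None else float(x0)
        if not 0.0 <= x <= 1.0:
            raise ParameterError(f"logistic initial condition must lie in [0, 1], got {x}")
        out = np.empty(transient + n)
        for i in range(transient + n):
            out[i] = x
            x = r * x * (1.0 - x)
        return out[transient:]
    if system == "lorenz":
        from scipy.integrate import solve_ivp

        sigma = float(params.get("sigma", 10.0))
        rho = float(params.get("rho", 28.0))
        beta = float(params.get("beta", 8.0 / 3.0))
        dt = float(params.get("dt", 0.05))
        y0 = params.get("y0")
        if y0 is None:
            y0 = 1.0 + 0.1 * rng.standard_normal(3)

        def deriv(_t, y):
            return [sigma * (y[1] - y[0]), y[0] * (rho - y[2]) - y[1], y[0] * y[1] - beta * y[2]]

        t_end = (transient + n) * dt
        sol = solve_ivp(deriv, (0.0, t_end), y0, t_eval=np.arange(transient + n) * dt,
                        rtol=1e-9, atol=1e-9, method="RK45")
        return sol.y[0, transient:]
    raise ParameterError(f"unknown chaotic system {system!r}; expected 'logistic' or 'lorenz'")


def gen_band_oscillation(band: str, fs: float, n: int, amplitude: float = 1.0,
                         seed=None) -> np.ndarray:
    """Narrow-band oscillation: randomised-phase sinusoid with slow
    frequency drift and amplitude modulation, >= 90% of its power inside
    the band's nominal range."""
    if band not in BANDS:
        raise ParameterError(f"unknown band {band!r}; expected one of {BAND_NAMES}")
    if fs <= 0 or n < 1:
        raise ParameterError("fs and n must be positive")
    if amplitude == 0:
        return np.zeros(n)
    rng = _rng(seed)
    lo, hi, _ = BANDS[band]
    lo = max(lo, 0.3)  # keep the delta carrier away from DC
    span = hi - lo
    f0 = rng.uniform(lo + 0.2 * span, hi - 0.2 * span)
    # slow frequency drift within +-5% of the carrier
    drift = np.cumsum(rng.standard_normal(n))
    drift = drift / (np.abs(drift).max() or 1.0) * 0.05 * f0
    phase = 2 * np.pi * np.cumsum(f0 + drift) / fs + rng.uniform(0, 2 * np.pi)
    # slow amplitude modulation (~0.2 Hz), 20% depth
    t = np.arange(n) / fs
    env = 1.0 + 0.2 * np.sin(2 * np.pi * 0.2 * t + rng.uniform(0, 2 * np.pi))
    return amplitude * env * np.sin(phase)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _band_component(band: str, n: int, fs: float, hurst: float, hurst_ref: float,
                    noise_fraction: float, amplitude: float,
                    rng: np.random.Generator) -> np.ndarray:
    """One band component: oscillation + band-projected fGn.

    The stochastic part is normalised against the *reference* Hurst
    exponent, not its own realisation: at the cohort baseline the
    oscillation/noise mix is exactly ``noise_fraction``, while a shifted
    Hurst exponent keeps its natural spectral footprint — the band's
    energy share of an fGn source changes with its exponent, and erasing
    that by per-realisation normalisation would leave nothing for the
    band-wise estimators to detect.
    """
    osc = gen_band_oscillation(band, fs, n, amplitude=1.0, seed=rng)
    sub_seed = int(rng.integers(2**31))
    z = gen_fgn(hurst, n, seed=np.random.default_rng(sub_seed))
    noise = band_project(z / z.std(), band, fs=fs)
    if hurst == hurst_ref:
        ref_sd = noise.std()
    else:
        # same underlying Gaussian draw at the reference exponent
        z_ref = gen_fgn(hurst_ref, n, seed=np.random.default_rng(sub_seed))
        ref_sd = band_project(z_ref / z_ref.std(), band, fs=fs).std()
    osc_sd = osc.std() or 1.0
    comp = (
        np.sqrt(1.0 - noise_fraction) * osc / osc_sd
        + np.sqrt(noise_fraction) * noise / (ref_sd or 1.0)
    )
    return amplitude * comp


def gen_cohort(config: CohortConfig) -> tuple[dict[str, EEGRecording], pd.DataFrame]:
    """Generate all recordings and the labelled subject table.

    Returns ``(recordings, subjects)`` where ``recordings`` maps subject
    id to :class:`EEGRecording` and ``subjects`` has columns
    ``subject``, ``group``, ``psqi``.  Identical config (including seed)
    reproduces the cohort bit for bit.
    """
    if config.fs != BANDMAP_FS:
        raise ParameterError(
            f"cohort synthesis uses the wavelet band projection, which is defined "
            f"at fs={BANDMAP_FS:g} Hz; got fs={config.fs:g}"
        )
    n = config.n_samples
    effects = {(e.channel, e.band): e for e in config.effect_spec}
    channels = [f"ch{i + 1:02d}" for i in range(config.n_channels)]

    n_total = sum(config.n_per_group)
    seeds = np.random.SeedSequence(config.seed).spawn(n_total + 1)
    score_rng = np.random.default_rng(seeds[-1])

    recordings: dict[str, EEGRecording] = {}
    rows = []
    subj_idx = 0
    for g, (label, n_group) in enumerate(zip(config.group_labels, config.n_per_group)):
        for k in range(n_group):
            rng = np.random.default_rng(seeds[subj_idx])
            data = np.empty((config.n_channels, n))
            for c in range(config.n_channels):
                sig = np.zeros(n)
                for band in BAND_NAMES:
                    hurst = config.hurst
                    amp = config.band_amplitude[band]
                    rho = config.noise_fraction
                    eff = effects.get((c, band))
                    if eff is not None and g == 1:
                        if eff.family == "hurst":
                            hurst = float(np.clip(hurst + eff.magnitude, 0.05, 0.95))
                        elif eff.family == "energy":
                            amp *= 1.0 + eff.magnitude
                        elif eff.family == "irregularity":
                            rho = float(np.clip(rho + eff.magnitude, 0.0, 1.0))
                    sig += _band_component(band, n, config.fs, hurst, config.hurst,
                                           rho, amp, rng)
                sig += SENSOR_NOISE_FRACTION * sig.std() * rng.standard_normal(n)
                data[c] = sig
            subject = f"{label}{k + 1:02d}"
            recordings[subject] = EEGRecording(data=data, fs=config.fs, channels=channels)
            psqi = int(score_rng.integers(0, 6)) if g == 0 else int(score_rng.integers(6, 16))
            rows.append(SubjectRecord(subject=subject, group=label, psqi=psqi))
            subj_idx += 1
    subjects = pd.DataFrame([(r.subject, r.group, r.psqi) for r in rows],
                            columns=["subject", "group", "psqi"])
    return recordings, subjects


# ---------------------------------------------------------------------------
# on-disk cohort layout
# ---------------------------------------------------------------------------

def write_cohort(recordings: dict[str, EEGRecording], subjects: pd.DataFrame,
                 out_dir, fmt: str = "npy") -> Path:
    """Write one matrix file per subject plus a delimited subject table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for subject, rec in recordings.items():
        save_recording(rec, out / f"{subject}.{fmt}")
    subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
    return out


def load_cohort(cohort_dir) -> tuple[dict[str, EEGRecording], pd.DataFrame]:
    """Read a cohort written by :func:`write_cohort`."""
    from eegcomplexity.preprocess import load_recording

    cohort_dir = Path(cohort_dir)
    subjects = pd.read_csv(cohort_dir / "subjects.tsv", sep="\t")
    recordings = {}
    for subject in subjects["subject"]:
        matches = sorted(
            p for p in cohort_dir.glob(f"{subject}.*") if p.suffix in {".npy", ".tsv", ".csv", ".txt", ".edf"}
        )
        if not matches:
            raise ParameterError(f"no recording file for subject {subject} in {cohort_dir}")
        recordings[subject] = load_recording(matches[0])
    return recordings, subjects
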