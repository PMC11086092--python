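"""End-to-end study driver: recordings -> features -> accuracy grids."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from eegcomplexity import classify, tables
from eegcomplexity.features import FEATURE_NAMES, extract_all
from eegcomplexity.multiband import decompose_to_subbands
from eegcomplexity.preprocess import (
    EEGRecording,
    bandpass_dc,
    rereference,
    resample_to,
    select_first_minute,
    window,
)

__all__ = ["preprocess_recording", "extract_subject_features", "extract_cohort_features", "run_study"]

log = logging.getLogger(__name__)


def preprocess_recording(
    rec: EEGRecording,
    band: tuple[float, float] = (0.1, 45.0),
    target_fs: float = 256.0,
    minute_s: float | None = 60.0,
    window_s: float = 5.0,
    reference_channels=None,
):
    """The standard chain: re-reference, band-pass + DC removal,
    downsample, first-minute selection, 5 s windowing.

    ``minute_s=None`` skips the minute selection (short test recordings).
    """
    rec = rereference(rec, reference_channels)
    rec = bandpass_dc(rec, *band)
    rec = resample_to(rec, target_fs)
    if minute_s is not None:
        rec = select_first_minute(rec, minute_s)
    return window(rec, window_s)


def extract_subject_features(rec: EEGRecording, subject: str, **preprocess_kwargs) -> pd.DataFrame:
    """Tidy per-window feature rows for one subject.

    Columns: subject, channel, band, window, feature, value, status.
    """
    windows = preprocess_recording(rec, **preprocess_kwargs)
    subbands = decompose_to_subbands(windows)
    rows = []
    for w in range(subbands.n_windows):
        for c, channel in enumerate(subbands.channels):
            for band in subbands.bands:
                fv = extract_all(subbands.series(w, c, band), fs=subbands.fs)
                for name in FEATURE_NAMES:
                    rows.append((subject, channel, band, w, name,
                                 fv.values[name], fv.status[name]))
    return pd.DataFrame(rows, columns=["subject", "channel", "band", "window",
                                       "feature", "value", "status"])


def extract_cohort_features(
    recordings: dict[str, EEGRecording],
    subjects: pd.DataFrame,
    **preprocess_kwargs,
) -> tuple[pd.DataFrame, tables.CohortFeatureTable]:
    """Per-window table and its window-mean aggregation for a whole cohort."""
    parts = []
    for subject in subjects["subject"]:
        log.info("extracting features for %s", subject)
        parts.append(extract_subject_features(recordings[subject], subject, **preprocess_kwargs))
    window_table = pd.concat(parts, ignore_index=True)
    return window_table, tables.aggregate_windows(window_table, subjects)


def run_study(
    table: tables.CohortFeatureTable,
    pairs: list[tables.GroupPair],
    specs: list[str] | None = None,
    fold_normalize: bool = False,
) -> dict[str, dict]:
    """Z-score, classify and summarise every group pair.

    Returns per pair: the normalised table, the accuracy grid, the
    band-wise summary and the best classifier.
    """
    out = {}
    for pair in pairs:
        if fold_normalize:
            # fold-safe mode: no pooled scaling; each training fold
            # standardises itself inside the LOOCV loop
            norm = tables.impute_pair(table, pair)
            grid = classify.run_pair(norm, pair, specs=specs, fold_normalize=True)
        else:
            norm = tables.zscore_pair(table, pair)
            grid = classify.run_pair(norm, pair, specs=specs)
        summary, best, note = classify.summarize(grid)
        out[pair.name] = {"normalized": norm, "grid": grid, "summary": summary,
                          "best": best, "note": note}
    return out
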