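"""Window aggregation and pairwise-group z-scoring of the feature grid.

Per-window features are compressed to one value per (subject, channel,
band, feature) by the mean over valid windows; for every group pair the
values are then z-scored per (channel, band, feature) against the
pooled two-group mean and SD.  Pooled normalisation mirrors the study
design it reproduces; because it uses all subjects before
cross-validation it leaks distributional information into LOOCV, so a
fold-safe alternative (train-fold statistics only) is available in the
classifier via ``fold_normalize=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from eegcomplexity.errors import ParameterError
from eegcomplexity.features import FEATURE_NAMES
from eegcomplexity.multiband import BAND_NAMES

__all__ = ["CohortFeatureTable", "GroupPair", "aggregate_windows", "impute_pair", "zscore_pair"]

_CELL = ["channel", "band", "feature"]


@dataclass(frozen=True)
class GroupPair:
    """A two-group contrast, e.g. young good sleepers vs older poor sleepers."""

    labels: tuple[str, str]
    name: str = ""

    def __post_init__(self) -> None:
        if self.labels[0] == self.labels[1]:
            raise ParameterError("a group pair needs two distinct labels")
        if not self.name:
            object.__setattr__(self, "name", f"{self.labels[0]}_vs_{self.labels[1]}")


@dataclass(frozen=True)
class CohortFeatureTable:
    """Tidy per-subject feature grid plus subject metadata.

    ``values`` columns: subject, channel, band, feature, value, n_windows;
    the grid is complete — cells whose estimator failed in every window
    hold NaN.  ``subjects`` columns: subject, group, psqi.
    """

    values: pd.DataFrame
    subjects: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"subject", *_CELL, "value"} - set(self.values.columns)
        if missing:
            raise ParameterError(f"feature table lacks column(s) {sorted(missing)}")

    @property
    def channels(self) -> list[str]:
        return sorted(self.values["channel"].unique())

    @property
    def bands(self) -> list[str]:
        present = set(self.values["band"].unique())
        return [b for b in BAND_NAMES if b in present]

    def group_of(self, subject: str) -> str:
        row = self.subjects.loc[self.subjects["subject"] == subject, "group"]
        if row.empty:
            raise ParameterError(f"unknown subject {subject!r}")
        return str(row.iloc[0])

    def pair_subjects(self, pair: GroupPair) -> tuple[list[str], list[str]]:
        out = []
        for label in pair.labels:
            subs = self.subjects.loc[self.subjects["group"] == label, "subject"].tolist()
            if not subs:
                raise ParameterError(f"group {label!r} has no subjects")
            out.append(subs)
        if set(out[0]) & set(out[1]):
            raise ParameterError("group sides of a pair must be disjoint")
        return out[0], out[1]

    def cell_matrix(self, channel: str, band: str, subjects: list[str]) -> np.ndarray:
        """(n_subjects, n_features) matrix for one (channel, band) cell."""
        sel = self.values[(self.values["channel"] == channel) & (self.values["band"] == band)]
        wide = sel.pivot(index="subject", columns="feature", values="value")
        wide = wide.reindex(index=subjects, columns=FEATURE_NAMES)
        return wide.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index=False)


def aggregate_windows(window_table: pd.DataFrame, subjects: pd.DataFrame) -> CohortFeatureTable:
    """Mean over valid windows per (subject, channel, band, feature).

    Rows whose estimator was flagged degenerate (NaN value) are excluded
    from the mean and from the window count; cells with no valid window
    stay in the grid as missing.
    """
    if window_table.empty:
        raise ParameterError("empty per-window feature table")
    t = window_table.copy()
    valid = t["value"].notna()
    agg = (
        t.assign(_valid=valid, _val=t["value"].where(valid))
        .groupby(["subject", *_CELL], sort=True, observed=True)
        .agg(value=("_val", "mean"), n_windows=("_valid", "sum"))
        .reset_index()
    )
    # complete grid over the observed axes
    idx = pd.MultiIndex.from_product(
        [sorted(t["subject"].unique()), sorted(t["channel"].unique()),
         [b for b in BAND_NAMES if b in set(t["band"])], FEATURE_NAMES],
        names=["subject", *_CELL],
    )
    agg = agg.set_index(["subject", *_CELL]).reindex(idx).reset_index()
    agg["n_windows"] = agg["n_windows"].fillna(0).astype(int)
    return CohortFeatureTable(values=agg, subjects=subjects.reset_index(drop=True))


def impute_pair(table: CohortFeatureTable, pair: GroupPair) -> CohortFeatureTable:
    """Restrict to a pair's subjects and mean-impute missing cells within
    group (pooled mean when a whole group side is missing), no scaling.

    This is the fold-safe entry point: feed the result to the classifier
    with ``fold_normalize=True`` so all standardisation statistics come
    from the training fold only.
    """
    side_a, side_b = table.pair_subjects(pair)
    subjects = side_a + side_b
    vals = table.values[table.values["subject"].isin(subjects)].copy()
    meta = table.subjects[table.subjects["subject"].isin(subjects)].reset_index(drop=True)
    group = vals["subject"].map(dict(zip(meta["subject"], meta["group"])))
    grp_mean = vals.groupby([group, *[vals[c] for c in _CELL]], observed=True)["value"].transform("mean")
    pooled_mean = vals.groupby(_CELL, observed=True)["value"].transform("mean")
    vals["value"] = vals["value"].fillna(grp_mean).fillna(pooled_mean)
    return CohortFeatureTable(values=vals.reset_index(drop=True), subjects=meta)


def zscore_pair(table: CohortFeatureTable, pair: GroupPair, impute: bool = True) -> CohortFeatureTable:
    """Normalise a pair's subjects per (channel, band, feature) cell.

    Subtracts the pooled two-group mean and divides by the pooled SD
    (denominator n-1).  Zero-variance cells are set to 0 with a warning.
    Missing values are mean-imputed within group first (falling back to
    the pooled mean when a whole group side is missing); cells missing
    everywhere propagate as NaN.
    """
    side_a, side_b = table.pair_subjects(pair)
    subjects = side_a + side_b
    if len(subjects) < 3:
        raise ParameterError("pooled z-scoring needs at least 3 subjects in the pair")
    if impute:
        imputed = impute_pair(table, pair)
        vals, meta = imputed.values.copy(), imputed.subjects
    else:
        vals = table.values[table.values["subject"].isin(subjects)].copy()
        meta = table.subjects[table.subjects["subject"].isin(subjects)].reset_index(drop=True)

    cell = vals.groupby(_CELL, observed=True)["value"]
    mu = cell.transform("mean")
    sd = cell.transform(lambda s: s.std(ddof=1))
    zero = sd.fillna(0.0) == 0.0
    if bool((zero & vals["value"].notna()).any()):
        warnings.warn("zero-variance cell(s) set to 0 after z-scoring", UserWarning, stacklevel=2)
    z = (vals["value"] - mu) / sd.where(~zero)
    vals["value"] = z.where(~zero, 0.0)
    return CohortFeatureTable(values=vals.reset_index(drop=True), subjects=meta)
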