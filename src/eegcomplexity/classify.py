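"""Sixteen-model classification suite with leave-one-out cross-validation.

The suite mirrors a standard classification-learner catalogue: three
decision trees (max splits 4/20/100), unpenalised logistic regression,
six SVMs (linear C=3, quadratic C=3, cubic C=4, Gaussian fine/medium/
coarse with kernel scales sqrt(P)/4, sqrt(P), 4*sqrt(P) over P=10
predictors and C=3/3/1) and six KNNs (fine k=1, medium k=10, coarse
k=100, cosine, cubic = Minkowski-3 and squared-inverse-distance
weighted, all k=10).  Every preset is a deterministic fit.

Accuracy is evaluated per (channel, band) cell on the cell's 10
features under leave-one-out cross-validation; ``fold_normalize=True``
re-standardises each training fold so the pooled z-scoring's leakage
can be quantified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from eegcomplexity.errors import ParameterError
from eegcomplexity.multiband import BAND_NAMES
from eegcomplexity.tables import CohortFeatureTable, GroupPair

__all__ = [
    "CLASSIFIER_NAMES", "AccuracyGrid", "build_classifier", "loocv",
    "run_pair", "summarize", "scalp_map",
]

log = logging.getLogger(__name__)

_N_PREDICTORS = 10  # the ten non-linear features


def _sq_inverse(dist: np.ndarray) -> np.ndarray:
    return 1.0 / np.maximum(dist, 1e-12) ** 2


def _presets() -> dict[str, dict]:
    p = _N_PREDICTORS
    return {
        "Fine Tree": {"family": "tree", "max_splits": 4},
        "Medium Tree": {"family": "tree", "max_splits": 20},
        "Coarse Tree": {"family": "tree", "max_splits": 100},
        "Logistic Regression": {"family": "logistic"},
        "Linear SVM": {"family": "svm", "kernel": "linear", "C": 3.0},
        "Quadratic SVM": {"family": "svm", "kernel": "poly", "degree": 2, "C": 3.0},
        "Cubic SVM": {"family": "svm", "kernel": "poly", "degree": 3, "C": 4.0},
        "Fine Gaussian SVM": {"family": "svm", "kernel": "rbf", "C": 3.0,
                              "kernel_scale": np.sqrt(p) / 4},
        "Medium Gaussian SVM": {"family": "svm", "kernel": "rbf", "C": 3.0,
                                "kernel_scale": np.sqrt(p)},
        "Coarse Gaussian SVM": {"family": "svm", "kernel": "rbf", "C": 1.0,
                                "kernel_scale": 4 * np.sqrt(p)},
        "Fine KNN": {"family": "knn", "k": 1, "metric": "euclidean"},
        "Medium KNN": {"family": "knn", "k": 10, "metric": "euclidean"},
        "Coarse KNN": {"family": "knn", "k": 100, "metric": "euclidean"},
        "Cosine KNN": {"family": "knn", "k": 10, "metric": "cosine"},
        "Cubic KNN": {"family": "knn", "k": 10, "metric": "minkowski3"},
        "Weighted KNN": {"family": "knn", "k": 10, "metric": "euclidean",
                         "weights": "squared_inverse"},
    }


PRESETS = _presets()
CLASSIFIER_NAMES = list(PRESETS)


def build_classifier(name: str):
    """Instantiate one named preset as an unfitted scikit-learn estimator."""
    if name not in PRESETS:
        raise ParameterError(f"unknown classifier preset {name!r}; see CLASSIFIER_NAMES")
    spec = PRESETS[name]
    fam = spec["family"]
    if fam == "tree":
        # a tree with at most s splits has at most s+1 leaves (Gini impurity)
        return DecisionTreeClassifier(max_leaf_nodes=spec["max_splits"] + 1, random_state=0)
    if fam == "logistic":
        # unpenalised in spirit; a tiny ridge keeps separable fits finite
        return LogisticRegression(C=1e8, max_iter=1000)
    if fam == "svm":
        if spec["kernel"] == "rbf":
            gamma = 1.0 / spec["kernel_scale"] ** 2
            return SVC(kernel="rbf", C=spec["C"], gamma=gamma)
        if spec["kernel"] == "poly":
            return SVC(kernel="poly", degree=spec["degree"], C=spec["C"],
                       gamma="scale", coef0=1.0)
        return SVC(kernel="linear", C=spec["C"])
    # knn; prediction ties break toward the smallest class index
    kwargs: dict = {"n_neighbors": spec["k"]}
    if spec["metric"] == "minkowski3":
        kwargs.update(metric="minkowski", p=3)
    else:
        kwargs.update(metric=spec["metric"])
    if spec.get("weights") == "squared_inverse":
        kwargs.update(weights=_sq_inverse)
    return KNeighborsClassifier(**kwargs)


def loocv(X: np.ndarray, y, spec: str, fold_normalize: bool = False) -> float:
    """Leave-one-out accuracy of one preset on one cell's feature matrix.

    Each subject is predicted by a model fitted on all others; KNN
    neighbour counts are capped at the training-fold size.  With
    ``fold_normalize`` the features are z-scored from the training fold
    only (the fold-safe alternative to pooled normalisation).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if X.ndim != 2 or X.shape[0] != n:
        raise ParameterError(f"feature matrix {X.shape} does not match {n} labels")
    if n < 2:
        raise ParameterError("LOOCV needs at least two subjects")
    if len(np.unique(y)) != 2:
        raise ParameterError("LOOCV needs both classes present")
    if np.isnan(X).any():
        raise ParameterError("feature matrix contains NaN; impute before classification")
    proto = build_classifier(spec)
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_tr, y_tr, X_te = X[mask], y[mask], X[i : i + 1]
        if fold_normalize:
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            X_tr = (X_tr - mu) / sd
            X_te = (X_te - mu) / sd
        model = clone(proto)
        if isinstance(model, KNeighborsClassifier) and model.n_neighbors > len(y_tr):
            model.set_params(n_neighbors=len(y_tr))
        model.fit(X_tr, y_tr)
        if model.predict(X_te)[0] == y[i]:
            correct += 1
    return correct / n


@dataclass(frozen=True)
class AccuracyGrid:
    """LOOCV accuracies of one group pair over (channel, band, classifier).

    ``accuracies`` columns: channel, band, classifier, accuracy; cells
    that could not be classified are recorded in ``failures`` with their
    reason rather than silently dropped.
    """

    pair: GroupPair
    accuracies: pd.DataFrame
    failures: pd.DataFrame

    def band_table(self, classifier: str) -> pd.DataFrame:
        """Mean and max accuracy over channels per band for one classifier."""
        sel = self.accuracies[self.accuracies["classifier"] == classifier]
        if sel.empty:
            raise ParameterError(f"no accuracies for classifier {classifier!r}")
        g = sel.groupby("band", observed=True)["accuracy"]
        out = pd.DataFrame({"mean": g.mean(), "max": g.max()})
        return out.reindex([b for b in BAND_NAMES if b in out.index])


def run_pair(
    norm_table: CohortFeatureTable,
    pair: GroupPair,
    specs: list[str] | None = None,
    fold_normalize: bool = False,
) -> AccuracyGrid:
    """LOOCV every (channel, band, classifier) cell of one group pair.

    ``norm_table`` is the pair's z-scored feature table (see
    :func:`eegcomplexity.tables.zscore_pair`).
    """
    specs = list(PRESETS) if specs is None else list(specs)
    for s in specs:
        if s not in PRESETS:
            raise ParameterError(f"unknown classifier preset {s!r}")
    side_a, side_b = norm_table.pair_subjects(pair)
    subjects = side_a + side_b
    y = np.array([norm_table.group_of(s) for s in subjects])
    rows, fails = [], []
    for channel in norm_table.channels:
        for band in norm_table.bands:
            X = norm_table.cell_matrix(channel, band, subjects)
            if np.isnan(X).any():
                fails.append((channel, band, "missing features after imputation"))
                continue
            for spec in specs:
                acc = loocv(X, y, spec, fold_normalize=fold_normalize)
                rows.append((channel, band, spec, acc))
    accuracies = pd.DataFrame(rows, columns=["channel", "band", "classifier", "accuracy"])
    failures = pd.DataFrame(fails, columns=["channel", "band", "reason"])
    return AccuracyGrid(pair=pair, accuracies=accuracies, failures=failures)


def summarize(grid: AccuracyGrid) -> tuple[pd.DataFrame, str, str]:
    """Per-band mean/max summary and the best classifier of one pair.

    Returns ``(summary, best, note)``: ``summary`` has one row per
    classifier and Mean/Max columns per band; ``best`` maximises the
    grand mean accuracy over all channels and bands, ties broken by
    lexicographic name with a logged note.
    """
    acc = grid.accuracies
    if acc.empty:
        raise ParameterError("empty accuracy grid")
    bands = [b for b in BAND_NAMES if b in set(acc["band"])]
    per = acc.groupby(["classifier", "band"], observed=True)["accuracy"].agg(["mean", "max"])
    summary = per.unstack("band").swaplevel(axis=1)
    summary = summary.reindex(
        columns=pd.MultiIndex.from_product([bands, ["mean", "max"]], names=["band", None])
    )
    grand = acc.groupby("classifier", observed=True)["accuracy"].mean()
    best_val = grand.max()
    tied = sorted(grand.index[grand == best_val])
    best = tied[0]
    note = ""
    if len(tied) > 1:
        note = f"tie on grand mean accuracy ({best_val:.3f}) between {', '.join(tied)}; " \
               f"reporting {best}"
        log.info("%s", note)
    return summary, best, note


def scalp_map(grid: AccuracyGrid, coordinates: dict[str, tuple[float, float]] | None,
              out_path, classifier: str | None = None):
    """Interpolated per-band accuracy maps for one classifier (best by
    default); falls back to a labelled bar chart when channel
    coordinates are unavailable.  Purely presentational."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if classifier is None:
        _, classifier, _ = summarize(grid)
    acc = grid.accuracies[grid.accuracies["classifier"] == classifier]
    bands = [b for b in BAND_NAMES if b in set(acc["band"])]
    channels = sorted(acc["channel"].unique())
    have_coords = coordinates is not None and all(c in coordinates for c in channels)

    fig, axes = plt.subplots(1, len(bands), figsize=(3.2 * len(bands), 3.4), squeeze=False)
    for ax, band in zip(axes[0], bands):
        sel = acc[acc["band"] == band].set_index("channel")["accuracy"].reindex(channels)
        if have_coords:
            from scipy.interpolate import griddata

            pts = np.array([coordinates[c] for c in channels], dtype=float)
            lim = np.abs(pts).max() * 1.15 or 1.0
            gx, gy = np.meshgrid(np.linspace(-lim, lim, 80), np.linspace(-lim, lim, 80))
            field = griddata(pts, sel.to_numpy(), (gx, gy), method="cubic")
            im = ax.pcolormesh(gx, gy, field, shading="auto", vmin=0.0, vmax=1.0, cmap="viridis")
            ax.scatter(pts[:, 0], pts[:, 1], s=8, c="k")
            ax.set_aspect("equal")
            ax.set_axis_off()
            fig.colorbar(im, ax=ax, shrink=0.75)
        else:
            ax.bar(range(len(channels)), sel.to_numpy())
            ax.set_xticks(range(len(channels)))
            ax.set_xticklabels(channels, rotation=90, fontsize=6)
            ax.set_ylim(0, 1)
        ax.set_title(f"{band} — {classifier}", fontsize=9)
    fig.suptitle(f"LOOCV accuracy, {grid.pair.name}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
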