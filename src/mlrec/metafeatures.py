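"""Dataset metafeatures for cold-start (metalearning) recommendations.

A metafeature vector is a fixed-length numeric summary of a labeled
classification table — size, class balance, feature-scale statistics —
that lets a recommender judge dataset similarity before any algorithm has
been run on the dataset.  The set is deliberately cheap and landmark-free;
a user can swap in their own vectors through the cache file.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: fixed metafeature names, in output order
METAFEATURE_NAMES = (
    "n_samples",
    "n_features",
    "n_classes",
    "log_n_samples",
    "log_n_features",
    "class_entropy",
    "imbalance",
    "frac_categorical",
    "mean_feature_variance",
    "median_feature_variance",
    "var_feature_variance",
    "mean_abs_corr",
)


@dataclass(frozen=True)
class MetafeatureVector:
    dataset_id: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.names) != len(self.values):
            raise ValueError("names and values must be aligned")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("metafeature values must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def compute_metafeatures(
    table: pd.DataFrame, target: str = "class", dataset_id: str = ""
) -> MetafeatureVector:
    """Compute the fixed metafeature set for one labeled table.

    ``table`` must have >= 2 rows, >= 1 feature column and a target column
    with >= 2 classes.  Missing numeric values are median-imputed per
    column (mode for categoricals) before computation, so every loadable
    table yields finite metafeatures.  Deterministic for a fixed table and
    invariant to row order.
    """
    if target not in table.columns:
        raise ValueError(f"target column {target!r} not in table")
    if len(table) < 2:
        raise ValueError("table must have at least 2 rows")
    features = table.drop(columns=[target])
    if features.shape[1] < 1:
        raise ValueError("table must have at least one feature column")
    y = table[target]
    class_counts = y.value_counts().to_numpy(dtype=float)
    n_classes = len(class_counts)
    if n_classes < 2:
        raise ValueError("target column must have at least 2 classes")

    n_samples, n_features = features.shape
    p = class_counts / class_counts.sum()
    class_entropy = float(-(p * np.log(p)).sum())
    imbalance = float(p.max() - 1.0 / n_classes)

    numeric = features.select_dtypes(include=[np.number])
    frac_categorical = 1.0 - numeric.shape[1] / n_features

    if numeric.shape[1] > 0:
        numeric = numeric.apply(lambda c: c.fillna(c.median()))
        variances = numeric.var(axis=0, ddof=1).to_numpy(dtype=float)
        variances = np.nan_to_num(variances, nan=0.0)
        y_codes = pd.factorize(y, sort=True)[0].astype(float)
        corrs = []
        for col in numeric.columns:
            x = numeric[col].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y_codes) == 0:
                corrs.append(0.0)
            else:
                corrs.append(abs(float(np.corrcoef(x, y_codes)[0, 1])))
        mean_abs_corr = float(np.mean(corrs))
    else:
        variances = np.array([0.0])
        mean_abs_corr = 0.0

    values = np.array(
        [
            n_samples,
            n_features,
            n_classes,
            np.log(n_samples),
            np.log(n_features),
            class_entropy,
            imbalance,
            frac_categorical,
            variances.mean(),
            np.median(variances),
            variances.var(ddof=0),
            mean_abs_corr,
        ]
    )
    return MetafeatureVector(dataset_id, METAFEATURE_NAMES, values)


def metafeature_distance(
    a: MetafeatureVector, b: MetafeatureVector, scaling: np.ndarray | None = None
) -> float:
    """Euclidean distance between two metafeature vectors on scaled axes.

    ``scaling`` gives a per-dimension divisor (e.g. an IQR from
    :func:`robust_scaling`); zero or missing scales fall back to 1 so
    constant dimensions never produce NaN.  Symmetric, and zero iff the
    scaled vectors are equal.
    """
    if a.names != b.names:
        raise ValueError("metafeature vectors have mismatched names")
    diff = a.values - b.values
    if scaling is not None:
        scaling = np.asarray(scaling, dtype=float)
        if scaling.shape != diff.shape:
            raise ValueError("scaling length must match metafeature length")
        safe = np.where(scaling > 0, scaling, 1.0)
        diff = diff / safe
    return float(np.sqrt(np.sum(diff**2)))


def robust_scaling(cache: pd.DataFrame) -> np.ndarray:
    """Per-dimension IQR over a metafeature cache (rows = datasets).

    Count-type metafeatures span orders of magnitude, so distances are
    taken on IQR-scaled axes.  Dimensions with zero IQR get scale 1.
    """
    q75 = cache.quantile(0.75)
    q25 = cache.quantile(0.25)
    iqr = (q75 - q25).to_numpy(dtype=float)
    return np.where(iqr > 0, iqr, 1.0)


def save_cache(vectors: list[MetafeatureVector], path) -> None:
    """Write a metafeature cache: one row per dataset, columns = names."""
    df = pd.DataFrame(
        [v.values for v in vectors],
        index=pd.Index([v.dataset_id for v in vectors], name="dataset"),
        columns=list(vectors[0].names),
    )
    df.to_csv(path)


def load_cache(path) -> pd.DataFrame:
    """Read a metafeature cache written by :func:`save_cache`.

    Any numeric column set is accepted, so users may replace the default
    metafeature set with their own.
    """
    return pd.read_csv(path, index_col="dataset")


def cache_to_vectors(cache: pd.DataFrame) -> dict[str, MetafeatureVector]:
    names = tuple(cache.columns)
    return {
        str(idx): MetafeatureVector(str(idx), names, row.to_numpy(dtype=float))
        for idx, row in cache.iterrows()
    }
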