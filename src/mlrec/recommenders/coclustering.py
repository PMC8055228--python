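"""Co-clustering collaborative filter.

Datasets and configurations are partitioned into a small number of
clusters; a rating is predicted as

    r̂ = cocluster_mean + (dataset_mean − dataset_cluster_mean)
       + (config_mean − config_cluster_mean)

Clustering is a deterministic k-means on row/column profiles of the
rating matrix (missing cells filled with the global mean): centroids are
initialized farthest-first from the largest-norm profile, then refined by
Lloyd iterations, followed by a few alternating reassignment passes that
move rows/columns to the cluster minimizing their observed squared
prediction error.  The procedure is exact on block-constant matrices with
matching cluster counts, and fully reproducible — no randomness is
involved, so identical knowledge bases always yield identical fits.
"""

from __future__ import annotations

import numpy as np

from ..knowledge_base import CV
from .base import RatingEstimate
from .baselines import MeanRecommender


def farthest_first_kmeans(
    points: np.ndarray, n_clusters: int, n_iter: int = 20
) -> np.ndarray:
    """Deterministic k-means labels for ``points`` (rows = items).

    Initialization: first centroid is the largest-norm point (lowest index
    on ties); each next centroid is the point farthest from all chosen so
    far.  Then standard Lloyd iterations.
    """
    n = points.shape[0]
    n_clusters = min(n_clusters, n)
    norms = np.linalg.norm(points, axis=1)
    chosen = [int(np.argmax(norms))]
    dist = np.linalg.norm(points - points[chosen[0]], axis=1)
    for _ in range(1, n_clusters):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(points - points[nxt], axis=1))
    centroids = points[chosen].copy()
    labels = np.zeros(n, dtype=int)
    for _ in range(n_iter):
        d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
        for c in range(n_clusters):
            members = points[labels == c]
            if len(members):
                centroids[c] = members.mean(axis=0)
    return labels


class CoClusteringRecommender(MeanRecommender):
    name = "coclustering"

    def __init__(
        self,
        seed: int = 0,
        n_dataset_clusters: int = 3,
        n_config_clusters: int = 3,
        n_refine: int = 5,
    ):
        super().__init__(seed=seed)
        self.n_dataset_clusters = int(n_dataset_clusters)
        self.n_config_clusters = int(n_config_clusters)
        self.n_refine = int(n_refine)
        self._fitted = False

    def _refit(self, new_results) -> None:
        super()._refit(new_results)
        mat, dataset_ids, config_ids = self.kb.ratings_matrix(CV)
        self._drow = {d: i for i, d in enumerate(dataset_ids)}
        self._ccol = {c: j for j, c in enumerate(config_ids)}
        self.fit_matrix(mat)

    def fit_matrix(self, mat: np.ndarray) -> None:
        """Fit cluster assignments and all mean tables for one matrix."""
        observed = ~np.isnan(mat)
        if not observed.any():
            self._fitted = False
            return
        self._mat = mat
        self._observed = observed
        self._global_mean_rating = float(np.nanmean(mat))
        filled = np.where(observed, mat, self._global_mean_rating)
        self._row_labels = farthest_first_kmeans(filled, self.n_dataset_clusters)
        self._col_labels = farthest_first_kmeans(filled.T, self.n_config_clusters)
        for _ in range(self.n_refine):
            means = self._compute_means()
            new_rows = self._reassign(axis=0, means=means)
            new_cols = self._reassign(axis=1, means=means)
            if np.array_equal(new_rows, self._row_labels) and np.array_equal(
                new_cols, self._col_labels
            ):
                break
            self._row_labels, self._col_labels = new_rows, new_cols
        self._means = self._compute_means()
        self._fitted = True

    # -- mean tables -------------------------------------------------------

    def _compute_means(self) -> dict:
        mat, obs = self._mat, self._observed
        g = self._global_mean_rating
        with np.errstate(invalid="ignore"):
            row_means = np.where(
                obs.sum(axis=1) > 0, np.nansum(mat, axis=1) / obs.sum(axis=1), g
            )
            col_means = np.where(
                obs.sum(axis=0) > 0, np.nansum(mat, axis=0) / obs.sum(axis=0), g
            )
        nr, nc = self.n_dataset_clusters, self.n_config_clusters
        co = np.full((nr, nc), g)
        rc = np.full(nr, g)
        cc = np.full(nc, g)
        for a in range(nr):
            sel = self._row_labels == a
            if obs[sel].sum():
                rc[a] = np.nansum(mat[sel]) / obs[sel].sum()
            for b in range(nc):
                cells = mat[np.ix_(sel, self._col_labels == b)]
                m = ~np.isnan(cells)
                if m.sum():
                    co[a, b] = np.nansum(cells) / m.sum()
        for b in range(nc):
            sel = self._col_labels == b
            if obs[:, sel].sum():
                cc[b] = np.nansum(mat[:, sel]) / obs[:, sel].sum()
        return {
            "row": row_means, "col": col_means,
            "co": co, "row_cluster": rc, "col_cluster": cc,
        }

    def _predict_matrix(self, means: dict, row_labels, col_labels) -> np.ndarray:
        co = means["co"][np.ix_(row_labels, col_labels)]
        row_dev = means["row"][:, None] - means["row_cluster"][row_labels][:, None]
        col_dev = means["col"][None, :] - means["col_cluster"][col_labels][None, :]
        return co + row_dev + col_dev

    def _reassign(self, axis: int, means: dict) -> np.ndarray:
        """Move each row (axis=0) or column (axis=1) to the cluster that
        minimizes its observed squared prediction error."""
        n_clusters = self.n_dataset_clusters if axis == 0 else self.n_config_clusters
        n = self._mat.shape[axis]
        labels = (self._row_labels if axis == 0 else self._col_labels).copy()
        errs = np.zeros((n, n_clusters))
        for c in range(n_clusters):
            trial = np.full(n, c)
            if axis == 0:
                pred = self._predict_matrix(means, trial, self._col_labels)
            else:
                pred = self._predict_matrix(means, self._row_labels, trial)
            sq = np.where(self._observed, (self._mat - pred) ** 2, 0.0)
            errs[:, c] = sq.sum(axis=1 - axis)
        new = np.argmin(errs, axis=1)
        counted = self._observed.sum(axis=1 - axis) > 0
        return np.where(counted, new, labels)

    # -- prediction --------------------------------------------------------

    def _predict(self, dataset_id: str, config_id: str) -> RatingEstimate:
        if not self._fitted:
            raise RuntimeError("co-clustering model is not fitted")
        d = getattr(self, "_drow", {}).get(dataset_id)
        c = getattr(self, "_ccol", {}).get(config_id)
        if d is None and c is None:
            return RatingEstimate(self._global_mean_rating, fallback=True)
        m = self._means
        if d is None:
            return RatingEstimate(float(m["col"][c]), fallback=True)
        if c is None:
            return RatingEstimate(float(m["row"][d]), fallback=True)
        r_hat = (
            m["co"][self._row_labels[d], self._col_labels[c]]
            + (m["row"][d] - m["row_cluster"][self._row_labels[d]])
            + (m["col"][c] - m["col_cluster"][self._col_labels[c]])
        )
        return RatingEstimate(float(r_hat))

    def training_error(self) -> float:
        """RMSE of the fitted model over observed cells."""
        if not self._fitted:
            raise RuntimeError("co-clustering model is not fitted")
        pred = self._predict_matrix(self._means, self._row_labels, self._col_labels)
        sq = (self._mat - pred)[self._observed] ** 2
        return float(np.sqrt(sq.mean()))
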