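"""Neighborhood collaborative filters and the metalearning cold-start one.

* KNN-data: user-based — similar *datasets* (over co-rated configs) vote
  on a configuration, mean-centered per dataset and re-centered.
* KNN-ML: item-based transpose — similar *configurations* (over
  co-rating datasets) vote.
* KNN-meta: metalearning — the metafeature-nearest rated datasets lend
  their best configurations; no ratings of the target dataset needed, so
  it works from a cold start.

Similarity for the first two is shrunk Pearson over co-rated cells:
``sim = pearson * n_common / (n_common + shrinkage)``; pairs with fewer
than two co-rated cells or zero variance get similarity 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..knowledge_base import CV
from ..metafeatures import MetafeatureVector, metafeature_distance, robust_scaling
from .base import Recommender, RatingEstimate
from .baselines import MeanRecommender


def shrunk_pearson(
    x: np.ndarray, y: np.ndarray, shrinkage: float = 10.0, min_support: int = 1
) -> float:
    """Pearson correlation over cells observed in both vectors, shrunk
    toward 0 by ``n/(n+shrinkage)``.  NaN marks missing cells."""
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < max(min_support, 2):
        return 0.0
    xs, ys = x[mask], y[mask]
    sx, sy = xs.std(), ys.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    rho = float(np.corrcoef(xs, ys)[0, 1])
    return rho * n / (n + shrinkage)


class _KNNBase(MeanRecommender):
    """Shared machinery: dense rating matrix + row/column means."""

    def __init__(
        self,
        seed: int = 0,
        k_neighbors: int = 10,
        shrinkage: float = 10.0,
        min_support: int = 1,
    ):
        super().__init__(seed=seed)
        self.k_neighbors = int(k_neighbors)
        self.shrinkage = float(shrinkage)
        self.min_support = int(min_support)
        self._mat = np.zeros((0, 0))
        self._dataset_ids: list[str] = []
        self._config_ids: list[str] = []
        self._drow: dict[str, int] = {}
        self._ccol: dict[str, int] = {}

    def _refit(self, new_results) -> None:
        super()._refit(new_results)
        self._mat, self._dataset_ids, self._config_ids = self.kb.ratings_matrix(CV)
        self._drow = {d: i for i, d in enumerate(self._dataset_ids)}
        self._ccol = {c: j for j, c in enumerate(self._config_ids)}

    def _sim(self, a: np.ndarray, b: np.ndarray) -> float:
        return shrunk_pearson(a, b, self.shrinkage, self.min_support)

    def _mean_fallback(self, dataset_id: str, config_id: str) -> RatingEstimate:
        est = MeanRecommender._predict(self, dataset_id, config_id)
        return RatingEstimate(est.r_hat, fallback=True)


class KNNDataRecommender(_KNNBase):
    """User-based KNN: datasets that rate configurations alike vote.

    r̂_dj = mean_d + Σ_v sim(d,v) (r_vj − mean_v) / Σ_v |sim(d,v)| over
    the k most similar datasets v that have rated configuration j; means
    are each dataset's own mean rating.
    """

    name = "knn-data"

    def _predict(self, dataset_id: str, config_id: str) -> RatingEstimate:
        i = self._drow.get(dataset_id)
        j = self._ccol.get(config_id)
        if i is None or j is None:
            return self._mean_fallback(dataset_id, config_id)
        row = self._mat[i]
        if np.all(np.isnan(row)):
            return self._mean_fallback(dataset_id, config_id)
        raters = [
            v for v in range(self._mat.shape[0])
            if v != i and not np.isnan(self._mat[v, j])
        ]
        sims = [(self._sim(row, self._mat[v]), v) for v in raters]
        sims = [(s, v) for s, v in sims if s != 0.0]
        sims.sort(key=lambda t: (-t[0], t[1]))
        sims = sims[: self.k_neighbors]
        denom = sum(abs(s) for s, _ in sims)
        if denom == 0.0:
            return self._mean_fallback(dataset_id, config_id)
        own_mean = float(np.nanmean(row))
        num = sum(
            s * (self._mat[v, j] - float(np.nanmean(self._mat[v])))
            for s, v in sims
        )
        return RatingEstimate(own_mean + num / denom)


class KNNMLRecommender(_KNNBase):
    """Item-based KNN: configurations rated alike across datasets vote.

    The exact transpose of :class:`KNNDataRecommender`: neighbors are
    configurations the target dataset has rated, similarity is taken over
    co-rating datasets, and centering uses per-configuration means.
    """

    name = "knn-ml"

    def _predict(self, dataset_id: str, config_id: str) -> RatingEstimate:
        i = self._drow.get(dataset_id)
        j = self._ccol.get(config_id)
        if i is None or j is None:
            return self._mean_fallback(dataset_id, config_id)
        col = self._mat[:, j]
        rated = [
            c for c in range(self._mat.shape[1])
            if c != j and not np.isnan(self._mat[i, c])
        ]
        sims = [(self._sim(col, self._mat[:, c]), c) for c in rated]
        sims = [(s, c) for s, c in sims if s != 0.0]
        sims.sort(key=lambda t: (-t[0], t[1]))
        sims = sims[: self.k_neighbors]
        denom = sum(abs(s) for s, _ in sims)
        if denom == 0.0:
            return self._mean_fallback(dataset_id, config_id)
        own_mean = float(np.nanmean(col)) if not np.all(np.isnan(col)) else float(
            np.nanmean(self._mat)
        )
        num = sum(
            s * (self._mat[i, c] - float(np.nanmean(self._mat[:, c])))
            for s, c in sims
        )
        return RatingEstimate(own_mean + num / denom)


class KNNMetaRecommender(Recommender):
    """Metalearning cold-start strategy.

    Given a metafeature cache (rows = datasets), it finds the k datasets
    nearest to the target in robust-scaled metafeature space among those
    with ratings, and recommends their best-scoring configurations,
    deduplicated and best-first.  Because it keys on dataset descriptors
    rather than the target's own ratings, it can recommend for a dataset
    the knowledge base has never seen.
    """

    name = "knn-meta"

    def __init__(
        self,
        seed: int = 0,
        metafeature_cache: pd.DataFrame | None = None,
        k_neighbors: int = 10,
    ):
        super().__init__(seed=seed)
        if metafeature_cache is None:
            metafeature_cache = pd.DataFrame()
        self.metafeature_cache = metafeature_cache
        self.k_neighbors = int(k_neighbors)

    def _vector(self, dataset_id: str) -> MetafeatureVector:
        if dataset_id not in self.metafeature_cache.index:
            raise KeyError(
                f"no metafeatures cached for dataset {dataset_id!r}; run "
                "compute_metafeatures on its table first"
            )
        row = self.metafeature_cache.loc[dataset_id]
        return MetafeatureVector(
            dataset_id,
            tuple(self.metafeature_cache.columns),
            row.to_numpy(dtype=float),
        )

    def neighbor_ids(self, dataset_id: str) -> list[str]:
        """The k metafeature-nearest datasets that have cv ratings."""
        target = self._vector(dataset_id)
        rated = [d for d in self.kb.datasets if d != dataset_id]
        rated = [d for d in rated if d in self.metafeature_cache.index]
        if not rated:
            raise RuntimeError("no rated dataset has cached metafeatures")
        scale = robust_scaling(self.metafeature_cache)
        dists = [
            (metafeature_distance(target, self._vector(d), scale), d) for d in rated
        ]
        dists.sort(key=lambda t: (t[0], t[1]))
        return [d for _, d in dists[: self.k_neighbors]]

    def _predict(self, dataset_id: str, config_id: str) -> RatingEstimate:
        # best rating any metafeature-neighbor gave this config
        best = None
        for d in self.neighbor_ids(dataset_id):
            r = self.kb.rating(d, config_id, CV)
            if r is not None and (best is None or r > best):
                best = r
        if best is None:
            ratings = [r.rating for r in self.kb.results(CV)]
            return RatingEstimate(float(np.mean(ratings)), fallback=True)
        return RatingEstimate(best)

    def _rank(self, dataset_id: str, candidates: list[str]) -> list[tuple[str, float]]:
        """Neighbors' rated configs, best rating first, restricted to the
        candidate set.  Configurations no neighbor has rated are not
        recommended by this strategy."""
        allowed = set(candidates)
        pool: dict[str, float] = {}
        for d in self.neighbor_ids(dataset_id):
            for cid in self.kb.rated_configs(d, CV):
                if cid not in allowed:
                    continue
                r = self.kb.rating(d, cid, CV)
                if cid not in pool or r > pool[cid]:
                    pool[cid] = r
        scored = [(cid, float(np.clip(r, 0.0, 1.0))) for cid, r in pool.items()]
        scored.sort(key=lambda t: (-t[1], t[0]))
        return scored
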