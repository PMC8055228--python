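"""Recommender strategies for algorithm-configuration selection.

Strategy names accepted everywhere: ``svd``, ``knn-data``, ``knn-ml``,
``knn-meta``, ``slopeone``, ``coclustering``, ``mean``, ``random``.
"""

from __future__ import annotations

from typing import Iterable

from ..knowledge_base import CV, KnowledgeBase
from .base import RatingEstimate, Recommendation, Recommender
from .baselines import MeanRecommender, RandomRecommender
from .coclustering import CoClusteringRecommender, farthest_first_kmeans
from .neighbors import (
    KNNDataRecommender,
    KNNMetaRecommender,
    KNNMLRecommender,
    shrunk_pearson,
)
from .slopeone import SlopeOneRecommender
from .svd import SVDRecommender

STRATEGIES: dict[str, type[Recommender]] = {
    "svd": SVDRecommender,
    "knn-data": KNNDataRecommender,
    "knn-ml": KNNMLRecommender,
    "knn-meta": KNNMetaRecommender,
    "slopeone": SlopeOneRecommender,
    "coclustering": CoClusteringRecommender,
    "mean": MeanRecommender,
    "random": RandomRecommender,
}


def make_recommender(strategy: str, seed: int = 0, **hyper) -> Recommender:
    """Instantiate a strategy by name with hyperparameter overrides."""
    try:
        cls = STRATEGIES[strategy]
    except KeyError:
        raise ValueError(
            f"unknown strategy {strategy!r}; choose from {sorted(STRATEGIES)}"
        ) from None
    return cls(seed=seed, **hyper)


def fit_from_kb(rec: Recommender, kb: KnowledgeBase) -> Recommender:
    """Train a fresh recommender on all cv results of a knowledge base."""
    rec.register_configs(kb.configs.values())
    cv_results = kb.results(CV)
    if cv_results:
        rec.update(cv_results)
    return rec


def recommend(
    strategy: Recommender | str,
    kb: KnowledgeBase,
    dataset_id: str,
    n: int,
    exclude: Iterable[str] = (),
    seed: int = 0,
    **hyper,
) -> list[Recommendation]:
    """One-shot functional surface: train on kb's cv ratings, recommend.

    ``strategy`` may be a name or an already-constructed recommender (in
    which case the kb is only used to register candidate configurations).
    """
    if isinstance(strategy, str):
        rec = make_recommender(strategy, seed=seed, **hyper)
        fit_from_kb(rec, kb)
    else:
        rec = strategy
        rec.register_configs(kb.configs.values())
    return rec.recommend(dataset_id, n, exclude=exclude)


__all__ = [
    "STRATEGIES",
    "Recommender",
    "Recommendation",
    "RatingEstimate",
    "SVDRecommender",
    "KNNDataRecommender",
    "KNNMLRecommender",
    "KNNMetaRecommender",
    "SlopeOneRecommender",
    "CoClusteringRecommender",
    "MeanRecommender",
    "RandomRecommender",
    "make_recommender",
    "fit_from_kb",
    "recommend",
    "shrunk_pearson",
    "farthest_first_kmeans",
]
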