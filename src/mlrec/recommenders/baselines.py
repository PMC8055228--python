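"""Control strategies: per-configuration mean and uniform random."""

from __future__ import annotations

import numpy as np

from ..knowledge_base import CV
from .base import Recommender, RatingEstimate


class MeanRecommender(Recommender):
    """Predicts each configuration's mean rating across all datasets.

    A configuration that has never been rated falls back to the global
    mean.  This is the natural popularity baseline: it ignores which
    dataset is asking.
    """

    name = "mean"

    def __init__(self, seed: int = 0):
        super().__init__(seed=seed)
        self._config_means: dict[str, float] = {}
        self._global_mean: float | None = None

    def _refit(self, new_results) -> None:
        sums: dict[str, list[float]] = {}
        for r in self.kb.results(CV):
            sums.setdefault(r.config.config_id, []).append(r.rating)
        if sums:
            self._config_means = {c: float(np.mean(v)) for c, v in sums.items()}
            self._global_mean = float(
                np.mean([r.rating for r in self.kb.results(CV)])
            )

    def _predict(self, dataset_id: str, config_id: str) -> RatingEstimate:
        if self._global_mean is None:
            raise RuntimeError("mean recommender has seen no cv ratings yet")
        return RatingEstimate(
            self._config_means.get(config_id, self._global_mean)
        )


class RandomRecommender(Recommender):
    """Uniform sample without replacement from the candidate set (seeded)."""

    name = "random"

    def __init__(self, seed: int = 0):
        super().__init__(seed=seed)
        self._rng = np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(1)[0]
        )

    def update(self, new_results):
        # random needs no model; still validate and store like the others
        super().update(new_results)

    def _predict(self, dataset_id: str, config_id: str) -> RatingEstimate:
        ratings = [r.rating for r in self.kb.results(CV)]
        prior = float(np.mean(ratings)) if ratings else 0.5
        return RatingEstimate(prior)

    def _rank(self, dataset_id, candidates):
        prior = self._predict(dataset_id, "").r_hat if len(self.kb) else 0.5
        prior = float(np.clip(prior, 0.0, 1.0))
        order = self._rng.permutation(len(candidates))
        return [(candidates[i], prior) for i in order]
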