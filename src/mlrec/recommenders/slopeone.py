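"""Slope-one collaborative filter.

For every pair of configurations (i, j) the model stores the average
rating deviation dev(i, j) = mean_d(r_di − r_dj) over datasets that rated
both.  A prediction for configuration i on dataset d averages the
deviation-adjusted ratings r_dj + dev(i, j) over all configurations j the
dataset has rated that were co-rated with i.
"""

from __future__ import annotations

import numpy as np

from ..knowledge_base import CV
from .base import RatingEstimate
from .baselines import MeanRecommender


class SlopeOneRecommender(MeanRecommender):
    name = "slopeone"

    def __init__(self, seed: int = 0):
        super().__init__(seed=seed)
        self._mat = np.zeros((0, 0))
        self._ccol: dict[str, int] = {}
        self._drow: dict[str, int] = {}
        self._dev = np.zeros((0, 0))
        self._support = np.zeros((0, 0), dtype=int)

    def _refit(self, new_results) -> None:
        super()._refit(new_results)
        mat, dataset_ids, config_ids = self.kb.ratings_matrix(CV)
        self._mat = mat
        self._drow = {d: i for i, d in enumerate(dataset_ids)}
        self._ccol = {c: j for j, c in enumerate(config_ids)}
        n_cfg = mat.shape[1]
        observed = ~np.isnan(mat)
        filled = np.nan_to_num(mat)
        # pairwise co-rating counts and deviation sums, vectorized
        self._support = observed.T.astype(int) @ observed.astype(int)
        sums = filled.T @ observed.astype(float)
        # dev[i, j] = mean over co-raters of (r_i - r_j)
        with np.errstate(invalid="ignore", divide="ignore"):
            self._dev = np.where(
                self._support > 0, (sums - sums.T) / self._support, 0.0
            )
        assert self._dev.shape == (n_cfg, n_cfg)

    def _predict(self, dataset_id: str, config_id: str) -> RatingEstimate:
        d = self._drow.get(dataset_id)
        i = self._ccol.get(config_id)
        if d is None or i is None:
            return self._fallback(dataset_id, config_id)
        row = self._mat[d]
        rated = np.where(~np.isnan(row))[0]
        rated = rated[rated != i]
        usable = rated[self._support[i, rated] > 0]
        if usable.size == 0:
            return self._fallback(dataset_id, config_id)
        preds = row[usable] + self._dev[i, usable]
        return RatingEstimate(float(np.mean(preds)))

    def _fallback(self, dataset_id: str, config_id: str) -> RatingEstimate:
        est = MeanRecommender._predict(self, dataset_id, config_id)
        return RatingEstimate(est.r_hat, fallback=True)
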