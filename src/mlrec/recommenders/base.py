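"""Common recommender interface.

Every strategy follows the same loop: (1) ``update`` the internal model
whenever new experiment results arrive; (2) on request, estimate a rating
r̂ for every candidate (dataset, configuration) pair not yet recommended;
(3) return the top candidates in order of best predicted rating to worst.
A pair is never recommended twice within one recommender's lifetime.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from ..knowledge_base import (
    CV,
    AlgorithmConfig,
    ExperimentResult,
    KnowledgeBase,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RatingEstimate:
    """A predicted rating r̂, with the residual e = r − r̂ when r is known.

    ``fallback`` marks estimates produced by a degraded path (e.g. a
    neighborhood method that found no usable neighbor and fell back to a
    mean prediction).
    """

    r_hat: float
    error: float | None = None
    fallback: bool = False


@dataclass(frozen=True)
class Recommendation:
    dataset_id: str
    config: AlgorithmConfig
    predicted: RatingEstimate
    rank: int


class Recommender:
    """Base class: rating store, candidate bookkeeping, ranked output.

    Subclasses implement :meth:`_predict` (and may override :meth:`_rank`
    for strategies that do not score candidates one by one).  The base
    class owns the seen-ratings store (a cv-only :class:`KnowledgeBase`),
    the registry of known configurations, and the set of already
    recommended pairs.
    """

    name = "base"

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self.kb = KnowledgeBase()
        self._known_configs: dict[str, AlgorithmConfig] = {}
        self._recommended: set[tuple[str, str]] = set()
        self._n_seen = 0

    # -- configuration universe ------------------------------------------

    def register_configs(self, configs: Iterable[AlgorithmConfig]) -> None:
        """Declare configurations as recommendable (identity only, no scores)."""
        for cfg in configs:
            self._known_configs.setdefault(cfg.config_id, cfg)

    @property
    def known_configs(self) -> dict[str, AlgorithmConfig]:
        merged = dict(self._known_configs)
        merged.update(self.kb.configs)
        return merged

    # -- learning ---------------------------------------------------------

    def update(self, new_results: Sequence[ExperimentResult]) -> None:
        """Absorb new experiment results and refresh the internal model."""
        new_results = list(new_results)
        if not new_results:
            raise ValueError("update requires at least one new result")
        for r in new_results:  # validates before any mutation
            if not 0.0 <= r.rating <= 1.0:
                raise ValueError(f"rating {r.rating} outside [0, 1]")
        self.kb.add_many(new_results)
        self._n_seen += len(new_results)
        self._refit(new_results)

    def _refit(self, new_results: Sequence[ExperimentResult]) -> None:
        """Hook: strategies that keep derived state refresh it here."""

    # -- prediction & ranking ---------------------------------------------

    def predict(self, dataset_id: str, config_id: str) -> RatingEstimate:
        """Raw rating estimate (not clamped; clamping happens at ranking)."""
        if len(self.kb) == 0:
            raise RuntimeError(f"{self.name} recommender has seen no ratings yet")
        est = self._predict(dataset_id, config_id)
        known = self.kb.rating(dataset_id, config_id, CV)
        if known is not None:
            est = RatingEstimate(est.r_hat, known - est.r_hat, est.fallback)
        return est

    def _predict(self, dataset_id: str, config_id: str) -> RatingEstimate:
        raise NotImplementedError

    def candidate_ids(self, dataset_id: str, exclude: Iterable[str] = ()) -> list[str]:
        """All known configs minus exclusions, already-rated and
        already-recommended ones, in sorted order."""
        out = set(self.known_configs)
        out -= set(exclude)
        out -= self.kb.rated_configs(dataset_id, CV)
        out -= {c for (d, c) in self._recommended if d == dataset_id}
        return sorted(out)

    def _rank(self, dataset_id: str, candidates: list[str]) -> list[tuple[str, float]]:
        """Return (config_id, clamped r̂) best-first.

        Default: score every candidate with :meth:`predict`, clamp to
        [0, 1], sort by descending r̂ with lexicographic config_id
        tie-break for cross-platform reproducibility.
        """
        scored = []
        for cid in candidates:
            r_hat = float(np.clip(self.predict(dataset_id, cid).r_hat, 0.0, 1.0))
            scored.append((cid, r_hat))
        scored.sort(key=lambda t: (-t[1], t[0]))
        return scored

    def recommend(
        self, dataset_id: str, n: int, exclude: Iterable[str] = ()
    ) -> list[Recommendation]:
        """Top-``n`` configurations for a dataset, best predicted first."""
        if n < 1:
            raise ValueError("n must be >= 1")
        candidates = self.candidate_ids(dataset_id, exclude)
        if not candidates:
            warnings.warn(
                f"no candidate configurations left for dataset {dataset_id!r}",
                stacklevel=2,
            )
            return []
        ranked = self._rank(dataset_id, candidates)[:n]
        if len(ranked) < n:
            warnings.warn(
                f"only {len(ranked)} candidate(s) left for dataset "
                f"{dataset_id!r} (requested {n})",
                stacklevel=2,
            )
        recs = []
        configs = self.known_configs
        for rank, (cid, r_hat) in enumerate(ranked, start=1):
            self._recommended.add((dataset_id, cid))
            recs.append(
                Recommendation(
                    dataset_id=dataset_id,
                    config=configs[cid],
                    predicted=RatingEstimate(r_hat),
                    rank=rank,
                )
            )
        return recs
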