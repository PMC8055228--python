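"""Knowledge base of machine-learning experiment results.

The engine treats datasets as "users" and algorithm configurations as
"items": every cross-validated score of a configuration on a dataset is a
rating in [0, 1].  The knowledge base D is the deduplicated collection of
these ratings, kept separately per split tag ("cv" scores drive learning,
"holdout" scores are reserved for assessment).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: split tag for cross-validation ratings (fed to recommenders)
CV = "cv"
#: split tag for held-out test ratings (assessment only)
HOLDOUT = "holdout"

_SCALAR_TYPES = (int, float, str, bool, type(None))

REQUIRED_COLUMNS = ("dataset", "algorithm", "parameters", "score")
ALL_COLUMNS = ("dataset", "algorithm", "parameters", "metric", "score", "split")


class FormatError(ValueError):
    """Raised when a results file does not match the expected schema."""


def canonical_config_id(algorithm: str, params: Mapping[str, object]) -> str:
    """Build a canonical identifier for an algorithm configuration.

    The identifier is a pure function of the content of ``(algorithm,
    params)``: parameter keys are sorted lexicographically, so insertion
    order never matters.  Values must be scalars (numbers, strings,
    booleans, None).

    Examples
    --------
    >>> canonical_config_id("rf", {"b": 2, "a": 1})
    'rf|a=1,b=2'
    """
    if not algorithm:
        raise ValueError("algorithm name must be nonempty")
    parts = []
    for key in sorted(params):
        value = params[key]
        if not isinstance(value, _SCALAR_TYPES):
            raise TypeError(f"parameter {key!r} has non-scalar value {value!r}")
        parts.append(f"{key}={json.dumps(value)}")
    return f"{algorithm}|{','.join(parts)}"


@dataclass(frozen=True)
class AlgorithmConfig:
    """A learning algorithm plus one concrete hyperparameter setting."""

    algorithm: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        # freeze params so the config is hashable by id
        object.__setattr__(self, "params", dict(self.params))

    @property
    def config_id(self) -> str:
        return canonical_config_id(self.algorithm, self.params)

    def __hash__(self):
        return hash(self.config_id)

    def __eq__(self, other):
        if not isinstance(other, AlgorithmConfig):
            return NotImplemented
        return self.config_id == other.config_id


@dataclass(frozen=True)
class ExperimentResult:
    """One scored run: configuration ``config`` on dataset ``dataset_id``.

    ``rating`` is the score in [0, 1] (balanced accuracy in the intended
    use).  ``split_tag`` marks whether the rating is a cross-validation
    score ("cv") or a held-out test score ("holdout").
    """

    dataset_id: str
    config: AlgorithmConfig
    rating: float
    metric_name: str = "balanced_accuracy"
    split_tag: str = CV

    def __post_init__(self):
        if not 0.0 <= self.rating <= 1.0:
            raise ValueError(
                f"rating {self.rating} outside [0, 1] for "
                f"({self.dataset_id}, {self.config.config_id})"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        """Deduplication key ``(dataset_id, config_id, split_tag)``."""
        return (self.dataset_id, self.config.config_id, self.split_tag)


@dataclass
class LoadReport:
    n_rows: int = 0
    n_loaded: int = 0
    n_replaced: int = 0
    n_rejected: int = 0
    rejected: list = field(default_factory=list)  # (row index, reason)


class KnowledgeBase:
    """Deduplicated store of :class:`ExperimentResult`.

    One rating per ``(dataset_id, config_id, split_tag)`` key; re-adding a
    key replaces the previous rating (latest wins) and is logged.
    """

    def __init__(self, results: Iterable[ExperimentResult] = ()):
        self._results: dict[tuple[str, str, str], ExperimentResult] = {}
        self._configs: dict[str, AlgorithmConfig] = {}
        self.load_report: LoadReport | None = None
        self.add_many(results)

    # -- mutation ---------------------------------------------------------

    def add(self, result: ExperimentResult) -> bool:
        """Add one result. Returns True if an existing key was replaced."""
        replaced = result.key in self._results
        if replaced:
            old = self._results[result.key].rating
            logger.info(
                "replacing rating for %s: %.6g -> %.6g", result.key, old, result.rating
            )
        self._results[result.key] = result
        self._configs[result.config.config_id] = result.config
        return replaced

    def add_many(self, results: Iterable[ExperimentResult]) -> int:
        return sum(self.add(r) for r in results)

    # -- views ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self._results)

    def __iter__(self) -> Iterator[ExperimentResult]:
        return iter(self._results.values())

    @property
    def datasets(self) -> list[str]:
        """Sorted ids of all datasets with at least one result."""
        return sorted({r.dataset_id for r in self._results.values()})

    @property
    def configs(self) -> dict[str, AlgorithmConfig]:
        """Mapping config_id -> AlgorithmConfig over all stored results."""
        return dict(self._configs)

    def results(self, split_tag: str | None = None) -> list[ExperimentResult]:
        if split_tag is None:
            return list(self._results.values())
        return [r for r in self._results.values() if r.split_tag == split_tag]

    def rating(self, dataset_id: str, config_id: str, split_tag: str) -> float | None:
        res = self._results.get((dataset_id, config_id, split_tag))
        return None if res is None else res.rating

    def rated_configs(self, dataset_id: str, split_tag: str = CV) -> set[str]:
        return {
            cid
            for (did, cid, tag) in self._results
            if did == dataset_id and tag == split_tag
        }

    def best_score(self, dataset_id: str, split_tag: str) -> float:
        """Maximum rating over all stored configs for a dataset and split."""
        ratings = [
            r.rating
            for r in self._results.values()
            if r.dataset_id == dataset_id and r.split_tag == split_tag
        ]
        if not ratings:
            raise KeyError(
                f"no results for dataset {dataset_id!r} with split {split_tag!r}"
            )
        return max(ratings)

    def best_scores(self, split_tag: str = HOLDOUT) -> dict[str, float]:
        """Per-dataset best rating for one split tag."""
        best: dict[str, float] = {}
        for r in self._results.values():
            if r.split_tag != split_tag:
                continue
            cur = best.get(r.dataset_id)
            if cur is None or r.rating > cur:
                best[r.dataset_id] = r.rating
        return best

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame, one row per stored result."""
        rows = [
            {
                "dataset": r.dataset_id,
                "algorithm": r.config.algorithm,
                "parameters": json.dumps(r.config.params, sort_keys=True),
                "metric": r.metric_name,
                "score": r.rating,
                "split": r.split_tag,
            }
            for r in self._results.values()
        ]
        return pd.DataFrame(rows, columns=list(ALL_COLUMNS))

    def ratings_matrix(
        self, split_tag: str = CV
    ) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense datasets x configs matrix with NaN for missing cells."""
        dataset_ids = self.datasets
        config_ids = sorted(self._configs)
        drow = {d: i for i, d in enumerate(dataset_ids)}
        ccol = {c: j for j, c in enumerate(config_ids)}
        mat = np.full((len(dataset_ids), len(config_ids)), np.nan)
        for r in self._results.values():
            if r.split_tag == split_tag:
                mat[drow[r.dataset_id], ccol[r.config.config_id]] = r.rating
        return mat, dataset_ids, config_ids

    # -- persistence ------------------------------------------------------

    def save(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def load_results(path, sep: str | None = None) -> KnowledgeBase:
    """Load a delimited results file into a :class:`KnowledgeBase`.

    Required columns: ``dataset``, ``algorithm``, ``parameters`` (JSON
    object string), ``score``; optional ``metric`` and ``split``.  The
    delimiter is auto-detected unless ``sep`` is given.  Invalid rows
    (score outside [0, 1], unparseable parameters) are rejected with a
    reason; duplicate keys replace earlier rows.  Counts live in the
    returned kb's ``load_report`` and are logged.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype={"dataset": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"results file {path} is missing required column(s): {', '.join(missing)}"
        )
    report = LoadReport(n_rows=len(df))
    kb = KnowledgeBase()
    for idx, row in df.iterrows():
        try:
            params_raw = row["parameters"]
            if isinstance(params_raw, str):
                params = json.loads(params_raw)
            elif params_raw is None or (
                isinstance(params_raw, float) and np.isnan(params_raw)
            ):
                params = {}
            else:
                raise ValueError(f"unparseable parameters payload {params_raw!r}")
            if not isinstance(params, dict):
                raise ValueError("parameters payload is not a JSON object")
            result = ExperimentResult(
                dataset_id=str(row["dataset"]),
                config=AlgorithmConfig(str(row["algorithm"]), params),
                rating=float(row["score"]),
                metric_name=str(row.get("metric", "balanced_accuracy")),
                split_tag=str(row.get("split", CV)),
            )
        except (ValueError, TypeError, json.JSONDecodeError) as exc:
            report.n_rejected += 1
            report.rejected.append((idx, str(exc)))
            logger.warning("rejected row %d: %s", idx, exc)
            continue
        if kb.add(result):
            report.n_replaced += 1
        report.n_loaded = len(kb)
    logger.info(
        "loaded %d results from %s (%d rows, %d replaced, %d rejected)",
        len(kb), path, report.n_rows, report.n_replaced, report.n_rejected,
    )
    kb.load_report = report
    return kb
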