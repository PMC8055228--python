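"""Simulation and metrics for judging recommender strategies.

The core experiment replays the deployment loop against a cached
knowledge base: a recommender is seeded with ``n_init`` cross-validation
results, then for many iterations proposes ``n_recs`` configurations for
a randomly chosen dataset and receives their cached cv scores as
feedback.  Quality is always measured on the *holdout* scores — which
the recommender never sees — as the relative regret

    ΔBA_ad = (BA*_d − BA_ad) / BA*_d

against the best holdout score BA*_d on that dataset, and as the success
rate: the fraction of datasets for which some recommended configuration
landed within a small relative threshold (1% and 5% by default) of BA*_d.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import sklearn.metrics

from .knowledge_base import CV, HOLDOUT, ExperimentResult, KnowledgeBase
from .recommenders import Recommender, make_recommender
from .recommenders.base import RatingEstimate

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.01, 0.05)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def balanced_accuracy(y_true, y_pred) -> float:
    """Balanced accuracy: the unweighted mean of per-class recall.

    Robust to class imbalance — a constant predictor scores 1/n_classes
    no matter how skewed the labels are.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    return float(sklearn.metrics.balanced_accuracy_score(y_true, y_pred))


def delta_ba(ba_best: float, ba: float) -> float:
    """Relative distance to the best known score: (BA* − BA) / BA*."""
    if ba_best <= 0:
        raise ValueError("delta_ba undefined for ba_best <= 0")
    return (ba_best - ba) / ba_best


def success_rate(
    best_scores: Mapping[str, float],
    kb_best: Mapping[str, float],
    threshold: float,
) -> float:
    """Fraction of datasets whose best recommended score is within a
    relative ``threshold`` of the best known score.

    ``best_scores`` maps dataset -> best holdout score among its
    recommendations so far; datasets in ``kb_best`` with no entry count
    as failures.  A dataset with recommendations but unknown optimum is
    an error.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    unknown = set(best_scores) - set(kb_best)
    if unknown:
        raise KeyError(f"dataset(s) missing from kb_best: {sorted(unknown)}")
    if not kb_best:
        return 0.0
    hits = sum(
        1
        for d, best in kb_best.items()
        if d in best_scores and delta_ba(best, best_scores[d]) <= threshold
    )
    return hits / len(kb_best)


# --------------------------------------------------------------------------
# experiment configuration and records
# --------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Settings of one Fig-2-style simulated deployment experiment."""

    strategy: str = "svd"
    n_init: int = 1
    n_recs: int = 10
    n_trials: int = 30
    n_iterations: int = 100
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    seed: int = 0
    dataset_sampling: str = "replacement"  # or "no_replacement"
    strategy_params: dict = field(default_factory=dict)
    n_bootstrap: int = 1000

    def __post_init__(self):
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if self.n_recs < 1:
            raise ValueError("n_recs must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        for t in self.thresholds:
            if not 0.0 < t < 1.0:
                raise ValueError(f"threshold {t} outside (0, 1)")
        if self.dataset_sampling not in ("replacement", "no_replacement"):
            raise ValueError(
                "dataset_sampling must be 'replacement' or 'no_replacement'"
            )

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"experiment config {path} is not a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown experiment config field(s): {sorted(unknown)}")
        if "thresholds" in doc:
            doc["thresholds"] = tuple(doc["thresholds"])
        return cls(**doc)


@dataclass
class Trajectory:
    """Per-recommendation log of one trial."""

    records: list[dict] = field(default_factory=list)
    skipped: list[tuple[int, str, str]] = field(default_factory=list)
    seed: int | None = None
    strategy: str | None = None

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "iteration",
            "dataset",
            "config",
            "cv_score",
            "holdout_score",
            "delta_ba",
            "best_so_far",
            "delta_ba_best",
        ]
        return pd.DataFrame(self.records, columns=cols)

    def best_scores(self) -> dict[str, float]:
        """Best recommended holdout score per dataset over the whole run."""
        best: dict[str, float] = {}
        for r in self.records:
            d, s = r["dataset"], r["holdout_score"]
            if d not in best or s > best[d]:
                best[d] = s
        return best

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ExperimentSummary:
    """Aggregate of many trials: regret curve + success-rate curves."""

    config: ExperimentConfig
    per_iteration: pd.DataFrame  # iteration, median_delta_ba, ci_lo, ci_hi, ...
    trajectories: pd.DataFrame   # tidy per-recommendation rows incl. trial

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.per_iteration.to_csv(out_dir / "summary.csv", index=False)
        tidy = self.trajectories[
            ["trial", "iteration", "dataset", "config", "holdout_score", "delta_ba"]
        ]
        tidy.to_csv(out_dir / "trajectory.csv", index=False)


# --------------------------------------------------------------------------
# oracle (testing upper bound)
# --------------------------------------------------------------------------

class OracleRecommender(Recommender):
    """Cheating upper bound: ranks candidates by their *holdout* scores.

    Only for tests and ceiling analyses — it reads exactly the
    information real strategies are forbidden to see.
    """

    name = "oracle"

    def __init__(self, kb_full: KnowledgeBase, seed: int = 0):
        super().__init__(seed=seed)
        self._holdout = {
            (r.dataset_id, r.config.config_id): r.rating
            for r in kb_full.results(HOLDOUT)
        }

    def _predict(self, dataset_id: str, config_id: str) -> RatingEstimate:
        return RatingEstimate(self._holdout.get((dataset_id, config_id), 0.0))

    def _rank(self, dataset_id, candidates):
        scored = [
            (cid, float(np.clip(self._holdout.get((dataset_id, cid), 0.0), 0, 1)))
            for cid in candidates
        ]
        scored.sort(key=lambda t: (-t[1], t[0]))
        return scored


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def _build_recommender(
    config: ExperimentConfig,
    seed: int,
    kb_full: KnowledgeBase,
    metafeature_cache=None,
) -> Recommender:
    params = dict(config.strategy_params)
    if config.strategy == "oracle":
        return OracleRecommender(kb_full, seed=seed)
    if config.strategy == "knn-meta" and metafeature_cache is not None:
        params.setdefault("metafeature_cache", metafeature_cache)
    return make_recommender(config.strategy, seed=seed, **params)


def _derive_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_trial(
    config: ExperimentConfig,
    kb_full: KnowledgeBase,
    seed: int,
    metafeature_cache=None,
    recommender: Recommender | None = None,
) -> Trajectory:
    """One simulated deployment trial.

    The recommender is seeded with ``n_init`` uniformly sampled cv
    results; each iteration it recommends ``n_recs`` configurations for
    a randomly chosen dataset, the cached cv scores of which are fed
    back.  The trajectory logs the *holdout* scores of every
    recommendation — the recommender itself never receives a holdout
    rating.
    """
    ss = np.random.SeedSequence(seed)
    rec_ss, init_ss, pick_ss = ss.spawn(3)
    if recommender is None:
        recommender = _build_recommender(
            config, _derive_seed(rec_ss), kb_full, metafeature_cache
        )
    recommender.register_configs(kb_full.configs.values())

    cv_results = sorted(kb_full.results(CV), key=lambda r: r.key)
    if config.n_init > len(cv_results):
        raise ValueError(
            f"n_init={config.n_init} exceeds available cv results "
            f"({len(cv_results)})"
        )
    init_rng = np.random.default_rng(init_ss)
    idx = init_rng.choice(len(cv_results), size=config.n_init, replace=False)
    recommender.update([cv_results[i] for i in sorted(idx)])

    kb_best = kb_full.best_scores(HOLDOUT)
    datasets = kb_full.datasets
    pick_rng = np.random.default_rng(pick_ss)
    epoch_order: list[str] = []

    traj = Trajectory(seed=seed, strategy=config.strategy)
    best_so_far: dict[str, float] = {}
    for it in range(1, config.n_iterations + 1):
        if config.dataset_sampling == "replacement":
            dataset_id = datasets[pick_rng.integers(len(datasets))]
        else:
            if not epoch_order:
                epoch_order = [
                    datasets[i] for i in pick_rng.permutation(len(datasets))
                ]
            dataset_id = epoch_order.pop()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            recs = recommender.recommend(dataset_id, config.n_recs)
        feedback: list[ExperimentResult] = []
        for rec in recs:
            cid = rec.config.config_id
            cv_r = kb_full.rating(dataset_id, cid, CV)
            ho_r = kb_full.rating(dataset_id, cid, HOLDOUT)
            if cv_r is None or ho_r is None:
                traj.skipped.append((it, dataset_id, cid))
                logger.info(
                    "iteration %d: no cached rating for (%s, %s); skipped",
                    it, dataset_id, cid,
                )
                continue
            feedback.append(
                ExperimentResult(
                    dataset_id=dataset_id,
                    config=rec.config,
                    rating=cv_r,
                    split_tag=CV,
                )
            )
            cur_best = best_so_far.get(dataset_id)
            if cur_best is None or ho_r > cur_best:
                best_so_far[dataset_id] = ho_r
            traj.records.append(
                {
                    "iteration": it,
                    "dataset": dataset_id,
                    "config": cid,
                    "cv_score": cv_r,
                    "holdout_score": ho_r,
                    "delta_ba": delta_ba(kb_best[dataset_id], ho_r),
                    "best_so_far": best_so_far[dataset_id],
                    "delta_ba_best": delta_ba(
                        kb_best[dataset_id], best_so_far[dataset_id]
                    ),
                }
            )
        if feedback:
            recommender.update(feedback)
    return traj


def run_experiment(
    config: ExperimentConfig,
    kb_full: KnowledgeBase,
    metafeature_cache=None,
    recommender_factory=None,
) -> ExperimentSummary:
    """Repeat trials with independent derived seeds and aggregate.

    Per-iteration statistic: the median, over trials and datasets, of the
    relative regret ΔBA of the best configuration recommended so far for
    each dataset (datasets with no recommendation yet are excluded), with
    a bootstrap 95% confidence band from resampling trials.  This is the
    quantity a deployed assistant cares about — how far the best model it
    has handed the user is from the best known one — and it is identically
    zero for an oracle that always recommends the optimum first.
    Success-rate curves track, per threshold, the mean over trials of the
    fraction of all datasets whose best-so-far recommendation is within
    the threshold of the dataset's optimum.
    """
    ss = np.random.SeedSequence(config.seed)
    trial_seeds = [_derive_seed(child) for child in ss.spawn(config.n_trials)]
    boot_rng = np.random.default_rng(ss.spawn(1)[0])

    kb_best = kb_full.best_scores(HOLDOUT)
    dataset_ids = sorted(kb_best)
    dcol = {d: j for j, d in enumerate(dataset_ids)}
    best_vec = np.array([kb_best[d] for d in dataset_ids])
    n_datasets = len(dataset_ids)

    frames = []
    # best-so-far recommended holdout score per (trial, iteration, dataset);
    # NaN until the dataset has received a recommendation in that trial
    S = np.full((config.n_trials, config.n_iterations, n_datasets), np.nan)
    for trial, seed in enumerate(trial_seeds):
        try:
            rec = recommender_factory(seed) if recommender_factory else None
            traj = run_trial(
                config, kb_full, seed, metafeature_cache, recommender=rec
            )
        except Exception as exc:
            raise RuntimeError(f"trial {trial} (seed {seed}) failed: {exc}") from exc
        df = traj.to_frame()
        df.insert(0, "trial", trial)
        frames.append(df)
        cur = np.full(n_datasets, np.nan)
        by_iter = dict(tuple(df.groupby("iteration"))) if len(df) else {}
        for it in range(1, config.n_iterations + 1):
            rows = by_iter.get(it)
            if rows is not None:
                for d, s in zip(rows["dataset"], rows["holdout_score"]):
                    j = dcol[d]
                    if np.isnan(cur[j]) or s > cur[j]:
                        cur[j] = s
            S[trial, it - 1] = cur

    trajectories = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["trial", "iteration", "dataset", "config", "cv_score",
                     "holdout_score", "delta_ba", "best_so_far", "delta_ba_best"]
        )
    )

    # relative regret of the best configuration found so far, per dataset
    with np.errstate(invalid="ignore"):
        D = (best_vec[None, None, :] - S) / best_vec[None, None, :]

    iters = np.arange(1, config.n_iterations + 1)
    flat = D.reshape(config.n_trials, config.n_iterations, n_datasets)
    med = np.nanmedian(
        flat.transpose(1, 0, 2).reshape(config.n_iterations, -1), axis=1
    ) if config.n_iterations else np.array([])
    ci_lo = med.copy()
    ci_hi = med.copy()
    if config.n_bootstrap > 0 and config.n_trials > 1 and config.n_iterations:
        boots = np.empty((config.n_bootstrap, config.n_iterations))
        for b in range(config.n_bootstrap):
            pick = boot_rng.integers(0, config.n_trials, config.n_trials)
            sel = flat[pick]
            boots[b] = np.nanmedian(
                sel.transpose(1, 0, 2).reshape(config.n_iterations, -1), axis=1
            )
        ci_lo = np.nanpercentile(boots, 2.5, axis=0)
        ci_hi = np.nanpercentile(boots, 97.5, axis=0)

    success_curves = {}
    for thr in config.thresholds:
        with np.errstate(invalid="ignore"):
            hit = (D <= thr) & ~np.isnan(D)
        success_curves[thr] = hit.sum(axis=2).mean(axis=0) / n_datasets

    per_iteration = pd.DataFrame(
        {
            "iteration": iters,
            "cumulative_evaluations": iters * config.n_recs,
            "median_delta_ba": med,
            "ci_lo": ci_lo,
            "ci_hi": ci_hi,
        }
    )
    for thr in config.thresholds:
        col = f"success_rate_{round(thr * 100):d}pct"
        per_iteration[col] = success_curves[thr]
    logger.info(
        "experiment done: strategy=%s trials=%d iterations=%d datasets=%d",
        config.strategy, config.n_trials, config.n_iterations, n_datasets,
    )
    return ExperimentSummary(config, per_iteration, trajectories)


def leave_one_out(
    kb_full: KnowledgeBase,
    dataset_id: str,
    budget: int,
    strategy: str = "svd",
    seed: int = 0,
    metafeature_cache=None,
    strategy_params: dict | None = None,
) -> Trajectory:
    """Deployment-style analysis for one held-out dataset.

    The recommender trains on the cv results of *all other* datasets,
    then iteratively recommends one configuration at a time for
    ``dataset_id``, receiving its cv score as feedback after each
    evaluation; holdout ΔBA is logged per evaluation.  The trajectory
    has ``min(budget, n_configs)`` entries.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if dataset_id not in kb_full.datasets:
        raise KeyError(f"unknown dataset {dataset_id!r}")
    cfg = ExperimentConfig(
        strategy=strategy,
        n_init=1,
        n_recs=1,
        n_trials=1,
        n_iterations=0,
        seed=seed,
        strategy_params=strategy_params or {},
    )
    ss = np.random.SeedSequence(seed)
    rec = _build_recommender(cfg, _derive_seed(ss.spawn(1)[0]), kb_full,
                             metafeature_cache)
    rec.register_configs(kb_full.configs.values())
    train = [r for r in kb_full.results(CV) if r.dataset_id != dataset_id]
    if not train:
        raise ValueError("no training results outside the held-out dataset")
    rec.update(sorted(train, key=lambda r: r.key))

    ba_best = kb_full.best_score(dataset_id, HOLDOUT)
    traj = Trajectory(seed=seed, strategy=strategy)
    best = None
    for it in range(1, budget + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            recs = rec.recommend(dataset_id, 1)
        if not recs:
            break
        cid = recs[0].config.config_id
        cv_r = kb_full.rating(dataset_id, cid, CV)
        ho_r = kb_full.rating(dataset_id, cid, HOLDOUT)
        if cv_r is None or ho_r is None:
            traj.skipped.append((it, dataset_id, cid))
            continue
        rec.update(
            [
                ExperimentResult(
                    dataset_id=dataset_id,
                    config=recs[0].config,
                    rating=cv_r,
                    split_tag=CV,
                )
            ]
        )
        best = ho_r if best is None or ho_r > best else best
        traj.records.append(
            {
                "iteration": it,
                "dataset": dataset_id,
                "config": cid,
                "cv_score": cv_r,
                "holdout_score": ho_r,
                "delta_ba": delta_ba(ba_best, ho_r),
                "best_so_far": best,
                "delta_ba_best": delta_ba(ba_best, best),
            }
        )
    return traj


def plot_summary(summaries: Mapping[str, ExperimentSummary], path) -> None:
    """Regret and success-rate curves, one line per strategy."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for name, summary in summaries.items():
        df = summary.per_iteration
        axes[0].plot(df["iteration"], df["median_delta_ba"], label=name)
        axes[0].fill_between(
            df["iteration"], df["ci_lo"], df["ci_hi"], alpha=0.2
        )
        for col in df.columns:
            if col.startswith("success_rate_"):
                axes[1].plot(
                    df["cumulative_evaluations"],
                    df[col],
                    label=f"{name} {col.removeprefix('success_rate_')}",
                )
    axes[0].set_xlabel("iteration")
    axes[0].set_ylabel("median ΔBA")
    axes[0].legend(fontsize=7)
    axes[1].set_xlabel("cumulative evaluations")
    axes[1].set_ylabel("success rate")
    axes[1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
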