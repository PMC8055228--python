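"""Synthetic knowledge bases and toy classification tables.

The generator emulates a PMLB-style cache of cross-validated
balanced-accuracy scores: a dense datasets × configurations matrix with
planted low-rank structure plus noise, written as two independent noisy
views ("cv" and "holdout") of the same clean score surface.  The planted
parameters are returned so tests can use them as ground-truth oracles.

Clean ratings follow the same additive model the matrix-factorization
recommender assumes:

    clean_ad = μ + b_a + b_d + q_a · p_d   (then a per-dataset margin
    boost on the best configuration, then clipping to [0, 1])

Default scales (μ=0.7, bias sd 0.05, factor entry sd 0.15/√k, noise sd
0.02) mimic the spread of balanced-accuracy caches where most scores land
between 0.5 and 0.95.  The margin boost (default 0.05) guarantees each
dataset has a clearly identifiable best configuration, so the argmax of a
noisy holdout view almost always agrees with the planted optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .knowledge_base import (
    CV,
    HOLDOUT,
    AlgorithmConfig,
    ExperimentResult,
    KnowledgeBase,
)


@dataclass
class PlantedModel:
    """Ground truth behind a generated knowledge base."""

    mu: float
    b_alg: np.ndarray          # per-config bias, shape (n_configs,)
    b_data: np.ndarray         # per-dataset bias, shape (n_datasets,)
    Q: np.ndarray              # config factors, shape (n_configs, k_true)
    P: np.ndarray              # dataset factors, shape (n_datasets, k_true)
    noise_sd: float
    best_margin: float
    dataset_ids: list[str]
    config_ids: list[str]
    clean: np.ndarray = field(repr=False)  # datasets x configs, post-margin, pre-clip

    @property
    def k_true(self) -> int:
        return self.Q.shape[1]

    def linear_part(self) -> np.ndarray:
        """μ + b_a + b_d + q·p without margin boost or clipping."""
        return (
            self.mu
            + self.b_data[:, None]
            + self.b_alg[None, :]
            + self.P @ self.Q.T
        )

    def best_config(self, dataset_index: int) -> int:
        return int(np.argmax(self.clean[dataset_index]))

    def to_json(self) -> str:
        doc = {
            "mu": self.mu,
            "b_alg": self.b_alg.tolist(),
            "b_data": self.b_data.tolist(),
            "Q": self.Q.tolist(),
            "P": self.P.tolist(),
            "k_true": self.k_true,
            "noise_sd": self.noise_sd,
            "best_margin": self.best_margin,
            "dataset_ids": self.dataset_ids,
            "config_ids": self.config_ids,
            "clean": self.clean.tolist(),
        }
        return json.dumps(doc)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


def generate_kb(
    n_datasets: int = 25,
    n_configs: int = 100,
    k_true: int = 2,
    noise_sd: float = 0.02,
    seed: int = 0,
    mu: float = 0.7,
    bias_sd: float = 0.05,
    factor_sd: float | None = None,
    best_margin: float = 0.05,
) -> tuple[KnowledgeBase, PlantedModel]:
    """Generate a dense synthetic knowledge base with planted structure.

    Every (dataset, config) cell gets both a cv and a holdout rating:
    ``clip(clean + noise)`` with independent noise draws per view, so the
    two views agree up to 2·noise_sd.  ``k_true=0`` reduces to a pure
    bias model.  Bit-reproducible for a fixed seed.
    """
    if n_datasets < 1 or n_configs < 1:
        raise ValueError("n_datasets and n_configs must be >= 1")
    if k_true < 0:
        raise ValueError("k_true must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if factor_sd is None:
        factor_sd = 0.15 / np.sqrt(k_true) if k_true > 0 else 0.0
    b_alg = rng.normal(0.0, bias_sd, size=n_configs)
    b_data = rng.normal(0.0, bias_sd, size=n_datasets)
    Q = rng.normal(0.0, factor_sd, size=(n_configs, k_true))
    P = rng.normal(0.0, factor_sd, size=(n_datasets, k_true))
    dataset_ids = [f"d{i:03d}" for i in range(n_datasets)]
    config_ids = [f"c{j:04d}" for j in range(n_configs)]

    clean = mu + b_data[:, None] + b_alg[None, :] + P @ Q.T
    if best_margin > 0 and n_configs > 1:
        # separate each dataset's best config from the runner-up so the
        # planted optimum survives observation noise
        for i in range(n_datasets):
            order = np.argsort(clean[i])
            top, second = order[-1], order[-2]
            gap = clean[i, top] - clean[i, second]
            if gap < best_margin:
                clean[i, top] = clean[i, second] + best_margin

    cv_noise = rng.normal(0.0, noise_sd, size=clean.shape)
    ho_noise = rng.normal(0.0, noise_sd, size=clean.shape)
    cv = np.clip(clean + cv_noise, 0.0, 1.0)
    ho = np.clip(clean + ho_noise, 0.0, 1.0)

    kb = KnowledgeBase()
    configs = [
        AlgorithmConfig("synthcfg", {"index": j}) for j in range(n_configs)
    ]
    # config ids in the kb are the canonical ones; keep a readable alias order
    for i, did in enumerate(dataset_ids):
        for j in range(n_configs):
            for split, matrix in ((CV, cv), (HOLDOUT, ho)):
                kb.add(
                    ExperimentResult(
                        dataset_id=did,
                        config=configs[j],
                        rating=float(matrix[i, j]),
                        metric_name="balanced_accuracy_synthetic",
                        split_tag=split,
                    )
                )
    planted = PlantedModel(
        mu=mu,
        b_alg=b_alg,
        b_data=b_data,
        Q=Q,
        P=P,
        noise_sd=noise_sd,
        best_margin=best_margin,
        dataset_ids=dataset_ids,
        config_ids=[c.config_id for c in configs],
        clean=clean,
    )
    return kb, planted


def hide_ratings(
    kb: KnowledgeBase, observed_fraction: float, seed: int = 0
) -> tuple[KnowledgeBase, set[tuple[str, str]]]:
    """Split a kb's (dataset, config) cells into observed and hidden.

    A uniform sample of cells is retained (both split tags of a retained
    cell survive); the complement is returned as the test cell set.  The
    retained count is ``round(observed_fraction * n_cells)``.
    """
    if not 0.0 < observed_fraction <= 1.0:
        raise ValueError("observed_fraction must be in (0, 1]")
    cells = sorted({(r.dataset_id, r.config.config_id) for r in kb})
    rng = np.random.default_rng(seed)
    n_keep = int(round(observed_fraction * len(cells)))
    keep_idx = rng.choice(len(cells), size=n_keep, replace=False)
    keep = {cells[i] for i in keep_idx}
    train = KnowledgeBase(
        r for r in kb if (r.dataset_id, r.config.config_id) in keep
    )
    test_cells = set(cells) - keep
    return train, test_cells


def generate_tables(
    n_datasets: int = 5,
    rows: int = 100,
    cols: int = 5,
    class_sep: float = 1.0,
    majority_fraction: float = 0.5,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Generate two-class Gaussian-blob tables with known metafeatures.

    Each table has ``rows`` samples, ``cols`` numeric features and a
    ``class`` column; labels are Bernoulli(majority_fraction) draws for
    class 0, and the class-0/class-1 blob centers are ``class_sep`` apart
    along every feature axis.  Planted sample/feature counts are
    recovered exactly by metafeature computation; the majority fraction
    is recovered up to binomial noise.
    """
    if rows < 10:
        raise ValueError("rows must be >= 10")
    if cols < 1:
        raise ValueError("cols must be >= 1")
    if not 0.0 < majority_fraction < 1.0:
        raise ValueError("majority_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    tables: dict[str, pd.DataFrame] = {}
    for t in range(n_datasets):
        labels = (rng.random(rows) >= majority_fraction).astype(int)
        # guarantee both classes are present
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        centers = np.stack([np.zeros(cols), np.full(cols, class_sep)])
        X = centers[labels] + rng.normal(0.0, 1.0, size=(rows, cols))
        df = pd.DataFrame(X, columns=[f"f{c}" for c in range(cols)])
        df["class"] = labels
        tables[f"synth{t:02d}"] = df
    return tables
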