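"""Biased matrix-factorization (Funk-SVD) recommender with online SGD.

Each rating of configuration *a* on dataset *d* is modeled as

    r̂_ad = μ + b_a + b_d + q_a · p_d

where μ is the average of all observed scores, b_a and b_d are per-config
and per-dataset biases (initially zero), and q_a, p_d are length-k latent
factor vectors drawn at initialization from N(0, init_sd²).  Parameters
are learned by SGD on the regularized squared loss

    L = Σ_{r_ad ∈ D} (r_ad − r̂_ad)² + λ(b_a² + b_d² + ‖q_a‖² + ‖p_d‖²)

and are maintained between updates: each call to :meth:`update` folds the
new results into the store, recomputes μ exactly, and runs a number of
epochs proportional to the number of new results over the full
accumulated rating set (shuffled, seeded).  This makes the model an
online learner — it never restarts from scratch as the knowledge base
grows.
"""

from __future__ import annotations

import json
import math
from typing import Sequence

import numpy as np

from ..knowledge_base import CV, AlgorithmConfig, ExperimentResult
from ._sgd import sgd_epochs
from .base import Recommender, RatingEstimate

STATE_FORMAT_VERSION = 1


class SVDRecommender(Recommender):
    """Funk-SVD collaborative filter.

    Parameters
    ----------
    k : latent dimension (default 40).
    gamma : SGD learning rate γ (default 0.01).
    lam : regularization weight λ (default 0.02).
    init_sd : std of the zero-mean normal initializer for factors (0.1).
    epochs_per_result : proportionality constant between new results and
        training epochs (default 1).
    min_epochs : lower bound on epochs per update (default 10).
    """

    name = "svd"

    def __init__(
        self,
        seed: int = 0,
        k: int = 40,
        gamma: float = 0.01,
        lam: float = 0.02,
        init_sd: float = 0.1,
        epochs_per_result: float = 1.0,
        min_epochs: int = 10,
        use_numba: bool = True,
    ):
        super().__init__(seed=seed)
        self.k = int(k)
        self.gamma = float(gamma)
        self.lam = float(lam)
        self.init_sd = float(init_sd)
        self.epochs_per_result = float(epochs_per_result)
        self.min_epochs = int(min_epochs)
        self.use_numba = use_numba

        ss = np.random.SeedSequence(self.seed)
        init_ss, shuffle_ss = ss.spawn(2)
        self._init_rng = np.random.default_rng(init_ss)
        self._shuffle_rng = np.random.default_rng(shuffle_ss)

        self.mu: float | None = None
        self._drow: dict[str, int] = {}
        self._ccol: dict[str, int] = {}
        self.b_data = np.zeros(0)
        self.b_alg = np.zeros(0)
        self.P = np.zeros((0, self.k))
        self.Q = np.zeros((0, self.k))
        # rating store in array form, aligned with kb contents
        self._rows: list[int] = []
        self._cols: list[int] = []
        self._ratings: list[float] = []
        self._cell_pos: dict[tuple[int, int], int] = {}

    # -- index bookkeeping -------------------------------------------------

    def _dataset_index(self, dataset_id: str) -> int:
        idx = self._drow.get(dataset_id)
        if idx is None:
            idx = len(self._drow)
            self._drow[dataset_id] = idx
            self.b_data = np.append(self.b_data, 0.0)
            vec = self._init_rng.normal(0.0, self.init_sd, size=self.k)
            self.P = np.vstack([self.P, vec[None, :]]) if self.P.size else vec[None, :]
        return idx

    def _config_index(self, config_id: str) -> int:
        idx = self._ccol.get(config_id)
        if idx is None:
            idx = len(self._ccol)
            self._ccol[config_id] = idx
            self.b_alg = np.append(self.b_alg, 0.0)
            vec = self._init_rng.normal(0.0, self.init_sd, size=self.k)
            self.Q = np.vstack([self.Q, vec[None, :]]) if self.Q.size else vec[None, :]
        return idx

    # -- learning ----------------------------------------------------------

    def _refit(self, new_results: Sequence[ExperimentResult]) -> None:
        for r in new_results:
            if r.split_tag != CV:
                # recommenders learn from cross-validation scores only
                continue
            i = self._dataset_index(r.dataset_id)
            j = self._config_index(r.config.config_id)
            pos = self._cell_pos.get((i, j))
            if pos is None:
                self._cell_pos[(i, j)] = len(self._ratings)
                self._rows.append(i)
                self._cols.append(j)
                self._ratings.append(r.rating)
            else:  # replacement, latest wins
                self._ratings[pos] = r.rating
        if not self._ratings:
            return
        # μ is the exact observed average, not an SGD parameter
        self.mu = float(np.mean(self._ratings))
        epochs = max(
            self.min_epochs, math.ceil(self.epochs_per_result * len(new_results))
        )
        self.run_epochs(epochs)

    def run_epochs(self, n_epochs: int) -> None:
        """Run extra SGD epochs over the accumulated ratings."""
        n = len(self._ratings)
        if n == 0 or n_epochs <= 0:
            return
        perms = np.stack(
            [self._shuffle_rng.permutation(n) for _ in range(n_epochs)]
        )
        sgd_epochs(
            np.array(self._rows),
            np.array(self._cols),
            np.array(self._ratings),
            self.mu,
            self.b_data,
            self.b_alg,
            self.P,
            self.Q,
            self.gamma,
            self.lam,
            perms,
            use_numba=self.use_numba,
        )

    # -- prediction --------------------------------------------------------

    def _predict(self, dataset_id: str, config_id: str) -> RatingEstimate:
        if self.mu is None:
            raise RuntimeError("svd recommender has seen no ratings yet")
        r_hat = self.mu
        i = self._drow.get(dataset_id)
        j = self._ccol.get(config_id)
        if i is not None:
            r_hat += self.b_data[i]
        if j is not None:
            r_hat += self.b_alg[j]
        if i is not None and j is not None:
            r_hat += float(self.Q[j] @ self.P[i])
        return RatingEstimate(float(r_hat))

    def _rank(self, dataset_id: str, candidates: list[str]) -> list[tuple[str, float]]:
        # vectorized scoring; same ordering contract as the base class
        if self.mu is None:
            raise RuntimeError("svd recommender has seen no ratings yet")
        i = self._drow.get(dataset_id)
        base = self.mu + (self.b_data[i] if i is not None else 0.0)
        scores = np.full(len(candidates), base)
        for c, cid in enumerate(candidates):
            j = self._ccol.get(cid)
            if j is not None:
                scores[c] += self.b_alg[j]
                if i is not None:
                    scores[c] += float(self.Q[j] @ self.P[i])
        scored = [
            (cid, float(np.clip(s, 0.0, 1.0))) for cid, s in zip(candidates, scores)
        ]
        scored.sort(key=lambda t: (-t[1], t[0]))
        return scored

    # -- diagnostics -------------------------------------------------------

    def training_loss(self) -> float:
        """Regularized squared loss over the accumulated ratings."""
        if self.mu is None:
            raise RuntimeError("svd recommender has seen no ratings yet")
        rows = np.array(self._rows)
        cols = np.array(self._cols)
        r = np.array(self._ratings)
        pred = (
            self.mu
            + self.b_data[rows]
            + self.b_alg[cols]
            + np.einsum("ij,ij->i", self.Q[cols], self.P[rows])
        )
        sq = (r - pred) ** 2
        reg = (
            self.b_alg[cols] ** 2
            + self.b_data[rows] ** 2
            + np.sum(self.Q[cols] ** 2, axis=1)
            + np.sum(self.P[rows] ** 2, axis=1)
        )
        return float(np.sum(sq + self.lam * reg))

    def rmse(self, results: Sequence[ExperimentResult]) -> float:
        """Root-mean-square prediction error on a set of known ratings."""
        errs = [
            r.rating - self._predict(r.dataset_id, r.config.config_id).r_hat
            for r in results
        ]
        return float(np.sqrt(np.mean(np.square(errs))))

    # -- persistence -------------------------------------------------------

    def to_json(self) -> str:
        """Serialize model state (μ, biases, factors, hyperparameters)."""
        doc = {
            "format_version": STATE_FORMAT_VERSION,
            "strategy": self.name,
            "hyper": {
                "k": self.k,
                "gamma": self.gamma,
                "lam": self.lam,
                "init_sd": self.init_sd,
                "epochs_per_result": self.epochs_per_result,
                "min_epochs": self.min_epochs,
                "seed": self.seed,
            },
            "mu": self.mu,
            "datasets": list(self._drow),
            "configs": list(self._ccol),
            "b_data": self.b_data.tolist(),
            "b_alg": self.b_alg.tolist(),
            "P": self.P.tolist(),
            "Q": self.Q.tolist(),
            "ratings": {
                "rows": self._rows,
                "cols": self._cols,
                "values": self._ratings,
            },
            "config_specs": {
                cid: {"algorithm": cfg.algorithm, "params": cfg.params}
                for cid, cfg in self.known_configs.items()
            },
            "recommended": sorted(self._recommended),
        }
        return json.dumps(doc)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "SVDRecommender":
        doc = json.loads(text)
        if doc.get("format_version") != STATE_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model state version {doc.get('format_version')!r}"
            )
        hyper = doc["hyper"]
        model = cls(
            seed=hyper["seed"],
            k=hyper["k"],
            gamma=hyper["gamma"],
            lam=hyper["lam"],
            init_sd=hyper["init_sd"],
            epochs_per_result=hyper["epochs_per_result"],
            min_epochs=hyper["min_epochs"],
        )
        model.mu = doc["mu"]
        model._drow = {d: i for i, d in enumerate(doc["datasets"])}
        model._ccol = {c: j for j, c in enumerate(doc["configs"])}
        model.b_data = np.array(doc["b_data"], dtype=float)
        model.b_alg = np.array(doc["b_alg"], dtype=float)
        model.P = np.array(doc["P"], dtype=float).reshape(len(model._drow), model.k)
        model.Q = np.array(doc["Q"], dtype=float).reshape(len(model._ccol), model.k)
        model._rows = list(doc["ratings"]["rows"])
        model._cols = list(doc["ratings"]["cols"])
        model._ratings = list(doc["ratings"]["values"])
        model._cell_pos = {
            (i, j): pos for pos, (i, j) in enumerate(zip(model._rows, model._cols))
        }
        datasets = doc["datasets"]
        configs = doc["configs"]
        for cid, spec in doc["config_specs"].items():
            model._known_configs[cid] = AlgorithmConfig(
                spec["algorithm"], spec["params"]
            )
        for pos, (i, j) in enumerate(zip(model._rows, model._cols)):
            model.kb.add(
                ExperimentResult(
                    dataset_id=datasets[i],
                    config=model._known_configs[configs[j]],
                    rating=model._ratings[pos],
                    split_tag=CV,
                )
            )
        model._recommended = {tuple(p) for p in doc["recommended"]}
        return model

    @classmethod
    def load(cls, path) -> "SVDRecommender":
        with open(path) as fh:
            return cls.from_json(fh.read())
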