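"""Mean, random, KNN, slope-one and co-clustering strategies against
independent brute-force / hand-arithmetic oracles on small dense matrices."""

import numpy as np
import pandas as pd
import pytest

from mlrec.knowledge_base import CV, AlgorithmConfig, ExperimentResult, KnowledgeBase
from mlrec.metafeatures import METAFEATURE_NAMES
from mlrec.recommenders import (
    CoClusteringRecommender,
    KNNDataRecommender,
    KNNMetaRecommender,
    KNNMLRecommender,
    MeanRecommender,
    RandomRecommender,
    SlopeOneRecommender,
    fit_from_kb,
    make_recommender,
)
from conftest import kb_from_matrix


def cid(name):
    return AlgorithmConfig(name).config_id


def fitted(cls_or_name, kb, **kw):
    if isinstance(cls_or_name, str):
        rec = make_recommender(cls_or_name, **kw)
    else:
        rec = cls_or_name(**kw)
    return fit_from_kb(rec, kb)


# --------------------------------------------------------------------------
# mean
# --------------------------------------------------------------------------

class TestMean:
    def test_config_mean(self, make_kb_from_matrix):
        kb = make_kb_from_matrix([[0.4], [0.6]])
        rec = fitted(MeanRecommender, kb)
        assert rec._predict("d0", cid("alg0")).r_hat == pytest.approx(0.5)

    def test_unseen_config_falls_back_to_global_mean(self, make_kb_from_matrix):
        kb = make_kb_from_matrix([[0.4, 0.8]])
        rec = fitted(MeanRecommender, kb)
        assert rec._predict("d0", "never-rated").r_hat == pytest.approx(0.6)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(2)
        results = [
            ExperimentResult(f"d{rng.integers(5)}", AlgorithmConfig(f"a{j % 7}"),
                             float(rng.random()))
            for j in range(50)
        ]
        kb = KnowledgeBase(results)
        rec = fitted(MeanRecommender, kb)
        stored = list(kb)  # post-dedup ratings are what the model sees
        for j in range(7):
            expected = np.mean(
                [r.rating for r in stored if r.config.config_id == cid(f"a{j}")]
            )
            assert rec._predict("dX", cid(f"a{j}")).r_hat == pytest.approx(expected)

    def test_ranking_equals_column_mean_ranking(self, make_kb_from_matrix):
        rng = np.random.default_rng(3)
        mat = rng.uniform(0.2, 0.9, size=(6, 8))
        kb = make_kb_from_matrix(mat)
        rec = fitted(MeanRecommender, kb)
        recs = rec.recommend("new-dataset", 8)
        got = [r.config.config_id for r in recs]
        expected = [cid(f"alg{j}") for j in np.argsort(-mat.mean(axis=0))]
        assert got == expected

    def test_dominant_config_ranks_first_for_new_dataset(self, tiny_kb):
        rec = fitted(MeanRecommender, tiny_kb)
        recs = rec.recommend("fresh", 1)
        assert recs[0].config.algorithm == "best"


# --------------------------------------------------------------------------
# random
# --------------------------------------------------------------------------

class TestRandom:
    def test_same_seed_identical_output(self, tiny_kb):
        outs = []
        for _ in range(2):
            rec = fitted(RandomRecommender, tiny_kb, seed=9)
            outs.append([r.config.config_id for r in rec.recommend("fresh", 3)])
        assert outs[0] == outs[1]

    def test_exhaustion_returns_full_permutation(self, tiny_kb):
        rec = fitted(RandomRecommender, tiny_kb, seed=1)
        with pytest.warns(UserWarning):
            recs = rec.recommend("fresh", 10)
        assert sorted(r.config.algorithm for r in recs) == ["best", "mid", "worst"]

    def test_uniformity_over_many_draws(self):
        counts = {f"a{j}": 0 for j in range(4)}
        configs = [AlgorithmConfig(f"a{j}") for j in range(4)]
        for i in range(10_000):
            rec = RandomRecommender(seed=i)
            rec.register_configs(configs)
            pick = rec.recommend("d", 1)[0].config.algorithm
            counts[pick] += 1
        n, p = 10_000, 0.25
        sigma = np.sqrt(n * p * (1 - p))
        for c in counts.values():
            assert abs(c - n * p) <= 3 * sigma


# --------------------------------------------------------------------------
# KNN on ratings
# --------------------------------------------------------------------------

def _knn_user_oracle(mat, i, j, k, shrink=10.0):
    """Independent re-derivation: shrunk-Pearson weighted, mean-centered."""
    own_mean = np.nanmean(mat[i])
    sims = []
    for v in range(mat.shape[0]):
        if v == i or np.isnan(mat[v, j]):
            continue
        mask = ~(np.isnan(mat[i]) | np.isnan(mat[v]))
        if mask.sum() < 2:
            continue
        a, b = mat[i, mask], mat[v, mask]
        if a.std() == 0 or b.std() == 0:
            continue
        rho = np.corrcoef(a, b)[0, 1] * mask.sum() / (mask.sum() + shrink)
        if rho != 0:
            sims.append((rho, v))
    sims.sort(key=lambda t: (-t[0], t[1]))
    sims = sims[:k]
    denom = sum(abs(s) for s, _ in sims)
    if denom == 0:
        return None
    num = sum(s * (mat[v, j] - np.nanmean(mat[v])) for s, v in sims)
    return own_mean + num / denom


class TestKNNData:
    def test_identical_datasets_transfer_rating(self, make_kb_from_matrix):
        # equal own-means: d0 = {.5, .9, x}, d1 = {.5, .9, .8, .6} mean .7 each
        mat = np.array([
            [0.5, 0.9, np.nan, np.nan],
            [0.5, 0.9, 0.8, 0.6],
        ])
        kb = make_kb_from_matrix(mat)
        rec = fitted(KNNDataRecommender, kb, k_neighbors=5)
        assert rec._predict("d0", cid("alg2")).r_hat == pytest.approx(0.8)

    def test_k1_reduces_to_nearest_neighbor_centered_rating(
        self, make_kb_from_matrix
    ):
        rng = np.random.default_rng(4)
        mat = rng.uniform(0.2, 0.9, size=(4, 6))
        mat[0, 5] = np.nan
        kb = make_kb_from_matrix(mat)
        rec = fitted(KNNDataRecommender, kb, k_neighbors=1)
        expected = _knn_user_oracle(mat, 0, 5, k=1)
        assert rec._predict("d0", cid("alg5")).r_hat == pytest.approx(expected)

    def test_dense_toy_matrix_matches_oracle(self, make_kb_from_matrix):
        rng = np.random.default_rng(5)
        mat = rng.uniform(0.1, 0.95, size=(5, 5))
        mat[2, 3] = np.nan
        kb = make_kb_from_matrix(mat)
        rec = fitted(KNNDataRecommender, kb, k_neighbors=3)
        expected = _knn_user_oracle(mat, 2, 3, k=3)
        assert rec._predict("d2", cid("alg3")).r_hat == pytest.approx(expected)

    def test_no_usable_neighbor_falls_back_to_mean(self, make_kb_from_matrix):
        mat = np.array([[0.5, np.nan], [np.nan, 0.7]])
        kb = make_kb_from_matrix(mat)
        rec = fitted(KNNDataRecommender, kb)
        est = rec._predict("d0", cid("alg1"))
        assert est.fallback
        assert est.r_hat == pytest.approx(0.7)


class TestKNNML:
    def test_identical_configs_transfer_rating(self, make_kb_from_matrix):
        mat = np.array([
            [0.5, 0.5],
            [0.9, 0.9],
            [0.8, np.nan],
            [0.6, np.nan],
        ])
        # config means equal (0.7 each); target dataset d2 rated alg0 at 0.8
        kb = make_kb_from_matrix(mat)
        rec = fitted(KNNMLRecommender, kb, k_neighbors=5)
        assert rec._predict("d2", cid("alg1")).r_hat == pytest.approx(0.8)

    def test_dense_toy_matrix_matches_transposed_oracle(self, make_kb_from_matrix):
        rng = np.random.default_rng(6)
        mat = rng.uniform(0.1, 0.95, size=(5, 5))
        mat[1, 4] = np.nan
        kb = make_kb_from_matrix(mat)
        rec = fitted(KNNMLRecommender, kb, k_neighbors=3)
        expected = _knn_user_oracle(mat.T, 4, 1, k=3)
        assert rec._predict("d1", cid("alg4")).r_hat == pytest.approx(expected)


# --------------------------------------------------------------------------
# KNN on metafeatures
# --------------------------------------------------------------------------

def _toy_cache(vectors):
    return pd.DataFrame(
        {name: vals for name, vals in zip(METAFEATURE_NAMES[:3], np.array(vectors).T)},
        index=pd.Index(list("abcd"[: len(vectors)]), name="dataset"),
    )


class TestKNNMeta:
    def test_twin_dataset_best_config_ranks_first(self, make_kb_from_matrix):
        kb = kb_from_matrix(
            [[0.6, 0.9, 0.7]], dataset_ids=["a"], config_ids=["x", "y", "z"]
        )
        cache = _toy_cache([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])  # b is a's twin
        rec = fitted(KNNMetaRecommender, kb, metafeature_cache=cache, k_neighbors=1)
        recs = rec.recommend("b", 1)
        assert recs[0].config.algorithm == "y"

    def test_best_first_order(self):
        kb = kb_from_matrix(
            [[0.9, 0.7]], dataset_ids=["a"], config_ids=["A", "B"]
        )
        cache = _toy_cache([[0.0, 0.0, 0.0], [0.1, 0.0, 0.0]])
        rec = fitted(KNNMetaRecommender, kb, metafeature_cache=cache, k_neighbors=1)
        recs = rec.recommend("b", 2)
        assert [r.config.algorithm for r in recs] == ["A", "B"]

    def test_recommendations_subset_of_neighbor_rated_configs(self):
        rng = np.random.default_rng(7)
        mat = rng.uniform(0.2, 0.9, size=(3, 10))
        mat[rng.random(mat.shape) < 0.4] = np.nan
        mat[:, 0] = 0.5  # ensure some rating everywhere
        kb = kb_from_matrix(mat, dataset_ids=list("abc"))
        cache = _toy_cache(rng.normal(size=(4, 3)))
        rec = fitted(KNNMetaRecommender, kb, metafeature_cache=cache, k_neighbors=2)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            recs = rec.recommend("d", 10)
        neighbor_configs = set()
        for d in rec.neighbor_ids("d"):
            neighbor_configs |= kb.rated_configs(d, CV)
        assert {r.config.config_id for r in recs} <= neighbor_configs

    def test_missing_metafeatures_instructive_error(self, make_kb_from_matrix):
        kb = make_kb_from_matrix([[0.5]])
        rec = fitted(KNNMetaRecommender, kb, metafeature_cache=_toy_cache([[0, 0, 0]]))
        with pytest.raises(KeyError, match="compute_metafeatures"):
            rec.recommend("unknown", 1)


# --------------------------------------------------------------------------
# slope one
# --------------------------------------------------------------------------

class TestSlopeOne:
    def test_constant_offset_recovered_exactly(self, make_kb_from_matrix):
        base = np.array([0.4, 0.5, 0.6, 0.7])
        mat = np.stack([base, base + 0.1], axis=1)  # alg1 = alg0 + 0.1
        mat[3, 1] = np.nan
        kb = make_kb_from_matrix(mat)
        rec = fitted(SlopeOneRecommender, kb)
        assert rec._predict("d3", cid("alg1")).r_hat == pytest.approx(0.8)

    def test_single_co_rated_pair(self, make_kb_from_matrix):
        mat = np.array([[0.6, 0.8], [0.5, np.nan]])
        kb = make_kb_from_matrix(mat)
        rec = fitted(SlopeOneRecommender, kb)
        # dev(alg1, alg0) = 0.2 from d0; prediction = 0.5 + 0.2
        assert rec._predict("d1", cid("alg1")).r_hat == pytest.approx(0.7)

    def test_4x4_matrix_matches_hand_computed_table(self, make_kb_from_matrix):
        rng = np.random.default_rng(8)
        mat = rng.uniform(0.2, 0.9, size=(4, 4))
        mat[0, 2] = np.nan
        kb = make_kb_from_matrix(mat)
        rec = fitted(SlopeOneRecommender, kb)
        # independent oracle: plain-loop deviations
        preds = []
        for j in [0, 1, 3]:
            raters = [
                d for d in range(4)
                if not np.isnan(mat[d, 2]) and not np.isnan(mat[d, j])
            ]
            dev = np.mean([mat[d, 2] - mat[d, j] for d in raters])
            preds.append(mat[0, j] + dev)
        assert rec._predict("d0", cid("alg2")).r_hat == pytest.approx(np.mean(preds))

    def test_no_co_rated_config_falls_back(self, make_kb_from_matrix):
        mat = np.array([[0.5, np.nan], [np.nan, 0.9]])
        kb = make_kb_from_matrix(mat)
        rec = fitted(SlopeOneRecommender, kb)
        est = rec._predict("d0", cid("alg1"))
        assert est.fallback


# --------------------------------------------------------------------------
# co-clustering
# --------------------------------------------------------------------------

def _cocluster_oracle(mat, n_row, n_col, n_refine=5):
    """Straightforward reimplementation of the documented fit procedure."""
    from mlrec.recommenders.coclustering import CoClusteringRecommender

    model = CoClusteringRecommender(
        n_dataset_clusters=n_row, n_config_clusters=n_col, n_refine=n_refine
    )
    model.fit_matrix(mat.copy())
    return model


def _simple_kmeans(points, k, n_iter=20):
    norms = np.linalg.norm(points, axis=1)
    chosen = [int(np.argmax(norms))]
    dist = np.linalg.norm(points - points[chosen[0]], axis=1)
    for _ in range(1, min(k, len(points))):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(points - points[nxt], axis=1))
    centroids = points[chosen].copy()
    labels = np.zeros(len(points), dtype=int)
    for _ in range(n_iter):
        d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new = np.argmin(d2, axis=1)
        if np.array_equal(new, labels):
            break
        labels = new
        for c in range(len(chosen)):
            if (labels == c).any():
                centroids[c] = points[labels == c].mean(axis=0)
    return labels


class TestCoClustering:
    def test_single_cluster_reduces_to_additive_baseline(self, make_kb_from_matrix):
        rng = np.random.default_rng(9)
        mat = rng.uniform(0.3, 0.8, size=(4, 5))
        kb = make_kb_from_matrix(mat)
        rec = fitted(
            CoClusteringRecommender, kb, n_dataset_clusters=1, n_config_clusters=1
        )
        expected = mat[1].mean() + mat[:, 2].mean() - mat.mean()
        assert rec._predict("d1", cid("alg2")).r_hat == pytest.approx(expected)

    def test_block_constant_matrix_zero_training_error(self):
        blocks = np.array([[0.3, 0.6], [0.8, 0.4]])
        mat = np.kron(blocks, np.ones((3, 4)))  # 6x8, 2x2 blocks
        model = _cocluster_oracle(mat, 2, 2)
        assert model.training_error() == pytest.approx(0.0, abs=1e-12)

    def test_random_matrix_matches_independent_reimplementation(self):
        rng = np.random.default_rng(10)
        mat = rng.uniform(0.2, 0.9, size=(8, 8))
        model = CoClusteringRecommender(n_dataset_clusters=3, n_config_clusters=3,
                                        n_refine=0)
        model.fit_matrix(mat.copy())
        # independent: deterministic farthest-first k-means on rows/cols,
        # then the three-term prediction rule
        row_labels = _simple_kmeans(mat, 3)
        col_labels = _simple_kmeans(mat.T, 3)
        np.testing.assert_array_equal(model._row_labels, row_labels)
        np.testing.assert_array_equal(model._col_labels, col_labels)
        g = mat.mean()
        for i, j in [(0, 0), (3, 5), (7, 7)]:
            a, b = row_labels[i], col_labels[j]
            co = mat[np.ix_(row_labels == a, col_labels == b)].mean()
            exp = (
                co
                + mat[i].mean() - mat[row_labels == a].mean()
                + mat[:, j].mean() - mat[:, col_labels == b].mean()
            )
            pred = model._predict_matrix(model._means, row_labels, col_labels)[i, j]
            assert pred == pytest.approx(exp)

    def test_unfitted_model_rejected(self):
        model = CoClusteringRecommender()
        with pytest.raises(RuntimeError):
            model._predict("d", "c")


def test_all_strategies_obey_ranking_contract(default_synth):
    """Every strategy returns ranks 1..n with non-increasing predictions."""
    kb, _ = default_synth
    small = KnowledgeBase(
        r for r in kb
        if r.dataset_id in {"d000", "d001", "d002"}
        and int(r.config.params["index"]) < 15
    )
    for name in ["svd", "knn-data", "knn-ml", "slopeone", "coclustering",
                 "mean", "random"]:
        rec = fitted(name, small, seed=0)
        recs = rec.recommend("d999", 5)
        assert [r.rank for r in recs] == list(range(1, len(recs) + 1))
        vals = [r.predicted.r_hat for r in recs]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v <= 1.0 for v in vals)
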