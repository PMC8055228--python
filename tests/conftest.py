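import numpy as np
import pytest

from mlrec.knowledge_base import (
    CV,
    HOLDOUT,
    AlgorithmConfig,
    ExperimentResult,
    KnowledgeBase,
)
from mlrec.synthetic import generate_kb


def kb_from_matrix(mat, split_tag=CV, dataset_ids=None, config_ids=None):
    """Build a kb from a dense datasets x configs matrix (NaN = missing)."""
    mat = np.asarray(mat, dtype=float)
    n_d, n_c = mat.shape
    dataset_ids = dataset_ids or [f"d{i}" for i in range(n_d)]
    config_ids = config_ids or [f"alg{j}" for j in range(n_c)]
    kb = KnowledgeBase()
    for i in range(n_d):
        for j in range(n_c):
            if np.isnan(mat[i, j]):
                continue
            kb.add(
                ExperimentResult(
                    dataset_id=dataset_ids[i],
                    config=AlgorithmConfig(config_ids[j]),
                    rating=float(mat[i, j]),
                    split_tag=split_tag,
                )
            )
    return kb


@pytest.fixture
def make_kb_from_matrix():
    return kb_from_matrix


@pytest.fixture(scope="session")
def default_synth():
    """The default 25x100 planted-structure knowledge base."""
    return generate_kb(seed=1)


@pytest.fixture
def tiny_kb():
    """3 datasets x 3 configs, cv + holdout, with a dominant config."""
    kb = KnowledgeBase()
    ratings = {
        "d1": {"best": 0.9, "mid": 0.7, "worst": 0.5},
        "d2": {"best": 0.85, "mid": 0.6, "worst": 0.55},
        "d3": {"best": 0.95, "mid": 0.65, "worst": 0.5},
    }
    for did, per_cfg in ratings.items():
        for alg, score in per_cfg.items():
            for split in (CV, HOLDOUT):
                kb.add(
                    ExperimentResult(
                        dataset_id=did,
                        config=AlgorithmConfig(alg),
                        rating=score,
                        split_tag=split,
                    )
                )
    return kb
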