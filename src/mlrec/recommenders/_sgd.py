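"""Inner SGD loop for the biased matrix-factorization recommender.

One epoch visits every stored rating once, in a shuffled order supplied by
the caller, and applies the four update rules

    b_a <- b_a + gamma * (e - lam * b_a)
    b_d <- b_d + gamma * (e - lam * b_d)
    q_a <- q_a + gamma * (e * p_d - lam * q_a)
    p_d <- p_d + gamma * (e * q_a - lam * p_d)

with e = r - (mu + b_a + b_d + q_a . p_d).  The cross-terms use the
pre-update vectors (simultaneous update).  A numba-jitted kernel carries
the load; a pure-python twin with the identical operation order exists for
environments without numba and as a cross-check in tests.
"""

from __future__ import annotations

import numpy as np


def _sgd_epochs_py(rows, cols, ratings, mu, b_d, b_a, P, Q, gamma, lam, perms):
    k = P.shape[1]
    for e in range(perms.shape[0]):
        for t in range(perms.shape[1]):
            idx = perms[e, t]
            i = rows[idx]
            j = cols[idx]
            pred = mu + b_d[i] + b_a[j]
            for f in range(k):
                pred += Q[j, f] * P[i, f]
            err = ratings[idx] - pred
            b_a[j] += gamma * (err - lam * b_a[j])
            b_d[i] += gamma * (err - lam * b_d[i])
            for f in range(k):
                qjf = Q[j, f]
                pif = P[i, f]
                Q[j, f] += gamma * (err * pif - lam * qjf)
                P[i, f] += gamma * (err * qjf - lam * pif)


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _sgd_epochs_jit = njit(cache=True)(_sgd_epochs_py)
except ImportError:  # pragma: no cover
    _sgd_epochs_jit = None


def sgd_epochs(
    rows: np.ndarray,
    cols: np.ndarray,
    ratings: np.ndarray,
    mu: float,
    b_d: np.ndarray,
    b_a: np.ndarray,
    P: np.ndarray,
    Q: np.ndarray,
    gamma: float,
    lam: float,
    perms: np.ndarray,
    use_numba: bool = True,
) -> None:
    """Run ``perms.shape[0]`` SGD epochs in place.

    ``rows``/``cols`` index datasets/configs per rating; ``perms`` is an
    (epochs, n_ratings) array of visit orders, one row per epoch.
    """
    args = (
        np.ascontiguousarray(rows, dtype=np.int64),
        np.ascontiguousarray(cols, dtype=np.int64),
        np.ascontiguousarray(ratings, dtype=np.float64),
        float(mu),
        b_d,
        b_a,
        P,
        Q,
        float(gamma),
        float(lam),
        np.ascontiguousarray(perms, dtype=np.int64),
    )
    if use_numba and _sgd_epochs_jit is not None:
        _sgd_epochs_jit(*args)
    else:
        _sgd_epochs_py(*args)
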