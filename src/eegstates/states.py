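"""Partitioning network space into functional states.

k-means under the correlation distance ``1 - r`` (Pearson correlation
between a feature vector and a centroid).  Each vector is standardized
(centered, scaled to unit norm), after which ``1 - r = ||u - v||^2 / 2``
and the within-cluster cost of a cluster with member sum ``s`` and
re-standardized centroid ``s / ||s||`` is ``n_c - ||s||``.  Lloyd batch
sweeps therefore converge, and single-point (online) moves can be scored
exactly through the change in ``sum_c ||s_c||``.

States are distinguished by the *pattern* of connections, not their overall
strength, which is why correlation rather than Euclidean distance is used.
Clustering runs on features of both conditions jointly so that state
symbols are comparable between conditions.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .data import DegenerateInputError
from .smvar import WindowedNetworks

__all__ = [
    "correlation_distance",
    "CorrelationKMeans",
    "kmeans_correlation",
    "symbolize",
]


def correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - Pearson correlation, in [0, 2]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    uc = u - u.mean()
    vc = v - v.mean()
    nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        raise DegenerateInputError("correlation distance undefined for a constant vector")
    return float(1.0 - (uc @ vc) / (nu * nv))


def _standardize_rows(X: np.ndarray, zero_rows: str = "error") -> np.ndarray:
    """Center each row and scale it to unit Euclidean norm.

    ``zero_rows="error"`` rejects constant rows (correlation undefined);
    ``zero_rows="neutral"`` maps them to the zero vector, which sits at
    correlation distance 1 from every centroid -- the natural embedding of
    an empty network, which carries no pattern.
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    bad = np.nonzero(norms == 0)[0]
    if bad.size:
        if zero_rows != "neutral":
            raise DegenerateInputError(f"feature {bad[0]} is constant")
        norms = norms.copy()
        norms[bad] = 1.0
    return Xc / norms[:, None]


def _cluster_sums(Z: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    S = np.zeros((k, Z.shape[1]))
    np.add.at(S, labels, Z)
    return S


def _batch_sweeps(Z, inits, k, max_iter):
    """Lloyd batch phase for many restarts at once.

    Restarts are advanced together so each sweep is one large matrix
    product; converged restarts drop out.  Returns (labels (R, n),
    n_sweeps (R,)).
    """
    R = inits.shape[0]
    n, D = Z.shape
    C = Z[inits].copy()  # (R, k, D); standardized rows are valid centroids
    labels = np.full((R, n), -1, dtype=np.intp)
    n_sweeps = np.full(R, max_iter, dtype=int)
    alive = np.arange(R)
    for it in range(1, max_iter + 1):
        sim = (Z @ C[alive].reshape(-1, D).T).reshape(n, alive.size, k)
        new = np.ascontiguousarray(sim.argmax(axis=2).T)  # (Ra, n)
        for j in range(alive.size):  # empty-cluster repair, rare
            counts = np.bincount(new[j], minlength=k)
            for c in np.nonzero(counts == 0)[0]:
                far = int(np.argmin(sim[:, j, c]))
                new[j, far] = c
                counts = np.bincount(new[j], minlength=k)
        conv = (new == labels[alive]).all(axis=1)
        labels[alive] = new
        n_sweeps[alive[conv]] = it
        alive = alive[~conv]
        if alive.size == 0:
            break
        onehot = np.zeros((alive.size, k, n))
        onehot[np.arange(alive.size)[:, None], labels[alive],
               np.arange(n)[None, :]] = 1.0
        S = (onehot.reshape(-1, n) @ Z).reshape(alive.size, k, D)
        C[alive] = S / np.maximum(
            np.linalg.norm(S, axis=2, keepdims=True), 1e-300)
    return labels, n_sweeps


def _online_refine(Z, labels, k, max_moves, gram, znorm2):
    """Exact single-point (Hartigan-style) moves after batch convergence.

    Repeatedly applies the best strictly-improving reassignment; the change
    in total cost of moving a point is computable from cluster-sum norms
    alone.  Mutates ``labels``; returns the cluster sums.
    """
    n = Z.shape[0]
    S = _cluster_sums(Z, labels, k)
    sn = np.linalg.norm(S, axis=1)
    counts = np.bincount(labels, minlength=k)
    zs = Z @ S.T  # (n, k)
    for _ in range(max_moves):
        own = labels
        # norms after removing the point from its own cluster ...
        rem = np.sqrt(np.maximum(
            sn[own] ** 2 - 2 * zs[np.arange(n), own] + znorm2, 0.0))
        # ... and after adding it to each candidate cluster
        add = np.sqrt(np.maximum(sn[None, :] ** 2 + 2 * zs + znorm2[:, None], 0.0))
        gain = (rem[:, None] - sn[own][:, None]) + (add - sn[None, :])
        gain[np.arange(n), own] = -np.inf
        gain[counts[own] <= 1] = -np.inf  # never empty a cluster
        i, b = np.unravel_index(np.argmax(gain), gain.shape)
        if gain[i, b] <= 1e-12:
            break
        a = labels[i]
        S[a] -= Z[i]
        S[b] += Z[i]
        sn[a] = np.linalg.norm(S[a])
        sn[b] = np.linalg.norm(S[b])
        counts[a] -= 1
        counts[b] += 1
        labels[i] = b
        zzi = gram[i] if gram is not None else Z @ Z[i]
        zs[:, a] -= zzi
        zs[:, b] += zzi
    return S


class CorrelationKMeans(ClusterMixin, BaseEstimator):
    """k-means with correlation distance and best-of-restarts selection.

    Parameters
    ----------
    n_clusters : int
        Number of functional states (2-8 in typical use).
    n_init : int
        Random restarts; the restart with the lowest cost wins.
    max_iter : int
        Cap on batch sweeps (and on online moves) per restart.
    random_state : int or numpy Generator
        Seeds centroid initialization; runs are deterministic given it.

    Attributes
    ----------
    cluster_centers_ : (k, n_features) standardized centroids.
    labels_ : per-point symbols in 0..k-1.
    inertia_ : total cost, sum over points of (1 - r) to the centroid.
    n_iter_ : batch sweeps used by the winning restart.
    """

    def __init__(self, n_clusters: int = 6, n_init: int = 1000, max_iter: int = 100,
                 random_state=None, zero_rows: str = "error"):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state
        self.zero_rows = zero_rows

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        k = self.n_clusters
        if X.ndim != 2 or X.shape[0] < k:
            raise ValueError(f"need at least {k} points")
        Z = _standardize_rows(X, self.zero_rows)
        rng = (self.random_state if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))
        n = Z.shape[0]
        # Z Z^T makes online moves O(n k); worth its memory up to a few
        # thousand points
        gram = Z @ Z.T if n <= 5000 else None
        znorm2 = np.einsum("ij,ij->i", Z, Z)
        inits = np.stack([rng.choice(n, size=k, replace=False)
                          for _ in range(self.n_init)])
        best = None
        chunk = max(1, int(2**22 // max(n, 1)))  # cap transient memory
        for lo in range(0, self.n_init, chunk):
            lab_chunk, sweeps = _batch_sweeps(Z, inits[lo : lo + chunk], k,
                                              self.max_iter)
            for labels, n_it in zip(lab_chunk, sweeps):
                S = _online_refine(Z, labels, k, self.max_iter, gram, znorm2)
                cost = float(n - np.linalg.norm(S, axis=1).sum())
                if best is None or cost < best[0]:
                    best = (cost, labels, S, int(n_it))
        cost, labels, S, n_it = best
        self.inertia_ = cost
        self.labels_ = labels
        self.cluster_centers_ = S / np.linalg.norm(S, axis=1, keepdims=True)
        self.n_iter_ = n_it
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Nearest-centroid symbols (0-based) under correlation distance."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.cluster_centers_.shape[1]:
            raise ValueError("feature dimension does not match fitted centroids")
        Z = _standardize_rows(X, self.zero_rows)
        return np.argmax(Z @ self.cluster_centers_.T, axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def kmeans_correlation(points, k, n_init=1000, max_iter=100, seed=None) -> CorrelationKMeans:
    """Functional-style wrapper over :class:`CorrelationKMeans`."""
    return CorrelationKMeans(
        n_clusters=k, n_init=n_init, max_iter=max_iter, random_state=seed
    ).fit(points)


def symbolize(features: WindowedNetworks, model: CorrelationKMeans) -> dict:
    """Per-condition symbol matrices (grouped trials x windows), symbols 1..k.

    Each window feature is assigned the symbol of its nearest centroid under
    correlation distance.
    """
    symbols = model.predict(features.V) + 1
    out = {}
    for label in features.index["condition"].unique():
        mask = (features.index["condition"] == label).to_numpy()
        sub = features.index[mask]
        n_groups = int(sub["grouped_trial"].max()) + 1
        S = np.zeros((n_groups, features.n_windows), dtype=int)
        S[sub["grouped_trial"].to_numpy(), sub["window"].to_numpy()] = symbols[mask]
        out[label] = S
    return out
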