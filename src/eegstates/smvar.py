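"""Sparse multivariate autoregressive (s-MVAR) network estimation.

An MVAR model of order ``p`` over ``m`` channels predicts each channel's
current sample from the ``p`` previous samples of all channels::

    y_i(t) = sum_j sum_k a_ij(k) y_j(t-k) + u_i(t)

Stacked as a multivariate regression ``Y = X A + U`` the coefficient matrix
``A`` has ``m*p`` rows (lag-major: lag-1 channels first, then lag-2, ...)
and ``m`` columns, one per target channel.  The sparse variant penalizes
each column's L1 norm, minimizing ``||y - X a||^2 + lam^2 * sum_j |a_j|``
(note the squared-``lam`` convention), which makes short-window estimation
feasible when the underlying network is sparse.  The lasso problem is
solved by Majorization-Minimization: the absolute value is majorized by a
quadratic at the current iterate, so each MM step is a reweighted ridge
solve and the objective never increases.

The sparsity level ``lam`` is chosen by generalized cross-validation
``GCV = RSS / (L - df)^2`` and the order by
``BIC = log(sigma) + (log(L) - 1) * df / L``, where ``L`` is the number of
response rows, ``df`` the number of nonzero coefficients and ``sigma`` the
pooled mean squared residual.

Windowed estimation pools a few consecutive trials per window: the w-th
window of each member trial is demeaned per channel and lagged separately,
and the lagged blocks are stacked, so no design row mixes samples from two
trials.  The resulting per-window network feature is the m x m matrix of
lag-averaged absolute coefficients, vectorized without its diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import TrialTensor

__all__ = [
    "MVARModel",
    "WindowSpec",
    "NetworkFeature",
    "WindowedNetworks",
    "SparseMVAR",
    "build_lagged_regression",
    "fit_ols",
    "fit_lasso_mm",
    "gcv_score",
    "bic_score",
    "select_lambda",
    "select_order",
    "network_from_coefficients",
    "window_networks",
]

#: values with absolute magnitude below this are treated as exact zeros
#: when counting degrees of freedom and reporting sparse coefficients
ZERO_TOL = 1e-6

#: guard on |a_j| in the reweighted-ridge surrogate, avoids division by zero
MM_EPS = 1e-8


@dataclass
class MVARModel:
    """Fitted (s-)MVAR coefficients.

    ``A`` is (m*p) x m, rows lag-major; ``A[(k-1)*m + j, i]`` is the
    influence of channel ``j``'s value ``k`` samples back on channel ``i``'s
    present value.
    """

    A: np.ndarray
    p: int
    m: int
    lam: float
    resid_var: np.ndarray

    def __post_init__(self) -> None:
        if self.A.shape != (self.m * self.p, self.m):
            raise ValueError("A must have shape (m*p, m)")
        if not 1 <= self.p <= 6:
            raise ValueError("order p must be in [1, 6]")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")


@dataclass
class WindowSpec:
    """Non-overlapping, left-aligned windowing with trial grouping."""

    width_samples: int
    group_size: int = 1

    def __post_init__(self) -> None:
        if self.width_samples < 2:
            raise ValueError("width_samples must be >= 2")
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")


@dataclass
class NetworkFeature:
    """Nonnegative m x m connection-strength matrix and its vectorization.

    ``W[i, j]`` is the mean over lags of ``|a_ij(k)|``; ``v`` is ``W``
    without the diagonal, row-major order of length m(m-1).
    """

    W: np.ndarray
    v: np.ndarray


def build_lagged_regression(
    segments: list[np.ndarray], p: int
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the pooled lagged design from per-trial window segments.

    Each segment is a (w, m) samples x channels block.  Per segment the
    channel means are removed, then rows ``p..w-1`` become responses and the
    design row at time t stacks ``y(t-1), ..., y(t-p)`` (lag-major).
    Segments contribute ``w - p`` rows each and are never mixed.
    """
    if not segments:
        raise ValueError("no segments given")
    m = segments[0].shape[1]
    xs, ys = [], []
    for s, seg in enumerate(segments):
        seg = np.asarray(seg, dtype=float)
        if seg.ndim != 2 or seg.shape[1] != m:
            raise ValueError(f"segment {s} has inconsistent channel count")
        w = seg.shape[0]
        if w < p + 1:
            raise ValueError(f"segment {s} has {w} samples, need at least p+1={p + 1}")
        seg = seg - seg.mean(axis=0, keepdims=True)
        ys.append(seg[p:])
        xs.append(np.hstack([seg[p - k : w - k] for k in range(1, p + 1)]))
    return np.vstack(xs), np.vstack(ys)


def fit_ols(X: np.ndarray, Yt: np.ndarray) -> np.ndarray:
    """Column-wise least-squares fit of Y = X A."""
    X = np.asarray(X, dtype=float)
    Yt = np.asarray(Yt, dtype=float)
    G = X.T @ X
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient; use a sparsity penalty (lam > 0)"
        )
    return np.linalg.solve(G, X.T @ Yt)


def _lasso_objective(G, C, yty, A, lam):
    """Per-column objective ||y - X a||^2 + lam^2 * ||a||_1 (vector, one per column)."""
    rss = yty - 2.0 * np.einsum("qm,qm->m", A, C) + np.einsum("qm,qr,rm->m", A, G, A)
    return rss + lam**2 * np.abs(A).sum(axis=0)


def fit_lasso_mm(
    X: np.ndarray,
    Yt: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_iter: int = 500,
    return_info: bool = False,
):
    """L1-penalized fit via Majorization-Minimization (reweighted ridge).

    Minimizes ``||y - X a||^2 + lam^2 * sum |a_j|`` per column of ``Yt``.
    At ``lam = 0`` this reduces to :func:`fit_ols`.  Convergence is a
    relative objective change below ``tol``; non-convergence within
    ``max_iter`` emits a warning and returns the current iterate.

    With ``return_info=True`` returns ``(A, info)`` where ``info`` carries
    ``converged``, ``n_iter`` and the per-iteration total objective.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if tol <= 0:
        raise ValueError("tol must be positive")
    X = np.asarray(X, dtype=float)
    Yt = np.asarray(Yt, dtype=float)
    if lam == 0:
        A = fit_ols(X, Yt)
        if return_info:
            G = X.T @ X
            C = X.T @ Yt
            yty = np.einsum("nm,nm->m", Yt, Yt)
            obj = float(_lasso_objective(G, C, yty, A, 0.0).sum())
            return A, {"converged": True, "n_iter": 0, "objective": [obj]}
        return A

    n, q = X.shape
    m = Yt.shape[1]
    G = X.T @ X
    C = X.T @ Yt
    yty = np.einsum("nm,nm->m", Yt, Yt)

    # ridge warm start keeps the first surrogate well conditioned
    A = np.linalg.solve(G + (lam**2 / 2.0) * np.eye(q), C)
    obj = _lasso_objective(G, C, yty, A, lam)
    history = [float(obj.sum())]
    active = np.ones(m, dtype=bool)
    support = np.abs(A) > ZERO_TOL
    stable = np.zeros(m, dtype=int)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        idx = np.nonzero(active)[0]
        w = lam**2 / (2.0 * np.maximum(np.abs(A[:, idx]), MM_EPS))  # (q, n_active)
        lhs = np.broadcast_to(G, (idx.size, q, q)).copy()
        lhs[:, np.arange(q), np.arange(q)] += w.T
        A_new = np.linalg.solve(lhs, C[:, idx].T[:, :, None])[:, :, 0].T
        delta = np.abs(A_new - A[:, idx]).max(axis=0)
        A[:, idx] = A_new
        new_obj = _lasso_objective(G, C, yty, A, lam)
        rel = np.abs(obj[idx] - new_obj[idx]) / np.maximum(np.abs(obj[idx]), 1e-300)
        new_support = np.abs(A[:, idx]) > ZERO_TOL
        same = (new_support == support[:, idx]).all(axis=0)
        stable[idx] = np.where(same, stable[idx] + 1, 0)
        support[:, idx] = new_support
        # a flat objective alone is not enough near the soft threshold: the
        # iterates must have settled, or the support must have stabilized
        # (the KKT polish below then resolves the coefficients exactly)
        active[idx[(rel < tol) & ((delta < tol) | (stable[idx] >= 5))]] = False
        obj = new_obj
        history.append(float(obj.sum()))
        if not active.any():
            break
    converged = not active.any()
    if not converged:
        warnings.warn(
            f"MM lasso did not converge in {max_iter} iterations", RuntimeWarning
        )
    A[np.abs(A) < ZERO_TOL] = 0.0
    # active-set polish: with the support and signs fixed, the stationarity
    # condition G_AA a_A = c_A - (lam^2/2) sign(a_A) is linear; solving it
    # removes the residual creep of the majorization iterates
    for col in range(m):
        sup = np.nonzero(A[:, col])[0]
        for _ in range(25):
            if sup.size:
                s = np.sign(A[sup, col])
                try:
                    a = np.linalg.solve(
                        G[np.ix_(sup, sup)], C[sup, col] - (lam**2 / 2.0) * s
                    )
                except np.linalg.LinAlgError:
                    break
                flipped = np.sign(a) != s
                if flipped.any():
                    # entries the stationarity solve pushes through zero
                    # belong out of the support; drop them and re-solve
                    A[sup[flipped], col] = 0.0
                    keep = ~flipped
                    A[sup[keep], col] = a[keep]
                    sup = sup[keep]
                    continue
                A[sup, col] = a
            # inactive coordinates must satisfy |2 (G a - c)_j| <= lam^2;
            # pull the worst violator into the support
            g = 2.0 * (G @ A[:, col] - C[:, col])
            viol = np.abs(g) - lam**2
            viol[sup] = -np.inf
            j = int(np.argmax(viol))
            if viol[j] <= 1e-10 * max(lam**2, 1.0):
                break
            A[j, col] = -np.sign(g[j]) * MM_EPS
            sup = np.sort(np.append(sup, j))
    if return_info:
        return A, {"converged": converged, "n_iter": n_iter, "objective": history}
    return A


def gcv_score(RSS: float, L: int, df: int) -> float:
    """Generalized cross-validation, RSS / (L - df)^2."""
    if L <= df:
        raise ValueError(f"GCV undefined: L={L} <= df={df}")
    return RSS / (L - df) ** 2


def bic_score(sigma: float, L: int, df: int) -> float:
    """Bayesian information criterion, log(sigma) + (log(L) - 1) * df / L."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if L <= 0:
        raise ValueError("L must be positive")
    return float(np.log(sigma) + (np.log(L) - 1.0) * df / L)


def default_lambda_grid(n: int = 30, lo: float = 0.01, hi: float = 100.0) -> np.ndarray:
    """Log-spaced candidate sparsity levels."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def _rss(X, Yt, A) -> float:
    R = Yt - X @ A
    return float(np.sum(R * R))


def _df(A) -> int:
    return int(np.count_nonzero(np.abs(A) > ZERO_TOL))


def select_lambda(
    windows: list[list[np.ndarray]],
    grid: np.ndarray,
    p: int,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> float:
    """Pick the sparsity level by GCV on a sample of windows.

    ``windows`` is a list of windows, each a list of per-trial segments.
    For each window, models are fitted over the grid and the GCV-minimizing
    lambda retained; the mean of the per-window winners is returned.

    Estimation is column-wise (one penalized regression per target
    channel), so the GCV of a window sums the per-column scores with the
    per-column degrees of freedom (nonzero-coefficient count, the standard
    lasso df estimator).  Grid points where any column has df >= L are
    invalid.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be sorted ascending")
    winners = []
    for segs in windows:
        X, Yt = build_lagged_regression(segs, p)
        L = X.shape[0]
        best_lam, best_score = None, np.inf
        for lam in grid:
            try:
                A = fit_lasso_mm(X, Yt, lam, tol=tol, max_iter=max_iter)
            except np.linalg.LinAlgError:
                continue
            R = Yt - X @ A
            rss_col = (R * R).sum(axis=0)
            df_col = (np.abs(A) > ZERO_TOL).sum(axis=0)
            if np.any(df_col >= L):
                continue
            score = float(sum(gcv_score(r, L, d) for r, d in zip(rss_col, df_col)))
            if score < best_score:
                best_lam, best_score = lam, score
        if best_lam is not None:
            winners.append(best_lam)
    if not winners:
        raise RuntimeError("lambda selection failed on every sampled window")
    return float(np.mean(winners))


def select_order(
    windows: list[list[np.ndarray]],
    lam: float,
    p_range: range = range(1, 7),
    tol: float = 1e-6,
    max_iter: int = 500,
) -> int:
    """Pick the model order by per-window BIC, modal across windows.

    ``sigma`` is the pooled mean squared residual across channels and the
    degrees of freedom are the mean per-column nonzero count (estimation is
    column-wise).  Ties in the mode go to the smallest order.
    """
    p_list = list(p_range)
    winners = []
    for segs in windows:
        best_p, best_score = None, np.inf
        for p in p_list:
            try:
                X, Yt = build_lagged_regression(segs, p)
                A = fit_lasso_mm(X, Yt, lam, tol=tol, max_iter=max_iter)
            except (ValueError, np.linalg.LinAlgError):
                continue
            L = X.shape[0]
            sigma = _rss(X, Yt, A) / (L * Yt.shape[1])
            if sigma <= 0:
                continue
            score = bic_score(sigma, L, _df(A) / Yt.shape[1])
            if score < best_score:
                best_p, best_score = p, score
        if best_p is not None:
            winners.append(best_p)
    if not winners:
        raise RuntimeError("order selection failed on every sampled window")
    counts = np.bincount(winners, minlength=max(p_list) + 1)
    return int(np.argmax(counts))  # argmax returns the smallest order on ties


def network_from_coefficients(model: MVARModel) -> NetworkFeature:
    """Lag-averaged absolute coefficients as a network feature.

    ``W[i, j] = mean_k |a_ij(k)|``; the vectorization ``v`` drops the
    diagonal and runs row-major.
    """
    m, p = model.m, model.p
    stacked = model.A.reshape(p, m, m)  # stacked[k, j, i] = a_ij(k+1)
    W = np.abs(stacked).mean(axis=0).T
    v = W[~np.eye(m, dtype=bool)]
    return NetworkFeature(W=W, v=v)


@dataclass
class WindowedNetworks:
    """Per-window network features over grouped trials and conditions.

    ``V`` stacks the off-diagonal vectorizations (one row per feature);
    ``index`` records (condition, grouped_trial, window) per row in the
    same order.
    """

    V: np.ndarray
    index: pd.DataFrame
    m: int
    n_windows: int
    groups_per_condition: dict = field(default_factory=dict)

    def condition_block(self, label) -> np.ndarray:
        mask = (self.index["condition"] == label).to_numpy()
        return self.V[mask]


class SparseMVAR(BaseEstimator):
    """Sparse MVAR estimator over pooled window segments.

    scikit-learn-style wrapper around :func:`fit_lasso_mm`.

    Parameters
    ----------
    p : int
        Model order (lags), 1-6.
    lam : float
        Sparsity level; 0 gives ordinary least squares.
    tol, max_iter :
        MM convergence controls.

    Attributes
    ----------
    coef_ : ndarray, (m*p, m)
        Lag-major coefficient matrix.
    resid_var_ : ndarray, (m,)
        Per-channel residual variances.
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, p: int = 1, lam: float = 0.0, tol: float = 1e-6, max_iter: int = 500):
        self.p = p
        self.lam = lam
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        """Fit from a list of (w, m) segments (or a single 2-D array)."""
        segments = [X] if isinstance(X, np.ndarray) and X.ndim == 2 else list(X)
        Xd, Yt = build_lagged_regression(segments, self.p)
        A, info = fit_lasso_mm(
            Xd, Yt, self.lam, tol=self.tol, max_iter=self.max_iter, return_info=True
        )
        R = Yt - Xd @ A
        self.coef_ = A
        self.resid_var_ = (R * R).mean(axis=0)
        self.n_iter_ = info["n_iter"]
        self.converged_ = info["converged"]
        self.n_features_in_ = Yt.shape[1]
        return self

    def model_(self) -> MVARModel:
        return MVARModel(
            A=self.coef_, p=self.p, m=self.n_features_in_, lam=self.lam,
            resid_var=self.resid_var_,
        )

    def network_(self) -> NetworkFeature:
        return network_from_coefficients(self.model_())


def _grouped_trial_indices(n_trials: int, group_size: int) -> list[np.ndarray]:
    n_groups = n_trials // group_size
    return [np.arange(g * group_size, (g + 1) * group_size) for g in range(n_groups)]


def window_networks(
    t: TrialTensor,
    spec: WindowSpec,
    lam: float,
    p: int,
    tol: float = 1e-6,
    max_iter: int = 500,
    logger=None,
) -> WindowedNetworks:
    """Estimate one network feature per (condition, grouped trial, window).

    Consecutive trials of each condition are grouped ``group_size`` at a
    time (trailing trials that do not fill a group are dropped); window ``w``
    of a group pools the w-th window of every member trial.
    """
    width = spec.width_samples
    if width <= p:
        raise ValueError("window width must exceed model order")
    n_windows = t.n_samples // width
    if n_windows < 1:
        raise ValueError("window wider than trial")
    rows, recs = [], []
    groups_per_condition = {}
    for label in t.conditions():
        block = t.select_condition(label)  # (m, n, d_c)
        d_c = block.shape[2]
        groups = _grouped_trial_indices(d_c, spec.group_size)
        if not groups:
            raise ValueError(
                f"condition {label!r} has {d_c} trials, fewer than one group of "
                f"{spec.group_size}"
            )
        dropped = d_c - len(groups) * spec.group_size
        if dropped and logger is not None:
            logger.info("condition %r: dropped %d trailing trials", label, dropped)
        groups_per_condition[label] = len(groups)
        for g, members in enumerate(groups):
            for w in range(n_windows):
                segs = [
                    block[:, w * width : (w + 1) * width, j].T for j in members
                ]
                X, Yt = build_lagged_regression(segs, p)
                A = fit_lasso_mm(X, Yt, lam, tol=tol, max_iter=max_iter)
                model = MVARModel(A=A, p=p, m=t.n_channels, lam=lam,
                                  resid_var=((Yt - X @ A) ** 2).mean(axis=0))
                rows.append(network_from_coefficients(model).v)
                recs.append((label, g, w))
    index = pd.DataFrame(recs, columns=["condition", "grouped_trial", "window"])
    return WindowedNetworks(
        V=np.vstack(rows), index=index, m=t.n_channels, n_windows=n_windows,
        groups_per_condition=groups_per_condition,
    )


def sample_windows(
    t: TrialTensor, spec: WindowSpec, fraction: float, rng: np.random.Generator
) -> list[list[np.ndarray]]:
    """Randomly sample a fraction of (condition, group, window) cells.

    Returns segment lists suitable for :func:`select_lambda` /
    :func:`select_order`.  At least one window is always returned.
    """
    width = spec.width_samples
    n_windows = t.n_samples // width
    cells = []
    for label in t.conditions():
        block = t.select_condition(label)
        for members in _grouped_trial_indices(block.shape[2], spec.group_size):
            for w in range(n_windows):
                cells.append((block, members, w))
    n_pick = max(1, int(round(fraction * len(cells))))
    picks = rng.choice(len(cells), size=min(n_pick, len(cells)), replace=False)
    out = []
    for i in sorted(picks):
        block, members, w = cells[i]
        out.append([block[:, w * width : (w + 1) * width, j].T for j in members])
    return out
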