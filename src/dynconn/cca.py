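"""Canonical correlation between dFC edge features and clinical measures.

Because the number of edges in an identified component typically exceeds
the number of subjects, X (subjects x edges) is first reduced by principal
components to ``reduction_rank`` (default min(n // 10, 30)); the first
canonical pair between the reduced X and the clinical matrix Y is then
computed in closed form (QR of both blocks, SVD of Q_x' Q_y).  Inference is
nonparametric: the rows of Y are shuffled (the X reduction is unchanged)
and the null distribution of the first canonical correlation gives
perm_p = (1 + #{null >= observed}) / (1 + n_perm).  Out-of-sample validity
is assessed with k-fold cross-validation: the model is fit on training
folds, held-out subjects are projected onto the trained variates, pooled
held-out score pairs give cv_r, and the whole CV loop is re-run on
row-shuffled Y for cv_perm_p.

Signs of a canonical pair are arbitrary; they are fixed so that the
connectivity variate correlates non-negatively with the first principal
component of X, and loadings are reported under that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold

from ._utils import check_random_state

__all__ = [
    "PermutationCCA",
    "CCAResult",
    "fit_cca",
    "cca_permutation",
    "cca_cross_validation",
    "canonical_loadings",
    "network_edge_means",
]


@dataclass
class CCAResult:
    canonical_r: float
    x_scores: np.ndarray
    y_scores: np.ndarray
    x_loadings: np.ndarray      # correlations of X columns with x_scores
    y_loadings: np.ndarray      # correlations of Y columns with y_scores
    reduction_rank: int
    higher_r: np.ndarray = field(default_factory=lambda: np.array([]))
    perm_p: float | None = None
    cv_r: float | None = None
    cv_perm_p: float | None = None
    n_perm: int | None = None
    seed: int | None = None


def _first_canonical(Xc: np.ndarray, Yc: np.ndarray):
    """First canonical pair of two centered blocks via QR + SVD.

    Returns (r, wx, wy, higher_r); weights act on the centered blocks.
    """
    qx, rx = np.linalg.qr(Xc)
    qy, ry = np.linalg.qr(Yc)
    if (np.abs(np.diag(rx)) < 1e-10 * max(1.0, np.abs(rx).max())).any() or \
       (np.abs(np.diag(ry)) < 1e-10 * max(1.0, np.abs(ry).max())).any():
        raise ValueError("rank-deficient block after reduction")
    u, s, vt = np.linalg.svd(qx.T @ qy)
    r_all = np.clip(s, 0.0, 1.0)
    wx = np.linalg.solve(rx, u[:, 0])
    wy = np.linalg.solve(ry, vt[0])
    return float(r_all[0]), wx, wy, r_all[1:]


class PermutationCCA(BaseEstimator):
    """First canonical pair with permutation inference and k-fold CV.

    Parameters
    ----------
    reduction_rank : int or None
        PCA rank for X before CCA; None means min(n // 10, 30), capped at
        min(n - 1, n_features).
    n_perm : int
        Permutations for the in-sample test (study default 10000).
    cv : int
        Folds for cross-validated prediction (study default 5).
    n_perm_cv : int
        Permutations for the CV null (each re-runs the whole CV loop).
    standardize : bool
        Z-score columns of X and Y before fitting.
    random_state : int or Generator, optional

    Fitted attributes: ``canonical_r_``, ``x_scores_``, ``y_scores_``,
    ``x_loadings_``, ``y_loadings_``, ``perm_p_``, ``cv_r_``,
    ``cv_perm_p_``, ``reduction_rank_``, ``n_dropped_``.
    """

    def __init__(self, reduction_rank: int | None = None, n_perm: int = 10000,
                 cv: int = 5, n_perm_cv: int = 1000, standardize: bool = True,
                 run_cv: bool = True, random_state=None):
        self.reduction_rank = reduction_rank
        self.n_perm = n_perm
        self.cv = cv
        self.n_perm_cv = n_perm_cv
        self.standardize = standardize
        self.run_cv = run_cv
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _prep(self, M: np.ndarray, mean=None, sd=None):
        if mean is None:
            mean = M.mean(axis=0)
            sd = M.std(axis=0, ddof=0)
            sd = np.where(sd > 0, sd, 1.0)
        Mc = M - mean
        if self.standardize:
            Mc = Mc / sd
        return Mc, mean, sd

    @staticmethod
    def _pca_basis(Xc: np.ndarray, rank: int) -> np.ndarray:
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        return vt[:rank].T        # features x rank

    def _fit_pair(self, X: np.ndarray, Y: np.ndarray, rank: int):
        """Fit PCA reduction + CCA; returns a projection closure and scores."""
        Xc, xm, xs = self._prep(X)
        Yc, ym, ys = self._prep(Y)
        V = self._pca_basis(Xc, rank)
        Xr = Xc @ V
        r, wx, wy, higher = _first_canonical(Xr, Yc)
        # sign convention: x variate correlates non-negatively with PC1 of X
        if np.corrcoef(Xr[:, 0], Xr @ wx)[0, 1] < 0:
            wx, wy = -wx, -wy

        def project(Xnew, Ynew):
            Xn = Xnew - xm
            Yn = Ynew - ym
            if self.standardize:
                Xn, Yn = Xn / xs, Yn / ys
            return (Xn @ V) @ wx, Yn @ wy

        return r, higher, project, Xr @ wx, Yc @ wy

    # -- main fit ----------------------------------------------------------

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        keep = ~(np.isnan(X).any(axis=1) | np.isnan(Y).any(axis=1))
        self.n_dropped_ = int((~keep).sum())
        X, Y = X[keep], Y[keep]
        n = X.shape[0]
        if n <= Y.shape[1]:
            raise ValueError("need more subjects than clinical measures")
        rank = self.reduction_rank
        if rank is None:
            rank = max(1, min(n // 10, 30))
        rank = min(rank, n - 1, X.shape[1])
        self.reduction_rank_ = rank
        rng = check_random_state(self.random_state)

        r, higher, project, xs_, ys_ = self._fit_pair(X, Y, rank)
        self.canonical_r_ = r
        self.higher_r_ = higher
        self.x_scores_ = xs_
        self.y_scores_ = ys_
        self.x_loadings_ = _col_corr(X, xs_)
        self.y_loadings_ = _col_corr(Y, ys_)

        # permutation test: shuffle rows of Y, X reduction unchanged
        Xc, _, _ = self._prep(X)
        V = self._pca_basis(Xc, rank)
        Xr = Xc @ V
        null = np.empty(self.n_perm)
        for b in range(self.n_perm):
            Yp = Y[rng.permutation(n)]
            Yc, _, _ = self._prep(Yp)
            null[b] = _first_canonical(Xr, Yc)[0]
        self.perm_p_ = (1.0 + float((null >= r).sum())) / (1.0 + self.n_perm)

        if self.run_cv:
            cv_seed = int(rng.integers(0, 2**31 - 1))
            self.cv_r_ = self._cv_r(X, Y, rank, cv_seed)
            null_cv = np.empty(self.n_perm_cv)
            for b in range(self.n_perm_cv):
                Yp = Y[rng.permutation(n)]
                null_cv[b] = self._cv_r(X, Yp, rank, cv_seed)
            self.cv_perm_p_ = (1.0 + float((null_cv >= self.cv_r_).sum())) \
                / (1.0 + self.n_perm_cv)
        else:
            self.cv_r_ = None
            self.cv_perm_p_ = None
        return self

    def _cv_r(self, X: np.ndarray, Y: np.ndarray, rank: int,
              seed: int) -> float:
        n = X.shape[0]
        kf = KFold(n_splits=self.cv, shuffle=True, random_state=seed)
        xs_pool, ys_pool = [], []
        for train, test in kf.split(X):
            if len(train) < Y.shape[1] + 2:
                raise ValueError("cross-validation fold too small")
            fold_rank = min(rank, len(train) - 1)
            _, _, project, _, _ = self._fit_pair(X[train], Y[train], fold_rank)
            xs_t, ys_t = project(X[test], Y[test])
            xs_pool.append(xs_t)
            ys_pool.append(ys_t)
        xs_pool = np.concatenate(xs_pool)
        ys_pool = np.concatenate(ys_pool)
        return float(np.corrcoef(xs_pool, ys_pool)[0, 1])

    def result_(self) -> CCAResult:
        return CCAResult(
            canonical_r=self.canonical_r_, x_scores=self.x_scores_,
            y_scores=self.y_scores_, x_loadings=self.x_loadings_,
            y_loadings=self.y_loadings_, reduction_rank=self.reduction_rank_,
            higher_r=self.higher_r_, perm_p=self.perm_p_, cv_r=self.cv_r_,
            cv_perm_p=self.cv_perm_p_, n_perm=self.n_perm,
            seed=self.random_state if isinstance(self.random_state, int)
            else None)


def _col_corr(M: np.ndarray, v: np.ndarray) -> np.ndarray:
    Mc = M - M.mean(axis=0)
    vc = v - v.mean()
    denom = np.sqrt((Mc ** 2).sum(axis=0) * (vc ** 2).sum())
    denom = np.where(denom > 0, denom, 1.0)
    return (Mc.T @ vc) / denom


# -- functional wrappers ----------------------------------------------------

def fit_cca(X, Y, reduction_rank: int | None = None,
            standardize: bool = True) -> CCAResult:
    """First canonical pair only (no permutation or CV fields)."""
    est = PermutationCCA(reduction_rank=reduction_rank, n_perm=100,
                         run_cv=False, standardize=standardize,
                         random_state=0)
    # skip the permutation loop: fit manually
    est.n_perm = 100
    est.fit_minimal_ = True
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    keep = ~(np.isnan(X).any(axis=1) | np.isnan(Y).any(axis=1))
    X, Y = X[keep], Y[keep]
    n = X.shape[0]
    rank = reduction_rank
    if rank is None:
        rank = max(1, min(n // 10, 30))
    rank = min(rank, n - 1, X.shape[1])
    r, higher, _, xs_, ys_ = est._fit_pair(X, Y, rank)
    return CCAResult(canonical_r=r, x_scores=xs_, y_scores=ys_,
                     x_loadings=_col_corr(X, xs_), y_loadings=_col_corr(Y, ys_),
                     reduction_rank=rank, higher_r=higher)


def cca_permutation(X, Y, reduction_rank: int | None = None,
                    n_perm: int = 10000, seed=None) -> float:
    est = PermutationCCA(reduction_rank=reduction_rank, n_perm=n_perm,
                         run_cv=False, random_state=seed)
    est.fit(X, Y)
    return est.perm_p_


def cca_cross_validation(X, Y, reduction_rank: int | None = None, k: int = 5,
                         n_perm: int = 1000, seed=None):
    est = PermutationCCA(reduction_rank=reduction_rank, n_perm=100, cv=k,
                         n_perm_cv=n_perm, run_cv=True, random_state=seed)
    est.fit(X, Y)
    return est.cv_r_, est.cv_perm_p_


# -- loadings against network-level summaries --------------------------------

def network_edge_means(delta: np.ndarray, edge_index, atlas: pd.DataFrame,
                       networks=None) -> pd.DataFrame:
    """Per-subject mean dFC over edges incident to each canonical network."""
    from .networks import CANONICAL_NETWORKS

    net_of = dict(zip(atlas["region_id"].astype(int), atlas["network"]))
    nets = list(networks) if networks is not None else \
        [n for n in CANONICAL_NETWORKS if n in set(atlas["network"])] or \
        sorted(set(atlas["network"]))
    delta = np.asarray(delta, dtype=float)
    cols = {}
    for net in nets:
        mask = np.array([net_of[i] == net or net_of[j] == net
                         for (i, j) in edge_index])
        cols[net] = delta[:, mask].mean(axis=1) if mask.any() \
            else np.zeros(delta.shape[0])
    return pd.DataFrame(cols)


def canonical_loadings(result: CCAResult, delta: np.ndarray, edge_index,
                       atlas: pd.DataFrame, clinical: pd.DataFrame):
    """Clinical-side and network-side canonical loadings.

    y loadings: correlation of each clinical column with the clinical
    variate.  x loadings: correlation of each subject's mean dFC over edges
    incident to each of the 8 networks with the connectivity variate.
    """
    net_means = network_edge_means(delta, edge_index, atlas)
    x_load = pd.Series(
        {net: float(_col_corr(net_means[[net]].to_numpy(), result.x_scores)[0])
         for net in net_means.columns}, name="loading")
    y_load = pd.Series(
        {col: float(_col_corr(clinical[[col]].to_numpy(dtype=float),
                              result.y_scores)[0])
         for col in clinical.columns}, name="loading")
    return y_load, x_load
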