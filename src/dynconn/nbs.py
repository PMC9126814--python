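"""Edgewise group inference and the Network-Based Statistic (NBS).

Edgewise model: ordinary least squares of each edge's dFC on
[intercept, group indicator, age, sex]; the group coefficient's t statistic
(df = n - 4) is the edge statistic.  NBS then thresholds edges at a primary
p (default 0.001, directional), takes connected components of the
supra-threshold graph over regions, and calibrates the maximal component
size (edge count) against a permutation null in which group labels are
exchanged across subjects while covariates stay attached; the family-wise
p of a component is (1 + #{null >= observed}) / (1 + n_perm).  When the
label-assignment space is smaller than ``n_perm`` the null is enumerated
exactly (p = #{null >= observed} / n_assignments, the observed assignment
included).

A continuous covariate-of-interest variant (t on the slope of a per-subject
predictor, permutation by shuffling the predictor) supports cross-phase
designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._utils import check_random_state

__all__ = [
    "GroupDesign",
    "EdgeStatMap",
    "NBSResult",
    "NetworkBasedStatistic",
    "edgewise_glm",
    "nbs",
    "component_level_ttest",
]


@dataclass
class GroupDesign:
    """Subject-level design: group labels plus age/sex nuisance covariates."""

    subject_id: list[str]
    group: np.ndarray
    age: np.ndarray
    sex: np.ndarray

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GroupDesign":
        for col in ("subject_id", "group", "age", "sex"):
            if col not in frame.columns:
                raise ValueError(f"design table lacks column {col!r}")
        if frame[["age", "sex"]].isna().any().any():
            raise ValueError("missing covariate values")
        return cls(subject_id=list(frame["subject_id"]),
                   group=frame["group"].to_numpy(),
                   age=frame["age"].to_numpy(dtype=float),
                   sex=frame["sex"].to_numpy(dtype=float))

    def subset(self, groups) -> "GroupDesign":
        mask = np.isin(self.group, list(groups))
        return GroupDesign(
            subject_id=[s for s, m in zip(self.subject_id, mask) if m],
            group=self.group[mask], age=self.age[mask], sex=self.sex[mask])


@dataclass
class EdgeStatMap:
    t: np.ndarray
    p: np.ndarray          # two-sided
    df: int
    contrast: tuple[str, str]


@dataclass
class NBSResult:
    components: list[dict]          # {"edges": [(i,j)...], "size": int, "p_fwe": float, "t": [...]}
    null_max_sizes: np.ndarray
    threshold_p: float
    n_perm: int
    direction: str
    exact: bool = False
    edge_stats: EdgeStatMap | None = None

    @property
    def significant(self) -> list[dict]:
        return [c for c in self.components if c["p_fwe"] < 0.05]


def _full_edge_index(m: int):
    """Upper-triangle edge index implied by a full R(R-1)/2 edge vector."""
    from ._utils import upper_edge_index

    R = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if R * (R - 1) // 2 != m:
        raise ValueError(
            f"{m} edges is not a full upper triangle; pass edge_index "
            f"explicitly for partial edge sets")
    return upper_edge_index(R)


def _design_matrix(indicator: np.ndarray, age: np.ndarray,
                   sex: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(age), indicator, age, sex])


def _ols_t(D: np.ndarray, Y: np.ndarray, coef: int = 1):
    """t statistics of one coefficient across many responses (columns of Y)."""
    n, p = D.shape
    DtD = D.T @ D
    try:
        DtD_inv = np.linalg.inv(DtD)
    except np.linalg.LinAlgError:
        raise ValueError("collinear design matrix") from None
    # guard near-collinearity (inv succeeds numerically but is meaningless)
    if np.linalg.cond(DtD) > 1e12:
        raise ValueError("collinear design matrix (condition number too large)")
    beta = DtD_inv @ (D.T @ Y)
    resid = Y - D @ beta
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(np.maximum(sigma2 * DtD_inv[coef, coef], 1e-300))
    return beta[coef] / se, df


def edgewise_glm(delta: np.ndarray, design: GroupDesign,
                 contrast: tuple[str, str]) -> EdgeStatMap:
    """Per-edge OLS of dFC on [intercept, group, age, sex].

    ``delta`` is subjects x edges; ``contrast = (A, B)`` codes group A as 1
    and B as 0, so positive t means A > B.
    """
    a, b = contrast
    mask = np.isin(design.group, [a, b])
    if mask.sum() != len(design.group):
        raise ValueError("design contains subjects outside the contrast groups")
    for g in contrast:
        if (design.group == g).sum() < 2:
            raise ValueError(f"fewer than 2 subjects in group {g!r}")
    indicator = (design.group == a).astype(float)
    D = _design_matrix(indicator, design.age, design.sex)
    t, df = _ols_t(D, np.asarray(delta, dtype=float))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return EdgeStatMap(t=t, p=p, df=df, contrast=contrast)


def _components_from_edges(edge_ids: np.ndarray, edge_i: np.ndarray,
                           edge_j: np.ndarray):
    """Connected components (lists of edge ids) of a supra-threshold graph,
    via union-find over region endpoints."""
    parent: dict[int, int] = {}

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for e in edge_ids:
        i, j = int(edge_i[e]), int(edge_j[e])
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for e in edge_ids:
        groups.setdefault(find(int(edge_i[e])), []).append(int(e))
    return list(groups.values())


def _max_component_size(t_null: np.ndarray, t_crit: float, edge_i, edge_j) -> int:
    supra = np.flatnonzero(t_null > t_crit)
    if supra.size == 0:
        return 0
    comps = _components_from_edges(supra, edge_i, edge_j)
    return max(len(c) for c in comps)


class NetworkBasedStatistic(BaseEstimator):
    """Family-wise-error-controlled component detection on edge statistics.

    Parameters
    ----------
    threshold_p : float
        Primary component-forming threshold on the directional edge p.
    n_perm : int
        Number of label permutations (exact enumeration is used instead
        whenever the assignment space is smaller).
    direction : {"greater", "less", "two-sided"}
        "greater" finds components where the first contrast group (or a
        positive slope for continuous predictors) exceeds the second.
    component_stat : {"extent", "intensity"}
        Component statistic: edge count, or summed |t| over edges.
    random_state : int or Generator, optional
    """

    def __init__(self, threshold_p: float = 0.001, n_perm: int = 5000,
                 direction: str = "greater", component_stat: str = "extent",
                 random_state=None):
        self.threshold_p = threshold_p
        self.n_perm = n_perm
        self.direction = direction
        self.component_stat = component_stat
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _signed_t(self, t: np.ndarray) -> np.ndarray:
        if self.direction == "greater":
            return t
        if self.direction == "less":
            return -t
        return np.abs(t)

    def _t_crit(self, df: int) -> float:
        if self.direction == "two-sided":
            return float(stats.t.isf(self.threshold_p / 2.0, df))
        return float(stats.t.isf(self.threshold_p, df))

    def _fit_engine(self, Y: np.ndarray, make_design, n_regions: int,
                    edge_index, contrast) -> "NetworkBasedStatistic":
        if not (0 < self.threshold_p < 1):
            raise ValueError("threshold_p must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        edge_i = np.array([e[0] for e in edge_index])
        edge_j = np.array([e[1] for e in edge_index])

        D0, perm_iter, exact, n_null = make_design()
        t_obs, df = _ols_t(D0, Y)
        self.edge_stats_ = EdgeStatMap(
            t=t_obs, p=2.0 * stats.t.sf(np.abs(t_obs), df), df=df,
            contrast=contrast)
        t_crit = self._t_crit(df)
        signed = self._signed_t(t_obs)
        supra = np.flatnonzero(signed > t_crit)
        comps = _components_from_edges(supra, edge_i, edge_j)

        def stat(edge_ids):
            if self.component_stat == "intensity":
                return float(np.abs(t_obs[edge_ids]).sum())
            return float(len(edge_ids))

        null = np.empty(n_null)
        for b, D in enumerate(perm_iter()):
            t_b, _ = _ols_t(D, Y)
            s_b = self._signed_t(t_b)
            if self.component_stat == "intensity":
                sup = np.flatnonzero(s_b > t_crit)
                if sup.size == 0:
                    null[b] = 0.0
                else:
                    cs = _components_from_edges(sup, edge_i, edge_j)
                    null[b] = max(float(np.abs(t_b[c]).sum()) for c in cs)
            else:
                null[b] = _max_component_size(s_b, t_crit, edge_i, edge_j)

        components = []
        for c in sorted(comps, key=len, reverse=True):
            obs = stat(np.array(c, dtype=int))
            if exact:
                p_fwe = float((null >= obs).sum()) / n_null
            else:
                p_fwe = (1.0 + float((null >= obs).sum())) / (1.0 + n_null)
            components.append({
                "edges": [(int(edge_i[e]), int(edge_j[e])) for e in c],
                "size": len(c),
                "stat": obs,
                "p_fwe": p_fwe,
                "t": t_obs[np.array(c, dtype=int)].tolist(),
            })
        self.components_ = components
        self.null_max_sizes_ = null
        self.exact_ = exact
        self.df_ = df
        return self

    # -- public fits -------------------------------------------------------

    def fit(self, delta: np.ndarray, design: GroupDesign,
            contrast: tuple[str, str], edge_index=None):
        """Group-difference NBS on a subjects x edges dFC matrix."""
        Y = np.asarray(delta, dtype=float)
        if edge_index is None:
            edge_index = _full_edge_index(Y.shape[1])
        a, b = contrast
        indicator = (design.group == a).astype(float)
        n = len(indicator)
        n_a = int(indicator.sum())
        rng = check_random_state(self.random_state)

        from math import comb
        n_assign = comb(n, n_a)

        def make_design():
            D0 = _design_matrix(indicator, design.age, design.sex)
            if n_assign <= self.n_perm:
                def perm_iter():
                    for rows in combinations(range(n), n_a):
                        ind = np.zeros(n)
                        ind[list(rows)] = 1.0
                        yield _design_matrix(ind, design.age, design.sex)
                return D0, perm_iter, True, n_assign
            def perm_iter():
                for _ in range(self.n_perm):
                    ind = indicator[rng.permutation(n)]
                    yield _design_matrix(ind, design.age, design.sex)
            return D0, perm_iter, False, self.n_perm

        n_regions = max(max(e) for e in edge_index) + 1
        return self._fit_engine(Y, make_design, n_regions, edge_index, contrast)

    def fit_continuous(self, predictor: np.ndarray, edge_fc: np.ndarray,
                       design: GroupDesign, edge_index=None):
        """NBS with a continuous covariate of interest.

        The edge statistic is the t of the per-subject ``predictor`` slope in
        OLS of each edge on [intercept, predictor, age, sex]; the null
        shuffles the predictor across subjects.
        """
        Y = np.asarray(edge_fc, dtype=float)
        x = np.asarray(predictor, dtype=float)
        if np.ptp(x) == 0:
            raise ValueError("constant predictor")
        if edge_index is None:
            edge_index = _full_edge_index(Y.shape[1])
        rng = check_random_state(self.random_state)
        n = len(x)

        def make_design():
            D0 = _design_matrix(x, design.age, design.sex)
            def perm_iter():
                for _ in range(self.n_perm):
                    yield _design_matrix(x[rng.permutation(n)], design.age,
                                         design.sex)
            return D0, perm_iter, False, self.n_perm

        n_regions = max(max(e) for e in edge_index) + 1
        return self._fit_engine(Y, make_design, n_regions, edge_index,
                                ("slope", "zero"))

    def result_(self) -> NBSResult:
        return NBSResult(components=self.components_,
                         null_max_sizes=self.null_max_sizes_,
                         threshold_p=self.threshold_p, n_perm=self.n_perm,
                         direction=self.direction, exact=self.exact_,
                         edge_stats=self.edge_stats_)


def nbs(delta: np.ndarray, design: GroupDesign, contrast: tuple[str, str],
        threshold_p: float = 0.001, n_perm: int = 5000,
        direction: str = "greater", component_stat: str = "extent",
        seed=None, edge_index=None) -> NBSResult:
    """Functional wrapper around :class:`NetworkBasedStatistic`."""
    est = NetworkBasedStatistic(threshold_p=threshold_p, n_perm=n_perm,
                                direction=direction,
                                component_stat=component_stat,
                                random_state=seed)
    est.fit(delta, design, contrast, edge_index=edge_index)
    return est.result_()


def component_level_ttest(series: np.ndarray, design: GroupDesign,
                          contrast: tuple[str, str]):
    """Plain pooled-variance two-sample t on per-subject component means.

    Returns (t, df, p) with df = n1 + n2 - 2 (no covariates; the covariate
    adjustment belongs to the edgewise stage that identified the component).
    """
    a, b = contrast
    xa = np.asarray(series, dtype=float)[design.group == a]
    xb = np.asarray(series, dtype=float)[design.group == b]
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("need at least 3 subjects per group")
    t, p = stats.ttest_ind(xa, xb, equal_var=True)
    return float(t), len(xa) + len(xb) - 2, float(p)
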