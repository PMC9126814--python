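"""Cross-phase association between learning-phase dFC and recall signals.

Three tools:

* region-level regression of recall-phase signals on a per-subject scalar
  predictor (mean dFC over an identified component), with age/sex
  covariates and family-wise error across regions controlled by a
  max-|t| permutation null (the covariate-residualized predictor is
  shuffled);
* NBS with a continuous predictor for recall-phase edge FC (positive and
  negative couplings run as separate directions);
* comparison of two correlation coefficients, either from independent
  groups (Fisher z) or dependent with a shared variable (Steiger's test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from ._utils import check_random_state
from .nbs import GroupDesign, NBSResult, NetworkBasedStatistic, _design_matrix, _ols_t

__all__ = [
    "CrossPhaseRegression",
    "crossphase_regression",
    "crossphase_nbs",
    "CorrelationComparison",
    "compare_correlations",
]


class CrossPhaseRegression(BaseEstimator):
    """Per-region OLS of recall signals on a scalar dFC predictor.

    For each region, fits ``response ~ intercept + predictor + age + sex``;
    reports the predictor's slope, partial correlation (from its t), raw
    two-sided p, and a family-wise p across regions from a max-|t|
    permutation null obtained by shuffling the covariate-residualized
    predictor (``n_perm`` draws).

    Fitted attributes: ``slope_``, ``partial_r_``, ``t_``, ``p_raw_``,
    ``p_fwe_``, ``df_``.
    """

    def __init__(self, n_perm: int = 2000, random_state=None):
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, predictor: np.ndarray, responses: np.ndarray,
            age: np.ndarray | None = None, sex: np.ndarray | None = None):
        x = np.asarray(predictor, dtype=float)
        Y = np.asarray(responses, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n = len(x)
        if n < 10:
            raise ValueError("need at least 10 subjects")
        if np.ptp(x) == 0:
            raise ValueError("constant predictor")
        if age is None:
            age = np.zeros(n)
        if sex is None:
            sex = np.zeros(n)
        age = np.asarray(age, dtype=float)
        sex = np.asarray(sex, dtype=float)

        cov_cols = [np.ones(n)]
        for c in (age, sex):
            if np.ptp(c) > 0:
                cov_cols.append(c)
        C = np.column_stack(cov_cols)

        def t_stats(xv: np.ndarray):
            D = np.column_stack([C[:, :1], xv, C[:, 1:]])
            return _ols_t(D, Y, coef=1)

        t_obs, df = t_stats(x)
        self.t_ = t_obs
        self.df_ = df
        self.partial_r_ = t_obs / np.sqrt(t_obs ** 2 + df)
        # slope via full solve (t_stats only returns t)
        D = np.column_stack([C[:, :1], x, C[:, 1:]])
        beta = np.linalg.lstsq(D, Y, rcond=None)[0]
        self.slope_ = beta[1]
        self.p_raw_ = 2.0 * stats.t.sf(np.abs(t_obs), df)

        # residualize the predictor on covariates, permute residuals
        x_res = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
        rng = check_random_state(self.random_state)
        null_max = np.empty(self.n_perm)
        for b in range(self.n_perm):
            t_b, _ = t_stats(x_res[rng.permutation(n)])
            null_max[b] = np.abs(t_b).max()
        exceed = (null_max[:, None] >= np.abs(t_obs)[None, :]).sum(axis=0)
        self.p_fwe_ = (1.0 + exceed) / (1.0 + self.n_perm)
        return self


def crossphase_regression(predictor, responses, age=None, sex=None,
                          n_perm: int = 2000, seed=None):
    """Functional wrapper; returns (slope, partial_r, p_raw, p_fwe) arrays."""
    est = CrossPhaseRegression(n_perm=n_perm, random_state=seed)
    est.fit(predictor, responses, age=age, sex=sex)
    return est.slope_, est.partial_r_, est.p_raw_, est.p_fwe_


def crossphase_nbs(predictor: np.ndarray, recall_edge_fc: np.ndarray,
                   design: GroupDesign, threshold_p: float = 0.001,
                   n_perm: int = 5000, direction: str = "greater",
                   seed=None, edge_index=None) -> NBSResult:
    """NBS on recall-phase edge FC with the dFC predictor as the covariate
    of interest; run with direction="greater" for positively coupled
    components and "less" for negatively coupled ones."""
    est = NetworkBasedStatistic(threshold_p=threshold_p, n_perm=n_perm,
                                direction=direction, random_state=seed)
    est.fit_continuous(predictor, recall_edge_fc, design,
                       edge_index=edge_index)
    return est.result_()


@dataclass
class CorrelationComparison:
    r1: float
    n1: int
    r2: float
    n2: int
    delta_r: float
    z_stat: float
    p: float
    method: str


def compare_correlations(r1: float, n1: int, r2: float, n2: int,
                         method: str = "independent_fisher",
                         r12: float | None = None) -> CorrelationComparison:
    """Test the difference between two correlation coefficients.

    ``independent_fisher`` (default, for correlations from disjoint groups):

        z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))

    ``dependent_steiger`` (two correlations sharing one variable in the same
    sample, n1 == n2): Steiger's (1980) Z with the inter-correlation of the
    two non-shared variables passed as ``r12``.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1 (z would be infinite)")
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    if method == "independent_fisher":
        se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
        z = (z1 - z2) / se
    elif method == "dependent_steiger":
        if n1 != n2:
            raise ValueError("dependent correlations require n1 == n2")
        if r12 is None:
            raise ValueError("dependent_steiger needs the inter-correlation "
                             "r12 of the two non-shared variables")
        n = n1
        rm2 = (r1 ** 2 + r2 ** 2) / 2.0
        f = min((1.0 - r12) / (2.0 * (1.0 - rm2)), 1.0)
        h = (1.0 - f * rm2) / (1.0 - rm2)
        z = (z1 - z2) * np.sqrt((n - 3.0) / (2.0 * (1.0 - r12) * h))
    else:
        raise ValueError(f"unknown method {method!r}")
    p = 2.0 * stats.norm.sf(abs(z))
    return CorrelationComparison(r1=r1, n1=n1, r2=r2, n2=n2,
                                 delta_r=r1 - r2, z_stat=float(z),
                                 p=float(p), method=method)
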