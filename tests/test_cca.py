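"""Canonical correlation: optimality, calibration, CV, loadings."""

import numpy as np
import pandas as pd
import pytest

from dynconn import PermutationCCA, cca_cross_validation, fit_cca
from dynconn.cca import network_edge_means


def planted_cca_data(n, rho, n_x=20, n_y=4, seed=0, informative=3):
    """Joint Gaussian with first canonical correlation exactly rho: latent
    u, v with corr(u, v) = rho; a few X and Y columns carry u resp. v."""
    g = np.random.default_rng(seed)
    u = g.normal(size=n)
    v = rho * u + np.sqrt(1 - rho ** 2) * g.normal(size=n)
    X = g.normal(size=(n, n_x))
    X[:, 0] = u                      # noise-free carrier: optimum is exactly rho
    for k in range(1, informative):
        X[:, k] += u
    Y = g.normal(size=(n, n_y))
    Y[:, 0] = v
    return X, Y


def test_perfect_dependence_gives_r_one(rng):
    X = rng.normal(size=(30, 5))
    Y = X[:, 2:3].copy()
    res = fit_cca(X, Y, reduction_rank=5)
    assert res.canonical_r == pytest.approx(1.0, abs=1e-8)


def test_large_n_recovery_of_construction(rng):
    rs = []
    for seed in (1, 2, 3):
        X, Y = planted_cca_data(10_000, 0.6, n_x=6, seed=seed)
        # full rank: the construction's optimum is rho itself
        rs.append(fit_cca(X, Y, reduction_rank=6).canonical_r)
    assert np.mean(rs) == pytest.approx(0.6, abs=0.02)


def test_scale_invariance(rng):
    X = rng.normal(size=(50, 8))
    Y = rng.normal(size=(50, 3)) + 0.4 * X[:, :3]
    r1 = fit_cca(X, Y, reduction_rank=6).canonical_r
    X2, Y2 = X.copy(), Y.copy()
    X2[:, 0] *= 37.0
    Y2[:, 1] *= 0.01
    r2 = fit_cca(X2, Y2, reduction_rank=6).canonical_r
    assert r1 == pytest.approx(r2, abs=1e-8)


def test_canonical_r_dominates_univariate_pairs(rng):
    """Optimality: the first canonical correlation is >= |r| of every
    (X column, Y column) pair on the same data."""
    X = rng.normal(size=(40, 6))
    Y = rng.normal(size=(40, 3)) + 0.3 * X[:, :3]
    res = fit_cca(X, Y, reduction_rank=6)
    for i in range(6):
        for j in range(3):
            assert res.canonical_r >= abs(
                np.corrcoef(X[:, i], Y[:, j])[0, 1]) - 1e-10


def test_matches_sklearn_cca(rng):
    """Independent cross-check on a well-conditioned instance."""
    from sklearn.cross_decomposition import CCA as SkCCA

    X = rng.normal(size=(200, 5))
    Y = rng.normal(size=(200, 3)) + 0.5 * X[:, :3]
    res = fit_cca(X, Y, reduction_rank=5)
    sk = SkCCA(n_components=1, max_iter=2000).fit(X, Y)
    xs, ys = sk.transform(X, Y)
    r_sk = abs(np.corrcoef(xs[:, 0], ys[:, 0])[0, 1])
    assert res.canonical_r == pytest.approx(r_sk, abs=1e-6)


def test_single_measure_reduces_to_multiple_R(rng):
    """One clinical column: canonical r equals the multiple correlation of
    a regression of that column on the X features."""
    import statsmodels.api as sm

    X = rng.normal(size=(60, 4))
    y = X @ np.array([1.0, -0.5, 0.2, 0.0]) + rng.normal(size=60)
    res = fit_cca(X, y, reduction_rank=4)
    R2 = sm.OLS(y, sm.add_constant(X)).fit().rsquared
    assert res.canonical_r == pytest.approx(np.sqrt(R2), abs=1e-8)
    assert abs(res.y_loadings[0]) == pytest.approx(1.0, abs=1e-10)


def test_permutation_floor_under_perfect_dependence(rng):
    X = rng.normal(size=(40, 6))
    Y = np.column_stack([X[:, 0], rng.normal(size=40)])
    est = PermutationCCA(reduction_rank=6, n_perm=199, run_cv=False,
                         random_state=0).fit(X, Y)
    assert est.perm_p_ == pytest.approx(1 / 200, abs=1e-12)


def test_permutation_reproducible(rng):
    X, Y = planted_cca_data(60, 0.5, seed=3)
    kw = dict(reduction_rank=5, n_perm=300, n_perm_cv=50, cv=5,
              random_state=11)
    a = PermutationCCA(**kw).fit(X, Y)
    b = PermutationCCA(**kw).fit(X, Y)
    assert a.perm_p_ == b.perm_p_
    assert a.cv_r_ == b.cv_r_ and a.cv_perm_p_ == b.cv_perm_p_


def test_cv_null_centered_at_zero():
    rs = []
    for s in range(10):
        g = np.random.default_rng(s)
        X, Y = g.normal(size=(80, 10)), g.normal(size=(80, 4))
        cv_r, _ = cca_cross_validation(X, Y, reduction_rank=5, k=5,
                                       n_perm=100, seed=s)
        rs.append(cv_r)
    assert abs(np.mean(rs)) < 0.15


def test_cv_recovers_planted_mode():
    X, Y = planted_cca_data(150, 0.6, seed=5)
    cv_r, cv_p = cca_cross_validation(X, Y, reduction_rank=10, k=5,
                                      n_perm=199, seed=6)
    assert cv_r > 0.3
    assert cv_p < 0.05


def test_listwise_deletion_counts(rng):
    X = rng.normal(size=(40, 5))
    Y = rng.normal(size=(40, 3))
    Y[3, 1] = np.nan
    X[7, 0] = np.nan
    est = PermutationCCA(reduction_rank=4, n_perm=100, run_cv=False,
                         random_state=0).fit(X, Y)
    assert est.n_dropped_ == 2


def test_network_loadings_identify_signal_carrier(rng):
    """A network carrying all the dFC signal gets the largest |loading|."""
    from dynconn import canonical_loadings

    atlas = pd.DataFrame({
        "region_id": range(12),
        "label": [f"r{i}" for i in range(12)],
        "network": ["NetA"] * 4 + ["NetB"] * 4 + ["NetC"] * 4,
    })
    edge_index = [(i, j) for i in range(12) for j in range(i + 1, 12)]
    n = 100
    latent = rng.normal(size=n)
    delta = rng.normal(size=(n, len(edge_index))) * 0.3
    for k, (i, j) in enumerate(edge_index):
        if i < 4 and j < 4:                 # NetA-internal edges carry signal
            delta[:, k] += latent
    Y = np.column_stack([latent + 0.5 * rng.normal(size=n),
                         rng.normal(size=n)])
    res = fit_cca(delta, Y, reduction_rank=8)
    y_load, x_load = canonical_loadings(
        res, delta, edge_index, atlas,
        pd.DataFrame({"m1": Y[:, 0], "m2": Y[:, 1]}))
    assert abs(x_load["NetA"]) == max(abs(x_load))
    assert abs(y_load["m1"]) > abs(y_load["m2"])


def test_network_edge_means_hand_check(rng):
    atlas = pd.DataFrame({
        "region_id": [0, 1, 2], "label": ["a", "b", "c"],
        "network": ["N1", "N1", "N2"],
    })
    edge_index = [(0, 1), (0, 2), (1, 2)]
    delta = np.array([[1.0, 2.0, 3.0]])
    means = network_edge_means(delta, edge_index, atlas)
    assert means["N1"][0] == pytest.approx(2.0)       # all three touch N1
    assert means["N2"][0] == pytest.approx(2.5)       # edges (0,2),(1,2)
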