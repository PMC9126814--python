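"""Edgewise GLM and Network-Based Statistic inference."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from dynconn import NetworkBasedStatistic, component_level_ttest, edgewise_glm, nbs
from dynconn._utils import upper_edge_index

from conftest import make_design


def test_identical_groups_give_zero_t(rng):
    half = rng.normal(size=(10, 12))
    delta = np.vstack([half, half])
    d = make_design(10, 10, seed=1)
    d.age = np.tile(d.age[:10], 2)          # covariates copied too
    d.sex = np.tile(d.sex[:10], 2)
    res = edgewise_glm(delta, d, ("HC", "AX"))
    assert np.allclose(res.t, 0.0, atol=1e-10)


def test_glm_matches_statsmodels_oracle(rng):
    import statsmodels.api as sm

    delta = rng.normal(size=(20, 6))
    d = make_design(9, 11, seed=2)
    res = edgewise_glm(delta, d, ("HC", "AX"))
    assert res.df == 20 - 4
    for e in range(6):
        X = sm.add_constant(np.column_stack(
            [(d.group == "HC").astype(float), d.age, d.sex]))
        fit = sm.OLS(delta[:, e], X).fit()
        assert res.t[e] == pytest.approx(fit.tvalues[1], abs=1e-10)
        assert res.p[e] == pytest.approx(fit.pvalues[1], abs=1e-10)


def test_glm_null_calibration(rng):
    """Under a global Gaussian null, ~5% of edges reach p < 0.05."""
    n_edges = 50_000
    delta = rng.normal(size=(30, n_edges))
    d = make_design(15, 15, seed=3)
    res = edgewise_glm(delta, d, ("HC", "AX"))
    frac = (res.p < 0.05).mean()
    se = np.sqrt(0.05 * 0.95 / n_edges)
    assert abs(frac - 0.05) < 3 * se


def test_collinear_design_rejected(rng):
    d = make_design(6, 6, seed=4)
    d.age = d.sex.copy() * 2.0              # age collinear with sex
    with pytest.raises(ValueError, match="collinear"):
        edgewise_glm(rng.normal(size=(12, 4)), d, ("HC", "AX"))


def brute_force_nbs_p(delta, design, contrast, threshold_p, direction="greater"):
    """Exhaustive-enumeration oracle for tiny cohorts: all label assignments,
    max component size each, p = #{null >= observed} / n_assignments."""
    n = len(design.group)
    n_a = int((design.group == contrast[0]).sum())
    R = int(round((1 + np.sqrt(1 + 8 * delta.shape[1])) / 2))
    edges = upper_edge_index(R)

    def max_comp(indicator):
        D = np.column_stack([np.ones(n), indicator, design.age, design.sex])
        beta, *_ = np.linalg.lstsq(D, delta, rcond=None)
        resid = delta - D @ beta
        df = n - D.shape[1]
        sig2 = (resid ** 2).sum(axis=0) / df
        cinv = np.linalg.inv(D.T @ D)[1, 1]
        t = beta[1] / np.sqrt(sig2 * cinv)
        tc = stats.t.isf(threshold_p, df)
        sup = [e for k, e in enumerate(edges)
               if (t[k] if direction == "greater" else -t[k]) > tc]
        # connected components by repeated merging
        comps = []
        for e in sup:
            hit = [c for c in comps if c & set(e)]
            new = set(e)
            for c in hit:
                new |= c
                comps.remove(c)
            comps.append(new)
        sizes = []
        for c in comps:
            sizes.append(sum(1 for e in sup if set(e) <= c))
        return (max(sizes) if sizes else 0), sup

    obs_max, obs_sup = max_comp((design.group == contrast[0]).astype(float))
    null = []
    for rows in combinations(range(n), n_a):
        ind = np.zeros(n)
        ind[list(rows)] = 1.0
        null.append(max_comp(ind)[0])
    null = np.array(null)
    return float((null >= obs_max).sum()) / len(null) if obs_max else None


def test_exhaustive_enumeration_matches_oracle(rng):
    """3-vs-3 cohorts: permutation space (20 assignments) is enumerated and
    the component p equals an independent brute-force enumeration."""
    from dynconn import GroupDesign

    for seed in range(5):
        g = np.random.default_rng(seed)
        delta = g.normal(size=(6, 45))
        delta[:3, :8] += 3.0                # group effect on first edges
        # continuous covariates: binary sex would coincide with one of the
        # 20 label assignments and make that permuted design singular
        d = GroupDesign(subject_id=[f"s{i}" for i in range(6)],
                        group=np.array(["HC"] * 3 + ["AX"] * 3),
                        age=g.normal(30, 8, 6), sex=g.normal(0.5, 0.2, 6))
        res = nbs(delta, d, ("HC", "AX"), threshold_p=0.05, n_perm=5000,
                  seed=seed)
        assert res.exact
        assert len(res.null_max_sizes) == 20
        oracle_p = brute_force_nbs_p(delta, d, ("HC", "AX"), 0.05)
        if res.components:
            assert res.components[0]["p_fwe"] == pytest.approx(oracle_p)


def test_no_suprathreshold_edges_is_not_an_error(rng):
    delta = rng.normal(size=(20, 15)) * 1e-2
    d = make_design(10, 10, seed=6)
    res = nbs(delta, d, ("HC", "AX"), threshold_p=1e-6, n_perm=100, seed=0)
    assert res.components == []
    assert len(res.null_max_sizes) > 0


def test_threshold_monotonicity(rng):
    """Lowering threshold_p never increases the supra-threshold edge count."""
    delta = rng.normal(size=(30, 100))
    delta[:15] += 0.4
    d = make_design(15, 15, seed=7)
    counts = []
    for thr in (0.05, 0.01, 0.001):
        res = nbs(delta, d, ("HC", "AX"), threshold_p=thr, n_perm=100,
                  seed=0, edge_index=[(0, k + 1) for k in range(100)])
        counts.append(sum(c["size"] for c in res.components))
    assert counts[0] >= counts[1] >= counts[2]


def test_fixed_seed_reproducible(rng):
    delta = rng.normal(size=(24, 28))
    delta[:12, :5] += 1.0
    d = make_design(12, 12, seed=8)
    r1 = nbs(delta, d, ("HC", "AX"), threshold_p=0.05, n_perm=300, seed=9)
    r2 = nbs(delta, d, ("HC", "AX"), threshold_p=0.05, n_perm=300, seed=9)
    assert [c["p_fwe"] for c in r1.components] == \
        [c["p_fwe"] for c in r2.components]
    assert np.array_equal(r1.null_max_sizes, r2.null_max_sizes)


def test_component_edges_all_pass_threshold(rng):
    delta = rng.normal(size=(40, 190))
    delta[:20, :30] += 0.8
    d = make_design(20, 20, seed=10)
    est = NetworkBasedStatistic(threshold_p=0.01, n_perm=100, random_state=0)
    est.fit(delta, d, ("HC", "AX"))
    t_crit = stats.t.isf(0.01, est.df_)
    for c in est.components_:
        assert np.all(np.asarray(c["t"]) > t_crit)


def test_component_ttest_matches_closed_form(rng):
    a, b = rng.normal(size=12), rng.normal(size=15) + 0.5
    d = make_design(12, 15, seed=11)
    t, df, p = component_level_ttest(np.concatenate([a, b]), d, ("HC", "AX"))
    sp = np.sqrt(((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
                 / (len(a) + len(b) - 2))
    t_exp = (a.mean() - b.mean()) / (sp * np.sqrt(1 / len(a) + 1 / len(b)))
    assert t == pytest.approx(t_exp, abs=1e-12)
    assert p == pytest.approx(2 * stats.t.sf(abs(t_exp), df), abs=1e-12)


@pytest.mark.parametrize("n1,n2,df_expected", [(77, 91, 166), (77, 81, 156)])
def test_two_sample_df_convention(n1, n2, df_expected, rng):
    d = make_design(n1, n2, seed=12)
    series = rng.normal(size=n1 + n2)
    _, df, _ = component_level_ttest(series, d, ("HC", "AX"))
    assert df == df_expected
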