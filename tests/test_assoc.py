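from itertools import combinations
from math import log

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from onsetmod import assoc, syndata
from conftest import make_matrix


# ------------------------------------------------------------- logistic IRLS
def test_logistic_2x2_closed_form():
    """Single binary predictor: beta equals the log cross-product OR and
    its Wald p matches the asymptotic z-test on the log-OR."""
    y = np.r_[np.ones(40), np.zeros(60)]
    x = np.r_[np.ones(30), np.zeros(10), np.ones(20), np.zeros(40)]
    fit = assoc.logistic_fit(y, np.column_stack([np.ones(100), x]))
    assert fit.beta[1] == pytest.approx(log(6), abs=1e-9)
    se_or = np.sqrt(1 / 30 + 1 / 10 + 1 / 20 + 1 / 40)
    p_or = 2 * stats.norm.sf(abs(log(6) / se_or))
    assert fit.p[1] == pytest.approx(p_or, rel=1e-6)


def test_logistic_matches_statsmodels():
    """Independent cross-check of the IRLS fit against statsmodels."""
    import statsmodels.api as sm

    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(300), rng.binomial(2, 0.3, 300),
                         rng.normal(size=300)])
    y = rng.binomial(1, 1 / (1 + np.exp(-(0.2 + 0.5 * X[:, 1] - X[:, 2]))))
    fit = assoc.logistic_fit(y.astype(float), X)
    ref = sm.Logit(y, X).fit(disp=False)
    np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
    np.testing.assert_allclose(fit.se, ref.bse, atol=1e-6)


def test_logistic_orthogonal_covariate_leaves_beta():
    rng = np.random.default_rng(1)
    n = 400
    d = rng.binomial(2, 0.3, n).astype(float)
    y = rng.binomial(1, 1 / (1 + np.exp(-(-0.3 + 0.6 * d)))).astype(float)
    base = assoc.logistic_fit(y, np.column_stack([np.ones(n), d]))
    # covariate orthogonalised against (1, d, y)
    c = rng.normal(size=n)
    M = np.column_stack([np.ones(n), d, y])
    c -= M @ np.linalg.lstsq(M, c, rcond=None)[0]
    ext = assoc.logistic_fit(y, np.column_stack([np.ones(n), d, c]))
    assert ext.beta[1] == pytest.approx(base.beta[1], abs=1e-4)


def test_logistic_separation_flagged():
    y = np.r_[np.ones(20), np.zeros(20)]
    x = y.copy()  # perfect separation
    fit = assoc.logistic_fit(y, np.column_stack([np.ones(40), x]))
    assert not fit.converged
    assert np.isnan(fit.p).all()


def test_logistic_single_class_raises():
    with pytest.raises(ValueError, match="single class"):
        assoc.logistic_fit(np.ones(10), np.ones((10, 1)))


# ------------------------------------------------------------------ gwas scan
def test_scan_label_swap_negates_betas(selected_cohort):
    co = selected_cohort
    pro = co.pedigree[(co.pedigree["role"] == "proband")]
    g = co.genotypes.subset(samples=list(pro["iid"]),
                            markers=list(co.genotypes.markers.index[:40]))
    grp = pro.set_index("iid")["aao_group"]
    res1 = assoc.gwas_scan(g, grp)
    swapped = grp.map({"earliest": "latest", "latest": "earliest"})
    res2 = assoc.gwas_scan(g, swapped)
    ok = res1["beta"].notna() & res2["beta"].notna()
    np.testing.assert_allclose(res1.loc[ok, "beta"],
                               -res2.loc[ok, "beta"], atol=1e-6)


def test_scan_or_is_exp_beta(selected_cohort):
    co = selected_cohort
    pro = co.pedigree[co.pedigree["role"] == "proband"]
    g = co.genotypes.subset(samples=list(pro["iid"]),
                            markers=list(co.genotypes.markers.index[:20]))
    res = assoc.gwas_scan(g, pro.set_index("iid")["aao_group"])
    ok = res["beta"].notna()
    np.testing.assert_allclose(res.loc[ok, "or_"],
                               np.exp(res.loc[ok, "beta"]), rtol=1e-12)


# -------------------------------------------------------------- permutation p
def test_empirical_p_exhaustive_enumeration():
    """n=6: the permutation p equals a test-side exhaustive enumeration
    computed with an independent (statsmodels) fit of every relabelling."""
    import statsmodels.api as sm

    d = np.array([0., 1., 2., 0., 1., 0.])
    y = np.array([1., 1., 1., 0., 0., 0.])
    g = make_matrix(d[:, None])
    groups = pd.Series(np.where(y == 1, "earliest", "latest"),
                       index=g.samples)
    p_impl, B = assoc.empirical_p(g, groups, "m0", B_max=10_000, seed=0)

    def absz(yy):
        try:
            with np.errstate(all="ignore"):
                r = sm.Logit(yy, np.column_stack([np.ones(6), d])).fit(disp=0)
            if np.abs(r.params[1]) > 15:
                return np.nan
            return abs(r.params[1] / r.bse[1])
        except Exception:
            return np.nan

    obs = absz(y)
    count = total = 0
    for pos in combinations(range(6), 3):
        yy = np.zeros(6)
        yy[list(pos)] = 1
        s = absz(yy)
        total += 1
        if np.isfinite(s) and s >= obs - 1e-12:
            count += 1
    assert B == total == 20
    assert p_impl == pytest.approx(count / total, abs=1e-12)


def test_empirical_p_floor_and_seed_stability():
    rng = np.random.default_rng(5)
    n = 120
    d = rng.binomial(2, 0.4, n).astype(float)
    y = rng.binomial(1, 1 / (1 + np.exp(-(0.8 * d - 0.6)))).astype(float)
    g = make_matrix(d[:, None], samples=[f"s{i}" for i in range(n)])
    groups = pd.Series(np.where(y == 1, "earliest", "latest"), index=g.samples)
    p1, b1 = assoc.empirical_p(g, groups, "m0", B_max=2000, seed=1)
    p2, b2 = assoc.empirical_p(g, groups, "m0", B_max=2000, seed=2)
    # two seeds agree within 3 binomial SEs at the smaller B
    B = min(b1, b2)
    tol = 3 * np.sqrt(max(p1, p2) * (1 - min(p1, p2)) / B) + 1e-9
    assert abs(p1 - p2) <= tol


# --------------------------------------------------------- candidates and LD
def test_select_candidates_strict_threshold():
    g = make_matrix(np.zeros((2, 3)))
    res = pd.DataFrame({"marker": ["m0", "m1", "m2"],
                        "beta": [1, 1, 1], "or_": [1, 1, 1],
                        "p_wald": [1e-4, 9.9e-5, 0.5]})
    cand = assoc.select_candidates(res, g)
    assert list(cand["marker"]) == ["m1"]  # p exactly 1e-4 excluded


def test_ld_collapse_matches_graph_oracle_and_order_invariance():
    """Greedy collapse retains each high-LD clique's smallest-p member;
    cross-checked against a brute-force connected-component oracle."""
    g, y, hits, clique = syndata.simulate_candidate_fixture(seed=2)
    groups = pd.Series(np.where(y == 1, "earliest", "latest"), index=g.samples)
    res = assoc.gwas_scan(g.subset(markers=hits), groups)
    cand = assoc.select_candidates(res, g)
    out = assoc.ld_collapse(cand, g)
    kept = set(out.loc[out["status"] == "retained", "marker"])
    assert len(kept) == 15

    # oracle: graph over candidate pairs with r2>0.8 within window
    import networkx as nx
    G = nx.Graph()
    G.add_nodes_from(cand["marker"])
    info = g.markers
    for a, b in combinations(cand["marker"], 2):
        if info.at[a, "chrom"] != info.at[b, "chrom"]:
            continue
        if abs(int(info.at[a, "pos"]) - int(info.at[b, "pos"])) > 500_000:
            continue
        da = g.dosage[:, info.index.get_loc(a)]
        db = g.dosage[:, info.index.get_loc(b)]
        if np.corrcoef(da, db)[0, 1] ** 2 > 0.8:
            G.add_edge(a, b)
    p_of = dict(zip(cand["marker"], cand["p_wald"]))
    oracle_kept = {min(c, key=lambda m: (p_of[m], m))
                   for c in nx.connected_components(G)}
    assert kept == oracle_kept

    # clique representative is its min-p member
    clique_p = {m: p_of[m] for m in clique}
    assert kept & set(clique) == {min(clique_p, key=clique_p.get)}

    # input-order invariance
    out2 = assoc.ld_collapse(cand.iloc[::-1].reset_index(drop=True), g)
    assert set(out2.loc[out2["status"] == "retained", "marker"]) == kept


def test_ld_collapse_identity_when_unlinked():
    rng = np.random.default_rng(3)
    g = make_matrix(rng.binomial(2, 0.3, size=(100, 4)).astype(float))
    cand = pd.DataFrame({"marker": [f"m{j}" for j in range(4)],
                         "p_wald": [1e-5, 2e-5, 3e-5, 4e-5],
                         "status": "retained", "collapsed_into": ""})
    out = assoc.ld_collapse(cand, g)
    assert (out["status"] == "retained").all()


# ----------------------------------------------------------------- power
def test_power_null_equals_alpha():
    assert assoc.power_two_group(0.3, 1.0, 1.0, 0.4, 80, 0.05) == \
        pytest.approx(0.05, abs=1e-12)


def test_power_monotone():
    grid_n = [40, 80, 160]
    pw_n = [assoc.power_two_group(0.3, 1.9, 2.0, 0.4, n) for n in grid_n]
    assert pw_n == sorted(pw_n)
    grid_g = [1.5, 2.0, 2.5]
    pw_g = [assoc.power_two_group(0.3, 1.4, g, 0.4, 80) for g in grid_g]
    assert pw_g == sorted(pw_g)


def test_power_matches_monte_carlo():
    """Analytic non-central-chi-square power vs direct simulation of the
    additive trend test, within +/-0.01."""
    maf, gh, gho, prev, n, alpha = 0.3, 2.0, 2.2, 0.4, 80, 0.05
    analytic = assoc.power_two_group(maf, gh, gho, prev, n, alpha)

    P = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2])
    grr = np.array([1.0, gh, gho])
    f0 = prev / float(P @ grr)
    f = f0 * grr
    p_case = f * P / prev
    p_ctrl = (1 - f) * P / (1 - prev)
    rng = np.random.default_rng(12)
    reps = 100_000
    cases = rng.multinomial(n, p_case, size=reps)
    ctrls = rng.multinomial(n, p_ctrl, size=reps)
    x = np.array([0.0, 1.0, 2.0])
    diff = (cases - ctrls) @ x / n
    pooled = (cases + ctrls) / (2.0 * n)
    var0 = pooled @ (x ** 2) - (pooled @ x) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        chi = n * diff ** 2 / (2 * var0)
    crit = stats.chi2.isf(alpha, 1)
    mc = np.mean(chi > crit)
    assert analytic == pytest.approx(mc, abs=0.01)


def test_power_penetrance_overflow():
    with pytest.raises(ValueError, match="penetrance"):
        assoc.power_two_group(0.5, 3.0, 8.0, 0.5, 80)
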