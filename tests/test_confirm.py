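from itertools import combinations
from math import log

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from onsetmod import confirm, syndata
from onsetmod.assoc import logistic_fit
from conftest import make_matrix


# ------------------------------------------------------------- replication
def test_replication_bonferroni_threshold():
    """14 candidate tests give the printed 0.05/14 = 0.0036 threshold."""
    rng = np.random.default_rng(0)
    d = rng.binomial(2, 0.3, size=(80, 14)).astype(float)
    g = make_matrix(d)
    groups = pd.Series(["earliest"] * 40 + ["latest"] * 40, index=g.samples)
    out = confirm.sibling_replication(g, groups, m_tests=14)
    thr = out.attrs["bonferroni_threshold"]
    assert thr == 0.05 / 14
    assert round(thr, 4) == 0.0036
    # p = 0.01 would not clear it
    assert not (0.01 < thr)


def test_replication_sign_agrees_with_learning(selected_cohort):
    """Sibs inherit the planted modifier: replication beta shares the
    learning beta's sign."""
    from onsetmod.assoc import gwas_scan

    co = selected_cohort
    mod = list(co.true_modifiers)[0]
    ped = co.pedigree
    pro = ped[ped["role"] == "proband"]
    res = gwas_scan(co.genotypes.subset(samples=list(pro["iid"]),
                                        markers=[mod]),
                    pro.set_index("iid")["aao_group"])
    sibs = ped[(ped["role"] == "co_sib") & (ped["aao_group"] != "none")]
    rep = confirm.sibling_replication(
        co.genotypes.subset(samples=list(sibs["iid"]), markers=[mod]),
        sibs.set_index("iid")["aao_group"], m_tests=1)
    assert np.sign(rep["beta"].iloc[0]) == np.sign(res["beta"].iloc[0])


# ------------------------------------------------------------ ordinal trend
def test_ordinal_two_levels_reduces_to_logistic():
    rng = np.random.default_rng(1)
    n = 300
    d = rng.binomial(2, 0.3, n).astype(float)
    y = rng.binomial(1, 1 / (1 + np.exp(-(-0.4 + 0.7 * d)))).astype(float)
    g = make_matrix(d[:, None], samples=[f"s{i}" for i in range(n)])
    grp = pd.Series(np.where(y == 1, "earliest", "latest"), index=g.samples)
    with pytest.warns(UserWarning, match="group levels"):
        tr = confirm.ordinal_trend(g, grp)
    ref = logistic_fit(y, np.column_stack([np.ones(n), d]))
    assert log(tr["or_trend"].iloc[0]) == pytest.approx(ref.beta[1], abs=1e-4)


def test_ordinal_null_p_uniformish():
    """Dosage independent of group: trend p has ~nominal rejection rate."""
    rng = np.random.default_rng(2)
    n = 160
    grp_vals = np.repeat(["earliest", "earlier", "later", "latest"], n // 4)
    ps = []
    for _ in range(120):
        d = rng.binomial(2, 0.3, n).astype(float)
        g = make_matrix(d[:, None], samples=[f"s{i}" for i in range(n)])
        grp = pd.Series(grp_vals, index=g.samples)
        ps.append(confirm.ordinal_trend(g, grp)["p_trend"].iloc[0])
    ps = np.array(ps)
    assert abs(np.mean(ps < 0.1) - 0.1) < 0.09


def test_ordinal_loglik_beats_random_grid():
    """The fitted cumulative-logit point dominates a random parameter grid."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    rng = np.random.default_rng(3)
    n = 200
    d = rng.binomial(2, 0.4, n).astype(float)
    lin = 0.5 * d + rng.logistic(size=n)
    y = np.digitize(lin, np.quantile(lin, [0.25, 0.5, 0.75])).astype(float)
    mod = OrderedModel(y, d[:, None], distr="logit")
    fit = mod.fit(method="bfgs", disp=False)
    best = fit.llf
    for _ in range(1000):
        beta = rng.normal(0, 2)
        cuts = np.sort(rng.normal(0, 2, size=3))
        # statsmodels parameterises thresholds incrementally (log-diffs)
        params = np.r_[beta, cuts[0], np.log(np.diff(cuts))]
        assert mod.loglike(params) <= best + 1e-6


# ----------------------------------------------------------------- GRS
def test_grs_weights_and_hand_scores():
    res = pd.DataFrame({"marker": ["a", "b"],
                        "beta": [log(2.0), log(0.5)]})
    g = make_matrix(np.array([[1.0, 2.0], [0.0, 0.0]]), samples=["x", "zero"])
    g.markers.index = pd.Index(["a", "b"], name="marker")
    prof = confirm.grs_learn(res, g)
    scores = confirm.grs_score(prof, g)
    assert scores["x"] == pytest.approx(log(2) * 1 + log(0.5) * 2, abs=1e-12)
    assert scores["zero"] == 0.0  # all-major-homozygote sample
    # OR round trip
    np.testing.assert_allclose(np.exp(prof.weights),
                               [2.0, 0.5], rtol=1e-12)


def test_grs_all_or_one_gives_zero_scores():
    res = pd.DataFrame({"marker": ["a", "b"], "beta": [0.0, 0.0]})
    rng = np.random.default_rng(4)
    g = make_matrix(rng.binomial(2, 0.3, size=(10, 2)).astype(float))
    g.markers.index = pd.Index(["a", "b"], name="marker")
    prof = confirm.grs_learn(res, g)
    assert (confirm.grs_score(prof, g) == 0).all()


def test_grs_missing_imputed_at_learning_mean():
    res = pd.DataFrame({"marker": ["a", "b"], "beta": [0.3, -0.2]})
    learn = make_matrix(np.array([[0., 1.], [2., 1.], [1., 0.]]))
    learn.markers.index = pd.Index(["a", "b"], name="marker")
    prof = confirm.grs_learn(res, learn)
    target = make_matrix(np.full((1, 2), np.nan), samples=["missing_all"])
    target.markers.index = pd.Index(["a", "b"], name="marker")
    s = confirm.grs_score(prof, target)
    expect = sum(prof.weights[m] * 2 * prof.learning_maf[m] for m in ["a", "b"])
    assert s["missing_all"] == pytest.approx(expect, abs=1e-12)


def test_grs_linear_over_marker_partition():
    rng = np.random.default_rng(5)
    res = pd.DataFrame({"marker": [f"m{j}" for j in range(6)],
                        "beta": rng.normal(size=6)})
    g = make_matrix(rng.binomial(2, 0.4, size=(8, 6)).astype(float))
    prof = confirm.grs_learn(res, g)
    full = confirm.grs_score(prof, g)
    p1 = confirm.GRSProfile(prof.weights[:3], prof.learning_maf[:3])
    p2 = confirm.GRSProfile(prof.weights[3:], prof.learning_maf[3:])
    part = confirm.grs_score(p1, g) + confirm.grs_score(p2, g)
    np.testing.assert_allclose(full, part, atol=1e-12)


def test_grs_zero_overlap_errors():
    prof = confirm.GRSProfile(pd.Series({"zz": 1.0}), pd.Series({"zz": 0.2}))
    g = make_matrix(np.zeros((2, 2)))
    with pytest.raises(ValueError, match="overlap"):
        confirm.grs_score(prof, g)


# ------------------------------------------------------------- Mann-Whitney
def test_mann_whitney_symmetry_and_separation():
    U, z, p = confirm.mann_whitney([1, 2, 3], [1, 2, 3])
    assert U == 4.5 and z == 0.0 and p == 1.0
    U, z, p = confirm.mann_whitney([1, 2, 3, 4], [100, 101, 102, 103])
    assert U in (0.0, 16.0)
    assert p < 0.05  # exact floor with n=4+4 is 2/70


def test_mann_whitney_exact_enumeration_oracle():
    rng = np.random.default_rng(6)
    a = rng.normal(size=4)
    b = rng.normal(1.0, size=4)
    U, z, p = confirm.mann_whitney(a, b)
    pooled = np.r_[a, b]
    ranks = stats.rankdata(pooled)
    mu = 4 * 4 / 2
    obs = abs(U - mu)
    count = total = 0
    for pos in combinations(range(8), 4):
        u = ranks[list(pos)].sum() - 4 * 5 / 2
        total += 1
        if abs(u - mu) >= obs - 1e-12:
            count += 1
    assert p == pytest.approx(count / total, abs=1e-12)
    # scipy agreement on a tie-free exact case
    assert p == pytest.approx(
        stats.mannwhitneyu(a, b, method="exact").pvalue, abs=1e-12)


def test_mann_whitney_large_sample_matches_scipy():
    rng = np.random.default_rng(7)
    a = rng.normal(size=40)
    b = rng.normal(0.4, size=45)
    _, _, p = confirm.mann_whitney(a, b)
    ref = stats.mannwhitneyu(a, b, method="asymptotic",
                             use_continuity=True).pvalue
    assert p == pytest.approx(ref, rel=1e-10)


# ------------------------------------------------------------- GRS trend
def test_grs_trend_closed_form_and_edges():
    groups = pd.Series(["earliest"] * 3 + ["earlier"] * 3
                       + ["later"] * 3 + ["latest"] * 3,
                       index=[f"s{i}" for i in range(12)])
    flat = pd.Series(np.ones(12), index=groups.index)
    slope, t, p = confirm.grs_group_trend(flat, groups)
    assert slope == 0.0 and p == 1.0
    perfect = pd.Series(groups.map({"latest": 1.0, "later": 2.0,
                                    "earlier": 3.0, "earliest": 4.0}).to_numpy(),
                        index=groups.index)
    slope, t, p = confirm.grs_group_trend(perfect, groups)
    assert slope == pytest.approx(1.0) and p < 1e-10
    rng = np.random.default_rng(8)
    y = rng.normal(size=12)
    scores = pd.Series(y, index=groups.index)
    slope, t, p = confirm.grs_group_trend(scores, groups)
    x = groups.map({"latest": 1, "later": 2, "earlier": 3, "earliest": 4}
                   ).to_numpy(dtype=float)
    ref = stats.linregress(x, y)
    assert slope == pytest.approx(ref.slope, abs=1e-10)
    assert p == pytest.approx(ref.pvalue, abs=1e-10)


# ------------------------------------------------------------- descriptives
def test_fisher_exact_enumeration_value():
    """2x2 (3,1;1,3): two-sided hypergeometric enumeration gives 0.4857..."""
    ped = pd.DataFrame({
        "aao_group": ["earliest"] * 4 + ["latest"] * 4,
        "sex": [1, 1, 1, 2, 1, 2, 2, 2],
        "age": np.r_[np.random.default_rng(0).normal(30, 5, 8)],
        "aao": np.r_[np.random.default_rng(1).normal(20, 5, 8)]})
    out = confirm.group_descriptives(ped)
    p_sex = out.loc[out["variable"] == "male_n", "p"].iloc[0]
    assert p_sex == pytest.approx(0.4857142857, abs=1e-9)


def test_descriptives_identical_groups():
    rng = np.random.default_rng(9)
    age = rng.normal(35, 5, 20)
    ped = pd.DataFrame({
        "aao_group": ["earliest"] * 20 + ["latest"] * 20,
        "sex": list(rng.integers(1, 3, 20)) * 2,
        "age": np.r_[age, age], "aao": np.r_[age - 10, age - 10]})
    out = confirm.group_descriptives(ped)
    means = out[out["variable"] == "age_mean"]
    assert means["earliest"].iloc[0] == pytest.approx(means["latest"].iloc[0])
    assert (out["p"].dropna() > 0.99).all()


# ------------------------------------------------- GRS attenuation property
def test_grs_attenuates_from_probands_to_siblings(selected_cohort):
    """Weights learned on probands separate sibling groups with a smaller
    standardized mean difference than in the probands themselves."""
    from onsetmod.assoc import gwas_scan

    co = selected_cohort
    ped = co.pedigree
    pro = ped[ped["role"] == "proband"]
    g_pro = co.genotypes.subset(samples=list(pro["iid"]))
    res = gwas_scan(g_pro, pro.set_index("iid")["aao_group"])
    top = res.nsmallest(10, "p_wald")
    prof = confirm.grs_learn(top, g_pro, list(top["marker"]))

    def smd(scores, grp):
        a = scores[grp == "earliest"]; b = scores[grp == "latest"]
        sp = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        return abs(a.mean() - b.mean()) / sp

    s_pro = confirm.grs_score(prof, g_pro)
    sibs = ped[(ped["role"] == "co_sib") & (ped["aao_group"] != "none")]
    s_sib = confirm.grs_score(
        prof, co.genotypes.subset(samples=list(sibs["iid"])))
    d_pro = smd(s_pro, pro.set_index("iid")["aao_group"])
    d_sib = smd(s_sib, sibs.set_index("iid")["aao_group"])
    assert d_sib < d_pro
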