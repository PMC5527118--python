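"""Candidate confirmation: sibling replication, four-group ordinal trend,
the multi-SNP genetic risk score, and descriptive group contrasts.

The genetic risk score (GRS) of a sample is ``sum_j w_j * g_j`` where
``w_j = ln(OR_j)`` comes from the learning-set association scan and
``g_j`` is the minor-allele dosage (0/1/2).  Weights are frozen after
learning: applying the profile to siblings or unrelated probands never
refits.  Missing genotypes are imputed at the learning-set mean dosage
``2 * MAF`` so scores stay comparable across missingness patterns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb, exp

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import logistic_fit
from .gio import GenotypeMatrix

__all__ = [
    "GRSProfile",
    "sibling_replication", "ordinal_trend",
    "grs_learn", "grs_score",
    "mann_whitney", "grs_group_trend", "group_descriptives",
]

GROUP_ORDER = ["latest", "later", "earlier", "earliest"]  # ordinal, low->high


@dataclass
class GRSProfile:
    """Frozen learning-set weights and MAFs for the multi-SNP risk score."""

    weights: pd.Series       # marker -> ln(OR) from the learning set
    learning_maf: pd.Series  # marker -> learning-set MAF (for imputation)


def sibling_replication(g_sibs: GenotypeMatrix, groups: pd.Series,
                        m_tests: int, alpha: float = 0.05,
                        sex: pd.Series | None = None) -> pd.DataFrame:
    """Unadjusted per-marker logistic replication in co-affected siblings.

    Siblings carry their family's group label (earliest vs latest).  The
    verdict applies a Bonferroni threshold ``alpha / m_tests``.  Passing
    ``sex`` adds it as a covariate (the gender-adjusted sensitivity
    model).
    """
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    samples = list(groups.index)
    gg = g_sibs.subset(samples=samples)
    y = (groups.astype(str) == "earliest").to_numpy(dtype=float)
    sx = (sex.loc[samples].to_numpy(dtype=float)[:, None]
          if sex is not None else np.empty((len(samples), 0)))
    thresh = alpha / m_tests
    rows = []
    for j, mid in enumerate(gg.markers.index):
        d = gg.dosage[:, j]
        ok = ~np.isnan(d)
        yy, dd = y[ok], d[ok]
        maf_e = dd[yy == 1].mean() / 2 if np.any(yy == 1) else np.nan
        maf_l = dd[yy == 0].mean() / 2 if np.any(yy == 0) else np.nan
        if len(dd) == 0 or dd.min() == dd.max() or yy.min() == yy.max():
            rows.append((mid, np.nan, np.nan, np.nan, np.nan,
                         maf_e, maf_l, int(ok.sum()), False))
            continue
        X = np.column_stack([np.ones(ok.sum()), dd, sx[ok]])
        fit = logistic_fit(yy, X)
        beta = fit.beta[1] if fit.converged else np.nan
        p = fit.p[1]
        rows.append((mid, beta, exp(beta) if np.isfinite(beta) else np.nan,
                     fit.se[1], p, maf_e, maf_l, int(ok.sum()),
                     bool(np.isfinite(p) and p < thresh)))
    out = pd.DataFrame(rows, columns=[
        "marker", "beta", "or_", "se", "p_wald",
        "maf_earliest", "maf_latest", "n_used", "significant"])
    out.attrs["bonferroni_threshold"] = thresh
    return out


def ordinal_trend(g: GenotypeMatrix, ordered_groups: pd.Series,
                  sex: pd.Series | None = None) -> pd.DataFrame:
    """Proportional-odds trend of each marker across the ordered AAO groups.

    The outcome is the family group coded ordinally with ``earliest``
    highest, so an odds ratio above 1 means the minor allele pushes
    toward earlier onset — the same sign convention as the two-group
    scan.  Fits a cumulative-logit model with dosage (and optionally
    sex) as predictor; separation or non-convergence yields missing
    p-values.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    samples = list(ordered_groups.index)
    gg = g.subset(samples=samples)
    lab = ordered_groups.astype(str)
    levels = [g_ for g_ in GROUP_ORDER if (lab == g_).any()]
    if len(levels) < 2:
        raise ValueError("need at least two represented groups")
    if len(levels) < 4:
        warnings.warn(f"only {len(levels)} group levels represented; "
                      "empty levels collapsed")
    code = lab.map({g_: i for i, g_ in enumerate(levels)}).to_numpy(dtype=float)
    sx = (sex.loc[samples].to_numpy(dtype=float)[:, None]
          if sex is not None else None)
    rows = []
    for j, mid in enumerate(gg.markers.index):
        d = gg.dosage[:, j]
        ok = ~np.isnan(d)
        yy, dd = code[ok], d[ok]
        group_maf = {lv: dd[yy == i].mean() / 2 if np.any(yy == i) else np.nan
                     for i, lv in enumerate(levels)}
        if dd.min() == dd.max():
            rows.append((mid, np.nan, np.nan, group_maf))
            continue
        exog = dd[:, None] if sx is None else np.column_stack([dd, sx[ok]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mod = OrderedModel(yy, exog, distr="logit")
                fit = mod.fit(method="bfgs", disp=False, maxiter=200)
            beta = float(fit.params[0])
            p = float(fit.pvalues[0])
            if abs(beta) > 15 or not np.isfinite(p):
                beta, p = np.nan, np.nan
        except Exception:
            beta, p = np.nan, np.nan
        rows.append((mid, exp(beta) if np.isfinite(beta) else np.nan, p,
                     group_maf))
    return pd.DataFrame(rows, columns=["marker", "or_trend", "p_trend",
                                       "group_maf"])


def grs_learn(results: pd.DataFrame, g_learning: GenotypeMatrix,
              markers: list[str] | None = None) -> GRSProfile:
    """Freeze ln(OR) weights and learning-set MAFs for the risk score.

    Markers without a finite learning beta are excluded with a warning.
    """
    res = results.set_index("marker")
    if markers is None:
        markers = list(res.index)
    weights, mafs = {}, {}
    maf_all = g_learning.maf()
    for m in markers:
        b = res.at[m, "beta"] if m in res.index else np.nan
        if not np.isfinite(b):
            warnings.warn(f"marker {m}: no finite learning beta; excluded")
            continue
        weights[m] = float(b)
        mafs[m] = float(maf_all[m])
    return GRSProfile(pd.Series(weights, name="weight"),
                      pd.Series(mafs, name="learning_maf"))


def grs_score(profile: GRSProfile, g: GenotypeMatrix) -> pd.Series:
    """Apply frozen GRS weights to a genotype matrix.

    Missing dosage is imputed as ``2 * learning MAF``; a sample carrying
    only major-allele homozygotes scores exactly 0.
    """
    overlap = [m for m in profile.weights.index if m in g.markers.index]
    if not overlap:
        raise ValueError("no marker overlap between profile and genotypes")
    gg = g.subset(markers=overlap)
    w = profile.weights.loc[overlap].to_numpy(dtype=float)
    fill = 2.0 * profile.learning_maf.loc[overlap].to_numpy(dtype=float)
    dose = gg.dosage.copy()
    miss = np.isnan(dose)
    dose[miss] = np.broadcast_to(fill, dose.shape)[miss]
    return pd.Series(dose @ w, index=gg.samples, name="grs")


def mann_whitney(scores_a, scores_b) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U with midranks, tie-corrected normal
    approximation and continuity correction; exact enumeration over all
    group assignments when the pooled size is at most 12.

    Returns (U of group a, z, p).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = len(a), len(b)
    pooled = np.r_[a, b]
    ranks = stats.rankdata(pooled)
    U = ranks[:na].sum() - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    if np.ptp(pooled) == 0:
        return U, 0.0, 1.0

    n = na + nb
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts)
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return U, 0.0, 1.0
    cc = 0.5 if abs(U - mu) >= 0.5 else 0.0
    z = (U - mu - np.sign(U - mu) * cc) / np.sqrt(var)

    if n <= 12 and comb(n, na) <= 1000:
        obs_dev = abs(U - mu)
        count = total = 0
        idx = np.arange(n)
        for pos in combinations(idx, na):
            sel = np.zeros(n, dtype=bool)
            sel[list(pos)] = True
            u = ranks[sel].sum() - na * (na + 1) / 2.0
            total += 1
            if abs(u - mu) >= obs_dev - 1e-12:
                count += 1
        return U, float(z), count / total
    p = 2.0 * stats.norm.sf(abs(z))
    return U, float(z), float(min(p, 1.0))


def grs_group_trend(scores: pd.Series, ordered_groups: pd.Series):
    """OLS trend of the GRS over group rank 1..4 (latest -> earliest).

    A positive slope means higher scores with earlier onset.  Returns
    (slope, t, p).
    """
    lab = ordered_groups.astype(str)
    levels = [g_ for g_ in GROUP_ORDER if (lab == g_).any()]
    if len(levels) < 2:
        raise ValueError("need at least two groups for a trend")
    rank = lab.map({g_: GROUP_ORDER.index(g_) + 1 for g_ in levels})
    x = rank.to_numpy(dtype=float)
    y = scores.loc[ordered_groups.index].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        return 0.0, 0.0, 1.0
    fit = stats.linregress(x, y)
    if fit.stderr > 0:
        t = fit.slope / fit.stderr
    else:  # perfect fit: infinite t unless the slope itself is zero
        t = 0.0 if fit.slope == 0 else np.inf * np.sign(fit.slope)
    return float(fit.slope), float(t), float(fit.pvalue)


def group_descriptives(ped: pd.DataFrame, group_col: str = "aao_group",
                       groups: tuple[str, str] = ("earliest", "latest")
                       ) -> pd.DataFrame:
    """Two-group descriptive contrasts: sex by two-sided Fisher exact,
    age and AAO by Welch t-test.  Returns one row per variable with
    group means/SDs (or counts) and the p-value."""
    a = ped[ped[group_col] == groups[0]]
    b = ped[ped[group_col] == groups[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    tab = np.array([[int((a["sex"] == 1).sum()), int((a["sex"] == 2).sum())],
                    [int((b["sex"] == 1).sum()), int((b["sex"] == 2).sum())]])
    if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
        p_sex = 1.0
    else:
        p_sex = float(stats.fisher_exact(tab)[1])
    rows.append(("male_n", tab[0, 0], tab[1, 0], p_sex))
    for var in ("age", "aao"):
        xa = a[var].dropna().to_numpy(dtype=float)
        xb = b[var].dropna().to_numpy(dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            continue
        if np.ptp(np.r_[xa, xb]) == 0:
            p = 1.0
        else:
            p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        rows.append((f"{var}_mean", xa.mean(), xb.mean(), p))
        rows.append((f"{var}_sd", xa.std(ddof=1), xb.std(ddof=1), np.nan))
    return pd.DataFrame(rows, columns=["variable", groups[0], groups[1], "p"])
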