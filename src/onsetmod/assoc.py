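"""Extreme-group association scan, permutation p-values, candidate
selection, LD collapsing, and design-stage power.

The screening contrast is a binary comparison of probands from families
at the two tails of the age-at-onset distribution (earliest coded 1), so
an odds ratio above 1 means the minor allele is enriched in the
early-onset group.  Per-marker tests are additive-dosage logistic fits,
optionally adjusted for multidimensional-scaling ancestry components.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .gio import GenotypeMatrix
from .qc import MdsComponents

__all__ = [
    "LogisticFit", "logistic_fit",
    "gwas_scan", "empirical_p",
    "select_candidates", "ld_collapse",
    "power_two_group",
    "SUGGESTIVE_P", "GENOMEWIDE_P",
]

SUGGESTIVE_P = 1e-4
GENOMEWIDE_P = 7.2e-8

_BETA_DIVERGE = 15.0     # |beta| beyond this flags separation
_MAX_ITER = 50
_SCORE_TOL = 1e-8


@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    converged: bool
    n_iter: int
    loglik: float


def logistic_fit(y: np.ndarray, X: np.ndarray) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    ``X`` must include the intercept column.  Convergence when the score
    norm drops below 1e-8 (max 50 iterations); complete or quasi-complete
    separation is detected by a diverging coefficient (|beta| > 15) and
    reported as non-converged with missing p-values.

    Raises ``ValueError`` when the outcome has a single class or a
    non-intercept column is constant.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    const_cols = np.where(X.std(axis=0) == 0)[0]
    if len(const_cols) > 1:
        raise ValueError("more than one constant column in design "
                         "(constant predictor besides the intercept)")
    k = X.shape[1]
    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < _SCORE_TOL:
            converged = True
            break
        XtWX = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(XtWX, score, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(beta)) > _BETA_DIVERGE:
            converged = False
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = mu * (1.0 - mu)
    XtWX = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(XtWX)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(k, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
        p = 2.0 * stats.norm.sf(np.abs(z))
    if not converged:
        p = np.full(k, np.nan)
    with np.errstate(divide="ignore"):
        ll = float(np.sum(y * np.log(np.clip(mu, 1e-300, 1))
                          + (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1))))
    return LogisticFit(beta, se, p, converged, it, ll)


def select_mds_covariates(mds: MdsComponents, y: np.ndarray,
                          alpha: float = 0.05) -> list[str]:
    """Components whose between-group two-sample t-test has p < alpha."""
    keep = []
    for c in mds.coords.columns:
        x = mds.coords[c].to_numpy(dtype=float)
        t = stats.ttest_ind(x[y == 1], x[y == 0], equal_var=False)
        if t.pvalue < alpha:
            keep.append(c)
    return keep


def gwas_scan(g: GenotypeMatrix, groups: pd.Series,
              mds: MdsComponents | None = None) -> pd.DataFrame:
    """Per-marker additive logistic scan of earliest- vs latest-onset probands.

    ``groups`` maps sample id to ``earliest``/``latest``.  Of the MDS
    components, every one that differs between the groups (two-sample
    t-test p < 0.05) enters as a covariate; with none significant the
    scan runs unadjusted.  Missing dosage drops the sample marker-wise.
    """
    samples = list(groups.index)
    gg = g.subset(samples=samples)
    lab = groups.astype(str)
    if not set(lab.unique()) <= {"earliest", "latest"}:
        raise ValueError("groups must be labelled earliest/latest")
    y = (lab == "earliest").to_numpy(dtype=float)

    covars = np.empty((len(samples), 0))
    used_components: list[str] = []
    if mds is not None:
        mc = mds.coords.loc[samples]
        used_components = select_mds_covariates(
            MdsComponents(mc, mds.eigenvalues), y)
        if used_components:
            covars = mc[used_components].to_numpy(dtype=float)
        else:
            warnings.warn("no MDS component differs between groups; "
                          "running unadjusted")
    rows = []
    for j, mid in enumerate(gg.markers.index):
        d = gg.dosage[:, j]
        ok = ~np.isnan(d)
        yy, dd, cc = y[ok], d[ok], covars[ok]
        maf_e = dd[yy == 1].mean() / 2 if np.any(yy == 1) else np.nan
        maf_l = dd[yy == 0].mean() / 2 if np.any(yy == 0) else np.nan
        if dd.min() == dd.max() or yy.min() == yy.max():
            rows.append((mid, np.nan, np.nan, np.nan, np.nan, np.nan,
                         maf_e, maf_l, int(ok.sum())))
            continue
        X = np.column_stack([np.ones(ok.sum()), dd, cc])
        fit = logistic_fit(yy, X)
        beta = fit.beta[1] if fit.converged else np.nan
        rows.append((mid, beta, math.exp(beta) if np.isfinite(beta) else np.nan,
                     fit.se[1], fit.p[1], np.nan, maf_e, maf_l, int(ok.sum())))
    res = pd.DataFrame(rows, columns=[
        "marker", "beta", "or_", "se", "p_wald", "p_empirical",
        "maf_earliest", "maf_latest", "n_used"])
    res.attrs["mds_components_used"] = used_components
    return res


def _wald_absz(y, X) -> float:
    fit = logistic_fit(y, X)
    if not fit.converged or not np.isfinite(fit.se[1]) or fit.se[1] == 0:
        return np.nan
    return abs(fit.beta[1] / fit.se[1])


def empirical_p(g: GenotypeMatrix, groups: pd.Series, marker: str,
                mds: MdsComponents | None = None, B_max: int = 10_000,
                seed: int = 0, adaptive_hits: int = 10,
                enumerate_limit: int = 5000) -> tuple[float, int]:
    """Permutation p-value for one marker's association.

    The statistic is the refit Wald |z| of the dosage term under permuted
    group labels.  Small samples (number of distinct label arrangements
    <= ``enumerate_limit``) are enumerated exhaustively and the p-value
    is exact; otherwise Monte-Carlo sampling with the add-one estimator
    ``(1 + #{perm >= obs}) / (1 + B)`` and adaptive early stopping once
    ``adaptive_hits`` exceedances accumulate.  Returns (p, B used).
    """
    if B_max < 100:
        raise ValueError("B_max must be >= 100")
    samples = list(groups.index)
    gg = g.subset(samples=samples, markers=[marker])
    y = (groups.astype(str) == "earliest").to_numpy(dtype=float)
    d = gg.dosage[:, 0]
    ok = ~np.isnan(d)
    y, d = y[ok], d[ok]
    covars = (mds.coords.loc[samples].to_numpy(dtype=float)[ok]
              if mds is not None else np.empty((ok.sum(), 0)))
    X = np.column_stack([np.ones(len(y)), d, covars])
    obs = _wald_absz(y, X)
    if not np.isfinite(obs):
        return np.nan, 0

    n, n1 = len(y), int(y.sum())
    if math.comb(n, n1) <= enumerate_limit:
        count = total = 0
        for pos in combinations(range(n), n1):
            yy = np.zeros(n)
            yy[list(pos)] = 1.0
            s = _wald_absz(yy, X)
            total += 1
            if np.isfinite(s) and s >= obs - 1e-12:
                count += 1
        return count / total, total

    rng = np.random.default_rng(seed)
    hits = 0
    b = 0
    yy = y.copy()
    while b < B_max:
        rng.shuffle(yy)
        s = _wald_absz(yy, X)
        b += 1
        if np.isfinite(s) and s >= obs - 1e-12:
            hits += 1
            if hits >= adaptive_hits:
                break
    return (1 + hits) / (1 + b), b


def select_candidates(results: pd.DataFrame, g: GenotypeMatrix,
                      suggestive: float = SUGGESTIVE_P,
                      genomewide: float = GENOMEWIDE_P) -> pd.DataFrame:
    """Markers below the suggestive threshold, sorted by (chrom, pos).

    Comparisons are strict; genome-wide hits carry an extra flag.
    Returns a candidate table with provenance column ``status`` =
    ``retained`` (for later LD collapsing to update).
    """
    if results.empty:
        raise ValueError("empty result table")
    hit = results[results["p_wald"] < suggestive].copy()
    hit["genomewide"] = hit["p_wald"] < genomewide
    hit["status"] = "retained"
    hit["collapsed_into"] = ""
    pos = g.markers.loc[hit["marker"], ["chrom", "pos"]].reset_index(drop=True)
    hit = hit.reset_index(drop=True)
    hit["chrom"], hit["pos"] = pos["chrom"], pos["pos"]
    return hit.sort_values(["chrom", "pos"], kind="mergesort",
                           key=lambda s: s.map(_chrom_key) if s.name == "chrom" else s
                           ).reset_index(drop=True)


def _chrom_key(c):
    try:
        return (0, int(c))
    except (TypeError, ValueError):
        return (1, str(c))


def ld_collapse(candidates: pd.DataFrame, g: GenotypeMatrix,
                r2_thresh: float = 0.8, window_bp: int = 500_000) -> pd.DataFrame:
    """Greedy LD pruning of the candidate set.

    Candidates are processed by ascending p; a marker is absorbed by an
    already-retained marker when their dosage r^2 exceeds the threshold
    and they lie within the window on the same chromosome.  Absorbed rows
    record their sink, so the bookkeeping (retained + collapsed) is
    conserved.  The result is order-independent of the input.
    """
    cand = candidates.copy().reset_index(drop=True)
    order = cand.sort_values(["p_wald", "marker"], kind="mergesort").index
    dose = {m: g.dosage[:, g.markers.index.get_loc(m)]
            for m in cand["marker"]}
    info = g.markers
    retained: list[int] = []
    for i in order:
        mi = cand.at[i, "marker"]
        ci, pi = info.at[mi, "chrom"], info.at[mi, "pos"]
        sink = None
        for r in retained:
            mr = cand.at[r, "marker"]
            if info.at[mr, "chrom"] != ci:
                continue
            if abs(int(info.at[mr, "pos"]) - int(pi)) > window_bp:
                continue
            a, b = dose[mi], dose[mr]
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < 2 or a[ok].std() == 0 or b[ok].std() == 0:
                warnings.warn(f"pair ({mi},{mr}): no usable dosage overlap; "
                              "treated as unlinked")
                continue
            r2 = np.corrcoef(a[ok], b[ok])[0, 1] ** 2
            if r2 > r2_thresh:
                sink = mr
                break
        if sink is None:
            retained.append(i)
        else:
            cand.at[i, "status"] = "ld_collapsed"
            cand.at[i, "collapsed_into"] = sink
    return cand


def power_two_group(maf: float, grr_het: float, grr_hom: float,
                    prev_early: float, n_per_group: int,
                    alpha: float = 0.05) -> float:
    """Analytic power of the two-group extreme design for one SNP.

    Genotype frequencies follow Hardy-Weinberg at the given MAF; the
    penetrance scale solves ``prev = sum_g f_g P(g)`` with
    ``f1 = grr_het * f0`` and ``f2 = grr_hom * f0``; group-wise genotype
    distributions follow by Bayes.  Power is that of the 1-df additive
    (Cochran-Armitage) trend test via its non-central chi-square with the
    non-centrality computed from the two genotype multinomials.
    """
    if not (0 < maf <= 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    if grr_het < 1 or grr_hom < 1:
        raise ValueError("genotype relative risks must be >= 1")
    if not (0 < prev_early < 1):
        raise ValueError("prev_early must lie in (0,1)")
    if n_per_group <= 0 or not (0 < alpha < 1):
        raise ValueError("invalid n_per_group or alpha")
    p = maf
    P = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    grr = np.array([1.0, grr_het, grr_hom])
    f0 = prev_early / float(P @ grr)
    f = f0 * grr
    if f[2] > 1:
        raise ValueError("penetrance overflow: implied f2 > 1")
    p_case = f * P / prev_early
    p_ctrl = (1 - f) * P / (1 - prev_early)
    x = np.array([0.0, 1.0, 2.0])
    d = float(x @ (p_case - p_ctrl))
    pbar = (p_case + p_ctrl) / 2
    var0 = float(x ** 2 @ pbar - (x @ pbar) ** 2)      # test's null variance
    var1 = (float(x ** 2 @ p_case - (x @ p_case) ** 2)
            + float(x ** 2 @ p_ctrl - (x @ p_ctrl) ** 2))
    if var0 <= 0 or var1 <= 0:
        return alpha
    se0 = np.sqrt(2.0 * var0 / n_per_group)
    se1 = np.sqrt(var1 / n_per_group)
    z_crit = stats.norm.isf(alpha / 2)
    # mean-score difference is Normal(d, se1^2); rejection when |D| > z*se0
    return float(stats.norm.sf((z_crit * se0 - abs(d)) / se1)
                 + stats.norm.sf((z_crit * se0 + abs(d)) / se1))
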