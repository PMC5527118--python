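"""Susceptibility-side confirmation: family-based association (additive
transmission test) and frequency-matched case-control logistic analysis.

The family-based statistic compares the minor-allele dosage transmitted
to affected offspring with its Mendelian expectation conditional on the
parental genotypes — the classical additive FBAT/TDT construction.  A
modifier locus that shifts onset age but not disease risk is null here
while remaining significant in the extreme-onset contrast; that contrast
is the design's central check.

Families with a missing parental genotype at a marker are excluded from
that marker's test (counted), a documented simplification relative to
full sufficient-statistic conditioning.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import logistic_fit
from .gio import GenotypeMatrix

__all__ = [
    "FamTestResult", "MatchError",
    "fbat_additive", "match_controls", "case_control_assoc",
]


class MatchError(ValueError):
    """Control pool cannot satisfy the requested matching ratio."""


# E[X] and Var[X] of the transmitted minor-allele dosage for one parent
# genotype: hom-major transmits 0, het transmits Bernoulli(1/2), hom-minor 1.
_PARENT_EV = {0.0: (0.0, 0.0), 1.0: (0.5, 0.25), 2.0: (1.0, 0.0)}


def fbat_additive(g: GenotypeMatrix, ped: pd.DataFrame, marker: str
                  ) -> pd.Series:
    """Additive family-based association test at one marker.

    ``S`` sums the minor-allele dosage of genotyped affected offspring
    over families with both parents genotyped; its expectation and
    variance follow from Mendelian transmission conditional on the
    parental pair (offspring independent given parents).  Families with
    both parents homozygous are uninformative.  Returns a Series with
    S, E_S, Var_S, z, p and the informative-family count; z/p are NaN
    when no family is informative.
    """
    col = g.markers.index.get_loc(marker)
    dose = {s: g.dosage[i, col] for i, s in enumerate(g.samples)}
    S = E = V = 0.0
    n_informative = 0
    n_excluded = 0
    for fid, fam in ped.groupby("fid"):
        parents = fam[fam["role"] == "parent"].set_index("iid")
        kids = fam[(fam["affected"] == "yes") & (fam["role"] != "parent")]
        if len(parents) < 2 or len(kids) == 0:
            n_excluded += 1
            continue
        pg = [dose.get(i, np.nan) for i in parents.index[:2]]
        if any(np.isnan(v) for v in pg):
            n_excluded += 1
            continue
        e1, v1 = _PARENT_EV[pg[0]]
        e2, v2 = _PARENT_EV[pg[1]]
        fam_var = 0.0
        used = 0
        for _, kid in kids.iterrows():
            x = dose.get(kid["iid"], np.nan)
            if np.isnan(x):
                continue
            S += x
            E += e1 + e2
            fam_var += v1 + v2
            used += 1
        if used and fam_var > 0:
            n_informative += 1
        V += fam_var
    if V > 0:
        z = (S - E) / np.sqrt(V)
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        z = p = np.nan
    return pd.Series({"marker": marker, "S": S, "E_S": E, "Var_S": V,
                      "z": z, "p": p, "n_informative": n_informative,
                      "n_excluded": n_excluded})


def _stratum(ped: pd.DataFrame, age_bin_years: float) -> pd.Series:
    b = (ped["age"] // age_bin_years).astype(int)
    return ped["sex"].astype(int).astype(str) + ":" + b.astype(str)


def match_controls(cases: pd.DataFrame, pool: pd.DataFrame, ratio: int = 5,
                   age_bin_years: float = 5.0, seed: int = 0) -> pd.DataFrame:
    """Frequency-match controls to cases on sex and binned age.

    Per-stratum quotas are ``ratio x case count`` apportioned by the
    largest-remainder rule (so they always sum to ``ratio x n_cases``),
    and controls are sampled without replacement within each stratum.
    Raises :class:`MatchError` naming the first deficient stratum.
    Returns the selected control pedigree rows with a ``stratum`` column.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    cs = _stratum(cases, age_bin_years)
    ps = _stratum(pool, age_bin_years)
    case_counts = cs.value_counts().sort_index()
    total = int(round(ratio * len(cases)))

    ideal = (case_counts * float(ratio)).astype(float)
    quota = np.floor(ideal).astype(int)
    shortfall = total - int(quota.sum())
    if shortfall > 0:
        remainders = (ideal - quota).sort_values(ascending=False,
                                                 kind="mergesort")
        for s in remainders.index[:shortfall]:
            quota[s] += 1

    rng = np.random.default_rng(seed)
    chosen = []
    for s, q in quota.items():
        avail = pool.index[ps == s]
        if len(avail) < q:
            raise MatchError(
                f"stratum {s}: need {q} controls, pool has {len(avail)}")
        pick = rng.choice(len(avail), size=q, replace=False)
        chosen.extend(avail[sorted(pick)])
    out = pool.loc[chosen].copy()
    out["stratum"] = ps.loc[chosen]
    return out


def case_control_assoc(g_cases: GenotypeMatrix, g_controls: GenotypeMatrix,
                       covars: pd.DataFrame) -> pd.DataFrame:
    """Per-marker additive logistic case-control test with age and sex
    covariates.

    ``covars`` is indexed by sample id with columns ``age`` and ``sex``
    covering all cases and controls.  Constant covariates are dropped
    (the fit then equals the unadjusted model).
    """
    common = [m for m in g_cases.markers.index if m in g_controls.markers.index]
    ga = g_cases.subset(markers=common)
    gb = g_controls.subset(markers=common)
    samples = list(ga.samples) + list(gb.samples)
    y = np.r_[np.ones(ga.n_samples), np.zeros(gb.n_samples)]
    dose = np.vstack([ga.dosage, gb.dosage])
    C = covars.loc[samples, ["age", "sex"]].to_numpy(dtype=float)
    C = C[:, C.std(axis=0) > 0]
    rows = []
    for j, mid in enumerate(common):
        d = dose[:, j]
        ok = ~np.isnan(d)
        yy, dd = y[ok], d[ok]
        maf_case = dd[yy == 1].mean() / 2 if np.any(yy == 1) else np.nan
        maf_ctrl = dd[yy == 0].mean() / 2 if np.any(yy == 0) else np.nan
        if dd.min() == dd.max():
            rows.append((mid, np.nan, np.nan, np.nan, np.nan,
                         maf_case, maf_ctrl, int(ok.sum())))
            continue
        X = np.column_stack([np.ones(ok.sum()), dd, C[ok]])
        fit = logistic_fit(yy, X)
        beta = fit.beta[1] if fit.converged else np.nan
        rows.append((mid, beta,
                     np.exp(beta) if np.isfinite(beta) else np.nan,
                     fit.se[1], fit.p[1], maf_case, maf_ctrl, int(ok.sum())))
    return pd.DataFrame(rows, columns=[
        "marker", "beta", "or_", "se", "p_wald",
        "maf_cases", "maf_controls", "n_used"])
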