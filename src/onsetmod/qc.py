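"""Sample and marker quality control for family GWAS data.

Implements the standard pre-association screen: per-sample and per-marker
call rates, minor-allele frequency, an exact Hardy-Weinberg test, the
KING-robust pairwise kinship estimator for duplicate/relative detection,
identity-by-state distances with classical (Torgerson) multidimensional
scaling for population-structure components, leave-one-out outlier
flagging on those components, and the genomic inflation factor.

Sample checks run in a fixed order — call rate, then kinship, then
ancestry — and a sample failing several checks is reported under the
first, so attrition counts are unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .gio import GenotypeMatrix

__all__ = [
    "QcReport", "MdsComponents",
    "sample_call_rate", "hwe_exact", "marker_filters",
    "ibs_distance", "classical_mds", "ancestry_outliers",
    "kinship_robust", "kinship_matrix", "genomic_inflation",
    "sample_qc",
]

CHI2_1_MEDIAN = float(stats.chi2.median(1))  # 0.4549364...

KINSHIP_DUPLICATE = 0.354  # > 1/2^(3/2): duplicate / MZ-twin range


@dataclass
class QcReport:
    """Outcome of a QC pass: removals with a single primary reason each."""

    removed_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["iid", "reason"]))
    removed_markers: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["marker", "reason"]))
    thresholds: dict = field(default_factory=dict)
    lambda_gc: float = np.nan

    @property
    def kept_sample_count(self) -> int | None:
        return self.thresholds.get("n_samples_kept")


@dataclass
class MdsComponents:
    """Classical-MDS coordinates (components ordered by eigenvalue)."""

    coords: pd.DataFrame           # samples x components c1..ck
    eigenvalues: np.ndarray

    @property
    def k(self) -> int:
        return self.coords.shape[1]


def sample_call_rate(g: GenotypeMatrix) -> pd.Series:
    """Fraction of non-missing genotypes per sample."""
    if g.n_markers < 1:
        raise ValueError("need at least one marker")
    return g.sample_call_rate()


def hwe_exact(nAA: int, nAa: int, naa: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Sums the probabilities of all heterozygote counts (conditional on the
    allele counts) that are no more probable than the observed one, i.e.
    the standard exact formulation used for GWAS marker QC.  Counts should
    come from founders / one member per family; relatedness distorts the
    null.  Returns NaN when all counts are zero.
    """
    if min(nAA, nAa, naa) < 0:
        raise ValueError("negative genotype count")
    n = nAA + nAa + naa
    if n == 0:
        return np.nan
    n_a = 2 * nAA + nAa          # copies of allele A
    rare = min(n_a, 2 * n - n_a)
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    logp = (hets * np.log(2.0)
            - gammaln((rare - hets) / 2 + 1)
            - gammaln(hets + 1)
            - gammaln((2 * n - rare - hets) / 2 + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == nAa][0]
    p = prob[prob <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def marker_filters(g: GenotypeMatrix, call_thresh: float = 0.98,
                   maf_thresh: float = 0.05, hwe_thresh: float = 0.001,
                   hwe_samples: list[str] | None = None) -> QcReport:
    """Marker QC in fixed order call rate -> MAF -> HWE.

    All comparisons are strict (a marker is kept only when its statistic
    is strictly greater than the threshold), matching the conventional
    ``>98%``, ``>0.05``, ``P > 0.001`` phrasing.  ``hwe_samples``
    restricts the HWE test to unrelated individuals (e.g. probands).
    """
    report = QcReport(thresholds={"marker_call": call_thresh,
                                  "maf": maf_thresh, "hwe": hwe_thresh})
    removed: list[tuple[str, str]] = []
    call = g.marker_call_rate()
    maf = g.maf()
    gh = g.subset(samples=hwe_samples) if hwe_samples is not None else g
    for j, mid in enumerate(g.markers.index):
        if not call.iloc[j] > call_thresh:
            removed.append((mid, "low_call"))
            continue
        if not maf.iloc[j] > maf_thresh:
            removed.append((mid, "low_maf"))
            continue
        col = gh.dosage[:, j]
        nAA = int(np.sum(col == 2)); nAa = int(np.sum(col == 1))
        naa = int(np.sum(col == 0))
        p = hwe_exact(nAA, nAa, naa)
        if not (np.isnan(p) or p > hwe_thresh):
            removed.append((mid, "hwe_fail"))
    report.removed_markers = pd.DataFrame(removed, columns=["marker", "reason"])
    return report


def ibs_distance(g: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise identity-by-state distance matrix.

    ``d(i,j) = 1 - shared_alleles / (2 M_ij)`` over the markers typed in
    both samples; on biallelic dosage this equals half the mean absolute
    dosage difference (the allele-sharing Hamming distance).
    """
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    D = np.asarray(g.dosage)
    ok = ~np.isnan(D)
    okf = ok.astype(float)
    # sum over markers of |di-dj|, decomposed by genotype-class pair counts
    ind = {v: (np.where(ok, D == v, False)).astype(float) for v in (0.0, 1.0, 2.0)}
    M = okf @ okf.T
    # |di-dj| summed = 1*(pairs differing by1) + 2*(pairs differing by 2)
    c02 = ind[0.0] @ ind[2.0].T
    diff2 = c02 + c02.T
    c01 = ind[0.0] @ ind[1.0].T
    c12 = ind[1.0] @ ind[2.0].T
    diff1 = c01 + c01.T + c12 + c12.T
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = (diff1 + 2.0 * diff2) / (2.0 * M)
    if np.any(M == 0):
        warnings.warn("sample pair(s) with no shared typed markers")
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=g.samples, columns=g.samples)


def classical_mds(d: pd.DataFrame | np.ndarray, k: int = 4) -> MdsComponents:
    """Torgerson scaling of a distance matrix into k components.

    Double-centres the squared distances, takes the top-k eigenpairs, and
    scales eigenvectors by the square root of their eigenvalues.  Sign
    convention: the largest-magnitude loading of each component is made
    positive, so coordinates are reproducible across runs and platforms.
    """
    if isinstance(d, pd.DataFrame):
        labels = list(d.index)
        D = d.to_numpy(dtype=float)
    else:
        D = np.asarray(d, dtype=float)
        labels = list(range(D.shape[0]))
    if not np.allclose(D, D.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    if pos.sum() < k:
        warnings.warn(f"only {int(pos.sum())} positive eigenvalues; "
                      f"returning {int(pos.sum())} of {k} components")
    k_eff = int(min(k, pos.sum()))
    coords = vecs[:, :k_eff] * np.sqrt(vals[:k_eff])
    for c in range(k_eff):
        i = np.argmax(np.abs(coords[:, c]))
        if coords[i, c] < 0:
            coords[:, c] = -coords[:, c]
    cols = [f"c{c + 1}" for c in range(k_eff)]
    return MdsComponents(pd.DataFrame(coords, index=labels, columns=cols),
                         vals[:k_eff].copy())


def ancestry_outliers(mds: MdsComponents, z_thresh: float = 5.0) -> list:
    """Leave-one-out z-score outliers on any MDS component.

    A sample is flagged when its coordinate lies more than ``z_thresh``
    SDs from the mean of the *other* samples on at least one component;
    leaving the sample out keeps a gross outlier from masking itself.
    Degenerate components (zero leave-one-out SD) flag nothing.
    """
    X = mds.coords.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples for outlier screening")
    flagged = []
    tot = X.sum(axis=0)
    totsq = (X ** 2).sum(axis=0)
    for i in range(n):
        mu = (tot - X[i]) / (n - 1)
        var = (totsq - X[i] ** 2) / (n - 1) - mu ** 2
        sd = np.sqrt(np.maximum(var * (n - 1) / (n - 2), 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.abs(X[i] - mu) / sd
        z = np.where(sd > 0, z, 0.0)
        if np.any(z > z_thresh):
            flagged.append(mds.coords.index[i])
    return flagged


def _king_counts(D: np.ndarray):
    ok = ~np.isnan(D)
    het = np.where(ok, D == 1.0, False).astype(float)
    hom0 = np.where(ok, D == 0.0, False).astype(float)
    hom2 = np.where(ok, D == 2.0, False).astype(float)
    okf = ok.astype(float)
    n_hh = het @ het.T                       # het in both
    c02 = hom0 @ hom2.T
    n_oo = c02 + c02.T                       # opposite homozygotes
    het_i_shared = het @ okf.T               # het in i over markers typed in j
    return n_hh, n_oo, het_i_shared


def kinship_robust(g: GenotypeMatrix, i: str, j: str) -> float:
    """KING-robust kinship estimate for one sample pair.

    ``phi = (N_het,het - 2 N_opp-hom) / (N_het(i) + N_het(j))`` over the
    markers typed in both samples.  0.5 for duplicates, ~0.25 for
    parent-offspring or full sibs.  NaN when the denominator is zero.
    """
    ii, jj = g.sample_index([i, j])
    D = g.dosage[[ii, jj], :]
    n_hh, n_oo, het_shared = _king_counts(D)
    denom = het_shared[0, 1] + het_shared[1, 0]
    if denom == 0:
        warnings.warn(f"pair ({i},{j}): no heterozygous shared markers")
        return np.nan
    return float((n_hh[0, 1] - 2.0 * n_oo[0, 1]) / denom)


def kinship_matrix(g: GenotypeMatrix) -> pd.DataFrame:
    """All-pairs KING-robust kinship (NaN diagonal-free convention: 0.5)."""
    n_hh, n_oo, het_shared = _king_counts(np.asarray(g.dosage))
    denom = het_shared + het_shared.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n_hh - 2.0 * n_oo) / denom
    return pd.DataFrame(phi, index=g.samples, columns=g.samples)


def genomic_inflation(p_values=None, chi2=None) -> float:
    """Genomic inflation factor: median test chi-square over its null median."""
    if chi2 is None:
        if p_values is None:
            raise ValueError("provide p_values or chi2")
        p = np.asarray(p_values, dtype=float)
        p = p[np.isfinite(p)]
        if p.size == 0:
            raise ValueError("no finite p-values")
        chi2 = stats.chi2.isf(p, 1)
    chi2 = np.asarray(chi2, dtype=float)
    chi2 = chi2[np.isfinite(chi2)]
    if chi2.size == 0:
        raise ValueError("no finite statistics")
    if chi2.size < 100:
        warnings.warn("fewer than 100 tests; inflation estimate is noisy")
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def sample_qc(g: GenotypeMatrix, call_thresh: float = 0.98,
              kinship_thresh: float = KINSHIP_DUPLICATE,
              z_thresh: float = 5.0, mds_k: int = 4) -> tuple[QcReport, MdsComponents]:
    """Sample-level QC in fixed order: call rate, kinship, ancestry.

    Kinship-flagged pairs drop the member with the lower call rate; MDS
    outlier screening runs on the samples surviving the first two checks.
    Returns the report plus the MDS components of the retained samples.
    """
    report = QcReport(thresholds={
        "sample_call": call_thresh, "kinship": kinship_thresh,
        "ancestry_z": z_thresh})
    removed: list[tuple[str, str]] = []

    call = g.sample_call_rate()
    for iid, cr in call.items():
        if not cr > call_thresh:
            removed.append((iid, "low_call"))
    keep = [s for s in g.samples if s not in {r[0] for r in removed}]

    g1 = g.subset(samples=keep)
    phi = kinship_matrix(g1)
    n = len(keep)
    kin_removed: set = set()
    for a in range(n):
        for b in range(a + 1, n):
            ia, ib = keep[a], keep[b]
            if ia in kin_removed or ib in kin_removed:
                continue
            if phi.iloc[a, b] > kinship_thresh:
                drop = ia if call[ia] <= call[ib] else ib
                kin_removed.add(drop)
                removed.append((drop, "high_kinship"))
    keep = [s for s in keep if s not in kin_removed]

    g2 = g.subset(samples=keep)
    mds = classical_mds(ibs_distance(g2), k=mds_k)
    for iid in ancestry_outliers(mds, z_thresh=z_thresh):
        removed.append((iid, "ancestry_outlier"))
    keep = [s for s in keep
            if s not in {r[0] for r in removed if r[1] == "ancestry_outlier"}]

    report.removed_samples = pd.DataFrame(removed, columns=["iid", "reason"])
    report.thresholds["n_samples_kept"] = len(keep)
    mds_final = classical_mds(ibs_distance(g.subset(samples=keep)), k=mds_k) \
        if len(keep) >= 3 else mds
    return report, mds_final
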