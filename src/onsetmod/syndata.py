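"""Seeded simulation of multiplex-family cohorts for the onset-modifier design.

The generator emulates the sampling frame of a family study of age at
onset (AAO): nuclear families ascertained for at least two affected
siblings, genotyped parents, an unrelated community-control pool, and the
quality-control defects that such studies screen out (low call rate,
duplicated samples, ancestry outliers).

Generative model
----------------
Founder alleles are drawn per marker from its minor-allele frequency;
under two-subpopulation structure the subpopulation frequencies follow a
Balding-Nichols Beta around the ancestral frequency.  Offspring genotypes
arise by gene dropping (one allele from each parent, markers independent).
AAO of an affected sibling is linear-Gaussian::

    AAO_i = mu + sum_j beta_j * g_ij + f_fam + eps_i,   AAO >= 7 years

with a family random intercept ``f_fam ~ N(0, family_sd^2)`` and
individual noise ``eps ~ N(0, residual_sd^2)``.  Current age is AAO plus
an illness duration ~ Uniform(5, 20) years.  An optional susceptibility
locus biases transmission from heterozygous parents to affected offspring
(minor allele transmitted with probability GRR/(1+GRR)), giving the
family-based susceptibility test a non-null bed; modifier loci shift AAO
only and are null for susceptibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gio import PED_COLUMNS, GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "FamilyCohort",
    "ConfigError",
    "SelectionError",
    "FixtureError",
    "simulate_cohort",
    "rank_and_select_extremes",
    "make_qc_fixture",
    "simulate_control_pool",
    "simulate_candidate_fixture",
]

AAO_FLOOR = 7.0
DURATION_RANGE = (5.0, 20.0)


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the field."""


class SelectionError(ValueError):
    """Extreme-group selection request exceeds the available families."""


class FixtureError(ValueError):
    """Invalid QC-defect fixture request (overlap or shortage)."""


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of a synthetic multiplex-family cohort.

    Defaults follow the target study design: families with two affected
    siblings, baseline mean AAO 23.7 years, and one planted modifier
    allele shifting onset by -4 years per copy at MAF 0.3.
    """

    n_families: int = 500
    sibs_per_family: int = 2
    markers: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_modifier_snps: int = 1
    modifier_effects_years: tuple[float, ...] = (-4.0,)
    modifier_maf: float | None = 0.3
    aao_mean_years: float = 23.7
    family_sd_years: float = 4.0
    residual_sd_years: float = 7.0
    fst: float = 0.0
    prop_pop2: float = 0.0
    missing_rate: float = 0.0
    susceptibility_grr: float = 1.0
    susceptibility_snp: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        if self.sibs_per_family < 2:
            raise ConfigError("sibs_per_family must be >= 2 (ascertainment)")
        if self.markers < 1:
            raise ConfigError("markers must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_modifier_snps > self.markers:
            raise ConfigError("n_modifier_snps cannot exceed markers")
        if len(self.modifier_effects_years) != self.n_modifier_snps:
            raise ConfigError(
                "modifier_effects_years length must equal n_modifier_snps")
        if self.modifier_maf is not None and not (0 < self.modifier_maf <= 0.5):
            raise ConfigError("modifier_maf must lie in (0, 0.5]")
        if self.family_sd_years < 0 or self.residual_sd_years < 0:
            raise ConfigError("family_sd_years/residual_sd_years must be >= 0")
        if not (0.0 <= self.fst < 1.0):
            raise ConfigError("fst must lie in [0, 1)")
        if not (0.0 <= self.prop_pop2 <= 1.0):
            raise ConfigError("prop_pop2 must lie in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.susceptibility_grr < 1.0:
            raise ConfigError("susceptibility_grr must be >= 1")
        if (self.susceptibility_snp is not None
                and not (0 <= self.susceptibility_snp < self.markers)):
            raise ConfigError("susceptibility_snp out of marker range")


@dataclass
class FamilyCohort:
    """A simulated cohort: genotypes over parents+sibs, pedigree, truth."""

    genotypes: GenotypeMatrix
    pedigree: pd.DataFrame
    true_modifiers: dict[str, float]   # marker id -> AAO shift per allele
    marker_maf: np.ndarray = field(repr=False)  # generative (ancestral) MAF
    subpop: np.ndarray | None = None   # per-family subpopulation (0/1)

    def probands(self) -> pd.DataFrame:
        return self.pedigree[self.pedigree["role"] == "proband"]


def _marker_map(n_markers: int) -> pd.DataFrame:
    """Markers spread over 22 autosomes, positions strictly increasing."""
    ids = [f"snp{j:05d}" for j in range(n_markers)]
    chroms, poss = [], []
    per = -(-n_markers // 22)
    for j in range(n_markers):
        chroms.append(str(j // per + 1))
        poss.append((j % per) * 50_000 + 10_000)
    alleles_minor = ["A"] * n_markers
    alleles_major = ["G"] * n_markers
    return pd.DataFrame(
        {"chrom": chroms, "pos": poss,
         "allele_minor": alleles_minor, "allele_major": alleles_major},
        index=pd.Index(ids, name="marker"))


def _draw_subpop_freqs(maf: np.ndarray, fst: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies around ancestral MAF."""
    a = maf * (1 - fst) / fst
    b = (1 - maf) * (1 - fst) / fst
    return np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)


def simulate_cohort(config: SimulationConfig) -> FamilyCohort:
    """Simulate a seeded multiplex-family cohort under the AAO model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.markers
    markers = _marker_map(L)

    maf = rng.uniform(*config.maf_range, size=L)
    mod_idx = np.arange(config.n_modifier_snps)
    if config.modifier_maf is not None:
        maf[mod_idx] = config.modifier_maf
    beta = np.zeros(L)
    beta[mod_idx] = np.asarray(config.modifier_effects_years)

    if config.fst > 0:
        p_pop = np.stack([_draw_subpop_freqs(maf, config.fst, rng),
                          _draw_subpop_freqs(maf, config.fst, rng)])
    else:
        p_pop = np.stack([maf, maf])
    fam_pop = (rng.random(config.n_families) < config.prop_pop2).astype(int)

    s_idx = config.susceptibility_snp
    s_bias = config.susceptibility_grr / (1.0 + config.susceptibility_grr)

    ids, fids, fathers, mothers, sexes, roles, affecteds = [], [], [], [], [], [], []
    aaos, ages = [], []
    hap_rows = []   # per-individual dosage rows
    n_sibs = config.sibs_per_family

    for f in range(config.n_families):
        fid = f"F{f:04d}"
        p = p_pop[fam_pop[f]]
        # founder haplotypes: 1 = minor allele
        dad = rng.random((2, L)) < p
        mom = rng.random((2, L)) < p
        fam_members = [(f"{fid}_P1", "0", "0", 1, "parent", "no",
                        dad.sum(axis=0)),
                       (f"{fid}_P2", "0", "0", 2, "parent", "no",
                        mom.sum(axis=0))]
        f_fam = rng.normal(0.0, config.family_sd_years)
        for s in range(n_sibs):
            pick_d = rng.random(L) < 0.5
            pick_m = rng.random(L) < 0.5
            if s_idx is not None and config.susceptibility_grr > 1.0:
                # over-transmission from het parents to affected offspring
                if dad[0, s_idx] != dad[1, s_idx]:
                    want_minor = rng.random() < s_bias
                    pick_d[s_idx] = dad[0, s_idx] == want_minor
                if mom[0, s_idx] != mom[1, s_idx]:
                    want_minor = rng.random() < s_bias
                    pick_m[s_idx] = mom[0, s_idx] == want_minor
            child = (np.where(pick_d, dad[0], dad[1]).astype(int)
                     + np.where(pick_m, mom[0], mom[1]).astype(int))
            fam_members.append((f"{fid}_S{s + 1}", f"{fid}_P1", f"{fid}_P2",
                                int(rng.integers(1, 3)), "co_sib", "yes",
                                child))
        parent_age_base = None
        for iid, pat, mat, sex, role, aff, dose in fam_members:
            ids.append(iid); fids.append(fid)
            fathers.append(pat); mothers.append(mat)
            sexes.append(sex); roles.append(role); affecteds.append(aff)
            if aff == "yes":
                aao = (config.aao_mean_years + float(beta @ dose) + f_fam
                       + rng.normal(0.0, config.residual_sd_years))
                aao = max(aao, AAO_FLOOR)
                age = aao + rng.uniform(*DURATION_RANGE)
                aaos.append(aao); ages.append(age)
            else:
                if parent_age_base is None:
                    parent_age_base = config.aao_mean_years + rng.uniform(25, 35)
                aaos.append(np.nan)
                ages.append(parent_age_base + rng.uniform(0, 5))
            hap_rows.append(dose)

    dosage = np.array(hap_rows, dtype=float)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    # orient each marker to its realized pooled minor allele, exactly as a
    # file reader would (ties keep the lexically smaller allele = "A")
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosage, axis=0) / 2.0
    flip = freq > 0.5
    if flip.any():
        dosage[:, flip] = 2.0 - dosage[:, flip]
        maf = np.where(flip, 1.0 - maf, maf)
        beta = np.where(flip, -beta, beta)
        markers.loc[flip, ["allele_minor", "allele_major"]] = \
            markers.loc[flip, ["allele_major", "allele_minor"]].to_numpy()

    ped = pd.DataFrame({
        "fid": fids, "iid": ids, "father": fathers, "mother": mothers,
        "sex": sexes, "affected": affecteds, "aao": aaos, "age": ages,
        "role": roles, "aao_group": "none",
    })[PED_COLUMNS]
    g = GenotypeMatrix(ids, markers, dosage)
    true_mod = {markers.index[j]: float(beta[j]) for j in mod_idx
                if beta[j] != 0.0}
    return FamilyCohort(g, ped, true_mod, maf, fam_pop)


def rank_and_select_extremes(cohort: FamilyCohort, n_extreme: int,
                             n_middle: int = 0) -> pd.DataFrame:
    """Rank families by mean affected-sib AAO and label the design groups.

    The ``n_extreme`` families at each tail become ``earliest``/``latest``;
    the next ``n_middle`` from each side become ``earlier``/``later``.  In
    each selected family one affected sibling whose AAO conforms to the
    family's side (minimum AAO on the early side, maximum on the late
    side) is promoted to ``proband``.  Ties in family mean AAO break by
    family id, so the ranking is invariant to input order.
    """
    ped = cohort.pedigree.copy()
    sibs = ped[(ped["role"].isin(["co_sib", "proband"]))
               & (ped["affected"] == "yes")]
    if sibs["aao"].isna().any():
        raise SelectionError("affected sibling with missing AAO")
    fam_mean = sibs.groupby("fid")["aao"].mean()
    n_fam = len(fam_mean)
    if 2 * (n_extreme + n_middle) > n_fam:
        raise SelectionError(
            f"requested 2*({n_extreme}+{n_middle}) families, "
            f"only {n_fam} available")
    order = fam_mean.sort_values(kind="mergesort").index.to_list()
    order = sorted(order, key=lambda f: (fam_mean[f], f))

    groups: dict[str, str] = {}
    for f in order[:n_extreme]:
        groups[f] = "earliest"
    for f in order[n_extreme:n_extreme + n_middle]:
        groups[f] = "earlier"
    for f in order[-n_extreme:] if n_extreme else []:
        groups[f] = "latest"
    for f in (order[-(n_extreme + n_middle):-n_extreme] if n_middle else []):
        groups[f] = "later"

    ped["aao_group"] = ped["fid"].map(groups).fillna("none")
    ped.loc[ped["role"].isin(["proband"]), "role"] = "co_sib"
    early = {"earliest", "earlier"}
    for fid, grp in groups.items():
        fam_sibs = sibs[sibs["fid"] == fid].sort_values(["aao", "iid"])
        chosen = fam_sibs.iloc[0 if grp in early else -1]["iid"]
        ped.loc[ped["iid"] == chosen, "role"] = "proband"
    return ped


def make_qc_fixture(base: FamilyCohort, n_lowcall: int, n_duplicate: int,
                    n_outlier: int, seed: int, fst: float = 0.1,
                    lowcall_rate: float = 0.90,
                    discordance: float = 0.01):
    """Plant QC defects among probands; returns (cohort, defect manifest).

    Low-call samples are degraded to the given call rate; a duplicate is a
    copy of another (clean) proband's genotypes with random discordance;
    ancestry outliers are redrawn from a diverged subpopulation
    (Balding-Nichols at the given Fst).
    """
    n_defects = n_lowcall + n_duplicate + n_outlier
    probands = list(base.pedigree.loc[base.pedigree["role"] == "proband", "iid"])
    if n_defects > len(probands) - n_duplicate:  # duplicates need clean sources
        raise FixtureError(
            f"{n_defects} defects requested but only {len(probands)} probands")
    if n_defects == 0:
        return base, pd.DataFrame(columns=["iid", "defect", "detail"])

    rng = np.random.default_rng(seed)
    g = base.genotypes
    dosage = g.dosage.copy()
    L = g.n_markers
    picked = rng.choice(len(probands), size=n_defects, replace=False)
    targets = [probands[i] for i in picked]
    if len(set(targets)) != n_defects:
        raise FixtureError("overlapping defect assignment")
    idx = g.sample_index(targets)

    manifest = []
    k = 0
    for _ in range(n_lowcall):
        i = idx[k]
        n_drop = int(round((1.0 - lowcall_rate) * L))
        drop = rng.choice(L, size=n_drop, replace=False)
        dosage[i, drop] = np.nan
        manifest.append((targets[k], "low_call", f"call_rate={lowcall_rate}"))
        k += 1
    for _ in range(n_duplicate):
        i = idx[k]
        clean = [p for p in probands if p not in targets]
        src = clean[int(rng.integers(len(clean)))]
        si = g.sample_index([src])[0]
        dosage[i, :] = dosage[si, :]
        n_flip = int(round(discordance * L))
        flip = rng.choice(L, size=n_flip, replace=False)
        for j in flip:
            cur = dosage[i, j]
            alts = [v for v in (0.0, 1.0, 2.0) if v != cur]
            dosage[i, j] = alts[int(rng.integers(len(alts)))]
        # a re-plated sample is slightly dirtier than the original, so the
        # kinship step's keep-higher-call-rate rule drops the copy
        n_degrade = max(1, int(round(0.005 * L)))
        dosage[i, rng.choice(L, size=n_degrade, replace=False)] = np.nan
        manifest.append((targets[k], "duplicate", src))
        k += 1
    if n_outlier:
        p_out = _draw_subpop_freqs(base.marker_maf, fst, rng)
        for _ in range(n_outlier):
            i = idx[k]
            dosage[i, :] = rng.binomial(2, p_out).astype(float)
            manifest.append((targets[k], "ancestry_outlier", f"fst={fst}"))
            k += 1

    g2 = GenotypeMatrix(list(g.samples), g.markers, dosage)
    cohort = FamilyCohort(g2, base.pedigree.copy(), dict(base.true_modifiers),
                          base.marker_maf)
    return cohort, pd.DataFrame(manifest, columns=["iid", "defect", "detail"])


def simulate_control_pool(n: int, maf: np.ndarray, markers: pd.DataFrame,
                          seed: int, age_range: tuple[float, float] = (10.0, 75.0)):
    """Unrelated community controls at the cohort's marker map.

    Genotypes are founder-like Binomial(2, MAF); ages Uniform over
    ``age_range``; sex Bernoulli(0.5).  Returns (pedigree, GenotypeMatrix).
    """
    if n <= 0:
        raise ConfigError("n must be > 0")
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, np.asarray(maf), size=(n, len(markers))).astype(float)
    ids = [f"C{i:05d}" for i in range(n)]
    ped = pd.DataFrame({
        "fid": ids, "iid": ids, "father": "0", "mother": "0",
        "sex": rng.integers(1, 3, size=n),
        "affected": "no", "aao": np.nan,
        "age": rng.uniform(*age_range, size=n),
        "role": "control", "aao_group": "none",
    })[PED_COLUMNS]
    return ped, GenotypeMatrix(ids, markers, dosage)


def simulate_candidate_fixture(n_per_group: int = 95, n_null: int = 50,
                               n_hits: int = 17, clique: tuple[int, int, int] = (8, 9, 10),
                               seed: int = 0, max_tries: int = 200):
    """Construct the candidate-selection fixture: a two-group genotype set
    in which exactly ``n_hits`` planted markers associate below the
    suggestive threshold (1e-4) and three of them form a tight high-LD
    clique (same chromosome, <300 bp apart, pairwise r^2 > 0.8).

    Planted markers separate the groups strongly (MAF ~0.45 vs ~0.10);
    each is redrawn until its Wald p clears the threshold, so the stated
    structure holds for every seed.  Returns (GenotypeMatrix, group labels,
    hit marker ids, clique marker ids).
    """
    from .assoc import logistic_fit

    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    y = np.r_[np.ones(n_per_group), np.zeros(n_per_group)]
    L = n_hits + n_null

    ids, chroms, poss = [], [], []
    for j in range(L):
        ids.append(f"cand{j:03d}")
        chroms.append(str(j % 20 + 1))
        poss.append(100_000 + j * 75_000)
    c0, c1, c2 = clique
    chroms[c1] = chroms[c2] = chroms[c0]
    poss[c1] = poss[c0] + 120
    poss[c2] = poss[c0] + 250

    dosage = np.empty((n, L))
    X = np.ones((n, 2))

    def draw_hit():
        early = rng.binomial(2, 0.45, size=n_per_group)
        late = rng.binomial(2, 0.10, size=n_per_group)
        return np.r_[early, late].astype(float)

    def wald_p(d):
        X[:, 1] = d
        fit = logistic_fit(y, X)
        return fit.p[1] if fit.converged else np.nan

    for j in range(L):
        if j in clique[1:]:
            continue
        if j < n_hits:
            for _ in range(max_tries):
                d = draw_hit()
                p = wald_p(d)
                if np.isfinite(p) and p < 1e-4:
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not plant a suggestive marker")
            dosage[:, j] = d
        else:
            f = rng.uniform(0.1, 0.5)
            dosage[:, j] = rng.binomial(2, f, size=n).astype(float)

    # clique copies: flip a couple of genotypes of the anchor; accept only
    # when the whole clique stays pairwise above the r^2 threshold and the
    # copy's p is above the anchor's (the anchor is the min-p member)
    p_anchor = wald_p(dosage[:, c0])
    done: list[int] = []
    for j in clique[1:]:
        for _ in range(max_tries):
            d = dosage[:, c0].copy()
            flip = rng.choice(n, size=max(1, n // 100), replace=False)
            for i in flip:
                alts = [v for v in (0.0, 1.0, 2.0) if v != d[i]]
                d[i] = alts[int(rng.integers(len(alts)))]
            partners = [dosage[:, c0]] + [dosage[:, k] for k in done]
            r2s = [np.corrcoef(d, q)[0, 1] ** 2 for q in partners]
            p = wald_p(d)
            if (min(r2s) > 0.8 and np.isfinite(p)
                    and p_anchor < p < 1e-4):
                dosage[:, j] = d
                done.append(j)
                break
        else:  # pragma: no cover
            raise RuntimeError("could not plant the LD clique")

    markers = pd.DataFrame(
        {"chrom": chroms, "pos": poss,
         "allele_minor": "A", "allele_major": "G"},
        index=pd.Index(ids, name="marker"))
    samples = [f"E{i:03d}" for i in range(n_per_group)] + \
              [f"L{i:03d}" for i in range(n_per_group)]
    g = GenotypeMatrix(samples, markers, dosage)
    hits = [ids[j] for j in range(n_hits)]
    return g, y, hits, [ids[j] for j in clique]
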