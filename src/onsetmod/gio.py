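"""Genotype/pedigree data model and file I/O.

The in-memory genotype container is a minor-allele dosage matrix
(samples x markers, values 0/1/2 with NaN for missing) plus a marker map.
Minor/major allele orientation is fixed once, at load or simulation time,
from the pooled allele frequency of the loaded samples; downstream modules
never re-orient, so group-wise MAF columns are always on the same scale.

Supported formats: white-space PED/MAP (PLINK text dialect), a VCF 4.x
subset (biallelic records, GT field, via cyvcf2), and TSV tables with
header for phenotypes and association results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PED_COLUMNS",
    "FormatError",
    "read_ped_map",
    "write_ped_map",
    "read_vcf_gt",
    "read_pheno_tsv",
    "write_pheno_tsv",
    "write_results_tsv",
    "read_results_tsv",
    "validate_pedigree",
]

#: canonical column order of a pedigree/phenotype table
PED_COLUMNS = [
    "fid", "iid", "father", "mother", "sex", "affected",
    "aao", "age", "role", "aao_group",
]

P_VALUE_COLUMNS = ("p_wald", "p_empirical", "p", "p_trend")


class FormatError(ValueError):
    """Malformed genotype file (ragged row, non-biallelic marker, ...)."""


@dataclass
class GenotypeMatrix:
    """Samples x markers minor-allele dosage matrix with marker map.

    Parameters
    ----------
    samples
        Ordered sample ids (unique).
    markers
        DataFrame indexed by marker id with columns ``chrom`` (str),
        ``pos`` (1-based bp, int), ``allele_minor``, ``allele_major``.
    dosage
        float array of shape (n_samples, n_markers); values in {0,1,2}
        counting the per-marker minor allele, NaN = missing.
    """

    samples: list[str]
    markers: pd.DataFrame
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.markers.index)

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None

    def maf(self) -> pd.Series:
        """Per-marker minor-allele frequency over non-missing genotypes."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            f = np.nanmean(self.dosage, axis=0) / 2.0
        return pd.Series(f, index=self.markers.index, name="maf")

    def sample_call_rate(self) -> pd.Series:
        cr = 1.0 - np.mean(np.isnan(self.dosage), axis=1)
        return pd.Series(cr, index=self.samples, name="call_rate")

    def marker_call_rate(self) -> pd.Series:
        cr = 1.0 - np.mean(np.isnan(self.dosage), axis=0)
        return pd.Series(cr, index=self.markers.index, name="call_rate")

    # -- subsetting ------------------------------------------------------
    def subset(self, samples=None, markers=None) -> "GenotypeMatrix":
        """Restrict to the given sample ids and/or marker ids (order kept)."""
        g = self
        if samples is not None:
            idx = g.sample_index(samples)
            g = GenotypeMatrix(list(samples), g.markers, g.dosage[idx, :])
        if markers is not None:
            col = g.markers.index.get_indexer(list(markers))
            if (col < 0).any():
                missing = [m for m, c in zip(markers, col) if c < 0]
                raise KeyError(f"unknown marker ids {missing[:3]}")
            g = GenotypeMatrix(g.samples, g.markers.iloc[col], g.dosage[:, col])
        return g

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = np.lexsort((self.markers["pos"].to_numpy(),
                            self.markers["chrom"].to_numpy()))
        return GenotypeMatrix(self.samples, self.markers.iloc[order],
                              self.dosage[:, order])


def _orient_minor(allele_counts: dict[str, int]) -> tuple[str, str]:
    """Pick (minor, major) from pooled allele counts; lexical tie-break."""
    alleles = sorted(allele_counts)  # lexical order stabilises ties
    if len(alleles) == 1:
        a = alleles[0]
        other = "0"  # monomorphic: synthesise a placeholder major? no --
        # monomorphic marker: observed allele is the major one by frequency
        return (other, a) if allele_counts[a] > 0 else (a, other)
    a, b = alleles
    if allele_counts[a] < allele_counts[b]:
        return a, b
    if allele_counts[b] < allele_counts[a]:
        return b, a
    return a, b  # exact 0.5: lexically smaller allele is "minor"


def read_ped_map(ped_path, map_path):
    """Read white-space PED/MAP into (GenotypeMatrix, pedigree DataFrame).

    The PED dialect is ``FID IID PAT MAT SEX PHENO`` followed by one allele
    pair per marker; ``0 0`` denotes a missing genotype.  The minor allele
    at each marker is the less frequent allele over all loaded samples
    (lexical tie-break), and dosage counts that allele.
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "marker", "cm", "pos"],
                     dtype={"chrom": str, "marker": str})
    n_markers = len(mp)

    fids, iids, fathers, mothers, sexes, phenos = [], [], [], [], [], []
    allele_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_path}: line {lineno}: expected "
                    f"{6 + 2 * n_markers} fields, found {len(tok)}"
                )
            fids.append(tok[0]); iids.append(tok[1])
            fathers.append(tok[2]); mothers.append(tok[3])
            sexes.append(tok[4]); phenos.append(tok[5])
            allele_rows.append(tok[6:])
    alleles = np.array(allele_rows, dtype=object).reshape(len(iids), n_markers, 2)

    dosage = np.full((len(iids), n_markers), np.nan)
    minor_l, major_l = [], []
    for j, mid in enumerate(mp["marker"]):
        a = alleles[:, j, :]
        nonmiss = a != "0"
        observed = a[nonmiss]
        counts: dict[str, int] = {}
        for al in observed:
            counts[al] = counts.get(al, 0) + 1
        if len(counts) > 2:
            raise FormatError(f"marker {mid!r} has >2 alleles: {sorted(counts)}")
        if not counts:
            minor, major = "0", "0"
        else:
            minor, major = _orient_minor(counts)
        minor_l.append(minor); major_l.append(major)
        complete = nonmiss.all(axis=1)
        dosage[complete, j] = (a[complete] == minor).sum(axis=1)

    markers = pd.DataFrame(
        {"chrom": mp["chrom"].to_numpy(), "pos": mp["pos"].to_numpy(dtype=int),
         "allele_minor": minor_l, "allele_major": major_l},
        index=pd.Index(mp["marker"], name="marker"),
    )
    g = GenotypeMatrix(iids, markers, dosage)

    sex = pd.Series(sexes).map({"1": 1, "2": 2}).fillna(0).astype(int)
    affected = pd.Series(phenos).map({"1": "no", "2": "yes"}).fillna("unknown")
    ped = pd.DataFrame({
        "fid": fids, "iid": iids, "father": fathers, "mother": mothers,
        "sex": sex.to_numpy(), "affected": affected.to_numpy(),
        "aao": np.nan, "age": np.nan, "role": "unknown", "aao_group": "none",
    })[PED_COLUMNS]
    return g, ped


def write_ped_map(g: GenotypeMatrix, ped: pd.DataFrame, ped_path, map_path) -> None:
    """Write the PED/MAP pair; AAO/age travel in the side TSV, never here."""
    with open(map_path, "w") as fh:
        for mid, row in g.markers.iterrows():
            fh.write(f"{row['chrom']}\t{mid}\t0\t{int(row['pos'])}\n")
    info = ped.set_index("iid")
    aff_code = {"no": "1", "yes": "2"}
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(g.samples):
            r = info.loc[iid]
            fields = [str(r["fid"]), iid, str(r["father"]), str(r["mother"]),
                      str(int(r["sex"])), aff_code.get(r["affected"], "0")]
            for j, (_, m) in enumerate(g.markers.iterrows()):
                d = g.dosage[i, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [m["allele_major"], m["allele_major"]]
                elif d == 1:
                    fields += [m["allele_minor"], m["allele_major"]]
                else:
                    fields += [m["allele_minor"], m["allele_minor"]]
            fh.write(" ".join(fields) + "\n")


def read_vcf_gt(vcf_path) -> GenotypeMatrix:
    """Read a biallelic VCF (GT field) into a GenotypeMatrix.

    Multi-allelic records are skipped with a single summary warning.  The
    dosage counts the *minor* allele recomputed from the loaded samples —
    ALT is not assumed to be minor.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_skipped = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(str(rec.CHROM)); poss.append(int(rec.POS))
        refs.append(rec.REF); alts.append(rec.ALT[0])
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = rec.gt_types.astype(float)
        alt_dosage = np.where(gt == 0, 0.0,
                      np.where(gt == 1, 1.0,
                      np.where(gt == 3, 2.0, np.nan)))
        rows.append(alt_dosage)
    if n_skipped:
        warnings.warn(f"{vcf_path}: skipped {n_skipped} multi-allelic record(s)")
    dosage = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))

    minor_l, major_l = [], []
    for j in range(dosage.shape[1]):
        col = dosage[:, j]
        n_ok = np.sum(~np.isnan(col))
        alt_freq = np.nansum(col) / (2 * n_ok) if n_ok else 0.0
        alt_is_minor = alt_freq < 0.5 or (
            alt_freq == 0.5 and alts[j] < refs[j])
        if alt_is_minor:
            minor_l.append(alts[j]); major_l.append(refs[j])
        else:
            minor_l.append(refs[j]); major_l.append(alts[j])
            dosage[:, j] = 2.0 - dosage[:, j]
    markers = pd.DataFrame(
        {"chrom": chroms, "pos": poss,
         "allele_minor": minor_l, "allele_major": major_l},
        index=pd.Index(ids, name="marker"),
    )
    return GenotypeMatrix(samples, markers, dosage)


def read_pheno_tsv(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype={"fid": str, "iid": str,
                                             "father": str, "mother": str})
    return ped[PED_COLUMNS]


def write_pheno_tsv(ped: pd.DataFrame, path) -> None:
    ped[PED_COLUMNS].to_csv(path, sep="\t", index=False)


def write_results_tsv(results: pd.DataFrame, path) -> None:
    """Write an association-result table; p-values in scientific notation."""
    out = results.copy()
    for c in out.columns:
        if c in P_VALUE_COLUMNS:
            out[c] = out[c].map(
                lambda p: "" if pd.isna(p) else f"{p:.4e}")
    out.to_csv(path, sep="\t", index=False)


def read_results_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"marker": str})


def validate_pedigree(ped: pd.DataFrame) -> None:
    """Check pedigree invariants; raise ValueError on the first violation."""
    iids = set(ped["iid"])
    for _, r in ped.iterrows():
        pat, mat = str(r["father"]), str(r["mother"])
        pat_in, mat_in = pat in iids, mat in iids
        founder = pat in ("0", "nan") and mat in ("0", "nan")
        if not founder and not (pat_in and mat_in):
            raise ValueError(
                f"individual {r['iid']}: parents must both be present "
                f"or both absent (father={pat}, mother={mat})")
    both = ped.dropna(subset=["aao", "age"])
    bad = both[both["aao"] > both["age"]]
    if len(bad):
        raise ValueError(f"aao > age for individuals {list(bad['iid'])[:3]}")
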