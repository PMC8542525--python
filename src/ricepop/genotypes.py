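"""Numeric genotype matrices for inbred rice accession panels.

Diploid bi-allelic calls are coded on a single numeric scale: homozygous
reference = 1.0, heterozygous = 0.5, homozygous alternate = 0.0, missing =
NaN.  All downstream stages (admixture fitting, PCA, distances, SNP scans)
consume this representation.  Locus filtering follows standard GBS practice:
a per-SNP call-rate floor applied first, then a minor-allele-frequency floor
computed on the surviving non-missing calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "encode_numeric",
    "filter_maf_callrate",
    "allele_freq",
    "impute_mean",
    "filter_biallelic_homozygous",
    "read_vcf",
    "write_vcf",
    "read_tsv",
    "write_tsv",
]

_VALID = np.array([0.0, 0.5, 1.0])

_GT_CODE = {"0/0": 1.0, "0|0": 1.0, "0/1": 0.5, "1/0": 0.5, "0|1": 0.5,
            "1|0": 0.5, "1/1": 0.0, "1|1": 0.0, "./.": np.nan, ".|.": np.nan,
            ".": np.nan}


def _default_loci(n_loci: int) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": ["1"] * n_loci,
        "pos": np.arange(1, n_loci + 1, dtype=np.int64),
        "ref": ["A"] * n_loci,
        "alt": ["T"] * n_loci,
    })


@dataclass
class GenotypeMatrix:
    """Accessions x loci numeric genotypes with locus metadata.

    Parameters
    ----------
    values : ndarray of shape (n_accessions, n_loci)
        Entries in {0, 0.5, 1} or NaN for missing.
    accession_ids : list of str
        Unique accession identifiers, one per row.
    loci : DataFrame with columns chrom, pos (1-based), ref, alt
        One row per locus; (chrom, pos) pairs unique.
    """

    values: np.ndarray
    accession_ids: list[str] = field(default=None)
    loci: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D accessions x loci array")
        n, L = self.values.shape
        if self.accession_ids is None:
            self.accession_ids = [f"ACC{i:04d}" for i in range(n)]
        self.accession_ids = list(self.accession_ids)
        if self.loci is None:
            self.loci = _default_loci(L)
        self.loci = self.loci.reset_index(drop=True)
        if len(self.accession_ids) != n:
            raise ValueError("accession_ids length does not match values")
        if len(self.loci) != L:
            raise ValueError("loci table length does not match values")
        if len(set(self.accession_ids)) != n:
            raise ValueError("accession_ids must be unique")
        key = list(zip(self.loci["chrom"], self.loci["pos"]))
        if len(set(key)) != L:
            raise ValueError("loci must be unique by (chrom, pos)")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, _VALID).all():
            bad = finite[~np.isin(finite, _VALID)][0]
            raise ValueError(f"non-missing genotype {bad!r} outside {{0, 0.5, 1}}")

    # -- basic properties -------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def call_rate(self) -> np.ndarray:
        """Per-locus fraction of accessions with a non-missing call."""
        return 1.0 - self.missing_mask.mean(axis=0)

    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.values[:, idx], self.accession_ids,
                              self.loci.iloc[idx])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values.copy(), list(self.accession_ids),
                              self.loci.copy())

    # convenience wrappers over the module-level operations
    def allele_freq(self) -> np.ndarray:
        return allele_freq(self)

    def impute_mean(self) -> "GenotypeMatrix":
        return impute_mean(self)


def encode_numeric(calls, accession_ids=None, loci=None) -> GenotypeMatrix:
    """Encode diploid genotype call strings to the numeric scale.

    ``calls`` is an (n, L) array-like of strings such as ``0/0``, ``0/1``,
    ``1/1`` or ``./.``.  0/0 maps to 1.0, heterozygotes to 0.5, 1/1 to 0.0
    and missing to NaN.  Multi-allelic or non-diploid calls raise a
    ``ValueError`` naming the offending site.
    """
    arr = np.asarray(calls, dtype=object)
    if arr.ndim == 1:
        arr = arr[None, :]
    out = np.empty(arr.shape, dtype=float)
    for j in range(arr.shape[1]):
        for i in range(arr.shape[0]):
            call = str(arr[i, j]).strip()
            if call not in _GT_CODE:
                raise ValueError(
                    f"call {call!r} at site column {j} (accession row {i}) "
                    "is not a bi-allelic diploid genotype")
            out[i, j] = _GT_CODE[call]
    return GenotypeMatrix(out, accession_ids, loci)


def allele_freq(G: GenotypeMatrix) -> np.ndarray:
    """Per-locus reference-allele frequency: mean of non-missing values.

    Loci with no non-missing call get NaN with a warning.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(G.values, axis=0)
    if np.isnan(freq).any():
        warnings.warn(f"{int(np.isnan(freq).sum())} all-missing loci have "
                      "undefined allele frequency (NaN)")
    return freq


def filter_maf_callrate(G: GenotypeMatrix, maf_min: float = 0.05,
                        callrate_min: float = 0.70) -> GenotypeMatrix:
    """Keep loci with call rate >= callrate_min and MAF >= maf_min.

    The call-rate filter is applied first; MAF = min(p, 1-p) with p the mean
    of the locus's non-missing numeric values.  The accession set is never
    changed.  An empty result is allowed (warning only).
    """
    for name, t in (("maf_min", maf_min), ("callrate_min", callrate_min)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name}={t} outside [0, 1]")
    cr_ok = G.call_rate() >= callrate_min
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(G.values, axis=0)
    maf = np.minimum(p, 1.0 - p)
    maf_ok = ~np.isnan(maf) & (maf >= maf_min)
    keep = np.flatnonzero(cr_ok & maf_ok)
    if keep.size == 0:
        warnings.warn("no loci survive MAF/call-rate filtering")
    return G.take_loci(keep)


def impute_mean(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing entries by the locus mean of non-missing values.

    Returns a complete (no-NaN) ndarray rather than a GenotypeMatrix:
    imputed means are generally not on the {0, 0.5, 1} grid.  Intended as
    the input to PCA and distance computations.  Non-missing entries are
    untouched.
    """
    miss = G.missing_mask
    if (miss.all(axis=0)).any():
        raise ValueError("all-missing locus: filter loci (call rate) before "
                         "mean imputation")
    out = G.values.copy()
    if miss.any():
        mean = np.nanmean(G.values, axis=0)
        out[miss] = np.broadcast_to(mean, out.shape)[miss]
    return out


def filter_biallelic_homozygous(G: GenotypeMatrix) -> GenotypeMatrix:
    """Keep loci at which every non-missing call is homozygous (no 0.5)."""
    has_het = np.nansum(G.values == 0.5, axis=0) > 0
    return G.take_loci(np.flatnonzero(~has_het))


# -- I/O -------------------------------------------------------------------

_NUM_TO_GT = {1.0: "0/0", 0.5: "0/1", 0.0: "1/1"}


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT-only bi-allelic SNP records."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(G.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.accession_ids) + "\n")
        vals = G.values
        for j, row in enumerate(G.loci.itertuples(index=False)):
            gts = ["./." if np.isnan(v) else _NUM_TO_GT[v] for v in vals[:, j]]
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t"
                     f"PASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read GT fields from a VCF into a numeric GenotypeMatrix (cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    cols, chroms, poss, refs, alts = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) > 1:
            raise ValueError(f"multi-allelic site {var.CHROM}:{var.POS} not supported")
        col = np.full(len(ids), np.nan)
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a is not None]
            if len(alleles) not in (0, 2):
                raise ValueError(f"non-diploid call at {var.CHROM}:{var.POS} "
                                 f"sample {ids[i]}")
            if len(alleles) == 2 and alleles[0] >= 0 and alleles[1] >= 0:
                col[i] = 1.0 - (alleles[0] + alleles[1]) / 2.0
        cols.append(col)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else "N")
    loci = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    return GenotypeMatrix(np.array(cols).T, ids, loci)


def write_tsv(G: GenotypeMatrix, path) -> None:
    """Plain TSV: rows = accessions, header = chrom:pos, NA = missing."""
    header = [f"{c}:{p}" for c, p in zip(G.loci["chrom"], G.loci["pos"])]
    df = pd.DataFrame(G.values, index=G.accession_ids, columns=header)
    df.to_csv(path, sep="\t", na_rep="NA", index_label="accession_id")


def read_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    chrom_pos = [c.rsplit(":", 1) for c in df.columns]
    loci = pd.DataFrame({
        "chrom": [c for c, _ in chrom_pos],
        "pos": [int(p) for _, p in chrom_pos],
        "ref": "A", "alt": "T",
    })
    return GenotypeMatrix(df.to_numpy(dtype=float), list(df.index.astype(str)), loci)
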