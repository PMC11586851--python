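"""Plain-text readers and writers for pedigrees, genotypes and daily records."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .relationships import MISSING, GenotypeMatrix

__all__ = [
    "write_pedigree",
    "read_pedigree",
    "write_genotypes_traw",
    "read_genotypes_traw",
    "write_genotypes_matrix",
    "read_genotypes_matrix",
]


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    """3-column tab-delimited pedigree (animal, sire, dam; 0 = unknown)."""
    pedigree[["animal", "sire", "dam"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", header=None, names=["animal", "sire", "dam"])
    return ped


def write_genotypes_traw(g: GenotypeMatrix, path) -> None:
    """PLINK-compatible transposed text (.traw-like): one row per SNP with
    CHR, SNP, (C)M, POS, COUNTED, ALT then one genotype column per animal;
    missing written as NA."""
    cols = {"CHR": g.chrom, "SNP": g.snp_ids}
    cols["(C)M"] = np.zeros(g.n_snps)
    cols["POS"] = np.arange(1, g.n_snps + 1)
    cols["COUNTED"] = ["A"] * g.n_snps
    cols["ALT"] = ["B"] * g.n_snps
    M = g.matrix.T.astype(object)
    M[M == MISSING] = "NA"
    geno = pd.DataFrame(M, columns=[str(a) for a in g.ids])
    df = pd.concat([pd.DataFrame(cols), geno], axis=1)
    df.to_csv(path, sep="\t", index=False)


def read_genotypes_traw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]
    animals = [c for c in df.columns if c not in meta]
    M = df[animals].to_numpy(dtype=float).T
    M = np.where(np.isnan(M), MISSING, M).astype(np.int8)
    return GenotypeMatrix(
        ids=np.array(animals, dtype=object),
        snp_ids=df["SNP"].to_numpy(dtype=object),
        chrom=df["CHR"].to_numpy(dtype=object),
        matrix=M,
    )


def write_genotypes_matrix(g: GenotypeMatrix, path) -> None:
    """Plain integer matrix (animals x SNPs) with animal-id row index and
    SNP-id header; missing as -9."""
    pd.DataFrame(g.matrix, index=g.ids, columns=g.snp_ids).to_csv(path, sep="\t")


def read_genotypes_matrix(path, chrom=None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    m = df.shape[1]
    if chrom is None:
        chrom = np.array(["1"] * m, dtype=object)
    return GenotypeMatrix(
        ids=df.index.to_numpy(),
        snp_ids=df.columns.to_numpy(dtype=object),
        chrom=chrom,
        matrix=df.to_numpy(dtype=np.int8),
    )
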