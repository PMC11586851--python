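"""Pedigree (A) and genomic (G) relationship matrices with SNP quality control.

A is the numerator relationship matrix from the tabular method on a
parents-first pedigree; G is the marker-based realized relationship matrix
G = (M - 2P)(M - 2P)' / (2 Σ p_j (1 - p_j)) with genotypes coded 0/1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "RelationshipMatrix",
    "qc_genotypes",
    "build_A",
    "build_G",
    "prune_pedigree",
    "stabilize",
]

MISSING = -9
_SEX_CHROMS = {"X", "Y", "XY", "MT", "23", "24", "25", "30", "31"}


@dataclass
class GenotypeMatrix:
    """Animals x SNPs genotype matrix coded 0/1/2 (MISSING = -9)."""

    ids: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    matrix: np.ndarray

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object).astype(str)
        self.matrix = np.asarray(self.matrix)
        n, m = self.matrix.shape
        if n != len(self.ids) or m != len(self.snp_ids):
            raise ValueError("matrix shape does not match id vectors")
        vals = self.matrix[self.matrix != MISSING]
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 2):
            raise ValueError("genotypes must be 0/1/2 or MISSING")

    @property
    def n_animals(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Observed frequency of the counted allele per SNP (missing ignored)."""
        M = np.where(self.matrix == MISSING, np.nan, self.matrix.astype(float))
        with np.errstate(invalid="ignore"):
            return np.nanmean(M, axis=0) / 2.0

    def subset(self, animal_mask=None, snp_mask=None) -> "GenotypeMatrix":
        am = slice(None) if animal_mask is None else animal_mask
        sm = slice(None) if snp_mask is None else snp_mask
        return GenotypeMatrix(
            ids=self.ids[am],
            snp_ids=self.snp_ids[sm],
            chrom=self.chrom[sm],
            matrix=self.matrix[am][:, sm],
        )


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix tagged as pedigree 'A' or genomic 'G'."""

    values: np.ndarray
    ids: np.ndarray
    kind: str = "A"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def inbreeding(self) -> np.ndarray:
        """F_i = a_ii - 1 (meaningful for the pedigree matrix)."""
        return np.diag(self.values) - 1.0

    def loc(self, i, j) -> float:
        idx = {a: k for k, a in enumerate(self.ids)}
        return float(self.values[idx[i], idx[j]])

    def submatrix(self, row_ids, col_ids=None) -> np.ndarray:
        idx = {a: k for k, a in enumerate(self.ids)}
        r = [idx[a] for a in row_ids]
        c = r if col_ids is None else [idx[a] for a in col_ids]
        return self.values[np.ix_(r, c)]


def qc_genotypes(
    raw: GenotypeMatrix,
    snp_call_rate: float = 0.95,
    maf: float = 0.05,
    animal_call_rate: float = 0.95,
    drop_sex_chromosomes: bool = True,
) -> tuple[GenotypeMatrix, dict]:
    """Apply SNP/animal quality control in the standard order.

    Filters, in order: sex chromosomes; SNPs with call rate *below*
    ``snp_call_rate``; SNPs with minor allele frequency *below* ``maf``
    (boundary values are kept); animals with call rate below
    ``animal_call_rate``.  Remaining missing genotypes are mean-imputed with
    2 p_j from the post-QC observed frequencies.  Returns the filtered
    (float-valued, complete) matrix and a report of counts removed.
    """
    g = raw
    report = {"n_snps_in": g.n_snps, "n_animals_in": g.n_animals}

    if drop_sex_chromosomes:
        keep = ~np.isin(np.char.upper(g.chrom.astype(str)), list(_SEX_CHROMS))
        report["snps_removed_sex_chrom"] = int((~keep).sum())
        g = g.subset(snp_mask=keep)
    else:
        report["snps_removed_sex_chrom"] = 0

    obs = g.matrix != MISSING
    cr = obs.mean(axis=0)
    keep = cr >= snp_call_rate
    report["snps_removed_call_rate"] = int((~keep).sum())
    g = g.subset(snp_mask=keep)

    p = g.allele_freq()
    m = np.minimum(p, 1 - p)
    keep = m >= maf
    report["snps_removed_maf"] = int((~keep).sum())
    g = g.subset(snp_mask=keep)

    if g.n_snps == 0:
        raise ValueError("quality control removed every SNP")

    obs = g.matrix != MISSING
    acr = obs.mean(axis=1)
    keep_a = acr >= animal_call_rate
    report["animals_removed_call_rate"] = int((~keep_a).sum())
    g = g.subset(animal_mask=keep_a)

    p = g.allele_freq()
    M = g.matrix.astype(float)
    miss = g.matrix == MISSING
    if miss.any():
        M[miss] = np.broadcast_to(2 * p, M.shape)[miss]
    report["n_snps_out"] = g.n_snps
    report["n_animals_out"] = g.n_animals
    report["n_imputed"] = int(miss.sum())
    out = GenotypeMatrix(ids=g.ids, snp_ids=g.snp_ids, chrom=g.chrom, matrix=np.clip(M, 0, 2))
    return out, report


def _parent_index(pedigree: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ids = pedigree["animal"].to_numpy()
    pos = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    si = np.full(n, n, dtype=np.int64)  # n = phantom "unknown" index
    di = np.full(n, n, dtype=np.int64)
    for i, (s, d) in enumerate(zip(pedigree["sire"], pedigree["dam"])):
        if s != 0:
            if s not in pos or pos[s] >= i:
                raise ValueError(f"sire {s} of animal {ids[i]} does not precede it")
            si[i] = pos[s]
        if d != 0:
            if d not in pos or pos[d] >= i:
                raise ValueError(f"dam {d} of animal {ids[i]} does not precede it")
            di[i] = pos[d]
    return ids, si, di


def prune_pedigree(
    pedigree: pd.DataFrame, max_generations: int = 10, anchor_ids=None
) -> pd.DataFrame:
    """Truncate pedigree depth: ancestors more than ``max_generations`` above
    any anchor animal (default: all animals without recorded offspring) are
    set to unknown parents and dropped if no longer referenced."""
    ids = pedigree["animal"].to_numpy()
    sire = dict(zip(ids, pedigree["sire"]))
    dam = dict(zip(ids, pedigree["dam"]))
    if anchor_ids is None:
        parents = set(pedigree["sire"]) | set(pedigree["dam"])
        anchor_ids = [a for a in ids if a not in parents]
    depth: dict = {}
    frontier = {a: 0 for a in anchor_ids}
    while frontier:
        nxt = {}
        for a, d in frontier.items():
            if d < depth.get(a, np.inf):
                depth[a] = d
                for p in (sire.get(a, 0), dam.get(a, 0)):
                    if p != 0:
                        nxt[p] = min(d + 1, nxt.get(p, np.inf))
        frontier = nxt
    keep = {a for a, d in depth.items() if d <= max_generations}
    out = pedigree[pedigree["animal"].isin(keep)].copy()
    out["sire"] = [s if s in keep else 0 for s in out["sire"]]
    out["dam"] = [d if d in keep else 0 for d in out["dam"]]
    return out.reset_index(drop=True)


def build_A(pedigree: pd.DataFrame, max_generations: int = 10) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    The pedigree must be sorted parents-before-offspring; unknown parents
    (coded 0) contribute nothing (base animals unrelated and non-inbred).
    a_ii = 1 + F_i with F_i = a(sire, dam)/2; a_ij = (a(j, sire_i) +
    a(j, dam_i)) / 2.  Pedigree depth beyond ``max_generations`` from the
    youngest animals is truncated first.
    """
    gen_depth = pedigree
    if max_generations is not None:
        gen_depth = prune_pedigree(pedigree, max_generations)
    ids, si, di = _parent_index(gen_depth)
    n = len(ids)
    # extra phantom row/col of zeros stands in for unknown parents
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        s, d = si[i], di[i]
        A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
        A[:i, i] = A[i, :i]
        A[i, i] = 1.0 + 0.5 * A[s, d]
    return RelationshipMatrix(values=A[:n, :n], ids=ids, kind="A")


def build_G(
    genotypes: GenotypeMatrix, freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix.

    G = (M - 2P)(M - 2P)' / (2 Σ_j p_j (1 - p_j)), where p_j is the frequency
    of the counted allele (observed in the genotyped set by default; pass
    ``freqs`` to use external base-population frequencies).
    """
    if genotypes.n_animals < 2:
        raise ValueError("need at least 2 animals")
    M = genotypes.matrix.astype(float)
    if (M == MISSING).any():
        raise ValueError("genotypes must be imputed/complete (run qc_genotypes)")
    p = genotypes.allele_freq() if freqs is None else np.asarray(freqs, dtype=float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs are monomorphic: VanRaden denominator is zero")
    Z = M - 2.0 * p
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(values=G, ids=genotypes.ids, kind="G")


def stabilize(
    G: RelationshipMatrix,
    epsilon: float = 0.01,
    A: RelationshipMatrix | None = None,
    blend: float | None = None,
) -> RelationshipMatrix:
    """Make G safely invertible: either add ``epsilon`` to the diagonal
    (default) or blend ``blend``·G + (1-blend)·A when a pedigree matrix is
    supplied.  Duplicate/cloned genotypes otherwise make raw G singular."""
    V = G.values.copy()
    if blend is not None:
        if A is None:
            raise ValueError("blending requires the pedigree matrix A")
        if not np.array_equal(G.ids, A.ids):
            raise ValueError("G and A must be indexed by the same animals")
        V = blend * V + (1.0 - blend) * A.values
    else:
        V[np.diag_indices_from(V)] += epsilon
    return RelationshipMatrix(values=V, ids=G.ids, kind=G.kind)
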