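"""Genotype QC, the VanRaden genomic relationship matrix G and the single-step H inverse."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import inv


@dataclass
class QCThresholds:
    min_call_rate: float = 0.95
    min_maf: float = 0.05  # strict: SNPs with MAF < min_maf are removed
    autosomes_only: bool = True


@dataclass
class QCReport:
    n_snp_in: int
    n_removed_non_autosomal: int
    n_removed_call_rate: int
    n_removed_maf: int
    n_snp_out: int
    n_animals: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class GenotypeData:
    """Post-QC genotypes: allele counts, marker map, frequencies and centred matrix."""

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    counts: np.ndarray  # float (missing already imputed to 2p)
    chrom: np.ndarray
    pos: np.ndarray
    freq: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.freq is None:
            self.freq = self.counts.mean(axis=0) / 2.0

    @property
    def n_animals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snp(self) -> int:
        return self.counts.shape[1]

    @property
    def centered(self) -> np.ndarray:
        """W_g: allele counts centred by twice the estimated allele frequency."""
        return self.counts - 2.0 * self.freq

    @property
    def scale(self) -> float:
        """sum_j 2 p_j (1 - p_j), the denominator of G and of the back-solving."""
        return float(np.sum(2.0 * self.freq * (1.0 - self.freq)))


_AUTOSOME_EXCLUDE = {"X", "Y", "MT", "M", "XY", "0"}


def _is_autosome(chrom) -> np.ndarray:
    out = []
    for c in chrom:
        s = str(c).strip().upper().removeprefix("CHR")
        out.append(s not in _AUTOSOME_EXCLUDE and s.isdigit() and int(s) > 0)
    return np.array(out, dtype=bool)


def load_and_qc_genotypes(
    geno_file,
    map_file,
    thresholds: QCThresholds | None = None,
) -> tuple[GenotypeData, QCReport]:
    """Read genotypes and map, apply QC filters in order: autosome, call rate, MAF.

    Genotype file: header of SNP names, rows ``animal,g1,...,gm`` with missing
    coded ``5`` or ``NA``.  Map file: ``snp,chrom,pos``.  Remaining missing
    genotypes are imputed to twice the observed allele frequency, after which
    frequencies are recomputed from the imputed matrix.
    """
    thresholds = thresholds or QCThresholds()
    geno = pd.read_csv(geno_file)
    animal_ids = geno.iloc[:, 0].astype(str).to_numpy()
    snp_ids = np.array(geno.columns[1:], dtype=object)
    M = geno.iloc[:, 1:].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    M[M == 5] = np.nan

    mp = pd.read_csv(map_file)
    mp.columns = [c.lower() for c in mp.columns]
    mp = mp.set_index(mp.columns[0])
    missing_map = [s for s in snp_ids if s not in mp.index]
    if missing_map:
        raise ValueError(f"map does not cover all SNPs, e.g. {missing_map[:5]}")
    chrom = mp.loc[snp_ids, "chrom"].to_numpy()
    pos = mp.loc[snp_ids, "pos"].to_numpy(float)

    n_in = M.shape[1]
    keep = np.ones(n_in, dtype=bool)
    n_auto = 0
    if thresholds.autosomes_only:
        auto = _is_autosome(chrom)
        n_auto = int(np.sum(~auto))
        keep &= auto

    called = ~np.isnan(M)
    call_rate = called.mean(axis=0)
    cr_fail = keep & (call_rate < thresholds.min_call_rate)
    n_cr = int(cr_fail.sum())
    keep &= ~cr_fail

    with np.errstate(invalid="ignore"):
        p = np.nanmean(M, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf_fail = keep & (maf < thresholds.min_maf)
    n_maf = int(maf_fail.sum())
    keep &= ~maf_fail

    if not keep.any():
        raise ValueError("all SNPs removed by QC")

    M = M[:, keep]
    p = p[keep]
    # impute missing to 2p, then recompute frequencies from the imputed matrix
    miss = np.isnan(M)
    if miss.any():
        M[miss] = np.broadcast_to(2.0 * p, M.shape)[miss]
    freq = M.mean(axis=0) / 2.0

    data = GenotypeData(
        animal_ids=animal_ids,
        snp_ids=snp_ids[keep],
        counts=M,
        chrom=chrom[keep],
        pos=pos[keep],
        freq=freq,
    )
    report = QCReport(
        n_snp_in=n_in,
        n_removed_non_autosomal=n_auto,
        n_removed_call_rate=n_cr,
        n_removed_maf=n_maf,
        n_snp_out=int(keep.sum()),
        n_animals=M.shape[0],
    )
    return data, report


def vanraden_g(geno: GenotypeData) -> np.ndarray:
    """G = W_g W_g' / sum_j 2 p_j (1 - p_j)."""
    k = geno.scale
    if k <= 0:
        raise ValueError("zero denominator: all SNPs monomorphic")
    W = geno.centered
    return (W @ W.T) / k


def blend_g(G: np.ndarray, A22: np.ndarray, blend: float = 0.05, tune: bool = False) -> np.ndarray:
    """G* = (1 - blend) G + blend A22, optionally rescaled so that the mean
    diagonal and mean off-diagonal of G match those of A22 before blending."""
    G = np.asarray(G, float)
    if tune:
        n = G.shape[0]
        off = ~np.eye(n, dtype=bool)
        gd, go = G.diagonal().mean(), G[off].mean() if n > 1 else 0.0
        ad, ao = A22.diagonal().mean(), A22[off].mean() if n > 1 else 0.0
        denom = gd - go
        if abs(denom) > 1e-12:
            b = (ad - ao) / denom
            a = ad - b * gd
            G = a + b * G
    return (1.0 - blend) * G + blend * A22


def build_h_inverse(
    A_inv: sparse.spmatrix,
    A22: np.ndarray,
    G: np.ndarray,
    genotyped_idx: np.ndarray,
    blend: float = 0.05,
    tune: bool = False,
) -> sparse.csr_matrix:
    """Single-step H inverse: A_inv augmented with (G*^-1 - A22^-1) on genotyped animals.

    ``genotyped_idx`` gives 0-based positions of genotyped animals in the
    pedigree ordering (matching rows of A22 and G).
    """
    A_inv = sparse.csr_matrix(A_inv)
    genotyped_idx = np.asarray(genotyped_idx, dtype=np.int64)
    if genotyped_idx.size == 0:
        return A_inv
    Gs = blend_g(G, A22, blend=blend, tune=tune)
    try:
        Gs_inv = inv(Gs)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "blended G is singular; increase the blending weight toward A22"
        ) from err
    block = Gs_inv - inv(A22)
    block = 0.5 * (block + block.T)
    rows = np.repeat(genotyped_idx, len(genotyped_idx))
    cols = np.tile(genotyped_idx, len(genotyped_idx))
    aug = sparse.csr_matrix((block.ravel(), (rows, cols)), shape=A_inv.shape)
    H_inv = (A_inv + aug).tocsr()
    return H_inv


def h_diagonal(
    A: np.ndarray,
    A22: np.ndarray,
    G: np.ndarray,
    genotyped_idx: np.ndarray,
    blend: float = 0.05,
    tune: bool = False,
) -> np.ndarray:
    """Diagonal of H (needed by the accuracy formula).

    H = A + [A12 A22^-1 (G* - A22) A22^-1 A21] on the appropriate blocks; the
    genotyped diagonal is simply diag(G*), and for non-genotyped animals the
    correction term is added to diag(A).
    """
    n = A.shape[0]
    g = np.zeros(n, dtype=bool)
    g[genotyped_idx] = True
    Gs = blend_g(G, A22, blend=blend, tune=tune)
    diag = A.diagonal().astype(float).copy()
    if genotyped_idx.size == 0:
        return diag
    diag[g] = Gs.diagonal()
    ng = ~g
    if ng.any():
        A12 = A[np.ix_(np.nonzero(ng)[0], genotyped_idx)]
        A22_inv = inv(A22)
        B = A12 @ A22_inv
        corr = np.einsum("ij,jk,ik->i", B, Gs - A22, B)
        diag[ng] += corr
    return diag
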