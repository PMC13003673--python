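"""GBLUP -> SNP-BLUP back-solving and windowed variance scans.

Animal-level posterior means (breeding values u or inbreeding loads i,
restricted to genotyped animals) are converted to per-allele SNP effects

    s = W_g' G^-1 a / sum_j 2 p_j (1 - p_j)

and each SNP's explained variance is 2 p_j (1 - p_j) s_j^2.  Windows of N
consecutive SNPs within a chromosome (sliding or disjoint) aggregate the
SNP-wise variances; percentages are relative to the genome-wide sum, which
ignores LD covariances and is therefore an approximation to the true genetic
variance captured by a region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genomic import GenotypeData


def backsolve_effects(geno: GenotypeData, G: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Per-allele SNP effects for animal-level values (u or i of genotyped animals)."""
    values = np.asarray(values, float)
    if values.shape[0] != G.shape[0]:
        raise ValueError("values must be indexed to G's animals")
    # G built from observed frequencies is singular along the all-ones vector
    # (centred columns); the minimum-norm solve keeps the projection identity
    # W_g s = values exact for values in the range of G.
    Ginv_v, _, rank, _ = np.linalg.lstsq(G, values, rcond=None)
    if rank == 0:
        raise ValueError("G has rank 0; nothing to back-solve")
    return geno.centered.T @ Ginv_v / geno.scale


def snp_variances(geno: GenotypeData, s: np.ndarray) -> np.ndarray:
    """Variance explained per SNP: 2 p_j (1 - p_j) s_j^2."""
    return 2.0 * geno.freq * (1.0 - geno.freq) * np.asarray(s, float) ** 2


def window_variances(
    geno: GenotypeData,
    var_by_snp: np.ndarray,
    window_size: int,
    mode: str = "sliding",
) -> pd.DataFrame:
    """Aggregate per-SNP variances into windows of ``window_size`` consecutive SNPs.

    SNPs must be ordered by chromosome then position (enforced here).  Windows
    never span chromosomes; a chromosome shorter than the window yields one
    chromosome-wide window.  ``pct`` is relative to the genome-wide total.
    """
    if mode not in ("sliding", "disjoint"):
        raise ValueError("mode must be 'sliding' or 'disjoint'")
    order = np.lexsort((geno.pos, np.asarray(geno.chrom, dtype=int)))
    chrom = np.asarray(geno.chrom, dtype=int)[order]
    pos = geno.pos[order]
    v = np.asarray(var_by_snp, float)[order]
    total = v.sum()
    rows = []
    for c in np.unique(chrom):
        m = chrom == c
        vc, pc = v[m], pos[m]
        idx = np.nonzero(m)[0]
        nc = len(vc)
        size = min(window_size, nc)
        if mode == "sliding":
            starts = range(nc - size + 1)
        else:
            starts = range(0, nc, size)
        for s0 in starts:
            s1 = min(s0 + size, nc)
            wv = vc[s0:s1].sum()
            rows.append(
                (
                    int(c),
                    int(idx[s0]),
                    int(idx[s1 - 1]),
                    float(pc[s0]),
                    float(pc[s1 - 1]),
                    s1 - s0,
                    wv,
                    100.0 * wv / total if total > 0 else 0.0,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "first_snp", "last_snp", "start_bp", "end_bp", "n_snp", "var", "pct"],
    )


def top_regions(windows: pd.DataFrame, threshold_pct: float = 1.0) -> pd.DataFrame:
    """Merge overlapping windows exceeding ``threshold_pct`` into regions.

    Returns one row per region with chromosome, bp bounds and the peak window
    percentage inside the region.
    """
    hot = windows.loc[windows["pct"] > threshold_pct].sort_values(["chrom", "start_bp"])
    regions = []
    for _, w in hot.iterrows():
        if (
            regions
            and regions[-1]["chrom"] == w["chrom"]
            and w["start_bp"] <= regions[-1]["end_bp"]
        ):
            regions[-1]["end_bp"] = max(regions[-1]["end_bp"], w["end_bp"])
            regions[-1]["peak_pct"] = max(regions[-1]["peak_pct"], w["pct"])
            regions[-1]["n_windows"] += 1
        else:
            regions.append(
                {
                    "chrom": int(w["chrom"]),
                    "start_bp": float(w["start_bp"]),
                    "end_bp": float(w["end_bp"]),
                    "peak_pct": float(w["pct"]),
                    "n_windows": 1,
                }
            )
    return pd.DataFrame(regions, columns=["chrom", "start_bp", "end_bp", "peak_pct", "n_windows"])


def manhattan_table(windows: pd.DataFrame) -> pd.DataFrame:
    """Plain tabular export for Manhattan plots: chrom, window midpoint bp, pct."""
    out = windows[["chrom", "pct"]].copy()
    out["mid_bp"] = 0.5 * (windows["start_bp"] + windows["end_bp"])
    return out[["chrom", "mid_bp", "pct"]]
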