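"""Genotype QC and construction of G and the single-step H inverse.

Reads the simulated genotypes, applies the QC filters (autosome, call rate
>= 0.95, MAF >= 0.05), builds the VanRaden G for the genotyped subset, blends
it with the pedigree block A22 and writes the H inverse in coordinate format.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from inbredload.genomic import QCThresholds, build_h_inverse, load_and_qc_genotypes, vanraden_g
from inbredload.pedigree import a_inverse, compute_inbreeding, load_and_sort, relationship_submatrix

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    ped = load_and_sort(ROOT / "simdata" / "pedigree.csv")
    compute_inbreeding(ped)
    geno, report = load_and_qc_genotypes(
        ROOT / "simdata" / "genotypes.csv", ROOT / "simdata" / "map.csv", QCThresholds()
    )
    print("QC report:", report.as_dict())

    gidx = np.array([ped.index_of(a) - 1 for a in geno.animal_ids])
    A22 = relationship_submatrix(ped, geno.animal_ids)
    G = vanraden_g(geno)
    print(f"G: {G.shape[0]} genotyped animals; mean diag {G.diagonal().mean():.3f} "
          f"(A22 mean diag {A22.diagonal().mean():.3f})")

    H_inv = build_h_inverse(a_inverse(ped), A22, G, gidx, blend=0.05)
    coo = sparse.coo_matrix(H_inv)
    pd.DataFrame({"i": coo.row + 1, "j": coo.col + 1, "value": coo.data}).to_csv(
        ROOT / "h_inverse.csv", index=False
    )
    print(f"H inverse: {H_inv.shape[0]} animals, {coo.nnz} nonzeros -> results/h_inverse.csv")
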