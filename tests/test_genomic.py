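import io

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from inbredload.genomic import (
    QCThresholds,
    blend_g,
    build_h_inverse,
    h_diagonal,
    load_and_qc_genotypes,
    vanraden_g,
)
from inbredload.pedigree import a_inverse, relationship_submatrix, tabular_a

from conftest import random_pedigree


def _write_geno(counts, snp_ids, animals):
    df = pd.DataFrame(counts, columns=snp_ids)
    df.insert(0, "animal", animals)
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return buf


def _write_map(snp_ids, chrom, pos):
    buf = io.StringIO()
    pd.DataFrame({"snp": snp_ids, "chrom": chrom, "pos": pos}).to_csv(buf, index=False)
    buf.seek(0)
    return buf


class TestQC:
    def test_non_autosomal_removed(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 3, size=(40, 10))
        snps = [f"s{i}" for i in range(10)]
        chrom = ["1"] * 9 + ["X"]
        geno, rep = load_and_qc_genotypes(
            _write_geno(counts, snps, [f"a{i}" for i in range(40)]),
            _write_map(snps, chrom, np.arange(10) * 1000),
        )
        assert rep.n_removed_non_autosomal == 1
        assert geno.n_snp <= 9 and "s9" not in geno.snp_ids

    def test_call_rate_below_threshold_removed(self):
        counts = np.ones((100, 2))
        counts[:50, 0] = 0  # keep SNP 0 polymorphic-ish
        counts[:10, 1] = 5  # 10% missing on SNP 1
        counts[10:60, 1] = 0
        geno, rep = load_and_qc_genotypes(
            _write_geno(counts.astype(int), ["s0", "s1"], [f"a{i}" for i in range(100)]),
            _write_map(["s0", "s1"], ["1", "1"], [1, 2]),
        )
        assert rep.n_removed_call_rate == 1
        assert list(geno.snp_ids) == ["s0"]

    def test_maf_boundary_retained(self):
        """MAF exactly 0.05 survives the strict < 0.05 exclusion."""
        counts = np.zeros((100, 2), dtype=int)
        counts[:10, 0] = 1  # p = 0.05 exactly
        counts[:50, 1] = 1  # clearly polymorphic companion
        geno, rep = load_and_qc_genotypes(
            _write_geno(counts, ["s0", "s1"], [f"a{i}" for i in range(100)]),
            _write_map(["s0", "s1"], ["1", "1"], [1, 2]),
        )
        assert rep.n_removed_maf == 0
        assert "s0" in geno.snp_ids

    def test_all_removed_errors(self):
        counts = np.zeros((20, 1), dtype=int)  # monomorphic -> MAF 0
        with pytest.raises(ValueError, match="all SNPs removed"):
            load_and_qc_genotypes(
                _write_geno(counts, ["s0"], [f"a{i}" for i in range(20)]),
                _write_map(["s0"], ["1"], [1]),
            )

    def test_missing_imputed_to_mean_and_centering(self):
        counts = np.array([[0, 2], [1, 5], [2, 0], [1, 2]])
        geno, _ = load_and_qc_genotypes(
            _write_geno(counts, ["s0", "s1"], list("abcd")),
            _write_map(["s0", "s1"], ["1", "1"], [1, 2]),
            QCThresholds(min_call_rate=0.5),
        )
        # columns of W_g have zero mean with frequencies from the data
        assert np.allclose(geno.centered.mean(axis=0), 0.0, atol=1e-12)


class TestVanRadenG:
    def test_single_snp_hand_arithmetic(self):
        """p = 0.5, genotypes {0,1,2}: centred {-1,0,1}, denominator 0.5, diag {2,0,2}."""
        from inbredload.genomic import GenotypeData

        geno = GenotypeData(
            animal_ids=np.array(list("abc")),
            snp_ids=np.array(["s0"]),
            counts=np.array([[0.0], [1.0], [2.0]]),
            chrom=np.array([1]),
            pos=np.array([1.0]),
        )
        G = vanraden_g(geno)
        assert np.allclose(np.diag(G), [2.0, 0.0, 2.0])
        assert G[0, 2] == pytest.approx(-2.0)

    def test_duplicate_animals_identical_rows(self):
        from inbredload.genomic import GenotypeData

        rng = np.random.default_rng(3)
        counts = rng.integers(0, 3, size=(5, 30)).astype(float)
        counts[4] = counts[0]
        geno = GenotypeData(
            animal_ids=np.array(list("abcde")),
            snp_ids=np.array([f"s{i}" for i in range(30)]),
            counts=counts,
            chrom=np.ones(30, int),
            pos=np.arange(30, dtype=float),
        )
        G = vanraden_g(geno)
        assert np.allclose(G[0], G[4])

    def test_rows_sum_to_zero_with_observed_frequencies(self):
        from inbredload.genomic import GenotypeData

        rng = np.random.default_rng(4)
        counts = rng.integers(0, 3, size=(12, 50)).astype(float)
        geno = GenotypeData(
            animal_ids=np.array([f"a{i}" for i in range(12)]),
            snp_ids=np.array([f"s{i}" for i in range(50)]),
            counts=counts,
            chrom=np.ones(50, int),
            pos=np.arange(50, dtype=float),
        )
        G = vanraden_g(geno)
        assert np.allclose(G.sum(axis=1), 0.0, atol=1e-10)


class TestHInverse:
    def test_no_genotyped_animals_gives_a_inverse(self):
        ped = random_pedigree(50, seed=1)
        A_inv = a_inverse(ped)
        H_inv = build_h_inverse(A_inv, np.empty((0, 0)), np.empty((0, 0)), np.array([], int))
        assert (H_inv - A_inv).nnz == 0

    def test_g_equal_a22_augmentation_vanishes(self):
        ped = random_pedigree(60, seed=2)
        gidx = np.arange(40, 60)
        A22 = relationship_submatrix(ped, ped.labels[gidx])
        A_inv = a_inverse(ped)
        H_inv = build_h_inverse(A_inv, A22, A22.copy(), gidx, blend=0.0)
        assert np.max(np.abs((H_inv - A_inv).toarray())) <= 1e-8

    def test_matches_brute_force_h(self):
        """H built explicitly from the joint identity, inverted numerically."""
        ped = random_pedigree(40, seed=5, n_founders=8)
        gidx = np.arange(25, 40)
        labels = ped.labels[gidx]
        A = tabular_a(ped)
        A22 = relationship_submatrix(ped, labels)
        rng = np.random.default_rng(6)
        W = rng.integers(0, 3, size=(15, 120)).astype(float)
        from inbredload.genomic import GenotypeData

        geno = GenotypeData(
            animal_ids=labels,
            snp_ids=np.array([f"s{i}" for i in range(120)]),
            counts=W,
            chrom=np.ones(120, int),
            pos=np.arange(120, dtype=float),
        )
        G = vanraden_g(geno)
        blend = 0.05
        Gs = blend_g(G, A22, blend=blend)
        H_inv = build_h_inverse(a_inverse(ped), A22, G, gidx, blend=blend).toarray()
        # brute force: H = A + corrections mapping A22 -> G* on the genotyped block
        ng = np.setdiff1d(np.arange(40), gidx)
        A11 = A[np.ix_(ng, ng)]
        A12 = A[np.ix_(ng, gidx)]
        A22f = A[np.ix_(gidx, gidx)]
        A22_inv = np.linalg.inv(A22f)
        D = Gs - A22f
        H = A.copy()
        H[np.ix_(ng, ng)] = A11 + A12 @ A22_inv @ D @ A22_inv @ A12.T
        H[np.ix_(ng, gidx)] = A12 @ A22_inv @ Gs
        H[np.ix_(gidx, ng)] = H[np.ix_(ng, gidx)].T
        H[np.ix_(gidx, gidx)] = Gs
        assert np.allclose(H_inv, np.linalg.inv(H), atol=1e-7)
        # h_diagonal agrees with the explicit H
        hd = h_diagonal(A, A22, G, gidx, blend=blend)
        assert np.allclose(hd, np.diag(H), atol=1e-10)

    def test_symmetry(self):
        ped = random_pedigree(30, seed=8)
        gidx = np.arange(18, 30)
        A22 = relationship_submatrix(ped, ped.labels[gidx])
        rng = np.random.default_rng(9)
        from inbredload.genomic import GenotypeData

        geno = GenotypeData(
            animal_ids=ped.labels[gidx],
            snp_ids=np.array([f"s{i}" for i in range(80)]),
            counts=rng.integers(0, 3, size=(12, 80)).astype(float),
            chrom=np.ones(80, int),
            pos=np.arange(80, dtype=float),
        )
        H_inv = build_h_inverse(a_inverse(ped), A22, vanraden_g(geno), gidx).toarray()
        assert np.allclose(H_inv, H_inv.T, atol=1e-10)
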