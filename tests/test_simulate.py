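import numpy as np
import pytest

from inbredload.decomposition import mendelian_decomposition
from inbredload.simulate import (
    SimulationConfig,
    draw_genetic_effects,
    simulate_dataset,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)

from conftest import make_pedigree


class TestSimulatePedigree:
    def test_no_close_matings_no_inbreeding(self):
        cfg = SimulationConfig(close_mating_fraction=0.0, n_generations=2, seed=1)
        ped = simulate_pedigree(cfg)
        # random mating among founders can still create half/full sibs mated by
        # chance at generation 2; with two generations only, founder-generation
        # parents are unrelated so generation-1 offspring are non-inbred
        assert np.all(ped.F[ped.birth_year <= 2001] == 0)

    def test_full_close_mating_produces_f_025(self):
        cfg = SimulationConfig(close_mating_fraction=1.0, n_generations=2, seed=2)
        ped = simulate_pedigree(cfg)
        assert np.any(np.isclose(ped.F, 0.25))

    def test_guaranteed_inbred_animal(self):
        cfg = SimulationConfig(close_mating_fraction=0.05, n_generations=3, seed=3)
        ped = simulate_pedigree(cfg)
        assert np.sum(ped.F > 0) >= 1

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=4)
        p1, p2 = simulate_pedigree(cfg), simulate_pedigree(cfg)
        assert np.array_equal(p1.sire, p2.sire)
        assert np.array_equal(p1.dam, p2.dam)
        assert np.array_equal(p1.sex, p2.sex)


class TestSimulateGenotypes:
    def test_founder_frequencies_match(self):
        """Founder-only pedigree: observed frequencies within binomial error."""
        cfg = SimulationConfig(n_founders=5000, n_generations=0, n_snp=50, seed=5)
        ped = simulate_pedigree(cfg)
        rng = np.random.default_rng(5)
        lo, hi = cfg.founder_freq_range
        p0 = rng.uniform(lo, hi, size=cfg.n_snp)  # same stream as the generator
        geno, _ = simulate_genotypes(ped, cfg, rng=np.random.default_rng(5))
        se = np.sqrt(p0 * (1 - p0) / (2 * cfg.n_founders))
        assert np.all(np.abs(geno.freq - p0) <= 5 * se)

    def test_monomorphic_stays_monomorphic(self):
        cfg = SimulationConfig(n_founders=20, n_generations=3, n_snp=10,
                               founder_freq_range=(1.0, 1.0), seed=6)
        ped = simulate_pedigree(cfg)
        geno, _ = simulate_genotypes(ped, cfg)
        assert np.all(geno.counts == 2.0)

    def test_realized_inbreeding_of_full_sib_offspring(self):
        """Excess homozygosity of F=0.25 animals over founder expectation ~ 0.25."""
        cfg = SimulationConfig(n_founders=200, n_generations=2, close_mating_fraction=1.0,
                               n_matings=100, offspring_per_mating=4, n_snp=400, seed=7)
        ped = simulate_pedigree(cfg)
        geno, _ = simulate_genotypes(ped, cfg)
        inbred = np.isclose(ped.F, 0.25)
        assert inbred.sum() > 100
        p = geno.counts[ped.is_founder()].mean(axis=0) / 2
        het_exp = (2 * p * (1 - p)).mean()
        het_obs = (geno.counts[inbred] == 1).mean()
        f_real = 1 - het_obs / het_exp
        assert f_real == pytest.approx(0.25, abs=0.03)


class TestGeneticEffects:
    def test_founder_moments_match_v(self):
        cfg = SimulationConfig(n_founders=10_000, n_generations=0, seed=8)
        ped = simulate_pedigree(cfg)
        u, i = draw_genetic_effects(ped, cfg.V, np.random.default_rng(8))
        assert np.var(u) == pytest.approx(cfg.sigma_u2, rel=0.05)
        assert np.var(i) == pytest.approx(cfg.sigma_i2, rel=0.05)
        r_true = cfg.sigma_ui / np.sqrt(cfg.sigma_u2 * cfg.sigma_i2)
        assert np.corrcoef(u, i)[0, 1] == pytest.approx(r_true, abs=0.05)

    def test_offspring_variance_scales_with_mendelian_sampling(self):
        """Full sibs share parents: var within family = 0.5 V (non-inbred parents)."""
        cfg = SimulationConfig(n_founders=2, n_generations=1, n_matings=1,
                               offspring_per_mating=5000, close_mating_fraction=0.0, seed=9)
        ped = simulate_pedigree(cfg)
        u, _ = draw_genetic_effects(ped, cfg.V, np.random.default_rng(9))
        off = u[2:]
        assert np.var(off) == pytest.approx(0.5 * cfg.sigma_u2, rel=0.06)


class TestSimulatePhenotypes:
    def test_zero_variances_give_fixed_part(self, full_sib_ped):
        cfg = SimulationConfig(sigma_u2=0, sigma_i2=0, sigma_ui=0, sigma_h2=0,
                               sigma_e2=0, d=0.0, sex_effect=0.0, record_founders=True)
        table = mendelian_decomposition(full_sib_ped)
        recs, _ = simulate_phenotypes(full_sib_ped, table, cfg)
        assert np.allclose(recs["value"], cfg.mu)

    def test_depression_shifts_inbred_record(self, full_sib_ped):
        """d=-10, F=0.25, all variances zero: inbred record sits 2.5 below."""
        cfg = SimulationConfig(sigma_u2=0, sigma_i2=0, sigma_ui=0, sigma_h2=0,
                               sigma_e2=0, d=-10.0, sex_effect=0.0, record_founders=True)
        table = mendelian_decomposition(full_sib_ped)
        recs, _ = simulate_phenotypes(full_sib_ped, table, cfg)
        recs = recs.set_index("animal")
        assert recs.loc["X", "value"] == pytest.approx(cfg.mu - 2.5)
        assert recs.loc["P1", "value"] == pytest.approx(cfg.mu)

    def test_singleton_phenotypic_variance(self):
        """Non-inbred singletons: var(y) ~ sigma_u2 + sigma_h2 + sigma_e2 within 5%."""
        cfg = SimulationConfig(n_founders=10_000, n_generations=0, record_founders=True,
                               n_hys=500, sex_effect=0.0, seed=10)
        ped = simulate_pedigree(cfg)
        table = mendelian_decomposition(ped)
        recs, _ = simulate_phenotypes(ped, table, cfg)
        expected = cfg.sigma_u2 + cfg.sigma_h2 + cfg.sigma_e2
        assert np.var(recs["value"]) == pytest.approx(expected, rel=0.05)


def test_dataset_determinism():
    cfg = SimulationConfig(n_founders=12, n_generations=3, n_matings=8,
                           offspring_per_mating=2, n_snp=40, seed=11)
    d1, d2 = simulate_dataset(cfg), simulate_dataset(cfg)
    assert np.array_equal(d1.ped.sire, d2.ped.sire)
    assert np.array_equal(d1.geno.counts, d2.geno.counts)
    assert np.allclose(d1.records["value"], d2.records["value"])
    assert np.allclose(d1.truth["u"], d2.truth["u"])
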