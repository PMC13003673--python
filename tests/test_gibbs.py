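import numpy as np
import pytest
from scipy import stats

from inbredload.design import DesignBundle, ModelSpec, assemble_design
from inbredload.gibbs import (
    GibbsConfig,
    accuracy,
    depression_summary,
    gibbs_sampler,
    heritability,
    hpd_interval,
    load_variance_ratio,
    solve_mme,
)
from inbredload.pedigree import a_inverse
from inbredload.simulate import SimulationConfig, default_model_spec, simulate_dataset
from scipy import sparse


def _toy_fit(n_iter=30_000, burn_in=3_000, seed=7, **sim_kw):
    kw = dict(n_founders=10, n_generations=3, n_matings=6, offspring_per_mating=2,
              close_mating_fraction=0.5, n_snp=10, n_hys=5, seed=3)
    kw.update(sim_kw)
    cfg = SimulationConfig(**kw)
    data = simulate_dataset(cfg)
    bundle = assemble_design(data.records, default_model_spec(cfg), data.ped, table=data.table)
    return cfg, data, bundle


def _batch_mcse(x, n_batches=30):
    """Monte-Carlo SE of the chain mean by batch means (accounts for autocorrelation)."""
    m = len(x) // n_batches
    means = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(n_batches)


class TestMmeEquivalence:
    def test_fixed_variance_posterior_means_match_mme(self):
        """With variances held fixed, posterior means of (b, h, u, i) solve
        Henderson's equations (<= 3 Monte-Carlo SE, ~50-record toy)."""
        cfg, data, bundle = _toy_fit()
        H_inv = a_inverse(data.ped)
        gc = GibbsConfig(n_iter=60_000, burn_in=5_000, thin=1, seed=21,
                         sample_ve=False, sample_vh=False, sample_vp=False, sample_V=False,
                         start_ve=cfg.sigma_e2, start_vh=cfg.sigma_h2, start_V=cfg.V)
        res = gibbs_sampler(bundle, H_inv, gc)
        mme = solve_mme(bundle, H_inv, cfg.sigma_e2, cfg.sigma_h2, cfg.V)
        # d: compare to its own MC uncertainty
        d_chain = res.samples["d"].to_numpy()
        assert abs(d_chain.mean() - mme["d"][0]) <= 3 * _batch_mcse(d_chain)
        # u and i: running means vs MME, allowing 3 x (PSD-based MCSE with a
        # conservative effective-sample deflation for autocorrelation)
        n_kept = gc.n_iter - gc.burn_in
        ess = n_kept / 20
        tol_u = 3 * res.u_psd / np.sqrt(ess)
        tol_i = 3 * res.i_psd / np.sqrt(ess)
        assert np.all(np.abs(res.u_mean - mme["u"]) <= np.maximum(tol_u, 1e-6))
        assert np.all(np.abs(res.i_mean - mme["i"]) <= np.maximum(tol_i, 1e-6))

    def test_no_inbreeding_no_covariance_information(self):
        """Without inbred animals K = 0; the u-i covariance posterior stays
        centred at zero (no information pathway)."""
        cfg, data, bundle = _toy_fit(close_mating_fraction=0.0, sigma_i2=30.0,
                                     sigma_ui=0.0, n_generations=1, n_founders=20)
        assert bundle.K.nnz == 0
        gc = GibbsConfig(n_iter=20_000, burn_in=5_000, thin=5, seed=3,
                         start_ve=cfg.sigma_e2, start_vh=cfg.sigma_h2,
                         start_V=np.array([[9.0, 0.0], [0.0, 30.0]]))
        res = gibbs_sampler(bundle, a_inverse(data.ped), gc)
        vui = res.samples["sigma_ui"].to_numpy()
        assert abs(vui.mean()) <= 0.5 * vui.std(ddof=1)


class TestDegeneratePosterior:
    def test_residual_variance_matches_analytic_inverse_chi_square(self):
        """Known-mean, residual-only model: sigma_e2 | y is the scaled inverse
        chi-square (flat prior), matched in mean, SD and upper quantile."""
        rng = np.random.default_rng(5)
        n = 200
        sigma2 = 4.0
        y = rng.normal(0.0, np.sqrt(sigma2), n)
        bundle = DesignBundle(
            y=y, f=np.zeros(n), t=None,
            fixed_codes=np.zeros((n, 0), dtype=np.int64), fixed_levels=[],
            hys_codes=np.zeros(n, dtype=np.int64), n_hys=1,
            animal_codes=np.zeros(n, dtype=np.int64), pe_codes=None, n_pe=0,
            K=sparse.csr_matrix((n, 1)), n_animals=1,
            spec=ModelSpec(trait="degenerate"), record_labels=np.array(["a"] * n),
        )
        H_inv = sparse.identity(1, format="csr")
        gc = GibbsConfig(n_iter=60_000, burn_in=2_000, thin=1, seed=17,
                         update_d=False, update_fixed=False, update_h=False,
                         update_animal=False, sample_vh=False, sample_vp=False,
                         sample_V=False, start_ve=1.0)
        res = gibbs_sampler(bundle, H_inv, gc)
        ve = res.samples["sigma_e2"].to_numpy()
        ss = float(y @ y)
        # flat prior => InvGamma(n/2 - 1, ss/2)
        a, b = n / 2 - 1, ss / 2
        dist = stats.invgamma(a, scale=b)
        assert ve.mean() == pytest.approx(dist.mean(), rel=0.02)
        assert ve.std(ddof=1) == pytest.approx(dist.std(), rel=0.06)
        assert np.quantile(ve, 0.95) == pytest.approx(dist.ppf(0.95), rel=0.03)


class TestAccuracy:
    @pytest.mark.parametrize(
        "psd,hjj,s2,expected",
        [
            (0.0, 1.3, 2.0, 1.0),
            (np.sqrt(1.3 * 2.0), 1.3, 2.0, 0.0),
            (np.sqrt(0.51), 1.0, 1.0, 0.7),
        ],
    )
    def test_edge_cases(self, psd, hjj, s2, expected):
        assert accuracy(psd, hjj, s2) == pytest.approx(expected, abs=1e-12)

    def test_clamped_to_unit_interval(self):
        psd = np.array([0.0, 0.5, 1.0, 10.0])
        acc = accuracy(psd, np.ones(4), 1.0)
        assert np.all((acc >= 0) & (acc <= 1))

    def test_monotone_in_information(self):
        """More records per animal -> larger accuracy (nested-data experiment)."""
        accs = []
        for n_rec in (1, 3, 6):
            cfg, data, bundle = _toy_fit(records_per_animal=n_rec, seed=11)
            gc = GibbsConfig(n_iter=10_000, burn_in=2_000, thin=5, seed=n_rec,
                             sample_ve=False, sample_vh=False, sample_vp=False,
                             sample_V=False, start_ve=cfg.sigma_e2,
                             start_vh=cfg.sigma_h2, start_V=cfg.V)
            res = gibbs_sampler(bundle, a_inverse(data.ped), gc)
            from inbredload.pedigree import tabular_a

            hd = np.diag(tabular_a(data.ped))
            accs.append(accuracy(res.u_psd, hd, cfg.sigma_u2).mean())
        assert accs[0] < accs[1] < accs[2]


class TestDerivedQuantities:
    def test_depression_zero(self):
        out = depression_summary(0.0, 0.1, 10.0, 2.0)
        assert out["dpm"] == 0.0 and out["dpsd"] == 0.0

    def test_ratio_zero_at_f0(self):
        assert load_variance_ratio(9.0, 58.0, 8.0, 29.0, F=0.0) == 0.0

    def test_ratio_arithmetic(self):
        """sigma_i2=100, other variances summing 900, F=1 -> 0.1."""
        assert load_variance_ratio(300.0, 100.0, 300.0, 300.0, F=1.0) == pytest.approx(0.1)

    def test_heritability(self):
        assert heritability(25.0, 25.0, 50.0) == pytest.approx(0.25)

    def test_hpd_contains_mass_and_is_shortest(self):
        rng = np.random.default_rng(1)
        x = rng.normal(3.0, 1.0, 20_000)
        lo, hi = hpd_interval(x, 0.95)
        inside = np.mean((x >= lo) & (x <= hi))
        assert inside >= 0.95
        assert lo == pytest.approx(3 - 1.96, abs=0.1)
        assert hi == pytest.approx(3 + 1.96, abs=0.1)
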