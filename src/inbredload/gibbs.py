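"""Gibbs sampler for the bivariate additive / inbreeding-load animal model.

The joint vector of additive effects u and ancestral inbreeding loads i has the
prior N(0, V (x) H) with V the 2x2 (co)variance matrix.  Location effects use
single-site updates except (u_j, i_j), which are sampled as per-animal 2-blocks
(required for mixing under a strong u-i covariance).  Variance priors are
uniform within the parametric space, implemented as the limiting conjugate
forms: scalar variances get scaled-inverse-chi-square full conditionals
InvGamma(q/2 - 1, SS/2), and V gets an inverse-Wishart full conditional
IW(S, nu = q - 3) with S the 2x2 matrix of H^-1 quadratic forms in (u, i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

from .design import DesignBundle

# sample column layout produced by the core
SAMPLE_COLUMNS = [
    "d",
    "c",
    "sigma_e2",
    "sigma_h2",
    "sigma_p2",
    "sigma_u2",
    "sigma_ui",
    "sigma_i2",
]


@dataclass
class GibbsConfig:
    n_iter: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 1234
    # starting / fixed values
    start_ve: float = 1.0
    start_vh: float = 1.0
    start_vp: float = 1.0
    start_V: np.ndarray = field(default_factory=lambda: np.array([[1.0, 0.0], [0.0, 1.0]]))
    # which variances are sampled (False = held fixed at the start value)
    sample_ve: bool = True
    sample_vh: bool = True
    sample_vp: bool = True
    sample_V: bool = True
    # which location effects are updated
    update_d: bool = True
    update_c: bool = True
    update_fixed: bool = True
    update_h: bool = True
    update_animal: bool = True


@dataclass
class GibbsResult:
    samples: pd.DataFrame
    u_mean: np.ndarray
    u_psd: np.ndarray
    i_mean: np.ndarray
    i_psd: np.ndarray
    config: GibbsConfig

    def posterior_mean(self, col: str) -> float:
        return float(self.samples[col].mean())

    def posterior_sd(self, col: str) -> float:
        return float(self.samples[col].std(ddof=1))

    def hpd(self, col: str, prob: float = 0.95) -> tuple[float, float]:
        return hpd_interval(self.samples[col].to_numpy(), prob)

    def corr_samples(self) -> np.ndarray:
        s = self.samples
        den = np.sqrt(s["sigma_u2"].to_numpy() * s["sigma_i2"].to_numpy())
        return s["sigma_ui"].to_numpy() / den

    def p_corr_negative(self) -> float:
        return float(np.mean(self.corr_samples() < 0))

    def summary(self) -> pd.DataFrame:
        rows = []
        for col in SAMPLE_COLUMNS:
            x = self.samples[col].to_numpy()
            if np.allclose(x, x[0]):
                lo = hi = x[0]
            else:
                lo, hi = hpd_interval(x, 0.95)
            rows.append((col, x.mean(), x.std(ddof=1), lo, hi))
        return pd.DataFrame(rows, columns=["parameter", "mean", "psd", "hpd95_low", "hpd95_high"])


@njit(cache=True)
def _chol2(a, b, c):  # pragma: no cover - 2x2 lower Cholesky of [[a,b],[b,c]]
    l11 = np.sqrt(a)
    l21 = b / l11
    l22 = np.sqrt(max(c - l21 * l21, 1e-300))
    return l11, l21, l22


@njit(cache=True)
def _gibbs_core(  # pragma: no cover - exercised through gibbs_sampler
    y,
    covs,
    fixed_codes,
    n_fixed_levels,
    hys_codes,
    n_hys,
    pe_codes,
    n_pe,
    z_indptr,
    z_records,
    k_indptr,
    k_rows,
    k_vals,
    h_indptr,
    h_indices,
    h_data,
    zz,
    zk,
    kk,
    n_iter,
    burn_in,
    thin,
    seed,
    ve,
    vh,
    vp,
    V0,
    sample_ve,
    sample_vh,
    sample_vp,
    sample_V,
    update_cov,
    update_fixed,
    update_h,
    update_animal,
    has_pe,
):
    np.random.seed(seed)
    n = y.shape[0]
    n_anim = z_indptr.shape[0] - 1
    ncov = covs.shape[1]
    nf = fixed_codes.shape[1]

    beta_cov = np.zeros(ncov)
    xx = np.zeros(ncov)
    for c in range(ncov):
        s = 0.0
        for r in range(n):
            s += covs[r, c] * covs[r, c]
        xx[c] = s

    max_lev = 0
    for f in range(nf):
        if n_fixed_levels[f] > max_lev:
            max_lev = n_fixed_levels[f]
    beta_fixed = np.zeros((nf, max_lev))
    fixed_counts = np.zeros((nf, max_lev))
    for f in range(nf):
        for r in range(n):
            fixed_counts[f, fixed_codes[r, f]] += 1.0

    h = np.zeros(n_hys)
    h_counts = np.zeros(n_hys)
    for r in range(n):
        h_counts[hys_codes[r]] += 1.0

    p = np.zeros(max(n_pe, 1))
    p_counts = np.zeros(max(n_pe, 1))
    if has_pe:
        for r in range(n):
            p_counts[pe_codes[r]] += 1.0

    u = np.zeros(n_anim)
    ii = np.zeros(n_anim)
    V = V0.copy()

    e = y.copy()

    n_saved = 0
    for it in range(n_iter):
        if it >= burn_in and (it - burn_in) % thin == 0:
            n_saved += 1
    samples = np.zeros((n_saved, 8))
    sum_u = np.zeros(n_anim)
    sq_u = np.zeros(n_anim)
    sum_i = np.zeros(n_anim)
    sq_i = np.zeros(n_anim)
    n_acc = 0

    save_row = 0
    for it in range(n_iter):
        # --- covariates (flat prior) ---
        if update_cov:
            for c in range(ncov):
                if xx[c] <= 0.0:
                    continue
                xr = 0.0
                for r in range(n):
                    xr += covs[r, c] * e[r]
                xr += xx[c] * beta_cov[c]
                new = xr / xx[c] + np.sqrt(ve / xx[c]) * np.random.standard_normal()
                diff = new - beta_cov[c]
                beta_cov[c] = new
                for r in range(n):
                    e[r] -= covs[r, c] * diff

        # --- fixed-effect levels (flat prior) ---
        if update_fixed:
            for f in range(nf):
                nl = n_fixed_levels[f]
                sums = np.zeros(nl)
                for r in range(n):
                    sums[fixed_codes[r, f]] += e[r]
                for l in range(nl):
                    cnt = fixed_counts[f, l]
                    if cnt <= 0.0:
                        continue
                    mean = (sums[l] + cnt * beta_fixed[f, l]) / cnt
                    newv = mean + np.sqrt(ve / cnt) * np.random.standard_normal()
                    sums[l] = newv - beta_fixed[f, l]  # reuse as diff
                    beta_fixed[f, l] = newv
                for r in range(n):
                    e[r] -= sums[fixed_codes[r, f]]

        # --- herd-year-season ---
        if update_h:
            sums = np.zeros(n_hys)
            for r in range(n):
                sums[hys_codes[r]] += e[r]
            for l in range(n_hys):
                cnt = h_counts[l]
                prec = cnt / ve + 1.0 / vh
                mean = (sums[l] + cnt * h[l]) / ve / prec
                newv = mean + np.random.standard_normal() / np.sqrt(prec)
                sums[l] = newv - h[l]
                h[l] = newv
            for r in range(n):
                e[r] -= sums[hys_codes[r]]

        # --- permanent environment ---
        if has_pe:
            sums = np.zeros(n_pe)
            for r in range(n):
                sums[pe_codes[r]] += e[r]
            for l in range(n_pe):
                cnt = p_counts[l]
                prec = cnt / ve + 1.0 / vp
                mean = (sums[l] + cnt * p[l]) / ve / prec
                newv = mean + np.random.standard_normal() / np.sqrt(prec)
                sums[l] = newv - p[l]
                p[l] = newv
            for r in range(n):
                e[r] -= sums[pe_codes[r]]

        # --- (u_j, i_j) bivariate blocks ---
        detV = V[0, 0] * V[1, 1] - V[0, 1] * V[0, 1]
        vi00 = V[1, 1] / detV
        vi01 = -V[0, 1] / detV
        vi11 = V[0, 0] / detV
        if update_animal:
            for j in range(n_anim):
                su = 0.0
                si = 0.0
                hjj = 0.0
                for ptr in range(h_indptr[j], h_indptr[j + 1]):
                    l = h_indices[ptr]
                    w = h_data[ptr]
                    if l == j:
                        hjj += w
                    else:
                        su += w * u[l]
                        si += w * ii[l]
                # data sums
                ze = 0.0
                for ptr in range(z_indptr[j], z_indptr[j + 1]):
                    ze += e[z_records[ptr]]
                ke = 0.0
                for ptr in range(k_indptr[j], k_indptr[j + 1]):
                    ke += k_vals[ptr] * e[k_rows[ptr]]
                rhs_u = (ze + zz[j] * u[j] + zk[j] * ii[j]) / ve - (vi00 * su + vi01 * si)
                rhs_i = (ke + zk[j] * u[j] + kk[j] * ii[j]) / ve - (vi01 * su + vi11 * si)
                q00 = zz[j] / ve + hjj * vi00
                q01 = zk[j] / ve + hjj * vi01
                q11 = kk[j] / ve + hjj * vi11
                detQ = q00 * q11 - q01 * q01
                m_u = (q11 * rhs_u - q01 * rhs_i) / detQ
                m_i = (q00 * rhs_i - q01 * rhs_u) / detQ
                # sample from N(m, Q^-1): Q^-1 = [[q11,-q01],[-q01,q00]]/detQ
                c00 = q11 / detQ
                c01 = -q01 / detQ
                c11 = q00 / detQ
                l11, l21, l22 = _chol2(c00, c01, c11)
                z1 = np.random.standard_normal()
                z2 = np.random.standard_normal()
                new_u = m_u + l11 * z1
                new_i = m_i + l21 * z1 + l22 * z2
                du = new_u - u[j]
                di = new_i - ii[j]
                u[j] = new_u
                ii[j] = new_i
                if du != 0.0:
                    for ptr in range(z_indptr[j], z_indptr[j + 1]):
                        e[z_records[ptr]] -= du
                if di != 0.0:
                    for ptr in range(k_indptr[j], k_indptr[j + 1]):
                        e[k_rows[ptr]] -= k_vals[ptr] * di

        # --- variance components ---
        if sample_ve:
            sse = 0.0
            for r in range(n):
                sse += e[r] * e[r]
            shape = 0.5 * n - 1.0
            ve = 0.5 * sse / np.random.gamma(shape, 1.0)
        if sample_vh and update_h:
            ssh = 0.0
            for l in range(n_hys):
                ssh += h[l] * h[l]
            shape = 0.5 * n_hys - 1.0
            vh = 0.5 * ssh / np.random.gamma(shape, 1.0)
        if has_pe and sample_vp:
            ssp = 0.0
            for l in range(n_pe):
                ssp += p[l] * p[l]
            shape = 0.5 * n_pe - 1.0
            vp = 0.5 * ssp / np.random.gamma(shape, 1.0)
        if sample_V and update_animal:
            # S = [u'H^-1 u, u'H^-1 i; ., i'H^-1 i]
            s00 = 0.0
            s01 = 0.0
            s11 = 0.0
            for j in range(n_anim):
                hu = 0.0
                hi = 0.0
                for ptr in range(h_indptr[j], h_indptr[j + 1]):
                    l = h_indices[ptr]
                    hu += h_data[ptr] * u[l]
                    hi += h_data[ptr] * ii[l]
                s00 += u[j] * hu
                s01 += u[j] * hi
                s11 += ii[j] * hi
            nu = n_anim - 3.0
            # V ~ IW(S, nu): draw W ~ Wishart(S^-1, nu) via Bartlett, V = W^-1
            detS = s00 * s11 - s01 * s01
            psi00 = s11 / detS
            psi01 = -s01 / detS
            psi11 = s00 / detS
            for _attempt in range(100):
                l11, l21, l22 = _chol2(psi00, psi01, psi11)
                a11 = np.sqrt(2.0 * np.random.gamma(0.5 * nu, 1.0))
                a21 = np.random.standard_normal()
                a22 = np.sqrt(2.0 * np.random.gamma(0.5 * (nu - 1.0), 1.0))
                # B = L A (lower); W = B B'
                b11 = l11 * a11
                b21 = l21 * a11 + l22 * a21
                b22 = l22 * a22
                w00 = b11 * b11
                w01 = b11 * b21
                w11 = b21 * b21 + b22 * b22
                detW = w00 * w11 - w01 * w01
                if detW > 0.0 and w00 > 0.0 and w11 > 0.0:
                    V[0, 0] = w11 / detW
                    V[0, 1] = -w01 / detW
                    V[1, 0] = -w01 / detW
                    V[1, 1] = w00 / detW
                    break

        # --- bookkeeping ---
        if it >= burn_in:
            n_acc += 1
            for j in range(n_anim):
                sum_u[j] += u[j]
                sq_u[j] += u[j] * u[j]
                sum_i[j] += ii[j]
                sq_i[j] += ii[j] * ii[j]
            if (it - burn_in) % thin == 0:
                samples[save_row, 0] = beta_cov[0] if ncov > 0 else 0.0
                samples[save_row, 1] = beta_cov[1] if ncov > 1 else 0.0
                samples[save_row, 2] = ve
                samples[save_row, 3] = vh
                samples[save_row, 4] = vp if has_pe else 0.0
                samples[save_row, 5] = V[0, 0]
                samples[save_row, 6] = V[0, 1]
                samples[save_row, 7] = V[1, 1]
                save_row += 1

    u_mean = sum_u / n_acc
    i_mean = sum_i / n_acc
    u_psd = np.sqrt(np.maximum(sq_u / n_acc - u_mean**2, 0.0))
    i_psd = np.sqrt(np.maximum(sq_i / n_acc - i_mean**2, 0.0))
    return samples, u_mean, u_psd, i_mean, i_psd


def _z_grouping(animal_codes: np.ndarray, n_animals: int):
    order = np.argsort(animal_codes, kind="stable")
    counts = np.bincount(animal_codes, minlength=n_animals)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return indptr, order.astype(np.int64)


def gibbs_sampler(
    bundle: DesignBundle,
    H_inv: sparse.spmatrix,
    config: GibbsConfig | None = None,
) -> GibbsResult:
    """Run the Gibbs sampler on an assembled design.

    Returns thinned samples of (d, c, variance components) and running
    posterior means / posterior SDs of u and i over all post-burn-in
    iterations.  Bit-reproducible for a given seed (single-threaded).
    """
    config = config or GibbsConfig()
    n = bundle.n_records
    n_anim = bundle.n_animals

    cov_list = []
    if config.update_d:
        cov_list.append(bundle.f)
    if bundle.t is not None and config.update_c:
        cov_list.append(bundle.t)
    covs = np.column_stack(cov_list) if cov_list else np.zeros((n, 0))
    has_c = bundle.t is not None and config.update_c

    n_fixed_levels = np.array([len(l) for l in bundle.fixed_levels], dtype=np.int64)
    fixed_codes = np.ascontiguousarray(bundle.fixed_codes, dtype=np.int64)
    if fixed_codes.size == 0:
        fixed_codes = np.zeros((n, 0), dtype=np.int64)

    has_pe = bundle.pe_codes is not None
    pe_codes = bundle.pe_codes if has_pe else np.zeros(n, dtype=np.int64)
    if config.sample_vh and config.update_h and bundle.n_hys < 3:
        raise ValueError("sampling sigma_h2 under the flat prior needs >= 3 HYS levels")
    if has_pe and config.sample_vp and bundle.n_pe < 3:
        raise ValueError("sampling sigma_p2 under the flat prior needs >= 3 PE levels")

    z_indptr, z_records = _z_grouping(bundle.animal_codes, n_anim)
    K = bundle.K.tocsc()
    H = sparse.csr_matrix(H_inv)
    if H.shape != (n_anim, n_anim):
        raise ValueError(f"H_inv has shape {H.shape}, expected {(n_anim, n_anim)}")

    zz = np.bincount(bundle.animal_codes, minlength=n_anim).astype(float)
    kk = np.asarray(K.multiply(K).sum(axis=0)).ravel()
    # cross term z_j'k_j: sum of K[r, j] over records r belonging to animal j
    coo = K.tocoo()
    zk = np.zeros(n_anim)
    own = bundle.animal_codes[coo.row] == coo.col
    np.add.at(zk, coo.col[own], coo.data[own])

    samples, u_mean, u_psd, i_mean, i_psd = _gibbs_core(
        np.ascontiguousarray(bundle.y, float),
        np.ascontiguousarray(covs, float),
        fixed_codes,
        n_fixed_levels,
        np.ascontiguousarray(bundle.hys_codes, np.int64),
        int(bundle.n_hys),
        np.ascontiguousarray(pe_codes, np.int64),
        int(bundle.n_pe),
        z_indptr,
        z_records,
        K.indptr.astype(np.int64),
        K.indices.astype(np.int64),
        K.data.astype(float),
        H.indptr.astype(np.int64),
        H.indices.astype(np.int64),
        H.data.astype(float),
        zz,
        zk,
        kk,
        int(config.n_iter),
        int(config.burn_in),
        int(config.thin),
        int(config.seed) % (2**31),
        float(config.start_ve),
        float(config.start_vh),
        float(config.start_vp),
        np.ascontiguousarray(config.start_V, float),
        config.sample_ve,
        config.sample_vh,
        config.sample_vp,
        config.sample_V,
        covs.shape[1] > 0,
        config.update_fixed and fixed_codes.shape[1] > 0,
        config.update_h,
        config.update_animal,
        has_pe,
    )
    df = pd.DataFrame(samples, columns=SAMPLE_COLUMNS)
    if not has_c:
        df["c"] = np.nan
    if not has_pe:
        df["sigma_p2"] = np.nan
    return GibbsResult(
        samples=df,
        u_mean=u_mean,
        u_psd=u_psd,
        i_mean=i_mean,
        i_psd=i_psd,
        config=config,
    )


def solve_mme(
    bundle: DesignBundle,
    H_inv: sparse.spmatrix,
    ve: float,
    vh: float,
    V: np.ndarray,
    vp: float | None = None,
) -> dict:
    """Direct solution of Henderson's mixed-model equations at fixed variances.

    Independent check of the sampler: with variances held fixed, posterior
    means of location effects equal the MME solution.
    """
    n = bundle.n_records
    n_anim = bundle.n_animals
    blocks = []
    prior_diag = []
    names = []
    if True:  # covariates: d (and c)
        cols = [bundle.f]
        names.append(("d", 1))
        if bundle.t is not None:
            cols.append(bundle.t)
            names.append(("c", 1))
        blocks.append(sparse.csc_matrix(np.column_stack(cols)))
        prior_diag.append(np.zeros(len(cols)))
    for k, levels in enumerate(bundle.fixed_levels):
        nl = len(levels)
        X = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), bundle.fixed_codes[:, k])), shape=(n, nl)
        )
        blocks.append(X)
        prior_diag.append(np.zeros(nl))
        names.append((f"fixed{k}", nl))
    W = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), bundle.hys_codes)), shape=(n, bundle.n_hys)
    )
    blocks.append(W)
    prior_diag.append(np.full(bundle.n_hys, 1.0 / vh))
    names.append(("h", bundle.n_hys))
    if bundle.pe_codes is not None:
        L = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), bundle.pe_codes)), shape=(n, bundle.n_pe)
        )
        blocks.append(L)
        prior_diag.append(np.full(bundle.n_pe, 1.0 / vp))
        names.append(("p", bundle.n_pe))
    Z = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), bundle.animal_codes)), shape=(n, n_anim)
    )
    blocks.append(Z)
    blocks.append(bundle.K)
    names.append(("u", n_anim))
    names.append(("i", n_anim))

    M = sparse.hstack(blocks).tocsr()
    n_loc = M.shape[1]
    lhs = (M.T @ M) / ve
    # scalar priors
    diag = np.concatenate(prior_diag + [np.zeros(2 * n_anim)])
    lhs = lhs + sparse.diags(diag)
    # V (x) H^-1 prior on (u, i)
    Vinv = np.linalg.inv(V)
    Hk = sparse.kron(sparse.csr_matrix(Vinv), sparse.csr_matrix(H_inv))
    off = n_loc - 2 * n_anim
    pad = sparse.csr_matrix((n_loc, n_loc))
    idx = np.arange(off, n_loc)
    expander = sparse.csr_matrix(
        (np.ones(2 * n_anim), (idx, np.arange(2 * n_anim))), shape=(n_loc, 2 * n_anim)
    )
    lhs = lhs + expander @ Hk @ expander.T + pad
    rhs = (M.T @ bundle.y) / ve

    # flat priors on confounded fixed-effect levels make the system singular in
    # the level directions; the minimum-norm solution leaves every estimable
    # quantity (d, c, h, u, i, level contrasts) unchanged
    sol, *_ = np.linalg.lstsq(lhs.toarray(), rhs, rcond=None)
    out = {}
    pos = 0
    for name, size in names:
        out[name] = sol[pos : pos + size]
        pos += size
    return out


def accuracy(psd, h_diag, sigma2) -> np.ndarray:
    """Prediction accuracy: sqrt(1 - PSD^2 / (H_jj sigma^2)), clamped to [0, 1]."""
    psd = np.asarray(psd, float)
    h_diag = np.asarray(h_diag, float)
    arg = 1.0 - psd**2 / (h_diag * sigma2)
    return np.sqrt(np.clip(arg, 0.0, 1.0))


def depression_summary(d_mean: float, d_psd: float, trait_mean: float, trait_sd: float) -> dict:
    """Depression at F=1 as a percentage of the phenotypic mean and SD.

    Returns D%-M and D%-SD with their posterior SDs (the same linear transform
    applied to the posterior SD of d).
    """
    if trait_mean <= 0 or trait_sd <= 0:
        raise ValueError("trait mean and SD must be positive")
    return {
        "dpm": 100.0 * abs(d_mean) / trait_mean,
        "dpm_psd": 100.0 * d_psd / trait_mean,
        "dpsd": 100.0 * abs(d_mean) / trait_sd,
        "dpsd_psd": 100.0 * d_psd / trait_sd,
    }


def _phenotypic_variance(sigma_u2, sigma_i2, sigma_h2, sigma_e2, sigma_p2, F):
    """Phenotypic variance at inbreeding level F; the load contributes F^2 sigma_i^2."""
    return (
        np.asarray(sigma_u2, float)
        + np.asarray(sigma_h2, float)
        + np.asarray(sigma_p2, float)
        + np.asarray(sigma_e2, float)
        + F**2 * np.asarray(sigma_i2, float)
    )


def load_variance_ratio(sigma_u2, sigma_i2, sigma_h2, sigma_e2, sigma_p2=0.0, F=0.10):
    """Proportion of phenotypic variance explained by the inbreeding load at
    inbreeding level F: F^2 sigma_i^2 / (sigma_u^2 + sigma_h^2 + sigma_p^2 +
    sigma_e^2 + F^2 sigma_i^2).

    Accepts scalars (posterior means) or sample arrays (posterior of the ratio).
    """
    denom = _phenotypic_variance(sigma_u2, sigma_i2, sigma_h2, sigma_e2, sigma_p2, F)
    return F**2 * np.asarray(sigma_i2, float) / denom


def heritability(sigma_u2, sigma_h2, sigma_e2, sigma_p2=0.0, sigma_i2=0.0, F=0.0):
    """h2 = sigma_u^2 / phenotypic variance, optionally at inbreeding level F
    (the load then contributes F^2 sigma_i^2 to the denominator)."""
    denom = _phenotypic_variance(sigma_u2, sigma_i2, sigma_h2, sigma_e2, sigma_p2, F)
    return np.asarray(sigma_u2, float) / denom


def hpd_interval(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the samples."""
    x = np.sort(np.asarray(samples, float))
    m = len(x)
    k = max(int(np.ceil(prob * m)), 2)
    if k >= m:
        return float(x[0]), float(x[-1])
    widths = x[k - 1 :] - x[: m - k + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k - 1])
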