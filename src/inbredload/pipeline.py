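"""End-to-end orchestration: simulate/load -> decompose -> relationships -> fit -> scan.

All randomness flows from one root seed; per-stage seeds are derived from it
deterministically, so a rerun with the same configuration reproduces every
table bit-for-bit (single-threaded).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .backsolve import backsolve_effects, manhattan_table, snp_variances, top_regions, window_variances
from .decomposition import ancestor_summary, mendelian_decomposition
from .design import ModelSpec, assemble_design, filter_outliers
from .genomic import blend_g, build_h_inverse, h_diagonal, vanraden_g
from .gibbs import (
    GibbsConfig,
    accuracy,
    depression_summary,
    gibbs_sampler,
    heritability,
    load_variance_ratio,
)
from .pedigree import a_inverse, ped_stats, relationship_submatrix, tabular_a
from .simulate import SimulationConfig, default_model_spec, simulate_dataset


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:16]


def run_full_analysis(
    sim_cfg: SimulationConfig,
    outdir,
    mcmc: GibbsConfig | None = None,
    window_sizes=(25, 50),
    blend: float = 0.05,
    ratio_F: float = 0.10,
) -> dict:
    """Run the whole pipeline on a synthetic dataset and write report tables.

    Returns a dict of in-memory results (summaries, scans, accuracies) and
    writes CSV tables plus a run manifest under ``outdir``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings = {}

    # --- simulate ---
    data = simulate_dataset(sim_cfg)
    ped = data.ped
    timings["simulate"] = time.time() - t0

    # --- pedigree & decomposition summaries ---
    stats = ped_stats(ped)
    stats["bins"].to_csv(out / "inbreeding_bins.csv", index=False)
    anc = ancestor_summary(data.table, ped)
    anc["per_ancestor"].to_csv(out / "ancestor_contributions.csv", index=False)
    data.table.to_frame().to_csv(out / "partial_inbreeding.csv", index=False)
    timings["decompose"] = time.time() - t0

    # --- relationship matrices ---
    gset = data.genotyped_internal
    A_inv = a_inverse(ped)
    A22 = relationship_submatrix(ped, ped.labels[gset - 1])
    # genomic data restricted to genotyped animals
    geno = data.geno
    sub = type(geno)(
        animal_ids=geno.animal_ids[gset - 1],
        snp_ids=geno.snp_ids,
        counts=geno.counts[gset - 1],
        chrom=geno.chrom,
        pos=geno.pos,
    )
    G = vanraden_g(sub)
    H_inv = build_h_inverse(A_inv, A22, G, gset - 1, blend=blend)
    timings["relmat"] = time.time() - t0

    # --- fit ---
    spec = default_model_spec(sim_cfg)
    records = filter_outliers(data.records)
    bundle = assemble_design(records, spec, ped, table=data.table)
    mcmc = mcmc or GibbsConfig(seed=stage_seed(sim_cfg.seed, "gibbs"))
    fit = gibbs_sampler(bundle, H_inv, mcmc)
    summ = fit.summary()
    summ.to_csv(out / "posterior_summary.csv", index=False)
    timings["fit"] = time.time() - t0

    # derived quantities (posterior means)
    s = fit.samples
    dep = depression_summary(
        s["d"].mean(), s["d"].std(ddof=1), float(np.mean(bundle.y)), float(np.std(bundle.y))
    )
    h2 = float(
        np.mean(
            heritability(
                s["sigma_u2"], s["sigma_h2"], s["sigma_e2"],
                s["sigma_p2"].fillna(0.0),
            )
        )
    )
    ratio = float(
        np.mean(
            load_variance_ratio(
                s["sigma_u2"], s["sigma_i2"], s["sigma_h2"], s["sigma_e2"],
                s["sigma_p2"].fillna(0.0), F=ratio_F,
            )
        )
    )
    derived = {
        "dpm": dep["dpm"],
        "dpsd": dep["dpsd"],
        "heritability": h2,
        f"load_variance_ratio_F{ratio_F}": ratio,
        "p_corr_negative": fit.p_corr_negative(),
    }
    pd.Series(derived).to_csv(out / "derived_summary.csv", header=False)

    # --- accuracies grouped by cohort ---
    A = tabular_a(ped)
    Hdiag = h_diagonal(A, A22, G, gset - 1, blend=blend)
    acc_u = accuracy(fit.u_psd, Hdiag, s["sigma_u2"].mean())
    acc_i = accuracy(fit.i_psd, Hdiag, s["sigma_i2"].mean())
    gen = ped.birth_year - np.nanmin(ped.birth_year)
    max_gen = np.nanmax(gen)
    group = np.where(gen == 0, "founders", np.where(gen >= max_gen - 1, "candidates", "parents"))
    acc_df = pd.DataFrame(
        {"animal": ped.labels, "group": group, "acc_u": acc_u, "acc_i": acc_i,
         "ebv": fit.u_mean, "load": fit.i_mean}
    )
    acc_df.to_csv(out / "accuracy_by_group.csv", index=False)
    timings["accuracy"] = time.time() - t0

    # --- back-solve & window scans ---
    scans = {}
    for component, values in (("u", fit.u_mean[gset - 1]), ("i", fit.i_mean[gset - 1])):
        Gs = blend_g(G, A22, blend=blend)
        eff = backsolve_effects(sub, Gs, values)
        var = snp_variances(sub, eff)
        for wsize in window_sizes:
            win = window_variances(sub, var, wsize, mode="sliding")
            win.to_csv(out / f"windows_{component}_{wsize}.csv", index=False)
            manhattan_table(win).to_csv(out / f"manhattan_{component}_{wsize}.csv", index=False)
            regions = top_regions(win, threshold_pct=1.0)
            regions.to_csv(out / f"regions_{component}_{wsize}.csv", index=False)
            scans[(component, wsize)] = {"windows": win, "regions": regions}
    timings["backsolve"] = time.time() - t0

    manifest = {
        "package_version": __version__,
        "config": asdict(sim_cfg) | {"V": None},
        "config_hash": config_hash({k: str(v) for k, v in asdict(sim_cfg).items()}),
        "root_seed": sim_cfg.seed,
        "mcmc": {
            "n_iter": mcmc.n_iter, "burn_in": mcmc.burn_in, "thin": mcmc.thin, "seed": mcmc.seed
        },
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
        "n_animals": ped.n,
        "n_records": int(bundle.n_records),
        "n_genotyped": int(len(gset)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return {
        "data": data,
        "bundle": bundle,
        "fit": fit,
        "summary": summ,
        "derived": derived,
        "accuracy": acc_df,
        "scans": scans,
        "manifest": manifest,
        "ped_stats": stats,
    }
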