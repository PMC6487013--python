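"""End-to-end recovery experiments on synthetic populations.

These are the package's benchmark workflows: REML parameter recovery under
the generating repeatability model, QTL-window recovery by weighted
single-step GWAS, and latent CNV-region recovery through the CNVR
pipeline. They are used both by the test suite and by the reproduction
script; problem sizes are desk-scale versions of a commercial sow
population (a few thousand pedigree animals, ~2,000 genotyped sows,
5,000 SNPs).
"""

from __future__ import annotations

import numpy as np

from .cnvr import merge_cnvrs, qc_calls
from .reml import VarianceComponents, build_model_spec, estimate_reml, heritability
from .simulate import (
    SimConfig,
    simulate_cnv_calls,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)
from .wssgwas import run_wssgwas, select_significant_windows, window_variance


def reml_recovery(seed: int) -> dict:
    """Estimate (σ²a, σ²pe, σ²e) on data generated at (0.78, 0.57, 5.68).

    ~2,100 sows with 3–6 records each in a four-generation pedigree of
    4,200 animals; estimation uses the pedigree A⁻¹ (no genotypes needed).
    """
    cfg = SimConfig(
        n_founders=200,
        n_generations=4,
        n_animals_per_gen=1000,
        n_snps=10,
        n_chromosomes=1,
        n_qtl=0,
        records_per_sow_range=(3, 6),
        seed=seed,
    )
    ped = simulate_pedigree(cfg)
    phen, truth = simulate_phenotypes(ped, cfg)
    model = build_model_spec(phen, ped)
    vc = estimate_reml(model)
    truth_vc = VarianceComponents(cfg.sigma_a2, cfg.sigma_pe2, cfg.sigma_e2)
    return {
        "n_sows": int(phen["animal"].nunique()),
        "n_records": len(phen),
        "sigma_a2": vc.sigma_a2,
        "sigma_pe2": vc.sigma_pe2,
        "sigma_e2": vc.sigma_e2,
        "h2": heritability(vc),
        "h2_se": vc.h2_se,
        "true_h2": heritability(truth_vc),
        "rel_err_a": abs(vc.sigma_a2 - cfg.sigma_a2) / cfg.sigma_a2,
        "rel_err_pe": abs(vc.sigma_pe2 - cfg.sigma_pe2) / cfg.sigma_pe2,
        "rel_err_e": abs(vc.sigma_e2 - cfg.sigma_e2) / cfg.sigma_e2,
    }


def qtl_window_ranks(seed: int, n_iter: int = 2) -> dict:
    """One WssGWAS replicate: ranks of the QTL-bearing windows.

    Five QTL jointly explaining 40% of σ²a, 5,000 SNPs, ~2,000 genotyped
    sows. For each iteration, all 1-Mb windows are collapsed to
    non-overlapping local maxima and ranked by the percentage of additive
    variance they explain; a QTL's rank is that of the first kept window
    containing it (a large sentinel when none does).
    """
    cfg = SimConfig(seed=seed)  # defaults are this experiment's conditions
    ped = simulate_pedigree(cfg)
    panel = simulate_genotypes(ped, cfg)
    phen, truth = simulate_phenotypes(ped, cfg, panel=panel)
    model = build_model_spec(phen, ped)
    vc = VarianceComponents(cfg.sigma_a2, cfg.sigma_pe2, cfg.sigma_e2)
    effects, _, _ = run_wssgwas(model, ped, panel, vc, n_iter=n_iter)
    qtl_chrom = panel.chrom[truth.qtl_snp_index]
    qtl_pos = panel.pos_bp[truth.qtl_snp_index]
    out = {"n_genotyped": panel.n_samples, "ranks": []}
    for eff in effects:
        wins = window_variance(eff, panel, vc.sigma_a2)
        kept = sorted(
            select_significant_windows(wins, 0.0, collapse=True),
            key=lambda w: -w.pct_variance,
        )
        ranks = []
        for c, p in zip(qtl_chrom, qtl_pos):
            rank = next(
                (
                    i + 1
                    for i, w in enumerate(kept)
                    if w.chrom == c and w.start_bp <= p <= w.end_bp
                ),
                len(kept) + 1,
            )
            ranks.append(rank)
        out["ranks"].append(ranks)
    return out


def qtl_recovery(seeds, n_iter: int = 2) -> dict:
    """Aggregate QTL-window recovery over replicates."""
    first, last = [], []
    for seed in seeds:
        res = qtl_window_ranks(seed, n_iter=n_iter)
        first.extend(res["ranks"][0])
        last.extend(res["ranks"][-1])
    first = np.array(first)
    last = np.array(last)
    return {
        "n_replicates": len(list(seeds)),
        "top10_fraction_iter1": float((first <= 10).mean()),
        "top10_fraction_final": float((last <= 10).mean()),
        "mean_rank_iter1": float(first.mean()),
        "mean_rank_final": float(last.mean()),
    }


def cnvr_recovery(seed: int) -> dict:
    """Latent CNV-region recovery through QC + concatenation + filtering."""
    cfg = SimConfig(seed=seed)
    ped = simulate_pedigree(cfg)
    panel = simulate_genotypes(ped, cfg)
    calls, truth = simulate_cnv_calls(panel, cfg)
    regions = merge_cnvrs(qc_calls(calls), total_samples=panel.n_samples)
    recovered = 0
    eligible = 0
    for latent in truth.cnvr_intervals.itertuples(index=False):
        if latent.carrier_freq < 2 / panel.n_samples:
            continue
        eligible += 1
        covering = [
            r
            for r in regions
            if r.chrom == latent.chrom
            and r.start_bp <= latent.start_bp
            and r.end_bp >= latent.end_bp
        ]
        if len(covering) == 1:
            recovered += 1
    n_loss = sum(c.state == "loss" for c in calls)
    n_gain = sum(c.state == "gain" for c in calls)
    return {
        "n_calls": len(calls),
        "n_regions": len(regions),
        "n_latent_eligible": eligible,
        "n_latent_recovered": recovered,
        "call_loss_gain_ratio": n_loss / n_gain if n_gain else float("inf"),
    }
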