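"""Statistical structure of the synthetic populations."""

import numpy as np
import pytest
from scipy import stats

from sowscan import (
    SimConfig,
    compute_A,
    simulate_cnv_calls,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)
from sowscan.errors import ConfigError
from sowscan.relationship import UNKNOWN
from sowscan.simulate import simulate_qc_metrics


def test_smallest_nonfounder_pedigree():
    cfg = SimConfig(n_founders=2, n_generations=1, n_animals_per_gen=1)
    ped = simulate_pedigree(cfg)
    assert len(ped) == 3
    assert ped.sire[2] == 0 and ped.dam[2] == 1
    assert np.all(ped.sire[:2] == UNKNOWN)


def test_pedigree_deterministic(small_config):
    p1 = simulate_pedigree(small_config)
    p2 = simulate_pedigree(small_config)
    assert np.array_equal(p1.sire, p2.sire) and np.array_equal(p1.dam, p2.dam)
    assert np.array_equal(p1.sex, p2.sex)


def test_late_generations_are_inbred():
    cfg = SimConfig(n_founders=10, n_generations=5, n_animals_per_gen=20,
                    n_snps=50, n_chromosomes=1, seed=7)
    ped = simulate_pedigree(cfg)
    A = compute_A(ped)  # tabular oracle for inbreeding
    last_gen = np.arange(len(ped) - 20, len(ped))
    assert np.mean(np.diag(A)[last_gen] - 1.0) > 0.0
    np.testing.assert_allclose(ped.inbreeding, np.diag(A) - 1.0, atol=1e-12)


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        SimConfig(n_founders=1)
    with pytest.raises(ConfigError):
        SimConfig(maf_range=(0.0, 0.5))
    with pytest.raises(ConfigError):
        SimConfig(genotyped_fraction=0.0)
    with pytest.raises(ConfigError):
        SimConfig(sigma_a2=-1.0)


def test_fixed_allele_gives_all_homozygotes():
    cfg = SimConfig(n_founders=4, n_generations=1, n_animals_per_gen=4,
                    n_snps=1, n_chromosomes=1, maf_range=(0.5, 0.5), seed=1)
    ped = simulate_pedigree(cfg)
    panel = simulate_genotypes(ped, cfg)
    # degenerate check via direct construction: force frequency 1
    object.__setattr__(cfg, "maf_range", (0.5, 0.5))
    full = panel.pedigree_genotypes
    # Mendelian constraint: parents both 0 -> offspring 0; both 2 -> 2
    for i in range(len(ped)):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN:
            continue
        both0 = (full[s] == 0) & (full[d] == 0)
        both2 = (full[s] == 2) & (full[d] == 2)
        assert np.all(full[i][both0] == 0)
        assert np.all(full[i][both2] == 2)


def test_mendelian_consistency_all_loci(small_config):
    ped = simulate_pedigree(small_config)
    panel = simulate_genotypes(ped, small_config)
    full = panel.pedigree_genotypes
    for i in range(len(ped)):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN:
            continue
        # offspring allele count lies within what the parents can donate
        lo = (full[s] == 2).astype(int) + (full[d] == 2).astype(int)
        hi = 2 - (full[s] == 0).astype(int) - (full[d] == 0).astype(int)
        assert np.all(full[i] >= lo) and np.all(full[i] <= hi)


def test_founder_genotype_frequency_expectation():
    cfg = SimConfig(n_founders=10_000, n_generations=1, n_animals_per_gen=2,
                    n_snps=1, n_chromosomes=1, maf_range=(0.3, 0.3), seed=2,
                    genotyped_fraction=1.0)
    ped = simulate_pedigree(cfg)
    panel = simulate_genotypes(ped, cfg)
    founders = panel.pedigree_genotypes[:10_000, 0]
    se = np.sqrt(2 * 0.3 * 0.7 / 10_000)
    assert abs(founders.mean() - 0.6) < 3 * se


def test_map_sorted_within_chromosome(small_config):
    ped = simulate_pedigree(small_config)
    panel = simulate_genotypes(ped, small_config)
    for c in np.unique(panel.chrom):
        pos = panel.pos_bp[panel.chrom == c]
        assert np.all(np.diff(pos) > 0)


def test_no_variation_phenotypes_equal_cg_mean(small_config):
    cfg = SimConfig(**{**small_config.to_dict(),
                       "sigma_a2": 0.0, "sigma_pe2": 0.0, "sigma_e2": 0.0})
    ped = simulate_pedigree(cfg)
    phen, truth = simulate_phenotypes(ped, cfg)
    means = truth.contemporary_group_means
    np.testing.assert_allclose(phen["value"], means[phen["cg"]], atol=1e-12)


def test_phenotypes_deterministic(small_config):
    ped = simulate_pedigree(small_config)
    t1, _ = simulate_phenotypes(ped, small_config)
    t2, _ = simulate_phenotypes(ped, small_config)
    assert t1.equals(t2)


def test_phenotypic_variance_matches_generating_components():
    cfg = SimConfig(n_founders=200, n_generations=2, n_animals_per_gen=1000,
                    n_snps=50, n_chromosomes=1, n_qtl=0, seed=5,
                    records_per_sow_range=(1, 1), n_contemporary_groups=1)
    ped = simulate_pedigree(cfg)
    phen, _ = simulate_phenotypes(ped, cfg)
    assert len(phen) >= 1000
    total = 0.78 + 0.57 + 5.68
    assert phen["value"].var() == pytest.approx(total, rel=0.10)


def test_regression_of_phenotype_on_true_bv_has_unit_slope():
    cfg = SimConfig(n_founders=200, n_generations=2, n_animals_per_gen=1000,
                    n_snps=50, n_chromosomes=1, n_qtl=0, seed=6,
                    records_per_sow_range=(2, 2), n_contemporary_groups=1)
    ped = simulate_pedigree(cfg)
    phen, truth = simulate_phenotypes(ped, cfg)
    pos = ped.position_of(phen["animal"].to_numpy())
    a = truth.true_breeding_values[pos]
    slope = np.cov(a, phen["value"])[0, 1] / np.var(a)
    assert slope == pytest.approx(1.0, abs=0.12)


def test_qtl_variance_fraction_is_honoured():
    cfg = SimConfig(n_founders=100, n_generations=2, n_animals_per_gen=400,
                    n_snps=500, n_chromosomes=2, n_qtl=5,
                    qtl_variance_fraction=0.4, seed=8)
    ped = simulate_pedigree(cfg)
    panel = simulate_genotypes(ped, cfg)
    phen, truth = simulate_phenotypes(ped, cfg, panel=panel)
    g = (panel.pedigree_genotypes[:, truth.qtl_snp_index].astype(float)
         @ truth.qtl_effects)
    assert g.var() == pytest.approx(0.4 * 0.78, rel=1e-9)
    assert truth.true_breeding_values.var() == pytest.approx(0.78, rel=0.25)


class TestCnvSimulation:
    def test_no_latent_regions_no_calls(self, small_config):
        cfg = SimConfig(**{**small_config.to_dict(), "cnv_n_latent_regions": 0})
        ped = simulate_pedigree(cfg)
        panel = simulate_genotypes(ped, cfg)
        calls, truth = simulate_cnv_calls(panel, cfg)
        assert calls == [] and truth.cnvr_intervals.empty

    def test_full_penetrance_no_jitter_identical_calls(self, small_config):
        cfg = SimConfig(**{**small_config.to_dict(),
                           "cnv_n_latent_regions": 1,
                           "cnv_carrier_freq_range": (1.0, 1.0),
                           "cnv_boundary_jitter_snps": 0,
                           "cnv_loss_gain_odds": 1e9})
        ped = simulate_pedigree(cfg)
        panel = simulate_genotypes(ped, cfg)
        calls, _ = simulate_cnv_calls(panel, cfg)
        assert len(calls) == panel.n_samples
        spans = {(c.chrom, c.start_bp, c.end_bp, c.state) for c in calls}
        assert len(spans) == 1
        assert calls[0].state == "loss"

    def test_loss_gain_odds_within_binomial_error(self):
        cfg = SimConfig(n_founders=60, n_generations=2, n_animals_per_gen=200,
                        n_snps=2000, n_chromosomes=10, seed=3,
                        cnv_n_latent_regions=50, cnv_loss_gain_odds=8.0,
                        cnv_carrier_freq_range=(0.1, 0.3))
        ped = simulate_pedigree(cfg)
        panel = simulate_genotypes(ped, cfg)
        calls, truth = simulate_cnv_calls(panel, cfg)
        n_loss = sum(c.state == "loss" for c in calls)
        # binomial test on the region states the calls were drawn from
        states = truth.cnvr_intervals["state"]
        k = int((states == "loss").sum())
        p = stats.binomtest(k, len(states), 8.0 / 9.0).pvalue
        assert p > 1e-3
        assert n_loss > sum(c.state == "gain" for c in calls)

    def test_calls_deterministic(self, small_config):
        ped = simulate_pedigree(small_config)
        panel = simulate_genotypes(ped, small_config)
        c1, _ = simulate_cnv_calls(panel, small_config)
        c2, _ = simulate_cnv_calls(panel, small_config)
        assert [c.__dict__ for c in c1] == [c.__dict__ for c in c2]


def test_qc_metrics_fail_fraction(small_config):
    ped = simulate_pedigree(small_config)
    panel = simulate_genotypes(ped, small_config)
    metrics = simulate_qc_metrics(panel, small_config, fail_fraction=0.2)
    assert len(metrics) == panel.n_samples
    assert (metrics["lrr_sd"] >= 0.30).mean() == pytest.approx(0.2, abs=0.1)
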