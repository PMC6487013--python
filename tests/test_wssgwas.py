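"""SNP back-solving, weight updates and window variance decomposition."""

import numpy as np
import pytest

from sowscan import (
    SimConfig,
    VarianceComponents,
    backsolve_snp_effects,
    build_model_spec,
    compute_G,
    run_wssgwas,
    select_significant_windows,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
    update_weights,
    window_variance,
)
from sowscan.errors import DataError
from sowscan.wssgwas import SnpEffects, WindowResult, snp_variance_ratio

from conftest import tiny_panel


class TestBacksolve:
    def test_zero_gebv_zero_effects(self):
        panel = tiny_panel([[0, 2], [2, 0]])
        eff = backsolve_snp_effects(panel, np.eye(2), np.zeros(2))
        np.testing.assert_allclose(eff.u_hat, 0.0)

    def test_identity_Zu_reproduces_gebv_on_column_space(self):
        """With unblended G (pseudo-inverse) and d = 1, Z·û = â_g for â_g in
        the genotype column space — the back-solve is exact, not approximate."""
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 3, size=(8, 30))
        panel = tiny_panel(geno)
        G = compute_G(panel)
        G_pinv = np.linalg.pinv(G)
        p = panel.allele_frequencies()
        Z = panel.genotypes - 2 * p
        a_g = Z @ rng.normal(size=30)  # guaranteed in the column space
        eff = backsolve_snp_effects(panel, G_pinv, a_g)
        np.testing.assert_allclose(Z @ eff.u_hat, a_g, atol=1e-8)

    def test_zero_weight_zeroes_that_snp(self):
        rng = np.random.default_rng(1)
        panel = tiny_panel(rng.integers(0, 3, size=(5, 4)))
        d = np.array([1.0, 0.0, 1.0, 1.0])
        eff = backsolve_snp_effects(panel, np.eye(5), rng.normal(size=5), d)
        assert eff.u_hat[1] == 0.0
        assert eff.u_hat[0] != 0.0

    def test_lambda_is_reciprocal_heterozygosity_sum(self):
        panel = tiny_panel([[0, 1], [2, 1], [1, 0], [1, 2]])
        p = panel.allele_frequencies()
        expected = 1.0 / (2 * np.sum(p * (1 - p)))
        assert snp_variance_ratio(panel) == pytest.approx(expected)


class TestWeights:
    def test_weight_formula_before_normalization(self):
        # û=0.1, p=0.5 -> raw d = 0.01 * 0.5 = 0.005
        u, p = 0.1, 0.5
        assert u**2 * 2 * p * (1 - p) == pytest.approx(0.005)

    def test_normalization_preserves_trace(self):
        rng = np.random.default_rng(2)
        panel = tiny_panel(rng.integers(0, 3, size=(6, 10)))
        eff = SnpEffects(rng.normal(size=10), np.ones(10), 0.1, 1)
        d = update_weights(eff, panel)
        assert d.sum() == pytest.approx(10.0, abs=1e-12)

    def test_two_snp_normalization_convention(self):
        # raw weights (1, 3) -> normalized (0.5, 1.5)
        panel = tiny_panel([[0, 0], [1, 1], [2, 2], [1, 1]])
        p = panel.allele_frequencies()
        h = 2 * p * (1 - p)
        u = np.sqrt(np.array([1.0, 3.0]) / h)
        eff = SnpEffects(u, np.ones(2), 0.1, 1)
        np.testing.assert_allclose(update_weights(eff, panel), [0.5, 1.5])

    def test_symmetric_effects_give_unit_weights(self):
        panel = tiny_panel([[0, 0, 0], [1, 1, 1], [2, 2, 2]])
        eff = SnpEffects(np.full(3, 0.2), np.ones(3), 0.1, 1)
        np.testing.assert_allclose(update_weights(eff, panel), 1.0)

    def test_all_zero_effects_reset_with_warning(self):
        panel = tiny_panel([[0, 1], [1, 0], [2, 1]])
        eff = SnpEffects(np.zeros(2), np.ones(2), 0.1, 1)
        with pytest.warns(UserWarning, match="zero"):
            d = update_weights(eff, panel)
        np.testing.assert_allclose(d, 1.0)


class TestWindowVariance:
    def test_zero_effects_zero_windows(self):
        rng = np.random.default_rng(3)
        panel = tiny_panel(rng.integers(0, 3, size=(5, 8)))
        eff = SnpEffects(np.zeros(8), np.ones(8), 0.1, 1)
        wins = window_variance(eff, panel, sigma_a2=1.0)
        assert all(w.pct_variance == 0.0 for w in wins)

    def test_single_snp_hw_window_explains_all_variance(self):
        rng = np.random.default_rng(4)
        n = 20_000
        geno = rng.binomial(2, 0.5, size=(n, 1))
        panel = tiny_panel(geno)
        c = 0.3
        eff = SnpEffects(np.array([c]), np.ones(1), 1.0, 1)
        wins = window_variance(eff, panel, sigma_a2=c**2 * 0.5)
        assert len(wins) == 1
        assert wins[0].pct_variance == pytest.approx(100.0, rel=0.03)

    def test_matches_per_animal_brute_force(self):
        rng = np.random.default_rng(5)
        m = 60
        panel = tiny_panel(
            rng.integers(0, 3, size=(50, m)),
            chrom=np.repeat([1, 2], 30),
            pos=np.concatenate([np.sort(rng.choice(3_000_000, 30, replace=False)) + 1] * 2),
        )
        u = rng.normal(size=m)
        eff = SnpEffects(u, np.ones(m), 0.1, 1)
        wins = window_variance(eff, panel, sigma_a2=2.0)
        p = panel.allele_frequencies()
        Z = panel.genotypes - 2 * p
        # brute force: explicit per-animal sums for every window
        k = 0
        for c in (1, 2):
            idx = np.nonzero(panel.chrom == c)[0]
            pos = panel.pos_bp[idx]
            for j, start in enumerate(pos):
                inside = idx[(pos >= start) & (pos < start + 1_000_000)]
                scores = [float(Z[i, inside] @ u[inside]) for i in range(50)]
                expected = np.var(scores) / 2.0 * 100.0
                assert wins[k].pct_variance == pytest.approx(expected, abs=1e-10)
                assert wins[k].n_snps == len(inside)
                k += 1
        assert k == len(wins)

    def test_invariant_to_constant_genotype_shift(self):
        rng = np.random.default_rng(6)
        geno = rng.integers(0, 2, size=(30, 5))  # codes 0/1 so +1 stays valid
        panel1 = tiny_panel(geno)
        panel2 = tiny_panel(geno + np.array([1, 0, 0, 0, 0]))
        u = rng.normal(size=5)
        eff = SnpEffects(u, np.ones(5), 0.1, 1)
        w1 = window_variance(eff, panel1, 1.0)
        w2 = window_variance(eff, panel2, 1.0)
        for a, b in zip(w1, w2):
            assert a.pct_variance == pytest.approx(b.pct_variance, abs=1e-12)

    def test_orthogonal_extension_never_decreases_variance(self):
        # two SNPs with zero covariance: the two-SNP window's variance is the
        # sum of the single-SNP variances
        geno = np.array([[0, 0], [0, 2], [2, 0], [2, 2]])  # orthogonal columns
        panel = tiny_panel(geno, pos=np.array([1000, 2000]))
        u = np.array([0.5, 0.7])
        eff = SnpEffects(u, np.ones(2), 0.1, 1)
        wins = window_variance(eff, panel, 1.0)
        assert wins[0].n_snps == 2
        single = window_variance(
            SnpEffects(np.array([u[0], 0.0]), np.ones(2), 0.1, 1), panel, 1.0
        )
        assert wins[0].pct_variance >= single[0].pct_variance


class TestSelectWindows:
    def test_all_below_threshold_empty(self):
        wins = [WindowResult(1, 1, 100, 3, 0.5)]
        assert select_significant_windows(wins, 1.0) == []

    def test_threshold_zero_returns_all_without_collapse(self):
        wins = [
            WindowResult(1, 1, 100, 3, 0.5),
            WindowResult(1, 50, 150, 3, 0.7),
            WindowResult(2, 1, 100, 2, 0.2),
        ]
        out = select_significant_windows(wins, 0.0, collapse=False)
        assert len(out) == 3

    def test_overlapping_survivors_collapse_to_maximum(self):
        wins = [
            WindowResult(1, 1, 100, 3, 1.5),
            WindowResult(1, 50, 150, 3, 2.5),
            WindowResult(1, 140, 240, 3, 1.2),
            WindowResult(2, 1, 100, 2, 1.1),
        ]
        out = select_significant_windows(wins, 1.0)
        assert [(w.chrom, w.start_bp) for w in out] == [(1, 50), (2, 1)]


@pytest.fixture(scope="module")
def small_gwas():
    cfg = SimConfig(n_founders=30, n_generations=2, n_animals_per_gen=80,
                    n_snps=300, n_chromosomes=3, chrom_length_bp=3_000_000,
                    n_qtl=2, qtl_variance_fraction=0.5, seed=13,
                    records_per_sow_range=(2, 4))
    ped = simulate_pedigree(cfg)
    panel = simulate_genotypes(ped, cfg)
    phen, truth = simulate_phenotypes(ped, cfg, panel=panel)
    model = build_model_spec(phen, ped)
    return cfg, ped, panel, model, truth


class TestFullIteration:
    def test_first_iteration_equals_unweighted_backsolve(self, small_gwas):
        cfg, ped, panel, model, truth = small_gwas
        vc = VarianceComponents(0.78, 0.57, 5.68)
        effects, _, _ = run_wssgwas(model, ped, panel, vc, n_iter=2)
        np.testing.assert_allclose(effects[0].d, 1.0)
        solo, _, _ = run_wssgwas(model, ped, panel, vc, n_iter=1)
        np.testing.assert_allclose(solo[0].u_hat, effects[0].u_hat, atol=1e-12)

    def test_deterministic_given_seed(self, small_gwas):
        cfg, ped, panel, model, truth = small_gwas
        vc = VarianceComponents(0.78, 0.57, 5.68)
        e1, w1, _ = run_wssgwas(model, ped, panel, vc, n_iter=2)
        e2, w2, _ = run_wssgwas(model, ped, panel, vc, n_iter=2)
        np.testing.assert_array_equal(e1[-1].u_hat, e2[-1].u_hat)
        assert [(w.chrom, w.start_bp, w.pct_variance) for w in w1] == [
            (w.chrom, w.start_bp, w.pct_variance) for w in w2
        ]

    def test_invalid_iteration_count(self, small_gwas):
        cfg, ped, panel, model, truth = small_gwas
        with pytest.raises(DataError):
            run_wssgwas(model, ped, panel, VarianceComponents(1, 1, 1), n_iter=0)
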