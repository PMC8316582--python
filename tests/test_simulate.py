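"""Generator checks: dosage domain, LD decay, calibration, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grexlink import simulate
from grexlink.ase import coverage_filter, imbalance_test, log_afc
from grexlink.cross_ancestry import fit_cross_ancestry
from grexlink.types import ConfigurationError, SimConfig


def test_reference_panel_domain_and_reproducibility():
    cfg = SimConfig(n_ref_samples=100, n_variants=50, n_genes=5,
                    weights_per_gene=2, seed=7)
    panel = simulate.simulate_reference_panel(cfg)
    assert panel.dosages.shape == (100, 50)
    assert set(np.unique(panel.dosages)) <= {0.0, 1.0, 2.0}
    panel2 = simulate.simulate_reference_panel(cfg)
    np.testing.assert_array_equal(panel.dosages, panel2.dosages)
    pd.testing.assert_frame_equal(panel.variants, panel2.variants)


def test_allele_frequencies_match_binomial_sampling():
    # at maf 0.5 exactly, observed frequencies are Binomial(2n, 0.5)/2n
    cfg = SimConfig(n_ref_samples=5000, n_variants=100, n_genes=5,
                    weights_per_gene=2, maf_range=(0.5, 0.5), ld_decay=0.0,
                    seed=1)
    panel = simulate.simulate_reference_panel(cfg)
    freqs = panel.dosages.mean(axis=0) / 2
    se = np.sqrt(0.25 / (2 * cfg.n_ref_samples))
    within = np.abs(freqs - 0.5) <= 3 * se
    assert within.mean() >= 0.95


def test_zero_ld_decay_gives_independent_variants():
    # under independence, E[r^2] between dosage columns is ~1/(n-1)
    n = 5000
    cfg = SimConfig(n_ref_samples=n, n_variants=60, n_genes=5,
                    weights_per_gene=2, ld_decay=0.0, seed=2)
    panel = simulate.simulate_reference_panel(cfg)
    cor = np.corrcoef(panel.dosages, rowvar=False)
    off = cor[np.triu_indices_from(cor, k=1)] ** 2
    expected = 1.0 / n
    mc_se = off.std(ddof=1) / np.sqrt(len(off))
    assert abs(off.mean() - expected) < 3 * mc_se + 1e-4


def test_positive_ld_decay_correlates_neighbours():
    cfg = SimConfig(n_ref_samples=2000, n_variants=50, n_genes=5,
                    weights_per_gene=2, ld_decay=0.9, seed=3)
    panel = simulate.simulate_reference_panel(cfg)
    cor = np.corrcoef(panel.dosages, rowvar=False)
    adjacent = np.array([cor[i, i + 1] for i in range(49)])
    assert adjacent.mean() > 0.5


def test_invalid_dimensions_rejected():
    with pytest.raises(ConfigurationError):
        SimConfig(n_ref_samples=1, n_variants=10)
    with pytest.raises(ConfigurationError):
        SimConfig(n_variants=0)


class TestWeightModels:
    def test_perfect_cross_tissue_correlation_gives_identical_weights(self):
        cfg = SimConfig(n_variants=50, n_genes=5, weights_per_gene=3,
                        cross_tissue_cor=1.0, seed=4)
        panel = simulate.simulate_reference_panel(cfg)
        models = simulate.simulate_weight_models(cfg, panel)
        by_gene = {}
        for m in models:
            by_gene.setdefault(m.gene_id, []).append(m)
        for ms in by_gene.values():
            ref = ms[0].weights
            for m in ms[1:]:
                assert m.weights == ref

    def test_zero_cross_tissue_correlation(self):
        cfg = SimConfig(n_variants=4000, n_genes=1000, weights_per_gene=4,
                        tissues=("a", "b"), cross_tissue_cor=0.0, seed=5)
        panel_cfg = SimConfig(n_ref_samples=2, n_variants=4000, n_genes=1000,
                              weights_per_gene=4, seed=5)
        panel = simulate.simulate_reference_panel(panel_cfg)
        models = simulate.simulate_weight_models(cfg, panel)
        by_gene = {}
        for m in models:
            by_gene.setdefault(m.gene_id, {})[m.tissue] = m.weight_array
        cors = [np.corrcoef(d["a"], d["b"])[0, 1] for d in by_gene.values()]
        mc_se = np.std(cors, ddof=1) / np.sqrt(len(cors))
        assert abs(np.mean(cors)) < 3 * mc_se + 0.01

    def test_single_weight_models(self):
        cfg = SimConfig(n_variants=30, n_genes=6, weights_per_gene=1, seed=6)
        panel = simulate.simulate_reference_panel(cfg)
        for m in simulate.simulate_weight_models(cfg, panel):
            assert len(m) == 1 and m.weight_array[0] != 0


class TestGwas:
    def test_null_z_scores_are_standard_normal(self):
        cfg = SimConfig(n_ref_samples=200, n_gwas_samples=4000,
                        n_variants=5000, n_genes=5, weights_per_gene=2,
                        ld_decay=0.0, seed=8)
        panel = simulate.simulate_reference_panel(cfg)
        weights = simulate.simulate_weight_models(cfg, panel)
        ss, _ = simulate.simulate_gwas(cfg, weights, panel)
        z = ss["z"].to_numpy()
        frac = np.mean(np.abs(z) > 1.96)
        assert 0.041 <= frac <= 0.059
        chi2 = z**2
        mc_se = chi2.std(ddof=1) / np.sqrt(len(chi2))
        assert abs(chi2.mean() - 1.0) <= 3 * mc_se

    def test_causal_gene_variants_carry_the_top_signal(self):
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            cfg = SimConfig(n_ref_samples=150, n_gwas_samples=10_000,
                            n_variants=100, n_genes=10, weights_per_gene=3,
                            tissues=("t1",), causal_genes={"gene0001": 0.1},
                            seed=1000 + rep)
            panel = simulate.simulate_reference_panel(cfg)
            weights = simulate.simulate_weight_models(cfg, panel)
            ss, _ = simulate.simulate_gwas(cfg, weights, panel)
            causal_vids = set(weights[0].variant_ids)
            absz = ss.set_index("variant_id")["z"].abs()
            top_causal = absz.loc[list(causal_vids)].max()
            top_null = absz.drop(list(causal_vids)).max()
            hits += top_causal > top_null
        assert hits >= 0.9 * n_rep

    def test_determinism_same_seed(self):
        cfg = SimConfig(n_variants=50, n_genes=5, weights_per_gene=2,
                        n_gwas_samples=500, causal_genes={"gene0002": 0.2},
                        seed=9)
        panel = simulate.simulate_reference_panel(cfg)
        weights = simulate.simulate_weight_models(cfg, panel)
        ss1, _ = simulate.simulate_gwas(cfg, weights, panel)
        ss2, _ = simulate.simulate_gwas(cfg, weights, panel)
        pd.testing.assert_frame_equal(ss1, ss2)


class TestAse:
    def test_negative_imbalance_rejected(self, small_weights):
        with pytest.raises(ConfigurationError):
            simulate.simulate_ase(small_weights, 10, 30, -1.0, seed=0)

    def test_low_coverage_mostly_filtered(self, small_weights):
        table, _ = simulate.simulate_ase(small_weights, 500, 4.0, 0.0, seed=1)
        kept = coverage_filter(table)
        assert len(kept) < 0.5 * len(table)

    def test_null_imbalance_p_values_uniform(self, small_weights):
        pvals = []
        for rep in range(200):
            table, _ = simulate.simulate_ase(small_weights[:1], 60, 50, 0.0,
                                             seed=2000 + rep)
            table = coverage_filter(table)
            afc = np.abs(log_afc(table["hapA_count"], table["hapB_count"]))
            het = afc[table["genotype_class"] == "het"]
            hom = afc[table["genotype_class"] == "hom"]
            pvals.append(imbalance_test(het, hom).p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_strong_imbalance_detected(self, small_weights):
        sig = 0
        for rep in range(100):
            table, _ = simulate.simulate_ase(small_weights[:1], 100, 100, 2.0,
                                             seed=3000 + rep)
            table = coverage_filter(table)
            afc = np.abs(log_afc(table["hapA_count"], table["hapB_count"]))
            het = afc[table["genotype_class"] == "het"]
            hom = afc[table["genotype_class"] == "hom"]
            sig += imbalance_test(het, hom).p < 0.05
        assert sig >= 95


class TestTwoAncestry:
    def test_zero_noise_is_exact(self):
        df = simulate.simulate_two_ancestry_effects(50, alpha=0.7, sigma2=0.0,
                                                    seed=1)
        np.testing.assert_allclose(df["beta_A"], 0.7 * df["beta_E"])

    def test_empty_table(self):
        df = simulate.simulate_two_ancestry_effects(0, 1.0, 1.0, seed=1)
        assert df.empty
        from grexlink.types import InsufficientDataError
        with pytest.raises(InsufficientDataError):
            fit_cross_ancestry(df)

    def test_alpha_recovered_at_large_n(self):
        df = simulate.simulate_two_ancestry_effects(5000, alpha=1.0,
                                                    sigma2=1.0, seed=2)
        fit = fit_cross_ancestry(df)
        assert abs(fit.alpha - 1.0) < 0.05


def test_ehr_case_counts_hit_target_prevalence(small_config, small_panel,
                                               small_weights):
    ehr = simulate.simulate_ehr(small_config, small_panel, small_weights,
                                n_individuals=3000, n_phecodes=20, n_labs=4,
                                target_prevalence=0.05, seed=42)
    counts = ehr.phecodes.sum(axis=0)
    # expected 150 cases per phecode; binomial 3 SE band
    se = np.sqrt(3000 * 0.05 * 0.95)
    assert ((counts - 150).abs() <= 3 * se).mean() >= 0.9
    assert set(ehr.covariates.columns) == {"age", "sex",
                                           *(f"PC{i}" for i in range(1, 11))}
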