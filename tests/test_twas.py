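"""Summary-based association: single-tissue Z, multi-tissue chi-square,
multiplicity thresholds, and the expression-vs-splicing signal comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grexlink import simulate, twas
from grexlink.harmonize import harmonize_sumstats
from grexlink.types import DegenerateModelError, InsufficientDataError, SimConfig

from conftest import make_model, make_panel


def _sumstats_for(panel, z):
    df = panel.variants[["variant_id", "chrom", "pos", "effect_allele",
                         "other_allele", "eaf"]].copy()
    df["z"] = z
    df["se"] = 0.1
    df["beta"] = df["z"] * df["se"]
    df["p"] = 2 * stats.norm.sf(np.abs(df["z"]))
    return df


class TestPredictedFeatureSd:
    def test_single_variant_reduces_to_dosage_sd(self):
        rng = np.random.default_rng(1)
        panel = make_panel(rng.integers(0, 3, (50, 1)))
        model = make_model([1.0])
        sigma_g, sigma_l = twas.predicted_feature_sd(model, panel)
        assert sigma_g == pytest.approx(panel.dosages[:, 0].std(ddof=1))
        assert sigma_l[0] == pytest.approx(sigma_g)

    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 3, (60, 1)).astype(float)
        panel = make_panel(np.hstack([col, col]))
        sigma_g, _ = twas.predicted_feature_sd(make_model([0.5, 0.5]), panel)
        assert sigma_g == pytest.approx(col[:, 0].std(ddof=1))

    def test_matches_brute_force_score_sd(self):
        rng = np.random.default_rng(3)
        panel = make_panel(rng.integers(0, 3, (80, 5)))
        w = rng.normal(size=5)
        model = make_model(w)
        sigma_g, _ = twas.predicted_feature_sd(model, panel)
        explicit = (panel.dosages @ w).std(ddof=1)
        assert sigma_g == pytest.approx(explicit, abs=1e-10)

    def test_constant_score_raises(self):
        panel = make_panel(np.ones((30, 1)) * 2)
        with pytest.raises(DegenerateModelError):
            twas.predicted_feature_sd(make_model([1.0]), panel)


class TestSingleTissue:
    def test_single_variant_model_passes_through_z(self):
        rng = np.random.default_rng(4)
        panel = make_panel(rng.integers(0, 3, (50, 1)))
        ss = _sumstats_for(panel, z=[2.5])
        res = twas.single_tissue_twas(ss, make_model([1.0]), panel)
        assert res.z == pytest.approx(2.5)
        assert res.p == pytest.approx(2 * stats.norm.sf(2.5))

    def test_correlated_pair_algebra(self):
        rng = np.random.default_rng(5)
        col = rng.integers(0, 3, (60, 1)).astype(float)
        panel = make_panel(np.hstack([col, col]))
        ss = _sumstats_for(panel, z=[2.0, 2.0])
        res = twas.single_tissue_twas(ss, make_model([0.5, 0.5]), panel)
        assert res.z == pytest.approx(2.0)

    def test_missing_variants_flagged_and_dropped(self):
        rng = np.random.default_rng(6)
        panel = make_panel(rng.integers(0, 3, (50, 3)))
        ss = _sumstats_for(panel, z=[1.0, 2.0, 3.0]).iloc[:1]  # only v1 left
        res = twas.single_tissue_twas(ss, make_model([0.1, 1.0, 1.0]), panel)
        assert res.n_model_variants == 1
        assert res.low_confidence  # lost > 50% of |weight| mass
        empty = ss.iloc[:0]
        res2 = twas.single_tissue_twas(empty, make_model([1.0, 1.0, 1.0]),
                                       panel)
        assert not res2.testable

    def test_matches_individual_level_regression(self):
        """Summary-based Z tracks the Z from regressing the trait on
        explicitly computed GReX in the GWAS cohort (r > 0.99)."""
        cfg = SimConfig(n_ref_samples=400, n_gwas_samples=2000,
                        n_variants=250, n_genes=50, weights_per_gene=4,
                        tissues=("t1",), ld_decay=0.5,
                        causal_genes={"gene0005": 0.1, "gene0030": 0.12},
                        seed=33)
        panel = simulate.simulate_reference_panel(cfg)
        weights = simulate.simulate_weight_models(cfg, panel)
        ss, truth = simulate.simulate_gwas(cfg, weights, panel,
                                           keep_cohort=True)
        h, _ = harmonize_sumstats(ss, panel)
        z_summary, z_indiv = [], []
        y = truth.liability
        yc = y - y.mean()
        for m in weights:
            z_summary.append(twas.single_tissue_twas(h, m, panel).z)
            cols = panel.column_index(m.variant_ids)
            g = truth.cohort_dosages[:, cols] @ m.weight_array
            gc = g - g.mean()
            beta = gc @ yc / (gc @ gc)
            resid = yc - beta * gc
            se = np.sqrt(resid @ resid / (len(y) - 2) / (gc @ gc))
            z_indiv.append(beta / se)
        r = np.corrcoef(z_summary, z_indiv)[0, 1]
        assert r > 0.99
        assert np.max(np.abs(np.array(z_summary) - z_indiv)) < 0.3

    def test_null_p_values_uniform(self):
        cfg = SimConfig(n_ref_samples=300, n_gwas_samples=3000,
                        n_variants=1300, n_genes=400, weights_per_gene=2,
                        tissues=("t1", "t2", "t3"), ld_decay=0.0, seed=17)
        panel = simulate.simulate_reference_panel(cfg)
        weights = simulate.simulate_weight_models(cfg, panel)
        ss, _ = simulate.simulate_gwas(cfg, weights, panel)
        h, _ = harmonize_sumstats(ss, panel)
        pvals = [twas.single_tissue_twas(h, m, panel).p for m in weights]
        assert len(pvals) >= 1000
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestTissueCorrelation:
    def test_identical_models_fully_correlated(self):
        rng = np.random.default_rng(7)
        panel = make_panel(rng.integers(0, 3, (80, 4)))
        m1 = make_model([1, 0.5, 0, 0], tissue="a")
        m2 = make_model([1, 0.5, 0, 0], tissue="b")
        cor = twas.tissue_correlation([m1, m2], panel)
        assert cor.loc["a", "b"] == pytest.approx(1.0)

    def test_symmetric_and_psd(self):
        rng = np.random.default_rng(8)
        panel = make_panel(rng.integers(0, 3, (100, 6)))
        models = [make_model(rng.normal(size=6), tissue=f"t{i}")
                  for i in range(4)]
        cor = twas.tissue_correlation(models, panel)
        np.testing.assert_allclose(cor, cor.T)
        assert np.linalg.eigvalsh(cor.to_numpy()).min() >= -1e-8
        np.testing.assert_allclose(np.diag(cor), 1.0)

    def test_disjoint_models_in_unlinked_panel_uncorrelated(self):
        cfg = SimConfig(n_ref_samples=4000, n_variants=10, n_genes=1,
                        weights_per_gene=2, ld_decay=0.0, seed=9)
        panel = simulate.simulate_reference_panel(cfg)
        m1 = make_model([1.0, -0.5] + [0] * 8, tissue="a")
        m2 = make_model([0] * 8 + [0.7, 1.2], tissue="b")
        m1.weights = {f"var{i:05d}": w for i, w in [(1, 1.0), (2, -0.5)]}
        m1.effect_alleles = {v: "A" for v in m1.weights}
        m2.weights = {f"var{i:05d}": w for i, w in [(9, 0.7), (10, 1.2)]}
        m2.effect_alleles = {v: "A" for v in m2.weights}
        cor = twas.tissue_correlation([m1, m2], panel)
        assert abs(cor.loc["a", "b"]) < 3.0 / np.sqrt(cfg.n_ref_samples)


class TestMultiTissue:
    def test_single_tissue_reduces_to_z_squared(self):
        cor = pd.DataFrame([[1.0]], index=["t1"], columns=["t1"])
        res = twas.multi_tissue_combine({"t1": 2.0}, cor)
        assert res.chi2 == pytest.approx(4.0)
        assert res.dof == 1
        assert res.p == pytest.approx(stats.chi2.sf(4.0, 1), abs=1e-4)
        assert res.p == pytest.approx(0.0455, abs=5e-4)

    def test_redundant_tissues_collapse_to_one_component(self):
        cor = pd.DataFrame(np.ones((2, 2)), index=["a", "b"],
                           columns=["a", "b"])
        res = twas.multi_tissue_combine({"a": 2.0, "b": 2.0}, cor)
        assert res.dof == 1
        assert res.chi2 == pytest.approx(4.0)

    def test_independent_tissues_sum_squares(self):
        cor = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        res = twas.multi_tissue_combine({"a": 1.0, "b": 2.0, "c": 3.0}, cor)
        assert res.chi2 == pytest.approx(14.0)
        assert res.dof == 3
        assert res.p == pytest.approx(stats.chi2.sf(14.0, 3))
        assert res.p == pytest.approx(0.00291, abs=2e-5)

    def test_condition_limit_drops_small_components(self):
        cor = pd.DataFrame([[1.0, 0.999], [0.999, 1.0]], index=["a", "b"],
                           columns=["a", "b"])
        res = twas.multi_tissue_combine({"a": 2.0, "b": -2.0}, cor,
                                        condition_limit=30)
        assert res.dof == 1  # lambda_min ~ 0.001, condition ~ 2000


@pytest.mark.parametrize("n,alpha,expected,tol", [
    (1031, 0.05, 4.85e-5, 5e-8),
    (323, 0.05, 1.55e-4, 5e-7),
    (1404, 0.05, 3.56e-5, 5e-8),
    (1, 0.05, 0.05, 0),
])
def test_bonferroni_threshold(n, alpha, expected, tol):
    assert twas.bonferroni_threshold(n, alpha) == pytest.approx(expected,
                                                                abs=tol)


def test_bonferroni_threshold_invalid():
    with pytest.raises(InsufficientDataError):
        twas.bonferroni_threshold(0)


class TestSignalComparison:
    @staticmethod
    def _results(signals, feature_type="expression"):
        rows = []
        for gene, tissue_ps in signals.items():
            for tissue, p in tissue_ps.items():
                rows.append(dict(gene_id=gene, feature_id=gene, tissue=tissue,
                                 feature_type=feature_type, p=p))
        return pd.DataFrame(rows)

    def test_identical_signals_not_significant(self):
        sig = {f"g{i}": {"t1": 0.01 * (i + 1)} for i in range(6)}
        a, b = self._results(sig), self._results(sig, "splicing")
        comp = twas.compare_signal_levels(a, b)
        assert comp.p_wilcoxon >= 0.5
        assert comp.p_sign >= 0.5

    def test_uniform_dominance_sign_test(self):
        a = self._results({f"g{i}": {"t1": 1e-3} for i in range(9)})
        b = self._results({f"g{i}": {"t1": 1e-5} for i in range(9)},
                          "splicing")
        comp = twas.compare_signal_levels(a, b)
        assert comp.n_b_greater == 9
        assert comp.p_sign == pytest.approx(2.0**-9, rel=1e-9)
        assert comp.p_wilcoxon < 0.01

    def test_per_gene_rank_sum_count(self):
        # 5 of 9 genes with overwhelming splicing signal across 8 tissues;
        # the other 4 identical between the scans
        tissues = [f"t{j}" for j in range(8)]
        a = self._results({f"g{i}": {t: 0.5 for t in tissues}
                           for i in range(9)})
        strong = {f"g{i}": {t: 1e-8 for t in tissues} for i in range(5)}
        flat = {f"g{i}": {t: 0.5 for t in tissues} for i in range(5, 9)}
        b = self._results({**strong, **flat}, "splicing")
        comp = twas.compare_signal_levels(a, b)
        assert comp.n_gene_level_significant == 5
        assert comp.gene_level_threshold == pytest.approx(0.05 / 9)

    def test_empty_intersection_raises(self):
        a = self._results({"g1": {"t1": 0.1}})
        b = self._results({"g2": {"t1": 0.1}}, "splicing")
        with pytest.raises(InsufficientDataError):
            twas.compare_signal_levels(a, b)
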