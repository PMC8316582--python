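"""Allelic-imbalance scan: do heterozygotes at trait variants show
haplotype expression imbalance?

Simulates haplotype read counts where heterozygous carriers of each
gene's regulatory variant express one haplotype 2^1.5 ~ 2.8-fold higher,
then scans GWAS variants near each gene, comparing |log2 allelic fold
change| between het and hom carriers with a one-sided rank-sum test.
"""

from grexlink import simulate
from grexlink.ase import ase_scan
from grexlink.harmonize import harmonize_sumstats
from grexlink.types import SimConfig

cfg = SimConfig(n_ref_samples=400, n_gwas_samples=8000, n_variants=200,
                n_genes=8, tissues=("muscle",), weights_per_gene=3,
                ld_decay=0.5, causal_genes={"gene0003": 0.2}, seed=7)
panel = simulate.simulate_reference_panel(cfg)
weights = simulate.simulate_weight_models(cfg, panel)
sumstats, _ = simulate.simulate_gwas(cfg, weights, panel)
harmonized, _ = harmonize_sumstats(sumstats, panel)

ase_table, truth = simulate.simulate_ase(
    weights, n_individuals=150, mean_coverage=40,
    imbalance_log2_afc=1.5, seed=9)
windows = simulate.gene_windows(weights, panel)
tests, per_gene = ase_scan(ase_table, harmonized, windows,
                           gwas_p_threshold=5e-5, window_bp=1_000_000)
print(f"gene-level significance cutoff: "
      f"{per_gene.attrs['alpha_cutoff']:.2e}")
print(per_gene[["gene_id", "n_tests", "min_p", "lead_variant",
                "significant", "lead_significant"]].to_string(index=False))
# Genes are only testable where a GWAS variant with p < 5e-5 lies within
# 1 Mb and has ASE observations; under the simulated 2.8-fold imbalance
# the het group's |log aFC| dominates and those genes clear the cutoff.
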