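# Declarative pipeline configuration; every `analysis` default shown.
seed: 11
sim:
  n_ref_samples: 400
  n_gwas_samples: 8000
  n_variants: 400
  n_genes: 40
  tissues: [muscle, lung, whole_blood]
  weights_per_gene: 4
  ld_decay: 0.5
  maf_range: [0.05, 0.5]
  cross_tissue_cor: 0.8
  causal_genes:
    gene0008: 0.15
    gene0030: 0.15
ase:
  n_individuals: 150
  mean_coverage: 40
  imbalance_log2_afc: 1.0
ehr:
  n_individuals: 2000
  n_phecodes: 24
  n_labs: 12
  target_prevalence: 0.15
two_ancestry:
  n_pairs: 32
  alpha: 0.87
  sigma2: 1.0
analysis:
  family_alpha: 0.05
  condition_limit: 30     # eigenvalue retention in the multi-tissue test
  min_cases: 100          # phecode inclusion floor
  min_lab_n: 100          # lab inclusion floor
  min_coverage: 8         # ASE total-read filter
  gwas_p_threshold: 5.0e-5
  ase_window_bp: 1000000
  clump_r2: 0.1
  clump_window_bp: 250000
  n_boot: 2000
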