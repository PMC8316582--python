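"""Synthetic-data generator for the full analysis chain.

Every input the pipeline consumes can be generated here with known ground
truth: an LD-structured dosage reference panel, sparse cis weight models
with tunable cross-tissue correlation, gene-mediated GWAS summary
statistics, haplotype-level allelic read counts, EHR-style phecode and lab
matrices driven by genetically regulated expression (GReX), and paired
two-ancestry effect estimates drawn under a heteroskedastic noise model.

LD is produced by a first-order autoregressive latent process on
haplotypes which are then summed to dosages: only the first two moments of
LD matter to the statistics under test, and an AR(1) process gives a
single tunable decay parameter. All randomness is routed through one seed,
with independent sub-streams keyed by stage name so that adding draws to
one generator never perturbs another.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from grexlink.types import (
    ConfigurationError,
    ReferencePanel,
    SimConfig,
    WeightModel,
)

logger = logging.getLogger(__name__)

# allele pairs used for simulated variants; none are palindromic so that the
# harmonization stage keeps every simulated record
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator for one stage, keyed by (seed, stage name)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _ar1_haplotypes(rng: np.random.Generator, n_hap: int, freqs: np.ndarray,
                    ld_decay: float) -> np.ndarray:
    """0/1 haplotype matrix from a latent Gaussian AR(1), thresholded at
    the per-variant allele-frequency quantile."""
    m = len(freqs)
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        innov = rng.standard_normal((n_hap, m - 1))
        rho = ld_decay
        scale = np.sqrt(1.0 - rho**2)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + scale * innov[:, j - 1]
    thresholds = stats.norm.ppf(freqs)
    return (z < thresholds).astype(float)


def simulate_dosages(rng: np.random.Generator, n_samples: int,
                     freqs: np.ndarray, ld_decay: float) -> np.ndarray:
    """Dosage matrix (samples x variants) with entries in {0, 1, 2}."""
    haps = _ar1_haplotypes(rng, 2 * n_samples, freqs, ld_decay)
    return haps[0::2] + haps[1::2]


def simulate_reference_panel(config: SimConfig) -> ReferencePanel:
    """LD reference panel of hard-call dosages.

    Variants are evenly spaced on one chromosome (``variant_spacing_bp``
    apart) with allele frequencies drawn uniformly within ``maf_range``.
    The true generating frequencies are stored on the returned panel as
    ``panel.true_freqs`` so that cohorts can be drawn from the same process.
    """
    rng = substream(config.seed, "panel")
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1],
                        config.n_variants)
    dosages = simulate_dosages(rng, config.n_ref_samples, freqs,
                               config.ld_decay)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), config.n_variants)
    alleles = [_ALLELE_PAIRS[i] for i in pair_idx]
    variants = pd.DataFrame({
        "variant_id": [f"var{i + 1:05d}" for i in range(config.n_variants)],
        "chrom": "1",
        "pos": 1 + np.arange(config.n_variants) * config.variant_spacing_bp,
        "effect_allele": [a for a, _ in alleles],
        "other_allele": [b for _, b in alleles],
        "eaf": dosages.mean(axis=0) / 2.0,
    })
    panel = ReferencePanel(dosages=dosages, variants=variants)
    panel.true_freqs = freqs  # generating frequencies, for matched cohorts
    panel.ld_decay = config.ld_decay
    return panel


def simulate_weight_models(config: SimConfig,
                           panel: ReferencePanel,
                           feature_type: str = "expression") -> list[WeightModel]:
    """Sparse cis weight models, one per gene x tissue.

    Each gene is assigned a contiguous window of ``weights_per_gene``
    variants; windows are tiled evenly along the variant axis, the way
    genes' cis regions lie along a chromosome (windows overlap only when
    ``n_genes * weights_per_gene`` exceeds ``n_variants``). Per tissue,
    weights are ``sqrt(c) * shared + sqrt(1-c) * tissue-specific`` with
    standard-normal components, so the cross-tissue weight correlation
    equals ``cross_tissue_cor`` exactly in expectation (and weights are
    identical across tissues when it is 1).
    """
    rng = substream(config.seed, f"weights:{feature_type}")
    k = config.weights_per_gene
    models: list[WeightModel] = []
    max_start = config.n_variants - k
    for g in range(config.n_genes):
        gene_id = f"gene{g + 1:04d}"
        if config.n_genes == 1:
            start = 0
        else:
            start = round(g * max_start / (config.n_genes - 1))
        vids = list(panel.variants["variant_id"].iloc[start:start + k])
        eas = dict(zip(vids, panel.variants["effect_allele"].iloc[start:start + k]))
        shared = rng.standard_normal(k)
        c = config.cross_tissue_cor
        for tissue in config.tissues:
            specific = rng.standard_normal(k)
            w = np.sqrt(c) * shared + np.sqrt(1.0 - c) * specific
            if not np.any(w != 0):  # vanishingly unlikely; keep model valid
                w[0] = 1.0
            models.append(WeightModel(
                gene_id=gene_id, tissue=tissue,
                weights=dict(zip(vids, w)), effect_alleles=eas,
                feature_type=feature_type,
            ))
    return models


def gene_windows(models: Sequence[WeightModel],
                 panel: ReferencePanel) -> pd.DataFrame:
    """Genomic window (min..max model-variant position) per gene, 1-based."""
    pos = panel.variants.set_index("variant_id")["pos"]
    chrom = panel.variants.set_index("variant_id")["chrom"]
    rows = {}
    for m in models:
        ps = pos.loc[m.variant_ids]
        key = m.gene_id
        lo, hi = int(ps.min()), int(ps.max())
        if key in rows:
            rows[key] = (rows[key][0], min(rows[key][1], lo), max(rows[key][2], hi))
        else:
            rows[key] = (chrom.loc[m.variant_ids[0]], lo, hi)
    return pd.DataFrame(
        [(g, c, lo, hi) for g, (c, lo, hi) in sorted(rows.items())],
        columns=["gene_id", "chrom", "start", "end"],
    )


def _grex_matrix(dosages: np.ndarray, panel: ReferencePanel,
                 models: Sequence[WeightModel]) -> np.ndarray:
    """(samples x models) raw GReX scores for dosages in panel column order."""
    out = np.empty((dosages.shape[0], len(models)))
    for j, m in enumerate(models):
        cols = panel.column_index(m.variant_ids)
        out[:, j] = dosages[:, cols] @ m.weight_array
    return out


@dataclass
class GwasTruth:
    """Ground truth for one simulated GWAS."""
    causal_genes: dict[str, float]
    liability_noise_var: float
    n_samples: int
    cohort_dosages: np.ndarray | None = None  # kept only on request
    liability: np.ndarray | None = None


def simulate_gwas(config: SimConfig, weights: Sequence[WeightModel],
                  panel: ReferencePanel,
                  keep_cohort: bool = False) -> tuple[pd.DataFrame, GwasTruth]:
    """Per-variant marginal GWAS summary statistics on a gene-mediated trait.

    An independent cohort of ``n_gwas_samples`` is drawn from the panel's
    generating LD process. The liability is the sum over causal genes of
    effect x standardized GReX (first-tissue model) plus Gaussian noise
    scaled so the total liability variance is ~1; marginal per-variant OLS
    then yields beta, SE, Z and p. Zero-variance variants are emitted with
    missing statistics and logged.
    """
    for g, b in config.causal_genes.items():
        if not np.isfinite(b):
            raise ConfigurationError(f"non-finite effect for causal gene {g}")
    rng = substream(config.seed, "gwas")
    n = config.n_gwas_samples
    dosages = simulate_dosages(rng, n, panel.true_freqs, panel.ld_decay)

    effects = config.causal_genes
    explained = float(sum(b * b for b in effects.values()))
    noise_var = max(1.0 - explained, 1e-6)
    y = rng.normal(0.0, np.sqrt(noise_var), n)
    first_tissue = {}
    for m in weights:
        if m.gene_id in effects and m.gene_id not in first_tissue:
            first_tissue[m.gene_id] = m
    for gene_id, beta in effects.items():
        if gene_id not in first_tissue:
            raise ConfigurationError(f"causal gene {gene_id} has no weight model")
        score = _grex_matrix(dosages, panel, [first_tissue[gene_id]])[:, 0]
        sd = score.std(ddof=1)
        if sd == 0:
            raise ConfigurationError(f"gene {gene_id} GReX has zero variance")
        y = y + beta * (score - score.mean()) / sd

    yc = y - y.mean()
    syy = float(yc @ yc)
    xc = dosages - dosages.mean(axis=0)
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_hat = sxy / sxx
        resid_ss = syy - beta_hat * sxy
        se = np.sqrt(resid_ss / ((n - 2) * sxx))
        z = beta_hat / se
    bad = sxx == 0
    if bad.any():
        for vid in panel.variants.loc[bad, "variant_id"]:
            logger.warning("variant %s has zero dosage variance; "
                           "statistics set to missing", vid)
    beta_hat[bad] = np.nan
    se[bad] = np.nan
    z[bad] = np.nan
    p = 2.0 * stats.norm.sf(np.abs(z))
    sumstats = panel.variants[["variant_id", "chrom", "pos",
                               "effect_allele", "other_allele"]].copy()
    sumstats["beta"] = beta_hat
    sumstats["se"] = se
    sumstats["z"] = z
    sumstats["p"] = p
    sumstats["eaf"] = dosages.mean(axis=0) / 2.0
    truth = GwasTruth(causal_genes=dict(effects),
                      liability_noise_var=noise_var, n_samples=n,
                      cohort_dosages=dosages if keep_cohort else None,
                      liability=y if keep_cohort else None)
    return sumstats, truth


@dataclass
class AseTruth:
    imbalance_log2_afc: float
    regulatory_variant: dict[str, str]  # gene -> variant used


def simulate_ase(weights: Sequence[WeightModel], n_individuals: int,
                 mean_coverage: float, imbalance_log2_afc: float,
                 seed: int, het_fraction: float = 0.5,
                 ) -> tuple[pd.DataFrame, AseTruth]:
    """Haplotype-level allelic read counts tied to a regulatory genotype.

    For each gene the largest-|weight| variant of its first model acts as
    the regulatory variant. Heterozygous carriers express the two
    haplotypes at a ratio of ``2**imbalance_log2_afc`` (favoured haplotype
    randomized per individual); homozygous carriers are balanced. Total
    read counts are Poisson(``mean_coverage``) and haplotype A counts are
    binomial given the total.
    """
    if mean_coverage <= 0:
        raise ConfigurationError("mean_coverage must be positive")
    if imbalance_log2_afc < 0:
        raise ConfigurationError(
            "imbalance_log2_afc is a magnitude and must be >= 0")
    rng = substream(seed, "ase")
    genes: dict[str, WeightModel] = {}
    for m in weights:
        genes.setdefault(m.gene_id, m)
    p_het = 2.0 ** imbalance_log2_afc / (1.0 + 2.0 ** imbalance_log2_afc)
    rows = []
    reg_variant = {}
    for gene_id, model in sorted(genes.items()):
        w = model.weight_array
        vid = model.variant_ids[int(np.argmax(np.abs(w)))]
        reg_variant[gene_id] = vid
        is_het = rng.random(n_individuals) < het_fraction
        totals = rng.poisson(mean_coverage, n_individuals)
        flip = rng.random(n_individuals) < 0.5
        prob = np.where(is_het, np.where(flip, 1.0 - p_het, p_het), 0.5)
        hap_a = rng.binomial(totals, prob)
        for i in range(n_individuals):
            rows.append((f"indiv{i + 1:05d}", gene_id, vid,
                         "het" if is_het[i] else "hom",
                         int(hap_a[i]), int(totals[i] - hap_a[i])))
    table = pd.DataFrame(rows, columns=["individual", "gene_id", "variant_id",
                                        "genotype_class", "hapA_count",
                                        "hapB_count"])
    return table, AseTruth(imbalance_log2_afc=imbalance_log2_afc,
                           regulatory_variant=reg_variant)


@dataclass
class EhrData:
    """Simulated biobank extract: phecode matrix, long lab table, covariates."""
    phecodes: pd.DataFrame          # persons x phecodes, 0/1
    labs: pd.DataFrame              # person, lab, value, age_at_measurement
    covariates: pd.DataFrame        # person-indexed: age, sex, PC1..PC10
    grex: pd.DataFrame              # persons x genes, raw GReX (first tissue)
    phecode_categories: pd.Series   # phecode -> category
    lab_categories: pd.Series       # lab -> category
    truth: dict = field(default_factory=dict)


def simulate_ehr(config: SimConfig, panel: ReferencePanel,
                 weights: Sequence[WeightModel], *,
                 n_individuals: int = 2000,
                 n_phecodes: int = 50, n_labs: int = 20,
                 phecode_categories: Sequence[str] = ("circulatory", "infectious",
                                                      "respiratory", "neoplasms"),
                 lab_categories: Sequence[str] = ("blood", "metabolic", "immune"),
                 phecode_effects: Mapping[str, tuple[str, float]] | None = None,
                 lab_effects: Mapping[str, tuple[str, float]] | None = None,
                 target_prevalence: float = 0.05,
                 mean_measurements: float = 2.0,
                 seed: int | None = None) -> EhrData:
    """EHR-style cohort with phecode case status and lab values driven by GReX.

    Case status follows a logistic model whose intercept hits
    ``target_prevalence`` at zero GReX and whose slope is the configured
    per-phecode effect (log-odds per SD of GReX). Labs are linear in
    standardized GReX with an age trend and repeated dated measurements.
    Covariates are age, sex (0/1) and 10 synthetic principal components.
    ``phecode_effects`` / ``lab_effects`` map phenotype name to
    ``(gene_id, effect)``; unlisted phenotypes are null.
    """
    rng = substream(config.seed if seed is None else seed, "ehr")
    dosages = simulate_dosages(rng, n_individuals, panel.true_freqs,
                               panel.ld_decay)
    persons = [f"person{i + 1:06d}" for i in range(n_individuals)]

    first_tissue: dict[str, WeightModel] = {}
    for m in weights:
        first_tissue.setdefault(m.gene_id, m)
    gene_ids = sorted(first_tissue)
    grex_raw = _grex_matrix(dosages, panel, [first_tissue[g] for g in gene_ids])
    sds = grex_raw.std(axis=0, ddof=1)
    sds[sds == 0] = 1.0
    grex_std = (grex_raw - grex_raw.mean(axis=0)) / sds

    age = np.clip(rng.normal(55.0, 15.0, n_individuals), 18.0, 90.0)
    sex = (rng.random(n_individuals) < 0.57).astype(int)
    pcs = rng.standard_normal((n_individuals, 10))
    covariates = pd.DataFrame(
        {"age": age, "sex": sex,
         **{f"PC{i + 1}": pcs[:, i] for i in range(10)}},
        index=pd.Index(persons, name="person"))

    phe_names = [f"phecode_{i + 1:03d}" for i in range(n_phecodes)]
    phe_cat = pd.Series([phecode_categories[i % len(phecode_categories)]
                         for i in range(n_phecodes)], index=phe_names)
    phecode_effects = dict(phecode_effects or {})
    intercept = np.log(target_prevalence / (1.0 - target_prevalence))
    grex_col = {g: grex_std[:, j] for j, g in enumerate(gene_ids)}
    phe_mat = np.empty((n_individuals, n_phecodes), dtype=int)
    for j, name in enumerate(phe_names):
        eta = np.full(n_individuals, intercept)
        if name in phecode_effects:
            gene_id, beta = phecode_effects[name]
            eta = eta + beta * grex_col[gene_id]
        prob = 1.0 / (1.0 + np.exp(-eta))
        phe_mat[:, j] = rng.random(n_individuals) < prob
    phecodes = pd.DataFrame(phe_mat, index=covariates.index, columns=phe_names)

    lab_names = [f"lab_{i + 1:03d}" for i in range(n_labs)]
    lab_cat = pd.Series([lab_categories[i % len(lab_categories)]
                         for i in range(n_labs)], index=lab_names)
    lab_effects = dict(lab_effects or {})
    lab_rows = []
    n_meas = 1 + rng.poisson(max(mean_measurements - 1.0, 0.0),
                             (n_individuals, n_labs))
    for j, name in enumerate(lab_names):
        gene_id, beta = lab_effects.get(name, (None, 0.0))
        signal = beta * grex_col[gene_id] if gene_id is not None else 0.0
        base = signal + 0.02 * age  # mild age trend, removed by the transform
        for i in range(n_individuals):
            for _ in range(n_meas[i, j]):
                age_at = age[i] + rng.uniform(-2.0, 2.0)
                value = base if np.isscalar(base) else base[i]
                lab_rows.append((persons[i], name,
                                 float(value) + rng.normal(0.0, 1.0),
                                 float(age_at)))
    labs = pd.DataFrame(lab_rows,
                        columns=["person", "lab", "value",
                                 "age_at_measurement"])
    grex_df = pd.DataFrame(grex_raw, index=covariates.index, columns=gene_ids)
    truth = {"phecode_effects": phecode_effects, "lab_effects": lab_effects,
             "target_prevalence": target_prevalence}
    return EhrData(phecodes=phecodes, labs=labs, covariates=covariates,
                   grex=grex_df, phecode_categories=phe_cat,
                   lab_categories=lab_cat, truth=truth)


def simulate_two_ancestry_effects(n_pairs: int, alpha: float, sigma2: float,
                                  se_E_range: tuple[float, float] = (0.05, 0.2),
                                  se_A_range: tuple[float, float] = (0.1, 0.4),
                                  seed: int = 0,
                                  beta_scale: float = 0.5) -> pd.DataFrame:
    """Paired discovery/replication effect estimates under the concordance model.

    Draws ``beta_A = alpha * beta_E + eps`` with
    ``eps ~ N(0, sigma2 * se_A**2)`` — exactly the heteroskedastic error
    model the cross-ancestry regression assumes. Discovery effects are
    N(0, beta_scale**2); standard errors are uniform within their ranges.
    """
    if sigma2 < 0:
        raise ConfigurationError("sigma2 must be nonnegative")
    if min(se_E_range) <= 0 or min(se_A_range) <= 0:
        raise ConfigurationError("standard-error ranges must be positive")
    rng = substream(seed, "two_ancestry")
    if n_pairs == 0:
        return pd.DataFrame(columns=["unit_id", "beta_E", "se_E",
                                     "beta_A", "se_A"])
    beta_e = rng.normal(0.0, beta_scale, n_pairs)
    se_e = rng.uniform(*se_E_range, n_pairs)
    se_a = rng.uniform(*se_A_range, n_pairs)
    beta_a = alpha * beta_e + rng.normal(0.0, 1.0, n_pairs) * np.sqrt(sigma2) * se_a
    return pd.DataFrame({
        "unit_id": [f"pair{i + 1:04d}" for i in range(n_pairs)],
        "beta_E": beta_e, "se_E": se_e, "beta_A": beta_a, "se_A": se_a,
    })
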