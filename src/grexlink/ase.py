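"""Allelic-imbalance testing from haplotype-level expression read counts.

Per individual and gene, cis-regulatory imbalance is quantified as the
log2 allelic fold change (log aFC) between the two haplotypes' read
counts, with one pseudocount. If a trait-associated variant regulates the
gene in cis, heterozygous carriers should show larger |log aFC| than
homozygous carriers: the scan compares the two groups with a one-sided
Wilcoxon rank-sum test, gene by gene, over GWAS variants that pass a
p-value cutoff within a window of the gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from grexlink.types import FormatError

DEFAULT_MIN_COVERAGE = 8
DEFAULT_GWAS_P = 5e-5
DEFAULT_WINDOW_BP = 1_000_000


def log_afc(hapA_count, hapB_count, pseudocount: float = 1.0):
    """log2 allelic fold change: log2((a + pc) / (b + pc)). Vectorized."""
    a = np.asarray(hapA_count, dtype=float)
    b = np.asarray(hapB_count, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise FormatError("haplotype read counts must be nonnegative")
    out = np.log2((a + pseudocount) / (b + pseudocount))
    return float(out) if out.ndim == 0 else out


def coverage_filter(observations: pd.DataFrame,
                    min_total_reads: int = DEFAULT_MIN_COVERAGE) -> pd.DataFrame:
    """Keep observations with raw total coverage >= min_total_reads.

    The filter applies to raw counts; the pseudocount enters only the
    log-ratio itself.
    """
    total = observations["hapA_count"] + observations["hapB_count"]
    return observations.loc[total >= min_total_reads].reset_index(drop=True)


@dataclass
class ImbalanceResult:
    gene_id: str
    variant_id: str
    n_het: int
    n_hom: int
    statistic: float
    p: float
    median_abs_log_afc_het: float
    median_abs_log_afc_hom: float
    testable: bool = True
    method: str = ""


def imbalance_test(het_values, hom_values, gene_id: str = "",
                   variant_id: str = "") -> ImbalanceResult:
    """One-sided rank-sum test that heterozygotes show larger |log aFC|.

    Uses the exact null distribution when the smaller group has at most 10
    observations and there are no ties; otherwise the midrank normal
    approximation with tie correction.
    """
    het = np.asarray(het_values, dtype=float)
    hom = np.asarray(hom_values, dtype=float)
    if len(het) == 0 or len(hom) == 0:
        return ImbalanceResult(gene_id=gene_id, variant_id=variant_id,
                               n_het=len(het), n_hom=len(hom),
                               statistic=np.nan, p=np.nan,
                               median_abs_log_afc_het=np.nan,
                               median_abs_log_afc_hom=np.nan,
                               testable=False, method="empty group")
    combined = np.concatenate([het, hom])
    has_ties = len(np.unique(combined)) < len(combined)
    if min(len(het), len(hom)) <= 10 and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(het, hom, alternative="greater",
                                 method="exact")
    else:
        method = "normal"
        res = stats.mannwhitneyu(het, hom, alternative="greater",
                                 method="asymptotic", use_continuity=False)
    return ImbalanceResult(
        gene_id=gene_id, variant_id=variant_id,
        n_het=len(het), n_hom=len(hom),
        statistic=float(res.statistic), p=float(res.pvalue),
        median_abs_log_afc_het=float(np.median(het)),
        median_abs_log_afc_hom=float(np.median(hom)),
        method=method)


def ase_scan(observations: pd.DataFrame, sumstats: pd.DataFrame,
             gene_windows: pd.DataFrame,
             gwas_p_threshold: float = DEFAULT_GWAS_P,
             window_bp: int = DEFAULT_WINDOW_BP,
             min_total_reads: int = DEFAULT_MIN_COVERAGE,
             gene_alpha_denominator: int | None = None,
             family_alpha: float = 0.05,
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allelic-imbalance scan over trait-associated variants near genes.

    For each gene and each GWAS variant with ``p < gwas_p_threshold``
    lying within ``window_bp`` of the gene window, the coverage-filtered
    |log aFC| values of heterozygous and homozygous carriers are compared.
    Returns ``(tests, per_gene)``: one row per gene x variant test, and a
    per-gene summary carrying the minimum p, a Bonferroni significance
    flag at ``family_alpha / gene_alpha_denominator`` (denominator
    defaults to the number of genes tested), and the same restricted to
    each gene's lead variant (lowest GWAS p among qualifying variants with
    ASE observations).
    """
    obs = coverage_filter(observations, min_total_reads)
    obs = obs.assign(abs_log_afc=np.abs(
        log_afc(obs["hapA_count"], obs["hapB_count"])))
    qual = sumstats.loc[sumstats["p"] < gwas_p_threshold]

    test_rows: list[ImbalanceResult] = []
    gene_rows = []
    tested_genes = []
    for gw in gene_windows.itertuples():
        near = qual.loc[(qual["chrom"].astype(str) == str(gw.chrom))
                        & (qual["pos"] >= gw.start - window_bp)
                        & (qual["pos"] <= gw.end + window_bp)]
        gene_obs = obs.loc[obs["gene_id"] == gw.gene_id]
        variant_ps = {}
        results_here = []
        for v in near.itertuples():
            vobs = gene_obs.loc[gene_obs["variant_id"] == v.variant_id]
            if vobs.empty:
                continue
            het = vobs.loc[vobs["genotype_class"] == "het", "abs_log_afc"]
            hom = vobs.loc[vobs["genotype_class"] == "hom", "abs_log_afc"]
            res = imbalance_test(het, hom, gene_id=gw.gene_id,
                                 variant_id=v.variant_id)
            results_here.append(res)
            variant_ps[v.variant_id] = float(v.p)
        testable = [r for r in results_here if r.testable]
        test_rows.extend(results_here)
        if testable:
            tested_genes.append(gw.gene_id)
            min_p = min(r.p for r in testable)
            lead = min(variant_ps, key=lambda k: variant_ps[k])
            lead_res = next((r for r in testable if r.variant_id == lead), None)
            gene_rows.append((gw.gene_id, len(testable), min_p, lead,
                              lead_res.p if lead_res else np.nan, True))
        else:
            gene_rows.append((gw.gene_id, 0, np.nan, None, np.nan, False))

    denom = gene_alpha_denominator or max(len(tested_genes), 1)
    cutoff = family_alpha / denom
    per_gene = pd.DataFrame(gene_rows, columns=[
        "gene_id", "n_tests", "min_p", "lead_variant", "lead_p", "tested"])
    per_gene["significant"] = per_gene["min_p"] < cutoff
    per_gene["lead_significant"] = per_gene["lead_p"] < cutoff
    per_gene.attrs["alpha_cutoff"] = cutoff
    tests = pd.DataFrame([vars(r) for r in test_rows])
    return tests, per_gene
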