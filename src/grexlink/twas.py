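"""Summary-statistics association of predicted molecular features with a trait.

Given a sparse cis weight model w and GWAS Z-scores, the single-tissue
association statistic is

    Z_g = sum_l  w_l * (sigma_l / sigma_g) * Z_l

where sigma_l is the dosage SD of variant l in the reference panel and
sigma_g = sqrt(w' Sigma w) is the SD of the predicted feature under the
panel's LD (Sigma is the sample dosage covariance). This is the standard
summary-based test of association between genetically predicted
expression/splicing/protein abundance and the GWAS trait.

Multi-tissue evidence is combined by regressing conceptually on all
tissues at once: the tissue-tissue correlation of the predicted feature is
eigendecomposed, ill-conditioned components (condition number above a
limit, default 30) are dropped, and the statistic

    chi2 = sum_retained (u_i' z)^2 / lambda_i

is referred to a chi-square with one degree of freedom per retained
component. With a single tissue this reduces exactly to z^2 on 1 df.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from grexlink.types import (
    DegenerateModelError,
    InsufficientDataError,
    ReferencePanel,
    WeightModel,
)

logger = logging.getLogger(__name__)


@dataclass
class TwasResult:
    gene_id: str
    feature_id: str
    tissue: str
    feature_type: str
    z: float
    p: float
    sigma_g: float
    n_model_variants: int
    testable: bool = True
    low_confidence: bool = False
    note: str = ""


@dataclass
class MultiTissueResult:
    gene_id: str
    chi2: float
    dof: int
    p: float
    tissues_used: tuple[str, ...] = ()


def predicted_feature_sd(model: WeightModel, panel: ReferencePanel,
                         ) -> tuple[float, np.ndarray]:
    """SD of the weighted dosage score, and the per-variant dosage SDs.

    Returns ``(sigma_g, sigma_l)`` where ``sigma_g = sqrt(w' Sigma w)``
    with Sigma the n-1-denominator sample covariance of panel dosages at
    the model variants.
    """
    dos = panel.dosage_for(model.variant_ids)
    w = model.weight_array
    sigma_l = dos.std(axis=0, ddof=1)
    cov = np.cov(dos, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    var_g = float(w @ cov @ w)
    if var_g <= 0:
        raise DegenerateModelError(
            f"model {model.gene_id}/{model.tissue} has zero predicted variance")
    return float(np.sqrt(var_g)), sigma_l


def single_tissue_twas(sumstats: pd.DataFrame, model: WeightModel,
                       panel: ReferencePanel) -> TwasResult:
    """Summary-based association Z for one weight model.

    Model variants missing from the (harmonized) summary statistics are
    dropped from both the numerator and the sigma_g computation; a model
    losing more than half of its absolute weight mass is flagged
    low-confidence. A model with no overlapping variants is returned as a
    non-testable result rather than silently skipped.
    """
    ss = sumstats.set_index("variant_id")
    avail = [v for v in model.variant_ids
             if v in ss.index and np.isfinite(ss.at[v, "z"])]
    base = dict(gene_id=model.gene_id, feature_id=model.feature_id,
                tissue=model.tissue, feature_type=model.feature_type)
    if not avail:
        return TwasResult(**base, z=np.nan, p=np.nan, sigma_g=np.nan,
                          n_model_variants=0, testable=False,
                          note="no model variant with summary statistics")
    sub = WeightModel(gene_id=model.gene_id, tissue=model.tissue,
                      feature_type=model.feature_type,
                      feature_id=model.feature_id,
                      weights={v: model.weights[v] for v in avail},
                      effect_alleles={v: model.effect_alleles[v] for v in avail})
    sigma_g, sigma_l = predicted_feature_sd(sub, panel)
    z_l = ss.loc[avail, "z"].to_numpy(dtype=float)
    w = sub.weight_array
    z_g = float(np.sum(w * sigma_l * z_l) / sigma_g)
    total_mass = float(np.sum(np.abs(model.weight_array)))
    kept_mass = float(np.sum(np.abs(w)))
    low_conf = kept_mass < 0.5 * total_mass
    return TwasResult(**base, z=z_g, p=2.0 * stats.norm.sf(abs(z_g)),
                      sigma_g=sigma_g, n_model_variants=len(avail),
                      low_confidence=low_conf)


def results_table(results) -> pd.DataFrame:
    """Stack TwasResult records into a tidy frame."""
    return pd.DataFrame([vars(r) for r in results])


def tissue_correlation(models: list[WeightModel], panel: ReferencePanel,
                       ) -> pd.DataFrame:
    """Correlation of the predicted feature across tissues, from the panel.

    Per-sample predicted scores are computed for each tissue model;
    zero-variance models are excluded with a warning. The correlation
    matrix is projected onto the PSD cone (negative eigenvalues clipped)
    and renormalized to a unit diagonal.
    """
    if not models:
        raise InsufficientDataError("need at least one tissue model")
    scores, tissues = [], []
    for m in models:
        s = panel.dosage_for(m.variant_ids) @ m.weight_array
        if s.std(ddof=1) == 0:
            warnings.warn(f"model {m.gene_id}/{m.tissue} has zero variance; "
                          "excluded from tissue correlation")
            continue
        scores.append(s)
        tissues.append(m.tissue)
    if not scores:
        raise DegenerateModelError("all tissue models degenerate")
    mat = np.corrcoef(np.array(scores))
    mat = np.atleast_2d(mat)
    # PSD projection: clip negative eigenvalues, restore unit diagonal
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    mat = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(mat))
    mat = mat / np.outer(d, d)
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=tissues, columns=tissues)


def multi_tissue_combine(z_by_tissue: pd.Series | dict,
                         correlation: pd.DataFrame,
                         condition_limit: float = 30.0,
                         gene_id: str = "") -> MultiTissueResult:
    """PCA-regularized joint chi-square across tissues.

    Eigencomponents i of the tissue correlation matrix are retained when
    ``lambda_max / lambda_i <= condition_limit``; the statistic is
    ``sum (u_i' z)^2 / lambda_i`` on one degree of freedom per retained
    component. The top component is always retained.
    """
    z = pd.Series(z_by_tissue)
    tissues = list(correlation.index)
    if set(z.index) != set(tissues):
        z = z.loc[tissues]
    zv = z.to_numpy(dtype=float)
    cor = correlation.loc[tissues, tissues].to_numpy(dtype=float)
    vals, vecs = np.linalg.eigh(cor)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    lam_max = vals[0]
    keep = (vals > 0) & (lam_max / np.maximum(vals, 1e-300) <= condition_limit)
    keep[0] = True
    proj = vecs[:, keep].T @ zv
    chi2 = float(np.sum(proj**2 / vals[keep]))
    dof = int(keep.sum())
    return MultiTissueResult(gene_id=gene_id, chi2=chi2, dof=dof,
                             p=float(stats.chi2.sf(chi2, dof)),
                             tissues_used=tuple(tissues))


def bonferroni_threshold(n_tests: int, family_alpha: float = 0.05) -> float:
    """Per-test significance cutoff controlling family-wise error."""
    if n_tests < 1:
        raise InsufficientDataError("n_tests must be >= 1")
    if not (0 < family_alpha < 1):
        raise ValueError("family_alpha must lie in (0, 1)")
    return family_alpha / n_tests


@dataclass
class SignalComparison:
    """Paired comparison of association signal between two feature types."""
    per_gene: pd.DataFrame
    p_wilcoxon: float
    p_sign: float
    n_genes: int
    n_b_greater: int
    n_gene_level_significant: int
    gene_level_threshold: float


def compare_signal_levels(results_a: pd.DataFrame, results_b: pd.DataFrame,
                          shared_genes: list[str] | None = None,
                          ) -> SignalComparison:
    """Compare per-gene association strength between two scans.

    Signal per gene is the max -log10 p across tissues (and across splice
    sites / features, for scans with several features per gene). The
    overall test is a one-sided Wilcoxon signed-rank (and exact sign test)
    for scan B exceeding scan A; per gene, a one-sided rank-sum across
    shared tissues is reported against a Bonferroni cutoff of
    0.05/n_shared_genes.
    """
    if shared_genes is None:
        shared_genes = sorted(set(results_a["gene_id"])
                              & set(results_b["gene_id"]))
    if not shared_genes:
        raise InsufficientDataError("no genes shared between the two scans")

    def neglogp(df):
        return -np.log10(np.clip(df["p"].to_numpy(dtype=float), 1e-300, 1.0))

    a = results_a.assign(signal=neglogp(results_a))
    b = results_b.assign(signal=neglogp(results_b))
    thr = bonferroni_threshold(len(shared_genes))
    rows = []
    for g in shared_genes:
        sa = a.loc[a["gene_id"] == g, ["tissue", "signal"]]
        sb = b.loc[b["gene_id"] == g, ["tissue", "signal"]]
        if sa.empty or sb.empty:
            raise InsufficientDataError(f"gene {g} missing from one scan")
        shared_tissues = sorted(set(sa["tissue"]) & set(sb["tissue"]))
        va = sa.loc[sa["tissue"].isin(shared_tissues), "signal"].to_numpy()
        vb = sb.loc[sb["tissue"].isin(shared_tissues), "signal"].to_numpy()
        if len(va) and len(vb):
            p_gene = stats.mannwhitneyu(vb, va, alternative="greater",
                                        method="auto").pvalue
        else:
            p_gene = np.nan
        rows.append((g, float(sa["signal"].max()), float(sb["signal"].max()),
                     float(p_gene)))
    per_gene = pd.DataFrame(rows, columns=["gene_id", "signal_a", "signal_b",
                                           "p_rank_sum"])
    per_gene["gene_level_significant"] = per_gene["p_rank_sum"] < thr
    diff = per_gene["signal_b"] - per_gene["signal_a"]
    nonzero = diff[diff != 0]
    if len(nonzero) == 0:
        p_wil = 1.0
    else:
        p_wil = float(stats.wilcoxon(diff, alternative="greater",
                                     zero_method="wilcox").pvalue)
    n_greater = int((diff > 0).sum())
    n_nonzero = int((diff != 0).sum())
    p_sign = (float(stats.binomtest(n_greater, n_nonzero, 0.5,
                                    alternative="greater").pvalue)
              if n_nonzero else 1.0)
    return SignalComparison(
        per_gene=per_gene, p_wilcoxon=p_wil, p_sign=p_sign,
        n_genes=len(shared_genes), n_b_greater=n_greater,
        n_gene_level_significant=int(per_gene["gene_level_significant"].sum()),
        gene_level_threshold=thr)
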