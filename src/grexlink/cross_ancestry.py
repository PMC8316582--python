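"""Cross-ancestry concordance of effect estimates, heterogeneity, clumping.

The concordance model regresses replication-ancestry effect estimates on
discovery-ancestry estimates with no intercept,

    beta_A,i = alpha * beta_E,i + eps_i,   eps_i ~ N(0, sigma^2 * SE_A,i^2),

fit by weighted least squares with weights 1/SE_A^2. alpha near 1 means
effects transfer across ancestries at full magnitude; sigma^2 is an
overdispersion scale relative to the replication sampling noise. Per-pair
heterogeneity uses the usual two-estimate difference z. LD clumping picks
approximately independent index variants greedily by ascending p subject
to pairwise r^2 and distance constraints measured in a dosage panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from grexlink.types import InsufficientDataError, ReferencePanel

logger = logging.getLogger(__name__)


@dataclass
class CrossAncestryFit:
    alpha: float
    alpha_se: float
    ci95: tuple[float, float]
    sigma2: float
    n_pairs: int
    p_slope: float


def fit_cross_ancestry(pairs: pd.DataFrame) -> CrossAncestryFit:
    """No-intercept WLS of beta_A on beta_E with weights 1/se_A^2.

    Closed form: ``alpha = sum(bE*bA/seA^2) / sum(bE^2/seA^2)``;
    ``sigma2 = sum(((bA - alpha*bE)/seA)^2) / (n-1)``;
    ``alpha_se = sqrt(sigma2 / sum(bE^2/seA^2))``; normal 95% CI and
    two-sided p against alpha = 0.
    """
    n = len(pairs)
    if n < 2:
        raise InsufficientDataError(f"need >= 2 pairs, got {n}")
    be = pairs["beta_E"].to_numpy(dtype=float)
    ba = pairs["beta_A"].to_numpy(dtype=float)
    sa = pairs["se_A"].to_numpy(dtype=float)
    if np.all(be == 0):
        raise InsufficientDataError("all discovery effects are zero")
    w = 1.0 / sa**2
    denom = float(np.sum(w * be**2))
    alpha = float(np.sum(w * be * ba)) / denom
    sigma2 = float(np.sum(((ba - alpha * be) / sa) ** 2)) / (n - 1)
    alpha_se = float(np.sqrt(sigma2 / denom))
    if alpha_se > 0:
        p = float(2.0 * stats.norm.sf(abs(alpha / alpha_se)))
    else:
        p = 0.0 if alpha != 0 else 1.0
    ci = (alpha - 1.96 * alpha_se, alpha + 1.96 * alpha_se)
    return CrossAncestryFit(alpha=alpha, alpha_se=alpha_se, ci95=ci,
                            sigma2=sigma2, n_pairs=n, p_slope=p)


def pairwise_heterogeneity(pairs: pd.DataFrame, n_tests: int | None = None,
                           family_alpha: float = 0.05) -> pd.DataFrame:
    """Difference z-test for each pair of ancestry-specific estimates.

    ``z = (beta_E - beta_A) / sqrt(se_E^2 + se_A^2)``, two-sided normal p,
    Bonferroni flag at ``family_alpha / n_tests``. Pairs with missing SEs
    are skipped with a warning.
    """
    ok = pairs[["se_E", "se_A"]].notna().all(axis=1) & \
        (pairs["se_E"] > 0) & (pairs["se_A"] > 0)
    if (~ok).any():
        logger.warning("%d pairs skipped for missing/invalid SEs",
                       int((~ok).sum()))
    sub = pairs.loc[ok].copy()
    z = (sub["beta_E"] - sub["beta_A"]) / np.sqrt(sub["se_E"]**2
                                                  + sub["se_A"]**2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    m = n_tests or len(sub)
    cutoff = family_alpha / max(m, 1)
    out = sub.assign(z_het=z, p_het=p, het_significant=p < cutoff)
    out.attrs["bonferroni_threshold"] = cutoff
    return out


def ld_clump(pvalues: pd.DataFrame, panel: ReferencePanel,
             r2_threshold: float = 0.1,
             window_bp: int = 250_000) -> list[str]:
    """Greedy selection of approximately independent index variants.

    ``pvalues`` has columns ``variant_id`` and ``p`` (``chrom``/``pos``
    taken from the panel). Variants are visited in ascending (p, chrom,
    pos) order; a variant is accepted iff its squared dosage correlation
    with every previously accepted variant within ``window_bp`` is at most
    ``r2_threshold``. Variants absent from the panel are skipped with a
    warning. The result does not depend on the input row order.
    """
    meta = panel.variants.set_index("variant_id")
    rows = []
    for rec in pvalues.itertuples():
        if rec.variant_id not in panel:
            logger.warning("variant %s absent from panel; skipped",
                           rec.variant_id)
            continue
        m = meta.loc[rec.variant_id]
        rows.append((float(rec.p), str(m["chrom"]), int(m["pos"]),
                     rec.variant_id))
    rows.sort()
    accepted: list[tuple[str, int, str, np.ndarray]] = []
    index_variants: list[str] = []
    for p, chrom, pos, vid in rows:
        x = panel.dosage_for([vid])[:, 0]
        keep = True
        for achrom, apos, avid, ax in accepted:
            if achrom != chrom or abs(apos - pos) > window_bp:
                continue
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(x, ax)[0, 1]
            if np.isfinite(r) and r**2 > r2_threshold:
                keep = False
                break
        if keep:
            accepted.append((chrom, pos, vid, x))
            index_variants.append(vid)
    return index_variants


def fdr_flag(pvalues, q: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg step-up FDR flags and adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    flags, adjusted, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return pd.DataFrame({"p": p, "p_adjusted": adjusted,
                         "significant": flags})
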