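"""Category enrichment statistics over phenome/lab scan results.

Two complementary procedures:

1. **Hypergeometric overrepresentation** of Bonferroni-significant hits
   within a clinical category, with fold enrichment
   ``(k / n_sig_total) / (n_category / n_total)``.

2. **Bootstrap mean-chi-square signal enrichment**, which uses all tested
   items regardless of significance: each item's chi-square is its squared
   association z-score, the category mean is compared with 1 (the null
   expectation), and the difference is scaled by a bootstrapped standard
   error of the category mean (resampling items within the category, with
   replacement, 2000 times by default). The resulting z is two-sided
   normal, capturing both enrichment and depletion of signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def hypergeom_enrichment(items: pd.DataFrame) -> pd.DataFrame:
    """Per-category fold enrichment and upper-tail hypergeometric p.

    ``items`` has one row per tested phenotype/lab with columns
    ``category`` and ``significant`` (bool). The p-value is
    ``P(X >= k)`` for drawing ``n_significant_total`` items from a
    population of ``n_total`` of which ``n_category`` belong to the
    category. With no significant items overall the fold is undefined and
    the category is reported not-evaluable.
    """
    n_total = len(items)
    n_sig_total = int(items["significant"].sum())
    rows = []
    for cat, grp in items.groupby("category", sort=True):
        n_cat = len(grp)
        k = int(grp["significant"].sum())
        if n_sig_total == 0:
            fold, p, evaluable = np.nan, np.nan, False
        else:
            fold = (k / n_sig_total) / (n_cat / n_total)
            p = float(stats.hypergeom.sf(k - 1, n_total, n_cat, n_sig_total))
            evaluable = True
        rows.append({"category": cat, "n_category": n_cat,
                     "n_total": n_total, "k_significant_in_category": k,
                     "n_significant_total": n_sig_total, "fold": fold,
                     "p_hypergeometric": p, "evaluable": evaluable})
    return pd.DataFrame(rows)


def chi2_bootstrap_enrichment(items: pd.DataFrame, n_boot: int = 2000,
                              seed: int = 0,
                              n_categories: int | None = None,
                              family_alpha: float = 0.05) -> pd.DataFrame:
    """Bootstrap mean-chi-square enrichment/depletion per category.

    ``items`` has columns ``category`` and ``z`` (per-item association
    z-score). For each category with at least 2 items:
    ``z_enrich = (mean(z^2) - 1) / boot_se`` where ``boot_se`` is the SD
    of the category's mean chi-square over ``n_boot`` within-category
    resamples. The mean chi-square is deterministic; only the SE is
    stochastic. A Bonferroni flag is reported at
    ``family_alpha / n_categories`` (default: categories present).
    """
    rng = np.random.default_rng(seed)
    cats = sorted(items["category"].unique())
    k_cats = n_categories or len(cats)
    cutoff = family_alpha / k_cats
    rows = []
    for cat in cats:
        chi2 = items.loc[items["category"] == cat, "z"].to_numpy(dtype=float) ** 2
        n = len(chi2)
        mean_chi2 = float(chi2.mean()) if n else np.nan
        if n < 2:
            rows.append({"category": cat, "n_category": n,
                         "mean_chi2": mean_chi2, "boot_se": np.nan,
                         "z_enrich": np.nan, "p_enrich": np.nan,
                         "significant": False, "evaluable": False})
            continue
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_means = chi2[idx].mean(axis=1)
        boot_se = float(boot_means.std(ddof=1))
        if boot_se == 0:
            # constant chi2 in the category: a zero numerator is an exact
            # null (z = 0); otherwise the statistic is not evaluable
            if mean_chi2 == 1.0:
                rows.append({"category": cat, "n_category": n,
                             "mean_chi2": mean_chi2, "boot_se": 0.0,
                             "z_enrich": 0.0, "p_enrich": 1.0,
                             "significant": False, "evaluable": True})
            else:
                rows.append({"category": cat, "n_category": n,
                             "mean_chi2": mean_chi2, "boot_se": 0.0,
                             "z_enrich": np.nan, "p_enrich": np.nan,
                             "significant": False, "evaluable": False})
            continue
        z_enrich = (mean_chi2 - 1.0) / boot_se
        p_enrich = float(2.0 * stats.norm.sf(abs(z_enrich)))
        rows.append({"category": cat, "n_category": n,
                     "mean_chi2": mean_chi2, "boot_se": boot_se,
                     "z_enrich": float(z_enrich), "p_enrich": p_enrich,
                     "significant": p_enrich < cutoff, "evaluable": True})
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = cutoff
    out.attrs["n_categories"] = k_cats
    return out
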