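"""Genetically regulated expression (GReX) and EHR-style phenome/lab scans.

GReX for an individual is the weight model applied to their dosages:
``sum_l dosage_l * w_l``. The phenome scan fits a logistic regression of
each dichotomous phenotype (phecode) on standardized GReX plus age, sex
and ten genetic principal components, restricted to phenotypes with
enough cases. The lab scan first cleans each quantitative lab: a
per-person median over repeated measurements, a residual on a natural
cubic spline of age with four knots, then a rank-based inverse normal
transform; it then fits ordinary least squares on the same covariates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix
from scipy import stats

from grexlink.types import InsufficientDataError, ReferencePanel, WeightModel

logger = logging.getLogger(__name__)

DEFAULT_MIN_CASES = 100
DEFAULT_MIN_N = 100
COVARIATE_COLUMNS = ["age", "sex"] + [f"PC{i}" for i in range(1, 11)]


def compute_grex(cohort: ReferencePanel, model: WeightModel) -> pd.Series:
    """Per-individual predicted feature score over model variants in the cohort.

    Dosages must already be coded on the model's effect alleles
    (post-harmonization). Variants absent from the cohort are dropped;
    zero overlap is an error.
    """
    avail = [v for v in model.variant_ids if v in cohort]
    if not avail:
        raise InsufficientDataError(
            f"no model variant of {model.gene_id}/{model.tissue} in cohort")
    w = np.array([model.weights[v] for v in avail])
    scores = cohort.dosage_for(avail) @ w
    return pd.Series(scores, name=f"{model.gene_id}:{model.tissue}")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise InsufficientDataError("GReX has zero variance in this cohort")
    return (x - x.mean()) / sd


def _design(grex: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    cov = covariates[COVARIATE_COLUMNS].to_numpy(dtype=float)
    cov = cov[:, cov.std(axis=0) > 0]  # constant covariates carry no signal
    return np.column_stack([np.ones(len(grex)), _standardize(grex), cov])


def run_phewas(grex: pd.Series, phecodes: pd.DataFrame,
               covariates: pd.DataFrame, min_cases: int = DEFAULT_MIN_CASES,
               categories: pd.Series | None = None,
               family_alpha: float = 0.05) -> pd.DataFrame:
    """Logistic scan of one GReX against every phecode with enough cases.

    Effects are log-odds per SD of GReX, adjusted for age, sex and ten
    PCs. Rows that fail to converge are kept but flagged ``reliable=False``
    (they still count toward the multiplicity denominator, having been
    fit); the Bonferroni threshold ``family_alpha / n_tested`` is recorded
    in ``result.attrs["bonferroni_threshold"]``.
    """
    grex_v = grex.to_numpy(dtype=float)
    X = _design(grex_v, covariates)
    rows = []
    for phe in phecodes.columns:
        y = phecodes[phe].to_numpy(dtype=float)
        n_cases = int(y.sum())
        if n_cases < min_cases:
            continue
        effect = se = p = np.nan
        reliable = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", True):
                reliable = False
            effect, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
        except Exception as exc:  # separation, singular Hessian, ...
            logger.warning("phecode %s: logistic fit failed (%s)", phe, exc)
            reliable = False
        rows.append({
            "phenotype_or_lab": phe,
            "category": (categories.get(phe, "") if categories is not None
                         else ""),
            "effect": float(effect), "se": float(se), "p": float(p),
            "n_cases": n_cases, "n_controls": int(len(y) - y.sum()),
            "reliable": reliable,
        })
    out = pd.DataFrame(rows)
    n_tested = len(out)
    out.attrs["n_tested"] = n_tested
    out.attrs["bonferroni_threshold"] = (family_alpha / n_tested
                                         if n_tested else np.nan)
    if n_tested:
        out["significant"] = out["p"] < out.attrs["bonferroni_threshold"]
    return out


def _natural_spline_basis(age: np.ndarray, n_knots: int = 4) -> np.ndarray:
    """Natural cubic spline design (with intercept), knots at age quantiles."""
    qs = np.linspace(0, 1, n_knots + 2)[1:-1]  # 0.2, 0.4, 0.6, 0.8 for 4 knots
    knots = np.quantile(age, qs)
    if len(np.unique(knots)) < len(knots) or np.ptp(age) == 0:
        # degenerate age distribution: fall back to intercept-only design
        return np.ones((len(age), 1))
    return np.asarray(dmatrix("cr(x, knots=knots)",
                              {"x": age, "knots": knots}))


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform Phi^-1((rank - 0.5)/n), midranked ties."""
    x = np.asarray(values, dtype=float)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def qualitylab_transform(lab_records: pd.DataFrame,
                         n_knots: int = 4) -> pd.DataFrame:
    """Median -> age-spline residual -> inverse-normal pipeline for one lab.

    ``lab_records`` has columns ``person``, ``value``,
    ``age_at_measurement``. Steps: (1) per-person median over repeated
    measurements, with age taken at the median-defining measurement (mean
    of the two central ages for even counts); (2) OLS residual of the
    medians on a natural cubic spline basis of age with ``n_knots`` knots
    at age quantiles; (3) rank-based inverse normal transform
    Phi^-1((rank - 0.5)/n) with midranks for ties. Returns a frame indexed
    by person with columns ``value`` (transformed) and ``age``.
    """
    rec = lab_records.sort_values(["person", "value"], kind="mergesort")
    pos = rec.groupby("person").cumcount()
    size = rec.groupby("person")["value"].transform("size")
    central = rec.loc[(pos == (size - 1) // 2) | (pos == size // 2)]
    med = (central.groupby("person")
           .agg(median=("value", "mean"), age=("age_at_measurement", "mean")))
    basis = _natural_spline_basis(med["age"].to_numpy(), n_knots)
    if len(med) <= basis.shape[1]:
        raise InsufficientDataError(
            f"only {len(med)} persons for a {basis.shape[1]}-df age spline")
    coef, *_ = np.linalg.lstsq(basis, med["median"].to_numpy(), rcond=None)
    resid = med["median"].to_numpy() - basis @ coef
    transformed = inverse_normal_transform(resid)
    return pd.DataFrame({"value": transformed, "age": med["age"]},
                        index=med.index)


def run_labwas(grex: pd.Series, labs: pd.DataFrame, covariates: pd.DataFrame,
               min_n: int = DEFAULT_MIN_N,
               categories: pd.Series | None = None,
               family_alpha: float = 0.05) -> pd.DataFrame:
    """Linear scan of one GReX against every transformed lab with enough people.

    ``grex`` and ``covariates`` are person-indexed; ``labs`` is the long
    measurement table. Labs measured in fewer than ``min_n`` persons (or
    too few for the age spline) are skipped with a warning. Effects are
    per SD of GReX on the inverse-normal scale.
    """
    rows = []
    for lab, grp in labs.groupby("lab", sort=True):
        persons = grp["person"].unique()
        if len(persons) < min_n:
            continue
        try:
            transformed = qualitylab_transform(grp)
        except InsufficientDataError as exc:
            logger.warning("lab %s skipped: %s", lab, exc)
            continue
        idx = transformed.index
        X = _design(grex.loc[idx].to_numpy(dtype=float), covariates.loc[idx])
        y = transformed["value"].to_numpy()
        flagged = np.linalg.matrix_rank(X) < X.shape[1]
        fit = sm.OLS(y, X).fit()
        rows.append({
            "phenotype_or_lab": lab,
            "category": (categories.get(lab, "") if categories is not None
                         else ""),
            "effect": float(fit.params[1]), "se": float(fit.bse[1]),
            "p": float(fit.pvalues[1]), "n_measured": len(idx),
            "reliable": not flagged,
        })
    out = pd.DataFrame(rows)
    n_tested = len(out)
    out.attrs["n_tested"] = n_tested
    out.attrs["bonferroni_threshold"] = (family_alpha / n_tested
                                         if n_tested else np.nan)
    if n_tested:
        out["significant"] = out["p"] < out.attrs["bonferroni_threshold"]
    return out
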