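"""Core containers shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class GrexlinkError(Exception):
    """Base class for grexlink errors."""


class ConfigurationError(GrexlinkError, ValueError):
    """Invalid simulation or analysis configuration."""


class FormatError(GrexlinkError, ValueError):
    """Malformed input record (bad allele code, negative count, ...)."""


class DegenerateModelError(GrexlinkError, ValueError):
    """Weight model whose predicted feature has zero variance in the panel."""


class InsufficientDataError(GrexlinkError, ValueError):
    """Not enough observations to carry out the requested fit."""


class AmbiguousVariantError(GrexlinkError, ValueError):
    """Duplicate variant records with conflicting allele annotations."""


VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class ReferencePanel:
    """Genotype dosage panel used for LD, variant SDs and GReX.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` array of alternate-allele dosages in
        ``{0, 1, 2}`` (floats allowed for imputed data).
    variants
        One row per variant with columns ``variant_id``, ``chrom``, ``pos``
        (1-based), ``effect_allele`` (the dosage-counted allele),
        ``other_allele`` and ``eaf`` (observed effect-allele frequency).
    """

    dosages: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ConfigurationError("dosages must be a 2-D samples x variants array")
        if self.dosages.shape[1] != len(self.variants):
            raise ConfigurationError(
                f"dosage columns ({self.dosages.shape[1]}) do not match "
                f"variant table rows ({len(self.variants)})"
            )
        self.variants = self.variants.reset_index(drop=True)
        self._index = {v: i for i, v in enumerate(self.variants["variant_id"])}

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> pd.Series:
        return self.variants["variant_id"]

    def column_index(self, variant_ids) -> np.ndarray:
        """Map variant ids to dosage column indices; missing ids raise KeyError."""
        try:
            return np.array([self._index[v] for v in variant_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise KeyError(f"variant {exc.args[0]!r} not present in panel") from exc

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def dosage_for(self, variant_ids) -> np.ndarray:
        """Dosage submatrix (samples x len(variant_ids)) in the given order."""
        return self.dosages[:, self.column_index(variant_ids)]

    def dosage_sd(self, variant_ids=None, ddof: int = 1) -> np.ndarray:
        """Per-variant dosage standard deviations (denominator n - ddof)."""
        mat = self.dosages if variant_ids is None else self.dosage_for(variant_ids)
        return mat.std(axis=0, ddof=ddof)


@dataclass
class WeightModel:
    """Sparse cis-variant weight model for one (gene, tissue, feature).

    ``weights`` maps variant id to the per-allele effect weight w_l; the
    dosage of ``effect_alleles[variant_id]`` is what the weight multiplies.
    ``feature_id`` equals ``gene_id`` for total-expression models and names
    the splice site or protein for splicing/protein models.
    """

    gene_id: str
    tissue: str
    weights: dict[str, float]
    effect_alleles: dict[str, str]
    feature_type: str = "expression"
    feature_id: str = field(default="")

    def __post_init__(self) -> None:
        if self.feature_type not in ("expression", "splicing", "protein"):
            raise ConfigurationError(f"unknown feature_type {self.feature_type!r}")
        if not self.feature_id:
            self.feature_id = self.gene_id
        if not self.weights or not any(w != 0 for w in self.weights.values()):
            raise ConfigurationError(
                f"model {self.gene_id}/{self.tissue} has no nonzero weight"
            )

    @property
    def variant_ids(self) -> list[str]:
        return list(self.weights)

    @property
    def weight_array(self) -> np.ndarray:
        return np.array(list(self.weights.values()), dtype=float)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class SimConfig:
    """Configuration for the synthetic-data generator.

    The defaults define a small but realistic study: a few hundred LD-
    structured variants, sparse cis weight models correlated across tissues,
    and a gene-mediated trait. ``causal_genes`` maps gene id to a
    liability-scale effect per standard deviation of that gene's GReX.
    """

    n_ref_samples: int = 500
    n_gwas_samples: int = 5000
    n_variants: int = 200
    n_genes: int = 20
    tissues: tuple[str, ...] = ("tissue_A", "tissue_B", "tissue_C")
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_decay: float = 0.7
    weights_per_gene: int = 5
    cross_tissue_cor: float = 0.8
    causal_genes: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    variant_spacing_bp: int = 10_000

    def __post_init__(self) -> None:
        if self.n_ref_samples < 2 or self.n_variants < 1:
            raise ConfigurationError("need n_ref_samples >= 2 and n_variants >= 1")
        if self.n_genes < 1 or self.weights_per_gene < 1:
            raise ConfigurationError("need at least one gene and one weight per gene")
        if self.weights_per_gene > self.n_variants:
            raise ConfigurationError("weights_per_gene exceeds n_variants")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0 <= self.ld_decay <= 1):
            raise ConfigurationError("ld_decay must lie in [0, 1]")
        if not (0 <= self.cross_tissue_cor <= 1):
            raise ConfigurationError("cross_tissue_cor must lie in [0, 1]")
        if not self.tissues:
            raise ConfigurationError("at least one tissue label required")
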