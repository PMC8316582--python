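"""Quality control and allele harmonization of GWAS summary statistics.

Summary statistics are matched to a genotype reference panel by genomic
position: palindromic (A/T, C/G) variants are removed outright, records
stored on the opposite strand are base-complemented, records with
effect/other alleles swapped relative to the panel have their effect sign
and frequency reflected, and records that cannot be reconciled are
dropped. The output is coded on the panel's effect alleles, so downstream
association statistics are invariant to how the input happened to be
stored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from grexlink.types import (
    COMPLEMENT,
    VALID_BASES,
    AmbiguousVariantError,
    FormatError,
    ReferencePanel,
)

SUMSTAT_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele",
                   "other_allele", "beta", "se", "z", "p", "eaf"]


@dataclass
class HarmonizationReport:
    """Bookkeeping for one harmonization run."""
    n_input: int = 0
    n_palindromic_removed: int = 0
    n_sign_flipped: int = 0
    n_strand_flipped: int = 0
    n_unmatched_removed: int = 0
    n_output: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def _check_base(b) -> str:
    b = str(b).upper()
    if b not in VALID_BASES:
        raise FormatError(f"allele {b!r} is not one of A/C/G/T")
    return b


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    a, b = _check_base(effect_allele), _check_base(other_allele)
    return {a, b} in ({"A", "T"}, {"C", "G"})


def harmonize_sumstats(sumstats: pd.DataFrame, panel: ReferencePanel,
                       ) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Harmonize summary statistics to the panel's allele coding.

    Variant identity is keyed by (chrom, pos); the variant_id column is
    advisory only. Raises :class:`AmbiguousVariantError` when duplicate
    positions carry conflicting allele sets.
    """
    report = HarmonizationReport(n_input=len(sumstats))
    offenders = []
    seen: dict[tuple, frozenset] = {}
    for _, rec in sumstats.iterrows():
        key = (str(rec["chrom"]), int(rec["pos"]))
        alleles = frozenset((_check_base(rec["effect_allele"]),
                             _check_base(rec["other_allele"])))
        if key in seen and seen[key] != alleles:
            offenders.append(rec["variant_id"])
        seen[key] = seen.get(key, alleles)
    if offenders:
        raise AmbiguousVariantError(
            "duplicate positions with conflicting alleles: "
            + ", ".join(map(str, offenders)))

    panel_by_pos = {
        (str(r.chrom), int(r.pos)): (r.effect_allele, r.other_allele, r.variant_id)
        for r in panel.variants.itertuples()
    }

    rows = []
    for _, rec in sumstats.iterrows():
        ea = _check_base(rec["effect_allele"])
        oa = _check_base(rec["other_allele"])
        if is_palindromic(ea, oa):
            report.n_palindromic_removed += 1
            continue
        key = (str(rec["chrom"]), int(rec["pos"]))
        match = panel_by_pos.get(key)
        if match is None:
            report.n_unmatched_removed += 1
            continue
        pea, poa, pid = match
        strand_flipped = False
        if (ea, oa) not in ((pea, poa), (poa, pea)):
            ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
            strand_flipped = True
        out = rec.copy()
        if (ea, oa) == (pea, poa):
            pass
        elif (ea, oa) == (poa, pea):
            out["beta"] = -rec["beta"]
            out["z"] = -rec["z"]
            if pd.notna(rec.get("eaf", np.nan)):
                out["eaf"] = 1.0 - rec["eaf"]
            report.n_sign_flipped += 1
        else:
            report.n_unmatched_removed += 1
            continue
        if strand_flipped:
            report.n_strand_flipped += 1
        out["effect_allele"] = pea
        out["other_allele"] = poa
        out["variant_id"] = pid
        rows.append(out)

    harmonized = (pd.DataFrame(rows).reset_index(drop=True)
                  if rows else pd.DataFrame(columns=sumstats.columns))
    report.n_output = len(harmonized)
    assert report.n_output == (report.n_input - report.n_palindromic_removed
                               - report.n_unmatched_removed)
    return harmonized, report
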