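"""Plain-text readers/writers for the pipeline's intermediate formats.

All tables are tab- or comma-separated text so every intermediate of a
run can be inspected, versioned and re-loaded. Weight models round-trip
through a long TSV (one row per gene x tissue x variant), the reference
panel through a dosage TSV plus variant metadata columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from grexlink.types import ReferencePanel, WeightModel

SUMSTAT_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele",
                   "other_allele", "beta", "se", "z", "p", "eaf"]
WEIGHT_COLUMNS = ["gene", "tissue", "feature_type", "feature_id",
                  "variant_id", "effect_allele", "weight"]


def write_sumstats(sumstats: pd.DataFrame, path) -> None:
    sumstats[SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SUMSTAT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sumstats file missing columns: {sorted(missing)}")
    return df


def write_weights(models: Sequence[WeightModel], path) -> None:
    rows = []
    for m in models:
        for vid, w in m.weights.items():
            rows.append((m.gene_id, m.tissue, m.feature_type, m.feature_id,
                         vid, m.effect_alleles[vid], w))
    pd.DataFrame(rows, columns=WEIGHT_COLUMNS).to_csv(path, sep="\t",
                                                      index=False)


def read_weights(path) -> list[WeightModel]:
    df = pd.read_csv(path, sep="\t")
    models = []
    keys = ["gene", "tissue", "feature_type", "feature_id"]
    for (gene, tissue, ftype, fid), grp in df.groupby(keys, sort=True):
        models.append(WeightModel(
            gene_id=gene, tissue=tissue, feature_type=ftype, feature_id=fid,
            weights=dict(zip(grp["variant_id"], grp["weight"])),
            effect_alleles=dict(zip(grp["variant_id"], grp["effect_allele"]))))
    return models


def write_panel(panel: ReferencePanel, path) -> None:
    """Dosage TSV: variant metadata columns then one column per sample."""
    dosage_cols = pd.DataFrame(
        panel.dosages.T,
        columns=[f"S{i + 1}" for i in range(panel.n_samples)])
    df = pd.concat([panel.variants.reset_index(drop=True), dosage_cols],
                   axis=1)
    df.to_csv(path, sep="\t", index=False)


def read_panel(path) -> ReferencePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["variant_id", "chrom", "pos", "effect_allele",
                 "other_allele", "eaf"]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    dosages = df[sample_cols].to_numpy(dtype=float).T
    return ReferencePanel(dosages=dosages, variants=df[meta_cols])


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default,
                                     allow_nan=True))


def read_json(path):
    return json.loads(Path(path).read_text())
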