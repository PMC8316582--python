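import numpy as np
import pandas as pd
import pytest

from grexlink import simulate
from grexlink.types import ReferencePanel, SimConfig, WeightModel


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_ref_samples=300, n_gwas_samples=2000, n_variants=100,
                     n_genes=10, tissues=("muscle", "lung", "blood"),
                     weights_per_gene=4, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate.simulate_reference_panel(small_config)


@pytest.fixture(scope="session")
def small_weights(small_config, small_panel):
    return simulate.simulate_weight_models(small_config, small_panel)


def make_panel(dosages, chrom="1", pos=None, effect=None, other=None):
    """Hand-built panel from an explicit dosage matrix."""
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    variants = pd.DataFrame({
        "variant_id": [f"v{i + 1}" for i in range(m)],
        "chrom": chrom,
        "pos": pos if pos is not None else 1 + np.arange(m) * 1000,
        "effect_allele": effect if effect is not None else ["A"] * m,
        "other_allele": other if other is not None else ["G"] * m,
        "eaf": dosages.mean(axis=0) / 2,
    })
    return ReferencePanel(dosages=dosages, variants=variants)


def make_model(weights, gene_id="geneX", tissue="muscle",
               feature_type="expression", effect_allele="A"):
    """WeightModel over variants v1..vk of a hand-built panel."""
    w = {f"v{i + 1}": wi for i, wi in enumerate(weights)}
    ea = {v: effect_allele for v in w}
    return WeightModel(gene_id=gene_id, tissue=tissue, weights=w,
                       effect_alleles=ea, feature_type=feature_type)
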