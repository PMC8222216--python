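import numpy as np
import pandas as pd
import pytest

from grscan import (
    Cohort,
    ExpressionMatrix,
    GenotypeMatrix,
    VariantWeightTable,
)


def make_genotypes(dosage, sample_ids=None, variant_ids=None, mafs=None):
    """Hand-built GenotypeMatrix from a dosage array (samples x variants)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    sample_ids = sample_ids or [f"S{j + 1:03d}" for j in range(n)]
    variant_ids = variant_ids or [f"v{i + 1}" for i in range(m)]
    if mafs is None:
        freq = dosage.mean(axis=0) / 2.0
        mafs = np.minimum(freq, 1 - freq)
    meta = pd.DataFrame(
        {
            "chrom": "1",
            "pos": [100 * (i + 1) for i in range(m)],
            "risk_allele": "A",
            "other_allele": "G",
            "maf": mafs,
        },
        index=pd.Index(variant_ids, name="variant_id"),
    )
    return GenotypeMatrix(
        sample_ids=np.array(sample_ids, dtype=object),
        variant_ids=np.array(variant_ids, dtype=object),
        dosage=dosage,
        variant_meta=meta,
    )


def make_weights(variant_ids, odds_ratios, risk_alleles=None):
    odds_ratios = np.asarray(odds_ratios, dtype=float)
    table = pd.DataFrame(
        {
            "risk_allele": risk_alleles or ["A"] * len(variant_ids),
            "other_allele": "G",
            "odds_ratio": odds_ratios,
            "weight": np.log(odds_ratios),
            "locus_label": "",
            "categories": [frozenset()] * len(variant_ids),
        },
        index=pd.Index(variant_ids, name="variant_id"),
    )
    return VariantWeightTable(table)


def make_cohort(dosage, expression, covariates=None, **kwargs):
    gm = make_genotypes(dosage, **kwargs)
    expression = np.asarray(expression, dtype=float)
    expr = ExpressionMatrix(
        gene_ids=[f"g{k + 1}" for k in range(expression.shape[0])],
        sample_ids=gm.sample_ids.copy(),
        values=expression,
    )
    if covariates is None:
        covariates = pd.DataFrame(index=pd.Index(gm.sample_ids, name="sample_id"))
    else:
        covariates = covariates.set_axis(pd.Index(gm.sample_ids, name="sample_id"))
    return Cohort(genotypes=gm, expression=expr, covariates=covariates)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_cohort(rng):
    """12 samples x 3 variants x 4 genes, no covariates."""
    dosage = rng.binomial(2, 0.4, size=(12, 3))
    expression = rng.normal(size=(4, 12))
    return make_cohort(dosage, expression)
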