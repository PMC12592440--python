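import numpy as np
import pandas as pd
import pytest

from coabund.datatables import AbundanceTable, FeatureTable, TaxonomyMap
from coabund.manocca import (
    covariance_test,
    fit_product_pca,
    inverse_normal_transform,
    pairwise_products,
    standardize_columns,
    transform_products,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_abundance():
    data = pd.DataFrame(
        [[0.1, 0.9], [0.5, 0.5], [0.0, 1.0]],
        index=["s1", "s2", "s3"],
        columns=["tA", "tB"],
    )
    return AbundanceTable(data, rank="genus")


@pytest.fixture
def small_taxonomy():
    lin = pd.DataFrame(
        {"species": ["s1", "s2", "s3"], "genus": ["g1", "g1", "g2"],
         "family": ["f1", "f1", "f2"]}
    ).set_index(pd.Index(["s1", "s2", "s3"], name="taxon_id"))
    return TaxonomyMap(lin)


@pytest.fixture
def feature_table():
    n = 40
    r = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "age": r.uniform(20, 60, n),
            "sex": r.binomial(1, 0.5, n).astype(float),
        },
        index=[f"s{i}" for i in range(n)],
    )
    return FeatureTable(df, {"age": "continuous", "sex": "binary"})


def run_chain(values, x, C, p, pre_int=True):
    """The full covariance-test chain at one fixed component count."""
    vals = np.asarray(values, dtype=float)
    if pre_int:
        vals = np.column_stack(
            [inverse_normal_transform(vals[:, j]) for j in range(vals.shape[1])]
        )
    Z = standardize_columns(vals)
    P = pairwise_products(Z)
    P_int, _ = transform_products(P)
    proj, Q = fit_product_pca(P_int, p)
    return covariance_test(Q, x, C), proj, P
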