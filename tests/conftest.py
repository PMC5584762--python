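import numpy as np
import pytest
from hypothesis import settings

from essnet import enrichment, ifs, mrmr, synthetic

settings.register_profile("repro", derandomize=True, database=None)
settings.load_profile("repro")


#: compact generator config for fast unit tests (same mechanism as the
#: default, roughly 1/8 the gene count)
SMALL_CONFIG = synthetic.SyntheticConfig(
    n_genes=150,
    n_pos=25,
    n_neg=100,
    n_go_terms=40,
    n_kegg_terms=10,
    term_size_range=(4, 8),
    n_informative_terms=5,
    p_signal=0.5,
    p_background=0.02,
    seed=7,
)


@pytest.fixture(scope="session")
def small_dataset():
    return synthetic.generate(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    ds = small_dataset
    background = enrichment.make_background(ds.network, ds.terms)
    return enrichment.build_feature_matrix(
        ds.network, ds.labeled.genes, ds.terms, background
    )


@pytest.fixture(scope="session")
def default_pipeline():
    """Full pipeline at the default generator config (the planted-signal
    study conditions): encode -> mRMR -> IFS.  Computed once per session."""
    ds = synthetic.generate(synthetic.SyntheticConfig())
    background = enrichment.make_background(ds.network, ds.terms)
    matrix = enrichment.build_feature_matrix(
        ds.network, ds.labeled.genes, ds.terms, background
    )
    labels = ds.labeled.labels()
    ranked = mrmr.mrmr_rank(matrix, labels)
    folds = ifs.stratified_folds(labels, n_folds=10, seed=1)
    result = ifs.run_ifs(
        matrix, labels, ranked, k_min=5, k_max=100, step=5, folds=folds
    )
    return {
        "dataset": ds,
        "matrix": matrix,
        "labels": labels,
        "ranking": ranked,
        "folds": folds,
        "ifs": result,
    }
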