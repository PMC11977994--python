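import numpy as np
import pytest

from sefx import (
    AnnotationCorpus,
    FilterConfig,
    GeneratorConfig,
    Ontology,
    SimilarityMatrix,
    apply_filters,
    build_universe,
    flag_evidence,
    generate,
    information_content,
    pairwise_similarity,
)


@pytest.fixture(scope="session")
def four_term_dag():
    """Root R with children A, B; C under A; A and B are top-level."""
    return Ontology([("C", "A"), ("A", "R"), ("B", "R")], top_level=["A", "B"])


@pytest.fixture(scope="session")
def uniform_corpus():
    return AnnotationCorpus({"R": 1, "A": 1, "B": 1, "C": 1})


@pytest.fixture(scope="session")
def uniform_ic(four_term_dag, uniform_corpus):
    return information_content(four_term_dag, uniform_corpus, smooth=False)


@pytest.fixture(scope="session")
def small_dataset():
    """Default-scale synthetic dataset shared across tests."""
    return generate(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def small_universe(small_dataset):
    ds = small_dataset
    uni = build_universe(ds.drugs, ds.se_records, ds.sim, ds.assocs)
    flag_evidence(uni)
    return uni


@pytest.fixture(scope="session")
def retained_universe(small_universe):
    sub, _ = apply_filters(small_universe)
    return sub


def identity_similarity(terms):
    """Similarity matrix with 1 on the diagonal and 0 elsewhere."""
    return SimilarityMatrix(terms=list(terms), values=np.eye(len(terms)))
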