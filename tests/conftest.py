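import numpy as np
import pytest

from biosparse import (
    DEFAULT_CLASSES_16,
    AnnotatedVariantTable,
    ClassVocabulary,
    PathwayMap,
    encode_gene_centric,
)


@pytest.fixture
def vocab4():
    return ClassVocabulary(classes=("intronic", "exonic stopgain", "UTR3", "splicing"))


@pytest.fixture
def small_table(vocab4):
    records = [
        ("s1", "g1", "intronic"),
        ("s1", "g1", "intronic"),
        ("s1", "g1", "exonic stopgain"),
        ("s1", "g2", "UTR3"),
        ("s2", "g2", "splicing"),
    ]
    return AnnotatedVariantTable.from_records(records, vocab4)


@pytest.fixture
def small_tensor(small_table, vocab4):
    return encode_gene_centric(small_table, ["g1", "g2", "g3"], vocab4)


@pytest.fixture
def pathway_map():
    return PathwayMap(
        memberships={
            "g1": frozenset({"p1"}),
            "g2": frozenset({"p1", "p2"}),
            "g3": frozenset({"p2"}),
        },
        pathway_ids=["p1", "p2"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_variant_records(rng, n_samples=6, n_genes=5, n_records=40, vocab=None):
    vocab = vocab or DEFAULT_CLASSES_16
    samples = [f"s{i}" for i in range(n_samples)]
    genes = [f"g{i}" for i in range(n_genes)]
    return [
        (
            samples[rng.integers(n_samples)],
            genes[rng.integers(n_genes)],
            vocab.classes[rng.integers(vocab.size)],
        )
        for _ in range(n_records)
    ]
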