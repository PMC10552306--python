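"""Gene-centric encoding: counting, standardization, pathway resources."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biosparse import (
    CLASSES_17,
    DEFAULT_CLASSES_16,
    DUMMY_PATHWAY,
    AnnotatedVariantTable,
    ClassVocabulary,
    GeneCentricTensor,
    SchemaError,
    VocabularyError,
    encode_gene_centric,
    inverse_standardize,
    read_gmt,
    read_variant_table,
    standardize,
)
from biosparse.encoding import fit_standardization_stats

from conftest import random_variant_records


class TestClassVocabulary:
    def test_default_merges_to_16_classes(self):
        assert DEFAULT_CLASSES_16.size == 16
        assert len(CLASSES_17) == 17
        # the two translation-boundary classes fold into one
        merged = DEFAULT_CLASSES_16.canonical("exonic stoploss")
        assert merged == DEFAULT_CLASSES_16.canonical("exonic startloss")
        assert merged in DEFAULT_CLASSES_16.classes

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            ClassVocabulary(classes=("a", "a"))


class TestReadVariantTable:
    def test_parses_valid_rows(self, tmp_path, vocab4):
        p = tmp_path / "v.tsv"
        p.write_text(
            "sample_id\tgene_id\tfunctional_class\n"
            "s1\tg1\tintronic\ns1\tg2\tUTR3\ns2\tg1\tsplicing\n"
        )
        table = read_variant_table(p, vocab4)
        assert table.n_records == 3
        assert table.sample_ids == ["s1", "s2"]

    def test_unknown_class_named_in_error(self, tmp_path, vocab4):
        p = tmp_path / "v.tsv"
        p.write_text(
            "sample_id\tgene_id\tfunctional_class\ns1\tg1\texonic_nonsense\n"
        )
        with pytest.raises(VocabularyError, match="exonic_nonsense"):
            read_variant_table(p, vocab4)

    def test_header_only_file_gives_empty_table(self, tmp_path, vocab4):
        p = tmp_path / "v.tsv"
        p.write_text("sample_id\tgene_id\tfunctional_class\n")
        assert read_variant_table(p, vocab4).n_records == 0

    def test_missing_column_is_schema_error(self, tmp_path, vocab4):
        p = tmp_path / "v.tsv"
        p.write_text("sample_id\tgene_id\ns1\tg1\n")
        with pytest.raises(SchemaError):
            read_variant_table(p, vocab4)


class TestEncode:
    def test_direct_counts(self, small_tensor, vocab4):
        s1g1 = small_tensor.counts[0, 0]
        assert s1g1[vocab4.index_of("intronic")] == 2
        assert s1g1[vocab4.index_of("exonic stopgain")] == 1
        assert s1g1.sum() == 3

    def test_sample_without_records_is_all_zero(self, small_table, vocab4):
        t = encode_gene_centric(
            small_table, ["g1", "g2"], vocab4, sample_ids=["s1", "s2", "s3"]
        )
        assert t.counts[2].sum() == 0

    def test_unknown_gene_policy(self, small_table, vocab4):
        with pytest.raises(VocabularyError):
            encode_gene_centric(small_table, ["g1"], vocab4)
        t = encode_gene_centric(small_table, ["g1"], vocab4, drop_unknown_genes=True)
        assert t.counts.sum() == 3  # only g1 records survive

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_counts_match_groupby_oracle(self, seed):
        rng = np.random.default_rng(seed)
        records = random_variant_records(rng)
        table = AnnotatedVariantTable.from_records(records, DEFAULT_CLASSES_16)
        genes = [f"g{i}" for i in range(5)]
        t = encode_gene_centric(table, genes, DEFAULT_CLASSES_16)
        # independent recount of the raw triples
        oracle = {}
        for s, g, c in records:
            key = (s, g, DEFAULT_CLASSES_16.canonical(c))
            oracle[key] = oracle.get(key, 0) + 1
        for (s, g, c), n in oracle.items():
            si = t.sample_ids.index(s)
            gi = genes.index(g)
            ci = DEFAULT_CLASSES_16.index_of(c)
            assert t.counts[si, gi, ci] == n
        assert t.counts.sum() == len(records)  # conservation

    def test_record_order_irrelevant(self, rng):
        records = random_variant_records(rng)
        genes = [f"g{i}" for i in range(5)]
        samples = sorted({r[0] for r in records})
        t1 = encode_gene_centric(
            AnnotatedVariantTable.from_records(records, DEFAULT_CLASSES_16),
            genes, DEFAULT_CLASSES_16, sample_ids=samples,
        )
        shuffled = [records[i] for i in rng.permutation(len(records))]
        t2 = encode_gene_centric(
            AnnotatedVariantTable.from_records(shuffled, DEFAULT_CLASSES_16),
            genes, DEFAULT_CLASSES_16, sample_ids=samples,
        )
        np.testing.assert_array_equal(t1.counts, t2.counts)


class TestStandardize:
    def test_constant_class_maps_to_zero(self, vocab4):
        counts = np.ones((4, 3, 4), dtype=np.int64)
        t = GeneCentricTensor(
            counts=counts, sample_ids=list("abcd"), gene_ids=list("xyz"), vocab=vocab4
        )
        z = standardize(t)
        assert np.allclose(z.counts, 0.0)

    def test_transform_with_fixed_stats_is_idempotent(self, small_tensor):
        z1 = standardize(small_tensor)
        z2 = standardize(small_tensor, fit_stats=z1.stats)
        np.testing.assert_array_equal(z1.counts, z2.counts)

    def test_pooled_moments_after_standardization(self, rng):
        counts = rng.poisson(1.0, size=(50, 8, 4))
        vocab = ClassVocabulary(classes=("a", "b", "c", "d"))
        t = GeneCentricTensor(
            counts=counts,
            sample_ids=[f"s{i}" for i in range(50)],
            gene_ids=[f"g{i}" for i in range(8)],
            vocab=vocab,
        )
        z = standardize(t).counts.astype(np.float64)
        # recompute moments from scratch, pooled per class
        flat = z.reshape(-1, 4)
        assert np.allclose(flat.mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(flat.std(axis=0), 1.0, atol=1e-6)

    def test_inverse_recovers_raw_counts(self, rng):
        counts = rng.poisson(2.0, size=(30, 5, 4))
        vocab = ClassVocabulary(classes=("a", "b", "c", "d"))
        t = GeneCentricTensor(
            counts=counts,
            sample_ids=[f"s{i}" for i in range(30)],
            gene_ids=[f"g{i}" for i in range(5)],
            vocab=vocab,
        )
        z = standardize(t)
        back = inverse_standardize(z)
        sd = z.stats.sd
        recovered = back.counts[:, :, sd > 0]
        np.testing.assert_allclose(recovered, counts[:, :, sd > 0], atol=1e-9)

    def test_vocabulary_mismatch_rejected(self, small_tensor, rng):
        other = ClassVocabulary(classes=("w", "x", "y", "z"))
        stats = fit_standardization_stats(
            rng.poisson(1.0, size=(5, 2, 4)), other
        )
        with pytest.raises(VocabularyError):
            standardize(small_tensor, fit_stats=stats)

    def test_already_standardized_rejected(self, small_tensor):
        z = standardize(small_tensor)
        with pytest.raises(ValueError):
            standardize(z)


class TestGMT:
    def test_shared_gene_maps_to_both(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("p1\tna\tg1\tg2\np2\tna\tg2\tg3\n")
        pm = read_gmt(p)
        assert pm.pathways_of("g2") == frozenset({"p1", "p2"})

    def test_vocabulary_gene_missing_from_gmt_goes_to_dummy(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("p1\tna\tg1\n")
        pm = read_gmt(p).finalize(["g1", "g2"])
        assert pm.pathways_of("g2") == frozenset({DUMMY_PATHWAY})
        assert pm.pathways_of("g1") == frozenset({"p1"})

    def test_empty_gmt_sends_all_genes_to_dummy(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("")
        pm = read_gmt(p).finalize([f"g{i}" for i in range(5)])
        assert all(
            pm.pathways_of(g) == frozenset({DUMMY_PATHWAY}) for g in pm.memberships
        )
        assert pm.pathway_ids == [DUMMY_PATHWAY]

    def test_duplicate_pathway_name_rejected(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("p1\tna\tg1\np1\tna\tg2\n")
        with pytest.raises(SchemaError):
            read_gmt(p)


class TestGeneGeneEdges:
    def test_read_edges_and_adjacency(self, tmp_path):
        from biosparse import read_gene_edges

        p = tmp_path / "edges.tsv"
        p.write_text("g1\tg2\ng2\tg3\n")
        edges = read_gene_edges(p)
        adj = edges.adjacency(["g1", "g2", "g3", "g4"])
        assert adj[0, 1] == adj[1, 0] == 1  # symmetric
        assert adj[1, 2] == 1 and adj[0, 2] == 0
        assert np.all(np.diag(adj) == 1)  # self-edges keep isolated genes alive

    def test_self_loop_rejected(self, tmp_path):
        from biosparse import read_gene_edges

        p = tmp_path / "edges.tsv"
        p.write_text("g1\tg1\n")
        with pytest.raises(ValueError):
            read_gene_edges(p)


def test_tensor_roundtrip_on_disk(tmp_path, small_tensor):
    z = standardize(small_tensor)
    z.save(tmp_path / "tensor")
    back = GeneCentricTensor.load(tmp_path / "tensor")
    np.testing.assert_array_equal(back.counts, z.counts)
    assert back.gene_ids == z.gene_ids
    assert back.standardized
    np.testing.assert_allclose(back.stats.mean, z.stats.mean)
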