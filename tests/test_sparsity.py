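"""Mask builders: knowledge, random, full-membership, L1-learned, RigL."""

import numpy as np
import pytest
from scipy import stats as sps

from biosparse import (
    GeneModuleSpec,
    HeadSpec,
    PathwayMap,
    RigLConfig,
    SparsityMask,
    TrainConfig,
    build_model,
    full_membership_mask,
    knowledge_mask,
    l1_learned_mask,
    random_mask,
    rigl_train,
)
from biosparse.simulate import SimConfig, simulate_tensor
from biosparse.sparsity import rigl_update


class TestKnowledgeMask:
    def test_single_membership_is_deterministic(self, pathway_map):
        m = knowledge_mask(pathway_map, ["g1", "g2", "g3"], seed=0)
        gi = m.gene_ids.index("g1")
        assert m.matrix[gi, m.hidden_ids.index("p1")] == 1
        assert m.gene_degrees[gi] == 1

    def test_orphan_gene_routed_to_dummy(self, pathway_map):
        genes = ["g1", "g2", "g3", "g_orphan"]
        m = knowledge_mask(pathway_map, genes, seed=0)
        from biosparse import DUMMY_PATHWAY

        gi = m.gene_ids.index("g_orphan")
        assert m.matrix[gi, m.hidden_ids.index(DUMMY_PATHWAY)] == 1

    def test_same_seed_identical_and_choice_uniform(self, pathway_map):
        genes = ["g1", "g2", "g3"]
        m1 = knowledge_mask(pathway_map, genes, seed=42)
        m2 = knowledge_mask(pathway_map, genes, seed=42)
        np.testing.assert_array_equal(m1.matrix, m2.matrix)
        # g2 belongs to {p1, p2}: over many seeds it picks p1 half the time
        picks = []
        for seed in range(1000):
            m = knowledge_mask(pathway_map, genes, seed=seed)
            picks.append(m.matrix[m.gene_ids.index("g2"), m.hidden_ids.index("p1")])
        assert abs(np.mean(picks) - 0.5) < 0.05

    def test_every_gene_has_degree_one(self, pathway_map):
        m = knowledge_mask(pathway_map, ["g1", "g2", "g3"], seed=1)
        assert np.all(m.gene_degrees == 1)


class TestRandomMask:
    def test_full_fraction_connects_every_gene(self):
        m = random_mask(100, 10, gene_fraction=1.0, seed=0)
        assert m.n_connections == 100
        assert np.all(m.gene_degrees == 1)

    def test_quarter_fraction_connects_quarter_of_genes(self):
        m = random_mask(100, 10, gene_fraction=0.25, seed=3)
        assert m.n_connected_genes == 25
        assert m.n_connections == 25

    def test_invalid_fraction_rejected(self):
        for f in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                random_mask(10, 2, gene_fraction=f)

    def test_hidden_occupancy_uniform(self):
        counts = np.zeros(10)
        for seed in range(100):
            m = random_mask(100, 10, gene_fraction=1.0, seed=seed)
            counts += m.matrix.sum(axis=0)
        # 10,000 draws over 10 neurons
        chi = sps.chisquare(counts)
        assert chi.pvalue > 0.01


class TestFullMembershipMask:
    def test_degrees_equal_membership_sizes(self, pathway_map):
        m = full_membership_mask(pathway_map, ["g1", "g2", "g3"])
        assert m.gene_degrees[m.gene_ids.index("g2")] == 2
        total = sum(len(pathway_map.pathways_of(g)) for g in ["g1", "g2", "g3"])
        assert m.n_connections == total

    def test_knowledge_support_subset_of_full_membership(self, pathway_map):
        genes = ["g1", "g2", "g3", "g_orphan"]
        full = full_membership_mask(pathway_map, genes)
        for seed in range(20):
            k = knowledge_mask(pathway_map, genes, seed=seed)
            kf = np.zeros_like(full.matrix)
            for gi, g in enumerate(k.gene_ids):
                for hi, h in enumerate(k.hidden_ids):
                    if k.matrix[gi, hi]:
                        kf[full.gene_ids.index(g), full.hidden_ids.index(h)] = 1
            assert np.all(kf <= full.matrix)


def _signal_data(seed=0, n=500, n_genes=12):
    cfg = SimConfig(
        n_samples=n, n_genes=n_genes, n_pathways=3, prevalence=0.5,
        additive=[(0, 2.0)], noise_sd=0.3, seed=seed,
    )
    tensor, y, _, _ = simulate_tensor(cfg)
    X = tensor.counts.astype(np.float64)
    mu, sd = X.mean(axis=(0, 1)), X.std(axis=(0, 1))
    Z = ((X - mu) / np.where(sd > 0, sd, 1)).astype(np.float32)
    return Z, y


class TestL1LearnedMask:
    def test_budget_and_degree_cap_enforced(self):
        Z, y = _signal_data()
        m = l1_learned_mask((Z, y), {"n_hidden": 4, "epochs": 5}, budget=6, seed=0)
        assert m.n_connections == 6
        assert np.all(m.gene_degrees <= 1)

    def test_degenerate_budget_rejected(self):
        Z, y = _signal_data()
        with pytest.raises(ValueError):
            l1_learned_mask((Z, y), {"n_hidden": 4}, budget=0)

    def test_signal_gene_retained(self):
        """Only gene 0 carries signal: L1 selection keeps it connected."""
        hits = 0
        for seed in range(10):
            Z, y = _signal_data(seed=seed)
            m = l1_learned_mask(
                (Z, y), {"n_hidden": 4, "epochs": 50, "learning_rate": 0.01},
                l1_strength=3e-3, budget=3, seed=seed,
            )
            hits += m.gene_degrees[0] > 0  # gene 0 is the signal gene
        assert hits >= 9


class TestRigL:
    def test_zero_drop_fraction_keeps_mask(self):
        Z, y = _signal_data()
        genes = [f"g{i:05d}" for i in range(Z.shape[1])]
        mask = random_mask(Z.shape[1], 4, seed=0, gene_ids=genes)
        model = build_model(GeneModuleSpec(16, 4), HeadSpec(kind="biosparse", mask=mask), genes)
        model, final = rigl_train(
            model, (Z, y), RigLConfig(update_interval=5, drop_fraction=0.0),
            TrainConfig(epochs=3, seed=0),
        )
        np.testing.assert_array_equal(final.matrix, mask.matrix)

    def test_update_conserves_connection_count(self, rng):
        mask = (rng.random((20, 5)) < 0.2).astype(np.float32)
        w = rng.normal(size=(20, 5)).astype(np.float32) * mask
        grad = rng.normal(size=(20, 5)).astype(np.float32)
        for frac in (0.1, 0.3, 0.6):
            new, grown = rigl_update(mask, w, grad, frac)
            assert new.sum() == mask.sum()
            assert np.all(new[grown // 5, grown % 5] == 1)

    def test_invalid_drop_fraction_rejected(self, rng):
        mask = np.ones((4, 2), dtype=np.float32)
        with pytest.raises(ValueError):
            rigl_update(mask, mask, mask, 1.0)

    def test_rigl_reconnects_signal_genes(self):
        """Signal genes start disconnected; drop/grow wires them back in."""
        recovered = []
        for seed in range(10):
            cfg = SimConfig(
                n_samples=2000, n_genes=30, n_pathways=4, prevalence=0.5,
                additive=[(g, 1.0) for g in range(3)], noise_sd=0.3, seed=seed,
            )
            tensor, y, _, _ = simulate_tensor(cfg)
            X = tensor.counts.astype(np.float64)
            mu, sd = X.mean(axis=(0, 1)), X.std(axis=(0, 1))
            Z = ((X - mu) / np.where(sd > 0, sd, 1)).astype(np.float32)
            genes = tensor.gene_ids
            m = np.zeros((30, 5), dtype=np.float32)
            rng = np.random.default_rng(seed)
            for g in range(3, 30):  # signal genes 0-2 start disconnected
                m[g, rng.integers(5)] = 1.0
            mask = SparsityMask(m, genes, [f"h{j}" for j in range(5)], "random")
            model = build_model(GeneModuleSpec(16, 4), HeadSpec(kind="multiconnect", mask=mask), genes, seed=seed)
            model, final = rigl_train(
                model, (Z, y),
                RigLConfig(update_interval=10, drop_fraction=0.4),
                TrainConfig(epochs=10, learning_rate=0.01, seed=seed),
            )
            assert final.n_connections == 27
            recovered.append(np.mean(final.gene_degrees[:3] > 0))
        assert np.mean(recovered) >= 0.5


def test_equal_budget_masks_have_equal_connection_counts(pathway_map):
    """The four builders at the same budget are comparable by construction."""
    genes = ["g1", "g2", "g3"]
    Z, y = _signal_data(n=300, n_genes=3)
    k = knowledge_mask(pathway_map, genes, seed=0)
    r = random_mask(3, len(k.hidden_ids), gene_fraction=1.0, seed=0, gene_ids=genes)
    l1 = l1_learned_mask(
        (Z, y), {"n_hidden": len(k.hidden_ids), "epochs": 3, "gene_ids": genes},
        budget=3, seed=0,
    )
    counts = {k.n_connections, r.n_connections, l1.n_connections}
    assert counts == {3}


def test_mask_roundtrip_serialization(tmp_path, pathway_map):
    m = knowledge_mask(pathway_map, ["g1", "g2", "g3"], seed=9)
    m.save(tmp_path / "mask")
    back = SparsityMask.load(tmp_path / "mask")
    np.testing.assert_array_equal(back.matrix, m.matrix)
    assert back.provenance == "knowledge"
    assert back.hidden_ids == m.hidden_ids
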