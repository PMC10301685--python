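import numpy as np
import pandas as pd
import pytest

from pathdrp.dataset import PPINetwork
from pathdrp.models_implicit import (
    build_hidra,
    build_pathdsp,
    compute_enrichment,
    enrichment_features,
    propagate_targets,
)
from pathdrp.nn import TrainConfig
from pathdrp.pathways import PathwayCollection


@pytest.fixture
def disjoint_collection():
    return PathwayCollection(
        "d",
        (("P1", frozenset({"A", "B"})), ("P2", frozenset({"C", "D"}))),
        ("A", "B", "C", "D"),
    )


class TestHiDRA:
    def test_pathway_isolation(self, disjoint_collection):
        """Perturbing a gene of pathway 1 leaves pathway 2's activation alone."""
        net = build_hidra(
            disjoint_collection, ["A", "B", "C", "D"], "targets", TrainConfig(seed=0)
        )
        rng = np.random.default_rng(0)
        X = rng.normal(size=(1, 8))  # 4 gex + 4 target
        X2 = X.copy()
        X2[0, 0] += 5.0  # gene A expression
        s1 = net.pathway_activations(X)
        s2 = net.pathway_activations(X2)
        assert s1[0, 1] == s2[0, 1]  # P2 untouched
        assert s1[0, 0] != s2[0, 0]  # P1 responds

    def test_drug_encoder_input_length(self, disjoint_collection):
        order = ["A", "B", "C", "D"]
        net_t = build_hidra(disjoint_collection, order, "targets", TrainConfig(seed=0))
        net_fp = build_hidra(disjoint_collection, order, "fingerprint", TrainConfig(seed=0))
        assert net_t.encoder[0].W.shape[0] == len(order)
        assert net_fp.encoder[0].W.shape[0] == 512

    def test_attention_weights_sum_to_one(self, disjoint_collection):
        net = build_hidra(
            disjoint_collection, ["A", "B", "C", "D"], "targets", TrainConfig(seed=0)
        )
        X = np.random.default_rng(1).normal(size=(6, 8))
        for att in net.attention_weights(X):
            assert np.allclose(att.sum(axis=1), 1.0)


class TestEnrichment:
    def test_constant_profile_scores_zero(self, disjoint_collection):
        profile = {g: 2.5 for g in "ABCD"}
        scores = compute_enrichment(profile, disjoint_collection, 200, seed=0)
        assert (scores == 0.0).all()

    def test_self_set_is_maximal(self):
        genes = tuple(f"g{i}" for i in range(100))
        pathways = tuple(
            (f"P{i}", frozenset(genes[5 * i : 5 * i + 5])) for i in range(10)
        )
        coll = PathwayCollection("c", pathways, genes)
        scores = compute_enrichment(frozenset(genes[0:5]), coll, 1000, seed=1)
        assert scores.idxmax() == "P0"
        assert scores["P0"] > 3.0

    def test_deterministic(self, disjoint_collection):
        prof = {"A": 1.0, "B": 0.2, "C": -0.5, "D": 3.0}
        s1 = compute_enrichment(prof, disjoint_collection, 300, seed=9)
        s2 = compute_enrichment(prof, disjoint_collection, 300, seed=9)
        assert s1.equals(s2)

    def test_overlap_monotone_in_profile(self, disjoint_collection):
        """Adding a member gene never decreases the observed overlap z-score
        (same permutation seed, so the null is held fixed)."""
        s_small = compute_enrichment(frozenset({"A"}), disjoint_collection, 500, seed=3)
        s_big = compute_enrichment(frozenset({"A", "B"}), disjoint_collection, 500, seed=3)
        assert s_big["P1"] >= s_small["P1"]

    def test_thousand_permutations_match_bruteforce_oracle(self):
        """Permutation z at n=1000 agrees with a 100k-permutation oracle
        within 3 SE on a 20-gene toy."""
        genes = tuple(f"g{i}" for i in range(20))
        coll = PathwayCollection(
            "c",
            (("P1", frozenset(genes[:6])), ("P2", frozenset(genes[10:14]))),
            genes,
        )
        rng = np.random.default_rng(12)
        profile = {g: float(v) for g, v in zip(genes, rng.normal(size=20))}
        scores = compute_enrichment(profile, coll, 1000, seed=5)

        # independent oracle: explicit permutation loop at 100k draws
        values = np.array([profile[g] for g in genes])
        orng = np.random.default_rng(999)
        n_oracle = 100_000
        for pid, members in coll.pathways:
            idx = [genes.index(g) for g in members]
            s_obs = values[idx].mean()
            s_perm = np.array(
                [values[orng.permutation(20)][idx].mean() for _ in range(n_oracle)]
            )
            z_oracle = (s_obs - s_perm.mean()) / s_perm.std()
            # SE of a z-score estimated from 1000 permutations ~ 1/sqrt(2*1000)
            se = np.sqrt(1 / 1000 + z_oracle**2 / (2 * 1000))
            assert abs(scores[pid] - z_oracle) < 3 * se + 0.05


class TestRWR:
    def path_graph(self):
        return PPINetwork.from_edges(
            [("a", "b", 500), ("b", "c", 500), ("c", "d", 500)]
        )

    def test_full_restart_returns_seed_vector(self):
        s = propagate_targets({"a"}, self.path_graph(), restart_prob=1.0)
        assert s["a"] == 1.0 and s[["b", "c", "d"]].sum() == 0.0

    def test_disconnected_component_unreachable(self):
        ppi = PPINetwork.from_edges([("a", "b", 500), ("x", "y", 500)])
        s = propagate_targets({"a"}, ppi)
        assert s["x"] == 0.0 and s["y"] == 0.0
        assert s.sum() == pytest.approx(1.0, abs=1e-8)

    def test_matches_closed_form_solve(self):
        """Iterative RWR equals s = a (I - (1-a) W)^-1 r on a 4-node path."""
        import networkx as nx

        ppi = self.path_graph()
        a = 0.5
        s = propagate_targets({"a"}, ppi, restart_prob=a, tol=1e-12)
        nodes = sorted(ppi.graph.nodes)
        W = nx.to_numpy_array(ppi.graph, nodelist=nodes, weight="weight")
        W = W / W.sum(axis=0)
        r = np.array([1.0, 0, 0, 0])
        expected = a * np.linalg.solve(np.eye(4) - (1 - a) * W, r)
        assert np.allclose(s[nodes].to_numpy(), expected, atol=1e-8)

    def test_conservation_and_positivity(self):
        s = propagate_targets({"b", "c"}, self.path_graph())
        assert (s >= 0).all()
        assert s.sum() == pytest.approx(1.0, abs=1e-6)

    def test_missing_targets_rejected(self):
        with pytest.raises(ValueError):
            propagate_targets({"zzz"}, self.path_graph())


class TestPathDSP:
    def features(self, small_dataset, blocks):
        ds, _ = small_dataset
        return enrichment_features(ds, blocks=blocks, n_permutations=50, seed=0), ds

    def test_input_length_scales_with_blocks(self, small_dataset):
        feats, ds = self.features(small_dataset, ("GEx", "T"))
        net = build_pathdsp(feats, TrainConfig(seed=0))
        m = ds.collection.m
        assert net.head.hidden_layers[0].W.shape[0] == 2 * m

        feats5, _ = self.features(small_dataset, ("GEx", "CNV", "Mut", "FP", "T"))
        net5 = build_pathdsp(feats5, TrainConfig(seed=0))
        assert net5.head.hidden_layers[0].W.shape[0] == 5 * m

    def test_zero_features_give_constant_predictor(self, small_dataset):
        feats, ds = self.features(small_dataset, ("GEx", "T"))
        zeroed = {k: v * 0.0 for k, v in feats.items()}
        net = build_pathdsp(zeroed, TrainConfig(seed=0))
        pairs = ds.responses.pairs()[:20]
        X = net.featurizer.build(ds, pairs)
        preds = net.predict(X)
        assert np.ptp(preds) < 1e-12

    def test_mismatched_block_indices_rejected(self, small_dataset):
        feats, ds = self.features(small_dataset, ("GEx", "T"))
        bad = dict(feats)
        bad["Mut"] = feats["GEx"].iloc[:3]
        with pytest.raises(ValueError, match="mismatch"):
            build_pathdsp(bad, TrainConfig(seed=0))
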