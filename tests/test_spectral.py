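"""Normalized-Laplacian embedding, stable subsets, Nystrom projection."""

import networkx as nx
import numpy as np
import pytest

from ibdnet.cluster import multilevel_cluster
from ibdnet.ibdseg import PairwiseIBD
from ibdnet.network import EdgeWeightModel, weight
from ibdnet.spectral import (
    embed,
    extract_stable_subsets,
    project_new_samples,
    second_pass_embedding,
)

from .conftest import planted_block_graph
from .oracles import union_find_components


def random_weighted_graph(n=200, p=0.05, seed=0):
    rng = np.random.default_rng(seed)
    G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    # guarantee connectivity with a light chain
    for i in range(n - 1):
        if not G.has_edge(i, i + 1):
            G.add_edge(i, i + 1)
    for u, v in G.edges:
        G.edges[u, v]["weight"] = float(rng.uniform(0.05, 1.0))
    return G


def dense_laplacian_oracle(G):
    """Independent dense construction of D^-1/2 W D^-1/2 with unit diagonal."""
    nodes = sorted(G.nodes)
    W = nx.to_numpy_array(G, nodelist=nodes, weight="weight") + np.eye(len(nodes))
    d = W.sum(axis=1)
    L = W / np.sqrt(np.outer(d, d))
    vals, vecs = np.linalg.eigh(L)
    order = np.argsort(vals)[::-1]
    return nodes, vals[order], vecs[:, order], d


class TestEmbed:
    def test_two_disconnected_cliques_block_structure(self):
        G = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        nx.set_edge_attributes(G, 1.0, "weight")
        emb = embed(G, m=3, require_connected=False)
        assert emb.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        assert emb.eigenvalues[1] == pytest.approx(1.0, abs=1e-10)
        # the eigenvalue-1 eigenspace is spanned by sqrt(d) per component
        for comp in (list(range(4)), list(range(4, 8))):
            idx = [emb.nodes.index(v) for v in comp]
            V = emb.vectors[idx, :2]
            ratios = V / np.sqrt(emb.degrees[idx])[:, None]
            assert np.allclose(ratios - ratios[0], 0.0, atol=1e-8)

    def test_disconnected_rejected_with_guidance(self):
        G = nx.disjoint_union(nx.path_graph(3), nx.path_graph(3))
        with pytest.raises(ValueError, match="largest connected component"):
            embed(G, m=2)

    def test_eigen_bounds_orthonormality_residual(self):
        G = random_weighted_graph(80, 0.1, seed=3)
        emb = embed(G, m=10)
        assert np.all(emb.eigenvalues <= 1.0 + 1e-10)
        assert np.all(emb.eigenvalues >= -1.0 - 1e-10)
        assert emb.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(emb.vectors.T @ emb.vectors, np.eye(10), atol=1e-8)
        _, _, _, d = dense_laplacian_oracle(G)
        nodes, vals, vecs, _ = dense_laplacian_oracle(G)
        L = (nx.to_numpy_array(G, nodelist=emb.nodes, weight="weight") + np.eye(80))
        L = L / np.sqrt(np.outer(L.sum(1), L.sum(1)))
        for k in range(emb.m):
            r = L @ emb.vectors[:, k] - emb.eigenvalues[k] * emb.vectors[:, k]
            assert np.linalg.norm(r) <= 1e-6

    def test_sparse_solver_matches_dense_oracle(self):
        G = random_weighted_graph(200, 0.05, seed=1)
        emb = embed(G, m=10, dense_cutoff=0)  # force the iterative solver
        nodes, vals, vecs, _ = dense_laplacian_oracle(G)
        assert emb.nodes == nodes
        np.testing.assert_allclose(emb.eigenvalues, vals[:10], atol=1e-8)
        for k in range(10):
            v, w = emb.vectors[:, k], vecs[:, k]
            assert min(np.abs(v - w).max(), np.abs(v + w).max()) < 1e-8

    def test_m_truncated_for_small_graphs(self):
        G = nx.complete_graph(5)
        nx.set_edge_attributes(G, 1.0, "weight")
        emb = embed(G, m=40)
        assert emb.m == 4


class TestStableSubsets:
    def test_planted_block_extracted(self):
        G, block = planted_block_graph(seed=4)
        emb = embed(G, m=6)
        labels = multilevel_cluster(G, seed=1)
        subsets = extract_stable_subsets(emb, labels, fp_cap=0.05, min_recall=0.9)
        assert subsets, "planted near-disconnected block not found"
        best = max(subsets, key=lambda s: len(s.members & block))
        assert best.fp_rate <= 0.05
        assert len(best.members & block) / len(block) >= 0.9

    def test_null_graph_accepts_nothing(self):
        rng = np.random.default_rng(8)
        G = nx.gnp_random_graph(260, 0.1, seed=17)
        nx.set_edge_attributes(G, 1.0, "weight")
        emb = embed(G, m=6)
        labels = multilevel_cluster(G, seed=1)
        assert extract_stable_subsets(emb, labels, fp_cap=0.05, min_recall=0.9) == []

    def test_sign_flip_invariance(self):
        G, block = planted_block_graph(seed=4)
        emb = embed(G, m=6)
        labels = multilevel_cluster(G, seed=1)
        s1 = extract_stable_subsets(emb, labels)
        emb.vectors = emb.vectors * -1.0
        s2 = extract_stable_subsets(emb, labels)
        assert [s.members for s in s1] == [s.members for s in s2]

    def test_exact_disconnection_limit_equals_components(self):
        """With zero cross weight, stable subsets = connected components."""
        G = nx.Graph()
        for b, n in enumerate((30, 25)):
            nodes = [f"c{b}_{i}" for i in range(n)]
            for i in range(n):
                for j in range(i + 1, n):
                    G.add_edge(nodes[i], nodes[j], weight=1.0)
        comps = union_find_components(list(G.nodes), list(G.edges))
        emb = embed(G, m=4, require_connected=False)
        labels = {v: v.split("_")[0] for v in G.nodes}
        subsets = extract_stable_subsets(emb, labels, fp_cap=0.0, min_recall=1.0, skip_leading=0)
        found = {s.members for s in subsets}
        assert any(frozenset(c) in found for c in comps)
        for s in subsets:
            assert s.fp_rate == 0.0


class TestSecondPass:
    def test_no_subsets_reembeds_same_graph(self):
        G = random_weighted_graph(50, 0.15, seed=6)
        e1 = embed(G, m=5)
        e2 = second_pass_embedding(G, [], m=5)
        assert e1.nodes == e2.nodes
        np.testing.assert_allclose(e1.eigenvalues, e2.eigenvalues, atol=1e-12)

    def test_removing_dominant_block_reveals_remaining_split(self):
        # three blocks; A nearly disconnected, B/C split only visible after removing A
        rng = np.random.default_rng(9)
        G = nx.Graph()
        blocks = {}
        for name, n in (("A", 40), ("B", 30), ("C", 30)):
            nodes = [f"{name}{i}" for i in range(n)]
            blocks[name] = nodes
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.5:
                        G.add_edge(nodes[i], nodes[j], weight=1.0)
        for u in blocks["B"]:
            for v in blocks["C"]:
                if rng.random() < 0.08:
                    G.add_edge(u, v, weight=0.3)
        G.add_edge("A0", "B0", weight=0.01)  # keep connected
        emb1 = embed(G, m=4)
        labels = multilevel_cluster(G, seed=3)
        subsets = extract_stable_subsets(emb1, labels, fp_cap=0.05, min_recall=0.9)
        dominant = max(subsets, key=lambda s: len(s.members & set(blocks["A"])))
        assert dominant.members <= set(blocks["A"]) | {"B0"}
        emb2 = second_pass_embedding(G, [dominant], m=4)
        assert set(emb2.nodes).isdisjoint(dominant.members)
        # B and C separate along the second eigenvector of the residual
        v1 = emb2.vectors[:, 1]
        sign_b = np.sign(np.mean([v1[emb2.nodes.index(v)] for v in blocks["B"] if v in emb2.nodes]))
        sign_c = np.sign(np.mean([v1[emb2.nodes.index(v)] for v in blocks["C"] if v in emb2.nodes]))
        assert sign_b != sign_c


class TestNystrom:
    def test_self_projection_recovers_coordinates(self):
        G = random_weighted_graph(60, 0.12, seed=10)
        model = EdgeWeightModel()
        # give edges total_cM consistent with their stored weights? project
        # a held-in vertex using its actual edge weights as cross-IBD
        emb = embed(G, m=6)
        target = emb.nodes[7]
        # cross-IBD totals chosen so that weight(total) reproduces the
        # target's actual edge weights (inverse of the Beta CDF)
        from scipy.stats import beta as beta_dist

        pairs = []
        for nbr in G.neighbors(target):
            w = G.edges[target, nbr]["weight"]
            total = float(beta_dist.ppf(w, model.alpha, model.beta) * model.scale_cM)
            a, b = sorted(["new", str(nbr)])
            pairs.append(PairwiseIBD(a, b, total, 1))
        emb_named = embed(nx.relabel_nodes(G, {v: str(v) for v in G}), m=6)
        coords, unstable = project_new_samples(emb_named, pairs, model)
        got = coords["new"]
        expected = emb_named.vectors[emb_named.nodes.index(str(target)), :]
        np.testing.assert_allclose(got, expected, atol=1e-6)
        assert not unstable["new"].any()

    def test_zero_cross_ibd_maps_to_origin(self):
        G = random_weighted_graph(30, 0.2, seed=2)
        emb = embed(nx.relabel_nodes(G, str), m=4)
        coords, _ = project_new_samples(emb, [], new_samples=["lonely"])
        assert np.allclose(coords["lonely"], 0.0)

    def test_new_block_members_land_in_block_halfplane(self):
        G, block = planted_block_graph(seed=12)
        emb = embed(G, m=6)
        labels = multilevel_cluster(G, seed=1)
        subsets = extract_stable_subsets(emb, labels, fp_cap=0.05, min_recall=0.9)
        best = max(subsets, key=lambda s: len(s.members & block))
        j, k = best.eigenvector_pair
        model = EdgeWeightModel()
        # a new sample with strong IBD to half the block members
        members = sorted(block)[:30]
        pairs = []
        for v in members:
            a, b = sorted(["zz_new", v])
            pairs.append(PairwiseIBD(a, b, 60.0, 3))
        coords, _ = project_new_samples(emb, pairs, model)
        x = np.array([coords["zz_new"][j], coords["zz_new"][k]])
        theta = np.deg2rad(-best.rotation_deg)
        y1 = x @ np.array([np.cos(theta), np.sin(theta)])
        assert y1 >= best.threshold
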