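"""Top-k ranking, Spearman edge retention and network statistics."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import fryflora as ff
from fryflora.conetwork import (
    build_network,
    export_network,
    network_stats,
    provenance_labels,
    read_network,
    spearman_edges,
    top_k_otus,
)


def rel_from_matrix(values, otus=None, samples=None) -> pd.DataFrame:
    arr = np.asarray(values, dtype=float)
    otus = otus or [f"O{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    df = pd.DataFrame(arr, index=otus, columns=samples)
    return df / df.sum()


class TestTopK:
    def test_small_table_returns_all(self):
        rel = rel_from_matrix([[1, 2], [3, 4]])
        assert top_k_otus(rel, k=50) == ["O1", "O0"]

    def test_ranked_by_mean_abundance(self):
        rel = pd.DataFrame(
            {"s1": [0.4, 0.3, 0.2, 0.1], "s2": [0.4, 0.3, 0.2, 0.1]},
            index=["d", "c", "b", "a"],
        )
        assert top_k_otus(rel, k=2) == ["d", "c"]

    def test_ties_break_by_otu_id(self):
        rel = pd.DataFrame({"s1": [0.5, 0.5]}, index=["z", "a"])
        assert top_k_otus(rel, k=2) == ["a", "z"]

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        rel = rel_from_matrix(rng.random((10, 6)))
        cols = list(rel.columns)[::-1]
        assert top_k_otus(rel, 5) == top_k_otus(rel[cols], 5)


class TestSpearmanEdges:
    def test_perfect_monotone_pair_retained(self):
        n = 30
        x = np.arange(1, n + 1, dtype=float)
        rel = pd.DataFrame([x, x ** 2 + 1], index=["a", "b"],
                           columns=[f"s{i}" for i in range(n)])
        edges = spearman_edges(rel)
        assert len(edges) == 1
        assert edges.iloc[0]["rho"] == pytest.approx(1.0)
        assert edges.iloc[0]["p_raw"] == 0.0

    def test_anti_monotone_pair_excluded(self):
        n = 30
        x = np.arange(1, n + 1, dtype=float)
        rel = pd.DataFrame([x, -x + 100], index=["a", "b"],
                           columns=[f"s{i}" for i in range(n)])
        assert len(spearman_edges(rel)) == 0

    def test_bonferroni_factor_for_k50(self):
        rng = np.random.default_rng(1)
        rel = rel_from_matrix(rng.random((60, 12)))
        g = build_network(rel, k=50)
        assert g.graph["bonferroni_factor"] == 1225
        assert g.number_of_nodes() == 50

    def test_constant_vector_pairs_skipped(self):
        rng = np.random.default_rng(2)
        rel = pd.DataFrame(rng.random((3, 8)),
                           index=["a", "b", "const"],
                           columns=[f"s{i}" for i in range(8)])
        rel.loc["const"] = 0.125
        edges = spearman_edges(rel, rho_min=-1.1, alpha_adj=1.0, return_all=True)
        pairs = {frozenset((r.otu_a, r.otu_b)) for r in edges.itertuples()}
        assert frozenset(("a", "const")) not in pairs

    def test_too_few_samples_rejected(self):
        rel = rel_from_matrix(np.random.default_rng(0).random((4, 4)))
        with pytest.raises(ValueError, match="at least 5"):
            spearman_edges(rel)

    def test_threshold_monotonicity(self):
        # raising rho_min or lowering alpha_adj never adds edges
        rng = np.random.default_rng(3)
        base = rng.random((12, 20))
        base[:4] *= np.exp(rng.normal(size=20))  # correlated block
        rel = rel_from_matrix(base)
        loose = spearman_edges(rel, rho_min=0.5, alpha_adj=1e-2)
        tight_rho = spearman_edges(rel, rho_min=0.8, alpha_adj=1e-2)
        tight_alpha = spearman_edges(rel, rho_min=0.5, alpha_adj=1e-5)
        as_pairs = lambda df: {frozenset((r.otu_a, r.otu_b)) for r in df.itertuples()}
        assert as_pairs(tight_rho) <= as_pairs(loose)
        assert as_pairs(tight_alpha) <= as_pairs(loose)

    def test_edge_set_invariant_to_sample_order(self):
        rng = np.random.default_rng(4)
        base = rng.random((8, 15))
        rel = rel_from_matrix(base)
        cols = list(rel.columns)
        rng.shuffle(cols)
        e1 = spearman_edges(rel, rho_min=0.3, alpha_adj=1.0)
        e2 = spearman_edges(rel[cols], rho_min=0.3, alpha_adj=1.0)
        as_pairs = lambda df: {frozenset((r.otu_a, r.otu_b)) for r in df.itertuples()}
        assert as_pairs(e1) == as_pairs(e2)


class TestProvenance:
    def build_simple_network(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        g.add_edge("a", "b", rho=0.95, p_raw=1e-9, p_adj=1e-6)
        return g

    def test_labels(self):
        g = self.build_simple_network()
        fry = pd.DataFrame({"f": [0.5, 0.5, 0.0]}, index=["a", "b", "c"])
        res = pd.DataFrame({"r": [0.5, 0.0, 0.5]}, index=["a", "b", "c"])
        labelled = provenance_labels(g, fry, res)
        assert labelled.nodes["a"]["provenance"] == "shared"
        assert labelled.nodes["b"]["provenance"] == "fry_only"
        assert labelled.nodes["c"]["provenance"] == "reservoir_only"

    def test_absent_nodes_dropped(self):
        g = self.build_simple_network()
        fry = pd.DataFrame({"f": [0.9, 0.1, 0.0]}, index=["a", "b", "c"])
        res = pd.DataFrame({"r": [0.9, 0.1, 0.0]}, index=["a", "b", "c"])
        labelled = provenance_labels(g, fry, res)
        assert "c" not in labelled

    def test_planted_fry_specific_otus_labelled(self, pipeline_products):
        _, pmeta, rel, truth = pipeline_products
        from fryflora.tables import Stage
        fry_cols = [r.sample_id for r in pmeta
                    if r.niche == "whole_fry" and r.stage is Stage.MUCUS]
        bdm_cols = [r.sample_id for r in pmeta if r.niche == "breeding_mucus"]
        g = build_network(rel, k=50, rho_min=0.5, alpha_adj=1.0)
        labelled = provenance_labels(g, rel[fry_cols], rel[bdm_cols])
        provs = nx.get_node_attributes(labelled, "provenance")
        fry_only = {n for n, p in provs.items() if p == "fry_only"}
        # planted transmission OTUs sit in fry and breeding mucus: "shared"
        planted_in_graph = set(truth.transmission_otus) & set(labelled.nodes)
        assert planted_in_graph
        assert all(provs[o] == "shared" for o in planted_in_graph)
        assert fry_only  # water-derived taxa absent from mucus exist too


class TestNetworkStats:
    def test_star_graph_mean_degree(self):
        g = nx.star_graph(4)  # hub degree 4, four leaves degree 1
        stats = network_stats(g)
        assert stats.n_nodes == 5
        assert stats.mean_degree == pytest.approx(1.6)

    def test_edgeless_network(self):
        g = nx.Graph()
        g.add_nodes_from("ab")
        assert network_stats(g).mean_degree == 0.0

    def test_relabel_invariance(self):
        g = nx.star_graph(4)
        h = nx.relabel_nodes(g, {n: f"otu_{n}" for n in g.nodes})
        assert network_stats(g).mean_degree == network_stats(h).mean_degree

    def test_missing_provenance_flagged(self):
        g = nx.Graph()
        g.add_node("a", provenance="shared")
        stats = network_stats(g, provenance="fry_only")
        assert stats.empty and stats.n_nodes == 0

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            network_stats(nx.Graph())


class TestExport:
    def test_graphml_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        base = rng.random((10, 25))
        base[:5] *= np.exp(1.5 * rng.normal(size=25))
        rel = rel_from_matrix(base)
        g = build_network(rel, k=10, rho_min=0.7, alpha_adj=0.05)
        path = tmp_path / "net.graphml"
        export_network(g, path)
        back = read_network(path)
        assert set(back.nodes) == set(g.nodes)
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in g.edges}
        for a, b in g.edges:
            assert back.edges[a, b]["rho"] == pytest.approx(g.edges[a, b]["rho"])

    def test_empty_network_valid_file(self, tmp_path):
        g = nx.Graph()
        path = tmp_path / "empty.graphml"
        export_network(g, path)
        assert read_network(path).number_of_edges() == 0

    def test_edge_list_tsv(self, tmp_path):
        g = nx.Graph()
        g.add_edge("a", "b", rho=0.95, p_raw=1e-9, p_adj=1e-6)
        path = tmp_path / "edges.tsv"
        export_network(g, path, format="edge_list_tsv")
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 1 and df.loc[0, "rho"] == 0.95


class TestBlockRecovery:
    def test_planted_blocks_recovered(self):
        table, _, truth = ff.simulate_block_community(seed=1)
        rel = ff.to_relative_abundance(table)
        g = ff.build_network(rel, k=50, rho_min=0.9, alpha_adj=1e-4)
        true_pairs = set()
        for block in truth.blocks:
            true_pairs |= {frozenset(p) for p in itertools.combinations(block, 2)}
        found = {frozenset(e) for e in g.edges}
        tp = len(found & true_pairs)
        assert tp / max(len(found), 1) >= 0.9   # precision
        assert tp / len(true_pairs) >= 0.8      # recall
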