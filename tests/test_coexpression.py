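import math

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from ferronet.coexpression import (
    NetworkConfig,
    bait_prey_network,
    build_network,
    extract_modules,
    pearson_matrix,
)
from ferronet.synthetic_data import CompendiumSimConfig, simulate_compendium
from conftest import make_expression


def table_from_rows(rows: dict[str, list[float]]):
    genes = list(rows)
    vals = np.array([rows[g] for g in genes], dtype=float)
    n = vals.shape[1]
    return make_expression(
        vals, genes, ["compendium"] * n, list(range(1, n + 1)), scale="log2"
    )


def naive_pearson(x, y):
    """Product-moment formula written out longhand (the oracle)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


class TestPearsonMatrix:
    def test_self_correlation_is_one(self):
        t = table_from_rows({"A": [1, 2, 3, 4]})
        r = pearson_matrix(t, ["A"], NetworkConfig(min_arrays=2))
        assert r.loc["A", "A"] == 1.0

    def test_exact_anticorrelation(self):
        t = table_from_rows({"A": [1, 2, 3], "B": [3, 2, 1]})
        r = pearson_matrix(t, ["A", "B"], NetworkConfig(min_arrays=2))
        assert math.isclose(r.loc["A", "B"], -1.0, abs_tol=1e-12)

    def test_hand_computed_value(self):
        """r((1,2,3),(1,2,4)) = 1.5/sqrt(1*21/9) = 0.981981 to 1e-6."""
        t = table_from_rows({"A": [1, 2, 3], "B": [1, 2, 4]})
        r = pearson_matrix(t, ["A", "B"], NetworkConfig(min_arrays=2))
        assert math.isclose(r.loc["A", "B"], 0.981981, abs_tol=1e-6)

    def test_matches_naive_double_loop(self):
        """Random 10x20 matrices: agreement with the longhand formula to 1e-12."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            vals = rng.normal(size=(10, 20))
            genes = [f"G{i}" for i in range(10)]
            t = table_from_rows(dict(zip(genes, vals)))
            r = pearson_matrix(t, genes, NetworkConfig(min_arrays=2))
            for i in range(10):
                for j in range(10):
                    expect = 1.0 if i == j else naive_pearson(vals[i], vals[j])
                    assert math.isclose(r.iloc[i, j], expect, abs_tol=1e-12)

    def test_zero_variance_gene_yields_missing(self):
        t = table_from_rows({"A": [1, 2, 3], "B": [5, 5, 5]})
        r = pearson_matrix(t, ["A", "B"], NetworkConfig(min_arrays=2))
        assert np.isnan(r.loc["A", "B"])
        g = build_network(t, ["A", "B"], None, NetworkConfig(min_arrays=2))
        assert g.number_of_edges() == 0

    def test_absent_gene_hard_error(self):
        t = table_from_rows({"A": [1, 2, 3]})
        with pytest.raises(KeyError, match="NOPE"):
            pearson_matrix(t, ["NOPE"], NetworkConfig(min_arrays=2))

    def test_too_few_arrays_hard_error(self):
        t = table_from_rows({"A": [1, 2, 3]})
        with pytest.raises(ValueError, match="min_arrays"):
            pearson_matrix(t, ["A"], NetworkConfig(min_arrays=10))


class TestBuildNetwork:
    def test_planted_triangle_background_dropped(self):
        cfg = CompendiumSimConfig(
            n_genes=4, n_arrays=300, modules=[(3, 0.9)], seed=21
        )
        table, truth = simulate_compendium(cfg)
        g = build_network(table, table.gene_ids, None, NetworkConfig())
        module_genes = set(truth.module_assignment)
        assert set(g.nodes) == module_genes
        assert g.number_of_edges() == 3  # a triangle

    def test_unit_cutoff_empty_on_noise(self):
        cfg = CompendiumSimConfig(n_genes=10, n_arrays=50, modules=[], seed=3)
        table, _ = simulate_compendium(cfg)
        g = build_network(table, table.gene_ids, None, NetworkConfig(r_cutoff=1.0))
        assert g.number_of_edges() == 0

    def test_deterministic(self):
        cfg = CompendiumSimConfig(n_genes=30, n_arrays=100, modules=[(10, 0.8)], seed=5)
        table, _ = simulate_compendium(cfg)
        g1 = build_network(table, table.gene_ids, None, NetworkConfig())
        g2 = build_network(table, table.gene_ids, None, NetworkConfig())
        assert set(g1.edges) == set(g2.edges)

    def test_threshold_monotonicity(self):
        cfg = CompendiumSimConfig(n_genes=40, n_arrays=60, modules=[(15, 0.7)], seed=8)
        table, _ = simulate_compendium(cfg)
        edges = {
            cut: set(
                build_network(
                    table, table.gene_ids, None,
                    NetworkConfig(r_cutoff=cut, drop_isolated=False),
                ).edges
            )
            for cut in (0.7, 0.8)
        }
        assert edges[0.8] <= edges[0.7]


class TestExtractModules:
    def graph_from_edges(self, edges):
        g = nx.Graph()
        for a, b in edges:
            g.add_edge(a, b, r=0.9)
        return g

    def test_two_components_named_by_size(self):
        g = self.graph_from_edges([("A", "B"), ("B", "C"), ("D", "E")])
        modules = extract_modules(g)
        assert [m.name for m in modules] == ["M1", "M2"]
        assert modules[0].members == {"A", "B", "C"}
        assert modules[1].members == {"D", "E"}

    def test_tie_broken_by_smallest_member(self):
        g = self.graph_from_edges([("X", "Y"), ("A", "B")])
        modules = extract_modules(g)
        assert modules[0].members == {"A", "B"}

    def test_empty_graph(self):
        assert extract_modules(nx.Graph()) == []

    def test_no_edges_cross_between_modules(self):
        cfg = CompendiumSimConfig(
            n_genes=100, n_arrays=300, modules=[(12, 0.85), (8, 0.85)], seed=13
        )
        table, _ = simulate_compendium(cfg)
        g = build_network(table, table.gene_ids, None, NetworkConfig())
        modules = extract_modules(g)
        for i, mi in enumerate(modules):
            for mj in modules[i + 1 :]:
                for a in mi.members:
                    assert not (set(g.neighbors(a)) & mj.members)

    def test_planted_module_recovery_ari(self):
        """Planted 30/20/10 modules at within-corr 0.85 over 300 arrays:
        the recovered partition matches the planted one with ARI >= 0.95
        and no background gene joins a module."""
        cfg = CompendiumSimConfig(
            n_genes=1000, n_arrays=300,
            modules=[(30, 0.85), (20, 0.85), (10, 0.85)], seed=17,
        )
        table, truth = simulate_compendium(cfg)
        g = build_network(table, table.gene_ids, None, NetworkConfig())
        modules = extract_modules(g)
        recovered = {gene: m.name for m in modules for gene in m.members}
        genes = table.gene_ids
        planted_labels = [str(truth.module_assignment.get(x, "bg")) for x in genes]
        found_labels = [recovered.get(x, "bg") for x in genes]
        assert adjusted_rand_score(planted_labels, found_labels) >= 0.95
        background = set(genes) - set(truth.module_assignment)
        assert not (set(recovered) & background)


class TestBaitPrey:
    def test_micro_example_rules(self):
        """Baits {K1}, preys {P1,P2} with r(K1,P1) high, r(P1,P2) high,
        r(K1,P2) low: only the K1-P1 edge survives and P2 is dropped."""
        rng = np.random.default_rng(0)
        # K1~P1 strong, P1~P2 strong, K1~P2 weak
        a = rng.normal(size=300)
        b = rng.normal(size=300)
        k1 = a
        p1 = 0.8 * a + 0.6 * b
        p2 = 0.35 * a + 0.937 * b
        t = table_from_rows({"K1": list(k1), "P1": list(p1), "P2": list(p2)})
        r = pearson_matrix(t, ["K1", "P1", "P2"], NetworkConfig(min_arrays=2))
        assert r.loc["K1", "P1"] >= 0.7
        assert r.loc["P1", "P2"] >= 0.7
        assert r.loc["K1", "P2"] < 0.7
        g = bait_prey_network(t, ["K1"], ["P1", "P2"], None, NetworkConfig(min_arrays=2))
        assert set(g.edges) == {("K1", "P1")}
        assert set(g.nodes) == {"K1", "P1"}

    def test_no_bait_correlation_empty_graph(self):
        cfg = CompendiumSimConfig(n_genes=10, n_arrays=100, modules=[], seed=33)
        table, _ = simulate_compendium(cfg)
        genes = table.gene_ids
        g = bait_prey_network(table, genes[:3], genes[3:], None, NetworkConfig())
        assert g.number_of_nodes() == 0

    def test_overlapping_baits_preys_rejected(self):
        cfg = CompendiumSimConfig(n_genes=5, n_arrays=20, modules=[], seed=1)
        table, _ = simulate_compendium(cfg)
        genes = table.gene_ids
        with pytest.raises(ValueError, match=genes[1]):
            bait_prey_network(table, genes[:2], genes[1:], None, NetworkConfig(min_arrays=2))

    def test_prey_only_module_removed_entirely(self):
        """A planted module of 2 baits + 10 preys survives; a prey-only
        module is erased by the two-prey edge exclusion."""
        cfg = CompendiumSimConfig(
            n_genes=30, n_arrays=300, modules=[(12, 0.85), (8, 0.85)], seed=44
        )
        table, truth = simulate_compendium(cfg)
        m0 = sorted(g for g, m in truth.module_assignment.items() if m == 0)
        m1 = sorted(g for g, m in truth.module_assignment.items() if m == 1)
        baits = set(m0[:2])
        preys = (set(table.gene_ids) - baits)
        g = bait_prey_network(table, baits, preys, None, NetworkConfig())
        assert set(g.nodes) == set(m0)
        assert not (set(g.nodes) & set(m1))

    def test_soundness_invariants(self):
        """No prey-prey edge, no isolated node, only bait-bait and
        bait-prey edges — on every output."""
        cfg = CompendiumSimConfig(
            n_genes=60, n_arrays=300, modules=[(10, 0.85), (10, 0.85)], seed=55
        )
        table, truth = simulate_compendium(cfg)
        members = sorted(truth.module_assignment)
        baits = set(members[::3])
        preys = set(table.gene_ids) - baits
        g = bait_prey_network(table, baits, preys, None, NetworkConfig())
        for a, b in g.edges:
            assert a in baits or b in baits
        for n, d in g.degree():
            assert d > 0
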