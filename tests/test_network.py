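import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from txlandscape import network, simulate
from txlandscape.network import (
    EnrichmentInput,
    assemble_candidate_genes,
    detect_modules,
    fisher_enrichment,
    induced_network,
    network_stats,
    random_network_null,
    z_score,
)


class TestFeatureSet:
    def test_disjoint_sets(self):
        fs = assemble_candidate_genes({"a", "b", "c"}, {"d", "e"}, {"f"})
        assert len(fs.union) == 6
        counts = fs.venn_counts()
        assert counts["de_as"] == counts["de_snv"] == counts["de_as_snv"] == 0

    def test_empty_union_errors(self):
        with pytest.raises(ValueError, match="empty candidate"):
            assemble_candidate_genes(set(), set(), set())

    def test_venn_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        universe = [f"G{i}" for i in range(40)]
        d, a, s = (set(rng.choice(universe, 15)) for _ in range(3))
        fs = assemble_candidate_genes(d, a, s)
        counts = fs.venn_counts()
        du, au, su = ({g.upper() for g in x} for x in (d, a, s))
        assert sum(counts.values()) == len(du | au | su)
        assert counts["de_as_snv"] == len(du & au & su)
        assert counts["de"] == len(du - au - su)

    def test_symbols_harmonized(self):
        fs = assemble_candidate_genes({"mpg"}, {"MPG"}, {"Mpg"})
        assert fs.venn_counts()["de_as_snv"] == 1


class TestInducedNetwork:
    def test_linker_excluded(self):
        g = nx.Graph([("A", "B"), ("A", "X")])
        model = induced_network({"A", "B", "C"}, g)
        assert set(model.nodes) == {"A", "B"}
        assert model.number_of_edges() == 1

    def test_no_internal_edges_gives_empty_model(self):
        g = nx.Graph([("A", "X"), ("B", "Y")])
        model = induced_network({"A", "B"}, g)
        assert model.number_of_nodes() == 0

    def test_matches_bruteforce_subgraph(self):
        rng = np.random.default_rng(1)
        g = nx.gnp_random_graph(30, 0.15, seed=2)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
        for _ in range(5):
            cand = set(rng.choice(sorted(g.nodes), 12, replace=False))
            model = induced_network(cand, g)
            edges = {frozenset(e) for e in g.edges if set(e) <= {c.upper() for c in cand}}
            nodes = {n for e in edges for n in e}
            assert {frozenset(e) for e in model.edges} == edges
            assert set(model.nodes) == nodes


class TestNetworkStats:
    def test_star_graph(self):
        g = nx.star_graph(4)
        table = network_stats(g).set_index("gene")
        assert table.loc[0, "degree"] == 4
        leaves = table.drop(index=0)
        assert (leaves["degree"] == 1).all()
        assert (leaves["neighborhood_connectivity"] == 4).all()

    def test_threshold_counts_match_bruteforce(self):
        g = nx.gnp_random_graph(60, 0.15, seed=3)
        table = network_stats(g)
        degs = [d for _, d in g.degree]
        assert table.attrs["n_degree_ge5"] == sum(d >= 5 for d in degs)
        assert table.attrs["n_degree_ge10"] == sum(d >= 10 for d in degs)

    def test_empty_model(self):
        table = network_stats(nx.Graph())
        assert len(table) == 0
        assert table.attrs["n_degree_ge5"] == 0


class TestRandomNull:
    def test_full_universe_draw_degenerate(self):
        g = nx.gnp_random_graph(8, 0.4, seed=4)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
        null = random_network_null(sorted(g.nodes), 8, g, n_draws=5, seed=0)
        assert null.sd_nodes == 0 and null.sd_edges == 0

    def test_exhaustive_matches_enumeration_oracle(self):
        g = nx.gnp_random_graph(10, 0.3, seed=5)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
        universe = sorted(g.nodes)
        null = random_network_null(universe, 3, g, exhaustive=True)
        # brute-force oracle: count nodes/edges in each induced subgraph
        nodes, edges = [], []
        for sub in itertools.combinations(universe, 3):
            e = [ed for ed in g.edges if set(ed) <= set(sub)]
            n = {v for ed in e for v in ed}
            nodes.append(len(n))
            edges.append(len(e))
        assert null.mean_nodes == pytest.approx(np.mean(nodes))
        assert null.mean_edges == pytest.approx(np.mean(edges))
        # Monte Carlo agrees within sampling error
        mc = random_network_null(universe, 3, g, n_draws=400, seed=1)
        assert mc.mean_edges == pytest.approx(np.mean(edges), abs=0.3)

    def test_z_from_printed_summary_exceeds_five(self):
        # an observed 244-node model against a null of mean 108, sd 22
        assert z_score(244, 108, 22) > 5

    def test_degenerate_sd_conventions(self):
        assert z_score(5, 5, 0) == 0
        assert z_score(6, 5, 0) == np.inf

    def test_uniform_draws_are_typical_of_their_own_null(self):
        g = nx.gnp_random_graph(80, 0.08, seed=6)
        g = nx.relabel_nodes(g, {i: f"G{i}" for i in g.nodes})
        universe = sorted(g.nodes)
        rng = np.random.default_rng(7)
        inside = 0
        for rep in range(20):
            obs = induced_network(set(rng.choice(universe, 25, replace=False)), g)
            null = random_network_null(universe, 25, g, n_draws=30, seed=100 + rep)
            if abs(null.z_edges(obs.number_of_edges())) <= 3:
                inside += 1
        assert inside >= 18


class TestModules:
    def test_two_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(4))
        modules = detect_modules(g, seed=0)
        assert len(set(modules.values())) == 2

    def test_single_edge(self):
        modules = detect_modules(nx.Graph([("A", "B")]), seed=0)
        assert len(set(modules.values())) == 1

    def test_planted_sbm_partition_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        cfg = simulate.SimulationConfig(seed=13)
        graph, _, truth = simulate.generate_network_and_sets(cfg)
        model = induced_network(set(truth.communities), graph)
        modules = detect_modules(model, seed=1)
        common = sorted(set(modules) & set(truth.communities))
        ari = adjusted_rand_score(
            [truth.communities[g] for g in common], [modules[g] for g in common]
        )
        assert ari >= 0.9

    def test_deterministic_given_seed(self):
        g = nx.gnp_random_graph(40, 0.2, seed=8)
        assert detect_modules(g, seed=5) == detect_modules(g, seed=5)


def _exhaustive_fisher_oracle(G, N, P, m):
    """Upper-tail probability by explicit enumeration of all tables."""
    total = 0.0
    for mm in range(max(0, N + P - G), min(N, P) + 1):
        p_table = (
            stats.hypergeom.pmf(mm, G, P, N)
        )
        if mm >= m:
            total += p_table
    return total


class TestFisherEnrichment:
    @pytest.mark.parametrize(
        "P,m,expected",
        [(6, 4, 2.82e-2), (9, 6, 6.43e-3), (9, 8, 5.39e-5), (23, 14, 9.59e-5), (33, 23, 9.59e-9)],
    )
    def test_printed_pathway_rows(self, P, m, expected):
        _, p = fisher_enrichment(EnrichmentInput(G=1055, N=244, P=P, m=m))
        assert p == pytest.approx(expected, rel=5e-3)

    def test_zero_overlap_gives_p_one(self):
        _, p = fisher_enrichment(EnrichmentInput(G=20, N=5, P=4, m=0))
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small(self):
        for G in range(4, 13):
            for N in range(1, G + 1):
                for P in range(1, G - N + min(N, G) + 1):
                    if P > G:
                        continue
                    for m in range(max(0, N + P - G), min(N, P) + 1):
                        _, p = fisher_enrichment(EnrichmentInput(G, N, P, m))
                        assert p == pytest.approx(
                            _exhaustive_fisher_oracle(G, N, P, m), abs=1e-10
                        )

    def test_monotone_in_m(self):
        ps = [fisher_enrichment(EnrichmentInput(100, 30, 10, m))[1] for m in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_negative_cell_errors(self):
        with pytest.raises(ValueError, match="negative contingency cell"):
            EnrichmentInput(G=10, N=9, P=9, m=0).table()


class TestValidationFlags:
    def test_planted_de_flagged_and_null_calibrated(self):
        cfg = simulate.SimulationConfig(seed=17, n_genes=120, n_de_genes=8)
        counts, truth = simulate.generate_cohort_counts(cfg)
        groups = simulate.sample_groups(cfg)
        flags = network.validation_de_flags(counts, groups, "HER2")
        planted = list(truth.de_genes)
        hit = flags.loc[planted].all(axis=1).mean()
        assert hit >= 0.9
        # per-comparison flag rate on non-planted genes stays near alpha
        null_rate = flags.drop(index=planted).to_numpy().mean()
        assert null_rate <= 0.06

    def test_missing_gene_unflagged(self):
        cfg = simulate.SimulationConfig(seed=18, n_genes=20, n_de_genes=2)
        counts, _ = simulate.generate_cohort_counts(cfg)
        counts.iloc[0] = np.nan
        groups = simulate.sample_groups(cfg)
        flags = network.validation_de_flags(counts, groups, "HER2")
        assert not flags.iloc[0].any()
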