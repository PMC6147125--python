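import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from paddyweb import conet
from paddyweb.conet import (
    AbundanceTable,
    CorrelationMatrices,
    aggregate_families,
    bh_fdr,
    build_network,
    modularity,
    module_profiles,
    node_degrees,
    partition_modules,
    prevalence_filter,
    spearman_all_pairs,
)
from paddyweb.errors import ValidationError

from .oracles import bh_brute, best_partition_brute, modularity_brute, spearman_brute


class TestAggregateFamilies:
    def test_counts_sum_within_family(self, small_table):
        fam = aggregate_families(small_table)
        # otu1 + otu2 share Ruminococcaceae: 5 + 7 = 12 in sample s1
        assert fam.counts.loc["Ruminococcaceae", "s1"] == 12

    def test_order_level_taxa_dropped_and_counts_conserved(self, small_table):
        fam = aggregate_families(small_table)
        assert set(fam.counts.index) == {"Ruminococcaceae", "Methanosarcinaceae"}
        assert fam.counts.values.sum() <= small_table.counts.values.sum()
        retained = small_table.counts.drop(index="otu4")
        assert fam.counts.values.sum() == retained.values.sum()

    def test_no_family_assignments_rejected(self, small_table):
        lineage = {t: "Bacteria;Firmicutes" for t in small_table.counts.index}
        table = AbundanceTable(small_table.counts, lineage, small_table.metadata)
        with pytest.raises(ValidationError):
            aggregate_families(table)


class TestPrevalenceFilter:
    def test_half_permille_boundary_is_inclusive(self, small_table):
        # grand total 10000: family at exactly 5 reads (0.5 permille)
        # is retained, 4 reads is discarded
        counts = pd.DataFrame(
            {"s%d" % i: [2491, 1, 1] for i in range(1, 5)},
            index=["big", "edge", "rare"],
        )
        counts.loc["edge"] = [2, 1, 1, 1]  # 5 total
        counts.loc["rare"] = [1, 1, 1, 1]  # 4 total
        counts.loc["big"] = [2498, 2497, 2498, 2498]  # fill to 10000
        assert counts.values.sum() == 10000
        from .conftest import make_metadata

        table = AbundanceTable(
            counts, {f: f"d;p;c;o;{f}" for f in counts.index},
            make_metadata(counts.columns, [5, 11, 16, 23]),
        )
        kept = prevalence_filter(table, threshold=5e-4)
        assert "edge" in kept.counts.index
        assert "rare" not in kept.counts.index

    @pytest.mark.parametrize("threshold", [0.0, 1.0, -0.1])
    def test_threshold_outside_open_interval_rejected(self, small_table, threshold):
        with pytest.raises(ValidationError):
            prevalence_filter(small_table, threshold=threshold)

    def test_filter_removing_all_families_rejected(self, small_table):
        with pytest.raises(ValidationError):
            prevalence_filter(small_table, threshold=0.999)


class TestSpearman:
    def test_tied_example_matches_hand_computation(self):
        relab = pd.DataFrame(
            [[1, 2, 3, 4, 5], [5, 6, 7, 8, 7]], index=["a", "b"], dtype=float
        )
        corr = spearman_all_pairs(relab)
        assert corr.rho[0, 1] == pytest.approx(8 / math.sqrt(95), abs=1e-12)
        assert corr.rho[0, 1] == pytest.approx(0.8208, abs=1e-4)

    def test_monotone_transform_gives_unit_rho(self):
        x = np.array([0.3, 1.2, 2.0, 5.5, 9.1])
        relab = pd.DataFrame([x, np.exp(x)], index=["a", "b"])
        corr = spearman_all_pairs(relab)
        assert corr.rho[0, 1] == pytest.approx(1.0)

    def test_constant_family_recorded_as_zero(self):
        relab = pd.DataFrame(
            [[1, 1, 1, 1], [1, 2, 3, 4], [2, 1, 4, 3]], index=list("abc"), dtype=float
        )
        corr = spearman_all_pairs(relab)
        assert corr.rho[0, 1] == 0.0
        assert corr.p[0, 1] == 1.0

    def test_matches_brute_force_and_scipy_on_random_tables(self, rng):
        for _ in range(30):
            data = rng.integers(0, 50, size=(10, 8)).astype(float)
            relab = pd.DataFrame(data, index=[f"f{i}" for i in range(10)])
            corr = spearman_all_pairs(relab)
            scipy_rho = stats.spearmanr(data, axis=1).statistic
            for i in range(10):
                for j in range(i + 1, 10):
                    brute = spearman_brute(data[i], data[j])
                    assert corr.rho[i, j] == pytest.approx(brute, abs=1e-12)
                    if not math.isnan(scipy_rho[i, j]):
                        assert corr.rho[i, j] == pytest.approx(scipy_rho[i, j], abs=1e-12)

    def test_p_values_match_scipy_t_approximation(self, rng):
        data = rng.normal(size=(6, 12))
        corr = spearman_all_pairs(pd.DataFrame(data))
        for i in range(6):
            for j in range(i + 1, 6):
                rho_s, p_s = stats.spearmanr(data[i], data[j])
                assert corr.p[i, j] == pytest.approx(p_s, abs=1e-10)

    def test_fewer_than_four_samples_rejected(self):
        with pytest.raises(ValidationError):
            spearman_all_pairs(pd.DataFrame([[1, 2, 3], [3, 2, 1]]))

    def test_q_never_below_p(self, rng):
        data = rng.poisson(20, size=(8, 10)).astype(float)
        corr = spearman_all_pairs(pd.DataFrame(data))
        iu = np.triu_indices(8, k=1)
        assert (corr.q[iu] >= corr.p[iu] - 1e-15).all()
        assert np.allclose(corr.q, corr.q.T)


class TestBhFdr:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.005, 0.009, 0.05], [0.0135, 0.0135, 0.05]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.37], [0.37]),
        ],
    )
    def test_hand_computed_step_up_examples(self, p, expected):
        assert bh_fdr(np.array(p)) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_step_up(self, p):
        p = np.array(p)
        assert bh_fdr(p) == pytest.approx(bh_brute(p), abs=1e-12)

    def test_order_preserving(self, rng):
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr(np.array([0.5, 1.5]))


def matrices_from(rho_pairs, q_pairs, families):
    k = len(families)
    rho = np.eye(k)
    p = np.zeros((k, k))
    q = np.zeros((k, k))
    for (i, j), r in rho_pairs.items():
        rho[i, j] = rho[j, i] = r
    for (i, j), v in q_pairs.items():
        q[i, j] = q[j, i] = v
        p[i, j] = p[j, i] = v / 2
    return CorrelationMatrices(families=families, rho=rho, p=p, q=q, n_samples=15)


class TestBuildNetwork:
    def test_threshold_triple(self):
        fams = ["a", "b", "c", "d"]
        corr = matrices_from(
            {(0, 1): 0.75, (0, 2): 0.95, (0, 3): -0.8, (1, 2): 0.7, (1, 3): 0.65},
            {(0, 1): 0.005, (0, 2): 0.001, (0, 3): 0.001, (1, 2): 0.5, (1, 3): 0.0099},
            fams,
        )
        net = build_network(corr)
        assert net.graph.has_edge("a", "b")  # in window, significant
        assert not net.graph.has_edge("a", "c")  # rho above 0.9
        assert not net.graph.has_edge("a", "d")  # negative correlation
        assert not net.graph.has_edge("b", "c")  # not significant
        assert net.graph.has_edge("b", "d")  # q = 0.0099 < 0.01
        assert net.graph.nodes["c"]["degree"] == 0  # isolated but retained

    def test_every_emitted_edge_satisfies_thresholds(self, rng):
        data = rng.poisson(30, size=(12, 15)).astype(float)
        corr = spearman_all_pairs(pd.DataFrame(data, index=[f"f{i}" for i in range(12)]))
        net = build_network(corr)
        for u, v, d in net.graph.edges(data=True):
            assert 0.6 <= d["rho"] <= 0.9
            assert d["q"] < 0.01


def two_triangles_bridge() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")])
    return g


class TestModularity:
    def test_two_triangles_partition_value(self):
        g = two_triangles_bridge()
        part = {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1}
        assert modularity(g, part) == pytest.approx(5 / 14, abs=1e-12)

    def test_single_community_is_zero(self):
        g = two_triangles_bridge()
        assert modularity(g, {n: 0 for n in g.nodes}) == pytest.approx(0.0, abs=1e-15)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 12))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(1 << 30)))
            labels = rng.integers(0, 3, size=n)
            part = {i: int(labels[i]) for i in g.nodes}
            brute = modularity_brute(nx.to_numpy_array(g), labels)
            assert modularity(g, part) == pytest.approx(brute, abs=1e-12)


def as_conet(g: nx.Graph) -> conet.CoNetwork:
    for n in g.nodes:
        g.nodes[n]["degree"] = g.degree[n]
    return conet.CoNetwork(graph=g, rho_min=0.6, rho_max=0.9, alpha=0.01)


class TestPartitionModules:
    def test_greedy_recovers_two_triangles(self):
        net = partition_modules(as_conet(two_triangles_bridge()), "greedy")
        mods = net.modules
        assert mods["a"] == mods["b"] == mods["c"]
        assert mods["d"] == mods["e"] == mods["f"]
        assert mods["a"] != mods["d"]
        assert net.modularity_score == pytest.approx(5 / 14, abs=1e-12)

    def test_empty_graph_yields_singletons_with_zero_q(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        net = partition_modules(as_conet(g), "greedy")
        assert len(set(net.modules.values())) == 3
        assert net.modularity_score == 0.0

    def test_greedy_attains_exhaustive_optimum_on_small_graphs(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(20):
            n = int(rng.integers(5, 9))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
            net = partition_modules(as_conet(g), "greedy")
            best_q, _ = best_partition_brute(nx.to_numpy_array(g, nodelist=sorted(g.nodes)))
            if net.modularity_score >= best_q - 1e-12:
                hits += 1
        assert hits >= 18

    def test_louvain_partitions_two_triangles(self):
        net = partition_modules(as_conet(two_triangles_bridge()), "louvain", seed=3)
        mods = net.modules
        assert mods["a"] == mods["b"] == mods["c"]
        assert mods["d"] == mods["e"] == mods["f"]

    def test_deterministic_given_seed(self):
        g = nx.gnp_random_graph(20, 0.2, seed=5)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        p1 = partition_modules(as_conet(g.copy()), "louvain", seed=11).modules
        p2 = partition_modules(as_conet(g.copy()), "louvain", seed=11).modules
        assert p1 == p2


class TestNodeDegreesAndProfiles:
    def test_degrees_of_two_triangle_graph(self):
        g = two_triangles_bridge()
        g.add_node("iso")
        net = as_conet(g)
        deg = node_degrees(net)
        assert deg["c"] == deg["d"] == 3
        assert deg["iso"] == 0
        assert sum(deg.values()) == 2 * g.number_of_edges()

    def test_module_abundances_sum_to_one_per_day(self, small_table):
        fam = aggregate_families(small_table)
        g = nx.Graph()
        g.add_nodes_from(fam.counts.index)
        net = partition_modules(as_conet(g), "greedy")
        module_series, _ = module_profiles(net, fam)
        per_day = module_series.groupby("day")["mean_abundance"].sum()
        assert np.allclose(per_day.values, 1.0)

    def test_single_family_module_tracks_its_abundance(self):
        from .conftest import make_metadata

        counts = pd.DataFrame(
            {"s1": [1, 9], "s2": [2, 8], "s3": [3, 7], "s4": [4, 6]},
            index=["solo", "rest"],
        )
        table = AbundanceTable(
            counts, {f: f"d;p;c;o;{f}" for f in counts.index},
            make_metadata(counts.columns, [5, 11, 16, 23]),
        )
        g = nx.Graph()
        g.add_nodes_from(["solo", "rest"])
        net = partition_modules(as_conet(g), "greedy")
        series, _ = module_profiles(net, table)
        solo_mod = net.modules["solo"]
        solo = series[series["module"] == solo_mod].sort_values("day")
        assert solo["mean_abundance"].tolist() == pytest.approx([0.1, 0.2, 0.3, 0.4])
        assert (series["se_abundance"] == 0).all()  # single replicate

    def test_family_missing_from_table_rejected(self, small_table):
        fam = aggregate_families(small_table)
        g = nx.Graph()
        g.add_node("Nonexistaceae")
        net = partition_modules(as_conet(g), "greedy")
        with pytest.raises(ValidationError):
            module_profiles(net, fam)


class TestSpearmanOptions:
    def test_permutation_p_agrees_with_t_for_strong_signal(self, rng):
        data = rng.normal(size=(5, 14))
        data[1] = data[0] + rng.normal(scale=0.3, size=14)  # strongly correlated pair
        relab = pd.DataFrame(data)
        t_corr = spearman_all_pairs(relab, method="t")
        perm = spearman_all_pairs(relab, method="permutation", n_permutations=2000, seed=1)
        assert np.allclose(perm.rho, t_corr.rho)
        assert perm.p[0, 1] < 0.01 and t_corr.p[0, 1] < 0.01
        assert ((perm.p >= 0) & (perm.p <= 1)).all()

    def test_permutation_p_deterministic_given_seed(self, rng):
        relab = pd.DataFrame(rng.poisson(20, size=(6, 10)).astype(float))
        a = spearman_all_pairs(relab, method="permutation", n_permutations=500, seed=3)
        b = spearman_all_pairs(relab, method="permutation", n_permutations=500, seed=3)
        assert np.array_equal(a.p, b.p)

    def test_replicate_mean_view_collapses_to_days(self, small_table):
        fam = aggregate_families(small_table)
        relab = fam.relative_abundance()
        avg = conet.replicate_mean_view(relab, fam.metadata)
        assert avg.shape == (2, 3)  # 2 families x 3 days
        day5 = fam.metadata.index[fam.metadata["day"] == 5]
        assert avg["d5"].values == pytest.approx(relab[day5].mean(axis=1).values)
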