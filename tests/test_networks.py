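"""Spearman statistics, typed network construction, census and persistence."""

import numpy as np
import pandas as pd
import pytest

import networkx as nx

from fmt_rewire.containers import FeatureTable
from fmt_rewire.networks import (
    MET_MET,
    TypedNetwork,
    build_network,
    class_pair,
    count_class_pairs,
    edge_persistence,
    export_network,
    load_edgelist_tsv,
    load_graphml,
    spearman,
)


class TestSpearman:
    def test_worked_five_point_example(self):
        # tie-free: rho = 1 - 6*sum(d^2)/(n(n^2-1)), d = (1,1,1,1,0) -> sum 4
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(1 - 6 * 4 / (5 * 24))
        assert rho == pytest.approx(0.8)

    def test_perfect_and_reversed(self):
        x = [3.0, 1.0, 4.0, 1.5, 9.0]
        assert spearman(x, x)[0] == pytest.approx(1.0)
        assert spearman(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_exact_permutation_p_for_perfect_monotone(self):
        # P(|rho| = 1) over all 5! orders = 2/120
        _, p = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert p == pytest.approx(2 / 120)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [3, 2, 1])


def _tables_from_frames(clin=None, taxa=None, mets=None):
    tables = []
    for df, cls in ((clin, "clinical"), (taxa, "taxon"), (mets, "metabolite")):
        if df is not None:
            tables.append(FeatureTable(df, cls))
    return tables


class TestBuildNetwork:
    def test_planted_monotone_pair_is_recovered(self):
        rng = np.random.default_rng(0)
        n = 10
        z = rng.normal(size=n)
        taxa = pd.DataFrame(
            {"t_sig": np.exp(z), **{f"t{i}": rng.random(n) for i in range(5)}},
            index=[f"s{i}" for i in range(n)],
        )
        mets = pd.DataFrame(
            {"m_sig": np.exp(z), **{f"m{i}": rng.random(n) for i in range(5)}},
            index=taxa.index,
        )
        net = build_network(_tables_from_frames(taxa=taxa, mets=mets), taxa.index,
                            min_prevalence=0.0)
        assert ("m_sig", "t_sig") in net.edges
        assert net.graph.edges["t_sig", "m_sig"]["sign"] == "positive"

    def test_independent_noise_yields_few_edges(self):
        """20 independent features at n=30: <=2 chance edges in >=90% of seeds."""
        ok = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            idx = [f"s{i}" for i in range(30)]
            taxa = pd.DataFrame(rng.random((30, 10)), index=idx,
                                columns=[f"t{i}" for i in range(10)])
            mets = pd.DataFrame(rng.random((30, 10)), index=idx,
                                columns=[f"m{i}" for i in range(10)])
            net = build_network(_tables_from_frames(taxa=taxa, mets=mets), idx,
                                min_prevalence=0.0)
            ok += net.graph.number_of_edges() <= 2
        assert ok >= 0.9 * n_seeds

    def test_monotone_transform_duplicate_gets_rho_one(self):
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(12)]
        taxa = pd.DataFrame({"t1": rng.random(12) + 0.1}, index=idx)
        mets = pd.DataFrame({"m1": taxa["t1"] ** 3}, index=idx)
        net = build_network(_tables_from_frames(taxa=taxa, mets=mets), idx,
                            min_prevalence=0.0)
        assert net.graph.edges["t1", "m1"]["rho"] == pytest.approx(1.0)

    def test_sample_order_invariance(self, default_cohort):
        taxa, mets, clin, meta, _ = default_cohort
        samples = meta.baseline_samples()
        net1 = build_network([clin, taxa, mets], samples)
        net2 = build_network([clin, taxa, mets], list(reversed(samples)))
        assert set(net1.edges) == set(net2.edges)

    def test_clinical_clinical_pairs_excluded_by_default(self, default_cohort):
        taxa, mets, clin, meta, _ = default_cohort
        samples = meta.baseline_samples()
        net = build_network([clin, taxa, mets], samples)
        assert all(net.edge_class_pair(a, b) != class_pair("clinical", "clinical")
                   for a, b in net.edges)

    def test_constant_feature_skipped_and_logged(self):
        rng = np.random.default_rng(2)
        idx = [f"s{i}" for i in range(10)]
        taxa = pd.DataFrame({"flat": np.ones(10), "t1": rng.random(10)}, index=idx)
        net = build_network(_tables_from_frames(taxa=taxa), idx, min_prevalence=0.0)
        assert "flat" in net.skipped_constant
        assert "flat" not in net.graph.nodes

    def test_too_few_samples_rejected(self):
        taxa = pd.DataFrame({"t1": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        with pytest.raises(ValueError):
            build_network(_tables_from_frames(taxa=taxa), ["a", "b", "c"])


def _toy_net(edges, context="baseline"):
    """edges: list of (a, a_class, b, b_class, rho)."""
    g = nx.Graph()
    for a, ca, b, cb, rho in edges:
        g.add_node(a, node_class=ca)
        g.add_node(b, node_class=cb)
        g.add_edge(a, b, rho=rho, p=0.01, sign="positive" if rho > 0 else "negative")
    return TypedNetwork(g, context=context)


class TestCensus:
    def test_counts_and_metabolite_exclusion(self):
        net = _toy_net([
            ("m1", "metabolite", "m2", "metabolite", 0.9),
            ("m1", "metabolite", "m3", "metabolite", 0.8),
            ("m4", "metabolite", "m5", "metabolite", -0.7),
            ("t1", "taxon", "m1", "metabolite", 0.7),
            ("t2", "taxon", "m2", "metabolite", -0.9),
        ])
        census = count_class_pairs(net)
        assert census["metabolite-metabolite"] == 3
        assert census["metabolite-taxon"] == 2
        assert census["total"] == 5
        assert census["total_after_exclusion"] == 2

    def test_empty_network(self):
        census = count_class_pairs(TypedNetwork(nx.Graph()))
        assert census == {"total": 0, "total_after_exclusion": 0}

    def test_no_exclusion(self):
        net = _toy_net([("m1", "metabolite", "m2", "metabolite", 0.9)])
        census = count_class_pairs(net, exclude=set())
        assert census["total_after_exclusion"] == census["total"] == 1


class TestPersistence:
    def test_identical_networks_fraction_one(self, default_cohort):
        taxa, mets, clin, meta, _ = default_cohort
        net = build_network([clin, taxa, mets], meta.baseline_samples())
        assert edge_persistence(net, net).fraction == 1.0

    def test_disjoint_edge_sets_fraction_zero(self):
        a = _toy_net([("t1", "taxon", "m1", "metabolite", 0.9)])
        b = _toy_net([("t2", "taxon", "m2", "metabolite", 0.9)], context="post")
        res = edge_persistence(a, b)
        assert res.fraction == 0.0
        assert res.baseline_only == {("m1", "t1")}
        assert res.post_only == {("m2", "t2")}

    def test_sign_flip_breaks_persistence_unless_ignored(self):
        a = _toy_net([("t1", "taxon", "m1", "metabolite", 0.9)])
        b = _toy_net([("t1", "taxon", "m1", "metabolite", -0.9)], context="post")
        assert edge_persistence(a, b).fraction == 0.0
        assert edge_persistence(a, b, require_sign_match=False).fraction == 1.0

    def test_metabolite_pairs_excluded_symmetrically(self):
        shared = [("m1", "metabolite", "m2", "metabolite", 0.9)]
        a = _toy_net(shared + [("t1", "taxon", "m3", "metabolite", 0.9)])
        b = _toy_net(shared, context="post")
        res = edge_persistence(a, b)
        # the only eligible baseline edge (t1-m3) does not recur
        assert res.fraction == 0.0

    def test_empty_baseline_after_exclusion_undefined(self):
        a = _toy_net([("m1", "metabolite", "m2", "metabolite", 0.9)])
        b = _toy_net([], context="post")
        res = edge_persistence(a, b)
        assert not res.defined

    def test_fraction_bounded(self, default_cohort):
        taxa, mets, clin, meta, _ = default_cohort
        nb = build_network([clin, taxa, mets], meta.baseline_samples())
        np_ = build_network([clin, taxa, mets], meta.post_samples(), context="post")
        res = edge_persistence(nb, np_)
        assert 0.0 <= res.fraction <= 1.0


class TestExport:
    def test_graphml_round_trip_preserves_census(self, tmp_path, default_cohort):
        taxa, mets, clin, meta, _ = default_cohort
        net = build_network([clin, taxa, mets], meta.baseline_samples())
        path = tmp_path / "net.graphml"
        export_network(net, path, format="graphml")
        back = load_graphml(path)
        assert count_class_pairs(back) == count_class_pairs(net)

    def test_edgelist_round_trip(self, tmp_path):
        net = _toy_net([
            ("t1", "taxon", "m1", "metabolite", 0.7),
            ("c1", "clinical", "t1", "taxon", -0.8),
            ("m1", "metabolite", "m2", "metabolite", 0.9),
        ])
        path = tmp_path / "edges.tsv"
        export_network(net, path, format="edgelist-tsv")
        assert len(pd.read_csv(path, sep="\t")) == 3
        back = load_edgelist_tsv(path)
        assert count_class_pairs(back) == count_class_pairs(net)

    def test_empty_network_exports(self, tmp_path):
        path = tmp_path / "empty.tsv"
        export_network(TypedNetwork(nx.Graph()), path, format="edgelist-tsv")
        assert pd.read_csv(path, sep="\t").empty

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_network(TypedNetwork(nx.Graph()), tmp_path / "x", format="gexf")
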