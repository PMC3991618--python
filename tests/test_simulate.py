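import math

import numpy as np
import pandas as pd
import pytest

from tsnba import (
    SimulationParams,
    SyntheticTruth,
    generate_network,
    log2_fold_change,
    make_fixture,
    null_preset,
    plant_truth,
    read_expression,
    read_gene_set,
    read_network,
    signal_preset,
    simulate_expression,
)


SMALL = SimulationParams(
    n_genes=300,
    edges_per_node=3,
    n_pathology=60,
    n_modules=3,
    n_tfs=6,
    n_decoys=30,
    seed=0,
)


class TestGenerateNetwork:
    def test_edge_count_formula(self):
        # growth from a complete (m+1)-clique: C(m+1,2) + (n-m-1)*m edges
        p = SimulationParams(n_genes=100, edges_per_node=2, n_pathology=10, seed=1)
        net = generate_network(p)
        assert net.number_of_nodes() == 100
        assert net.number_of_edges() == math.comb(3, 2) + (100 - 3) * 2  # 197

    def test_deterministic_per_seed(self):
        p = SimulationParams(n_genes=150, edges_per_node=2, n_pathology=10, seed=5)
        assert generate_network(p).edges == generate_network(p).edges

    def test_different_seeds_differ(self):
        p1 = SimulationParams(n_genes=150, edges_per_node=2, n_pathology=10, seed=5)
        p2 = SimulationParams(n_genes=150, edges_per_node=2, n_pathology=10, seed=6)
        assert generate_network(p1).edges != generate_network(p2).edges

    def test_connected_no_self_loops(self):
        import networkx as nx

        net = generate_network(SMALL)
        assert nx.is_connected(net.graph)
        assert all(a != b for a, b in net.graph.edges)

    def test_hub_heavy_degree_distribution(self):
        p = SimulationParams(n_genes=2000, edges_per_node=4, n_pathology=200, seed=3)
        degrees = generate_network(p).degrees()
        assert degrees.max() > 10 * np.median(degrees)


class TestPlantTruth:
    def test_all_genes_pathology_limit(self):
        p = SimulationParams(
            n_genes=50, edges_per_node=2, n_pathology=50, n_modules=2,
            n_tfs=2, n_decoys=0, seed=0,
        )
        net = generate_network(p)
        truth = plant_truth(net, p)
        assert truth.pathology_genes.members == frozenset(net.nodes)

    def test_membership_invariants(self):
        net = generate_network(SMALL)
        truth = plant_truth(net, SMALL)
        nodes = net.nodes
        assert set(truth.pathology_genes.members) <= nodes
        assert set(truth.decoy_genes.members) <= nodes
        assert not (set(truth.decoy_genes.members) & set(truth.pathology_genes.members))
        assert all(tf in nodes and t in nodes for tf, t in truth.regulatory_edges)
        assert set(truth.active_tfs.members) <= set(truth.tf_genes.members)
        assert len(truth.tf_genes) == SMALL.n_tfs

    def test_planted_module_is_connected_dense(self):
        # planted pathology subgraph has more internal edges than a
        # degree-matched random gene set of the same size (median over seeds)
        import networkx as nx

        planted, matched = [], []
        for seed in range(20):
            p = SimulationParams(
                n_genes=400, edges_per_node=3, n_pathology=60, n_modules=3,
                n_tfs=6, n_decoys=0, seed=seed,
            )
            net = generate_network(p)
            truth = plant_truth(net, p)
            sub = net.graph.subgraph(truth.pathology_genes.members)
            planted.append(sub.number_of_edges())
            # degree-matched control: sample genes with probability ~ degree
            rng = np.random.default_rng(seed + 1000)
            genes = net.node_list
            w = net.degrees(genes).astype(float)
            ctrl = rng.choice(genes, size=60, replace=False, p=w / w.sum())
            matched.append(net.graph.subgraph(ctrl).number_of_edges())
        assert np.median(planted) > np.median(matched)

    def test_scattered_placement_is_degree_typical(self):
        p = SimulationParams(
            n_genes=2000, edges_per_node=4, n_pathology=200, scattered=True, seed=2
        )
        net = generate_network(p)
        truth = plant_truth(net, p)
        path_deg = net.degrees(sorted(truth.pathology_genes.members)).mean()
        all_deg = net.degrees().mean()
        assert abs(path_deg - all_deg) < 0.35 * all_deg


class TestSimulateExpression:
    def test_delta_zero_fold_changes_indistinguishable(self):
        gaps = []
        for seed in range(10):
            p = null_preset(seed=seed, n_genes=300, edges_per_node=3,
                            n_pathology=60, n_modules=3, n_tfs=6, n_decoys=0)
            net = generate_network(p)
            truth = plant_truth(net, p)
            expr, con = simulate_expression(truth)
            f = log2_fold_change(expr, con.control, con.treated)
            path = sorted(truth.pathology_genes.members)
            rest = sorted(set(net.nodes) - set(path))
            gaps.append(f[path].abs().mean() - f[rest].abs().mean())
        # mean |FC| gap fluctuates around zero across seeds
        assert abs(np.mean(gaps)) < 0.05

    def test_effect_size_recovered(self):
        means = []
        for seed in range(10):
            p = signal_preset(seed=seed, n_genes=300, edges_per_node=3,
                              n_pathology=60, n_modules=3, n_tfs=6, n_decoys=0,
                              n_samples_control=4, n_samples_treated=4)
            net = generate_network(p)
            truth = plant_truth(net, p)
            expr, con = simulate_expression(truth)
            f = log2_fold_change(expr, con.control, con.treated)
            means.append(f[sorted(truth.pathology_genes.members)].mean())
        assert np.mean(means) == pytest.approx(2.0, abs=0.2)

    def test_within_module_correlation_exceeds_between(self):
        gaps = []
        for seed in range(5):
            p = signal_preset(seed=seed, n_genes=300, edges_per_node=3,
                              n_pathology=60, n_modules=3, n_tfs=6, n_decoys=0)
            net = generate_network(p)
            truth = plant_truth(net, p)
            expr, _ = simulate_expression(truth)
            mods = {}
            for g, m in truth.module_assignments.items():
                mods.setdefault(m, []).append(g)
            x = expr.loc[sorted(truth.module_assignments)]
            logx = np.log2(x)
            corr = np.corrcoef(logx.to_numpy())
            idx = {g: i for i, g in enumerate(x.index)}
            within, between = [], []
            for m, members in mods.items():
                for i, a in enumerate(members):
                    for b in members[i + 1:]:
                        within.append(corr[idx[a], idx[b]])
            for a in mods[0]:
                for b in mods[1]:
                    between.append(corr[idx[a], idx[b]])
            gaps.append(np.median(within) - np.median(between))
        assert np.median(gaps) > 0.3

    def test_linear_scale_strictly_positive(self):
        net = generate_network(SMALL)
        truth = plant_truth(net, SMALL)
        expr, _ = simulate_expression(truth)
        assert (expr.to_numpy() > 0).all()

    def test_deterministic_per_seed(self):
        net = generate_network(SMALL)
        truth = plant_truth(net, SMALL)
        e1, _ = simulate_expression(truth)
        e2, _ = simulate_expression(truth)
        pd.testing.assert_frame_equal(e1, e2)


class TestMakeFixture:
    def test_files_parse_and_round_trip(self, tmp_path):
        paths = make_fixture(SMALL, tmp_path)
        net = read_network(paths["network"])
        expr = read_expression(paths["expression"])
        bench = read_gene_set(paths["benchmark"])
        tfs = read_gene_set(paths["tfs"], "tfs")
        assert net.number_of_nodes() == SMALL.n_genes
        assert expr.shape == (
            SMALL.n_genes,
            SMALL.n_samples_control + SMALL.n_samples_treated,
        )
        assert len(bench) == SMALL.n_pathology
        assert len(tfs) == SMALL.n_tfs
        truth = SyntheticTruth.from_json(paths["truth"], net)
        assert truth.pathology_genes.members == bench.members
        assert truth.params == SMALL

    def test_two_seeds_same_schema_different_values(self, tmp_path):
        p1 = SimulationParams(**{**SMALL.__dict__, "seed": 1})
        p2 = SimulationParams(**{**SMALL.__dict__, "seed": 2})
        e1 = read_expression(make_fixture(p1, tmp_path / "a")["expression"])
        e2 = read_expression(make_fixture(p2, tmp_path / "b")["expression"])
        assert list(e1.columns) == list(e2.columns)
        assert not np.allclose(e1.to_numpy(), e2.to_numpy())
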