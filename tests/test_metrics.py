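"""Centrality, clustering and trajectory metrics against independent oracles."""

import networkx as nx
import numpy as np
import pytest

from sddam import (
    ScaleGrid,
    SummarySpec,
    bin_ten_ranges,
    centrality_importance,
    clustering_coefficient,
    degree_centrality,
    eigenvector_centrality,
    filter_high_level,
    multiscale_trajectories,
    summarize,
)
from sddam.metrics import TrajectoryRecord

from conftest import scale_graph_from_adjacency


def canonical_graphs(max_nodes=8, n_random=50, seed=0):
    """Paths, cycles, stars, cliques up to max_nodes plus random graphs."""
    graphs = []
    for n in range(2, max_nodes + 1):
        graphs.append(nx.path_graph(n))
        graphs.append(nx.complete_graph(n))
        if n >= 3:
            graphs.append(nx.cycle_graph(n))
            graphs.append(nx.star_graph(n - 1))
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        n = int(rng.integers(2, max_nodes + 1))
        graphs.append(nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.9)), seed=int(rng.integers(1 << 30))))
    return graphs


def to_scale_graph(g: nx.Graph):
    return scale_graph_from_adjacency(nx.to_numpy_array(g, nodelist=sorted(g.nodes)))


def dense_eig_oracle(adj):
    """Principal eigenvector by full symmetric eigendecomposition."""
    w, v = np.linalg.eigh(adj)
    vec = v[:, np.argmax(w)]
    vec = np.abs(vec)  # Perron vector is non-negative up to global sign
    return vec / np.linalg.norm(vec)


def triangle_count_oracle(adj, u):
    n = adj.shape[0]
    t = 0
    for i in range(n):
        for j in range(i + 1, n):
            if adj[u, i] and adj[u, j] and adj[i, j]:
                t += 1
    return t


class TestDegreeCentrality:
    def test_path_middle_and_ends(self):
        g = to_scale_graph(nx.path_graph(3))
        assert degree_centrality(g).tolist() == [0.5, 1.0, 0.5]

    def test_complete_graph_all_one(self):
        g = to_scale_graph(nx.complete_graph(4))
        assert degree_centrality(g).tolist() == [1.0] * 4

    def test_isolated_node_zero(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = adj[1, 0] = 1
        g = scale_graph_from_adjacency(adj)
        assert degree_centrality(g)[2] == 0.0

    def test_single_node_zero(self):
        g = scale_graph_from_adjacency(np.zeros((1, 1)))
        assert degree_centrality(g).tolist() == [0.0]


class TestEigenvectorCentrality:
    def test_complete_graph_symmetry(self):
        for n in (2, 4, 7):
            g = to_scale_graph(nx.complete_graph(n))
            assert np.allclose(eigenvector_centrality(g), 1 / np.sqrt(n), atol=1e-8)

    def test_star_against_closed_form(self):
        g = to_scale_graph(nx.star_graph(3))
        ec = sorted(eigenvector_centrality(g))
        # centre 1/sqrt(2), three leaves 1/sqrt(6)
        assert np.allclose(ec, [1 / np.sqrt(6)] * 3 + [1 / np.sqrt(2)], atol=1e-8)

    def test_edgeless_graph_is_all_zero(self):
        g = scale_graph_from_adjacency(np.zeros((4, 4)))
        assert eigenvector_centrality(g).tolist() == [0.0] * 4

    def test_bipartite_component_converges(self):
        # even cycles are bipartite; plain power iteration on A oscillates
        g = to_scale_graph(nx.cycle_graph(6))
        assert np.allclose(eigenvector_centrality(g), 1 / np.sqrt(6), atol=1e-8)


def test_centrality_importance_is_elementwise_average():
    assert centrality_importance([0.4], [0.6]).tolist() == [0.5]
    assert centrality_importance([0.0], [0.0]).tolist() == [0.0]
    # K4: dc = 1, ec = 1/sqrt(4) = 0.5 by symmetry
    g = to_scale_graph(nx.complete_graph(4))
    ci = centrality_importance(degree_centrality(g), eigenvector_centrality(g))
    assert np.allclose(ci, 0.75, atol=1e-8)
    with pytest.raises(ValueError, match="aligned"):
        centrality_importance([0.1, 0.2], [0.3])


class TestClusteringCoefficient:
    def test_triangle_all_one(self):
        g = to_scale_graph(nx.complete_graph(3))
        assert clustering_coefficient(g).tolist() == [1.0] * 3

    def test_path_middle_zero(self):
        g = to_scale_graph(nx.path_graph(3))
        assert clustering_coefficient(g)[1] == 0.0

    def test_k4_minus_edge(self):
        g = nx.complete_graph(4)
        g.remove_edge(0, 1)
        cc = clustering_coefficient(to_scale_graph(g))
        # nodes 2 and 3 have degree 3 touching 2 triangles: 2*2/(3*2) = 2/3
        assert cc[2] == pytest.approx(2 / 3)
        assert cc[3] == pytest.approx(2 / 3)


def test_ec_and_cc_match_oracles_on_canonical_library():
    """Dense-eigendecomposition / exhaustive-triangle / networkx cross-checks."""
    for g in canonical_graphs():
        sg = to_scale_graph(g)
        adj = sg.adjacency.astype(float)
        ec = eigenvector_centrality(sg)
        if adj.sum() > 0:
            oracle = dense_eig_oracle(adj)
            # compare only when the principal eigenvector is unique up to sign
            w = np.sort(np.linalg.eigvalsh(adj))
            if w[-1] - w[-2] > 1e-8:
                assert np.allclose(ec, oracle, atol=1e-6)
        cc = clustering_coefficient(sg)
        nx_cc = nx.clustering(nx.from_numpy_array(adj))
        for u in range(adj.shape[0]):
            assert cc[u] == pytest.approx(nx_cc[u], abs=1e-12)
            deg = adj[u].sum()
            if deg >= 2:
                expect = 2 * triangle_count_oracle(adj, u) / (deg * (deg - 1))
                assert cc[u] == pytest.approx(expect, abs=1e-12)


class TestTrajectories:
    def test_single_lesion_all_zero(self):
        recs = multiscale_trajectories([[0, 0, 0]], ScaleGrid(10, 5, 30))
        assert len(recs) == 1
        assert np.all(recs[0].ci == 0) and np.all(recs[0].cc == 0)

    def test_two_lesions_closed_form(self):
        recs = multiscale_trajectories([[0, 0, 0], [12, 0, 0]], ScaleGrid(10, 5, 15))
        for rec in recs:
            assert rec.ci[0] == 0 and rec.cc[0] == 0  # scale 10: no edge
            # scale 15: single edge, dc = 1, ec = 1/sqrt(2)
            assert rec.ci[1] == pytest.approx((1 + 1 / np.sqrt(2)) / 2)
            assert rec.cc[1] == 0

    def test_trajectory_length_equals_grid_length(self, rng):
        pts = rng.uniform(0, 50, size=(9, 3))
        grid = ScaleGrid(10, 5, 90)
        recs = multiscale_trajectories(pts, grid)
        assert all(len(r.scales) == len(grid) for r in recs)

    def test_values_in_unit_interval_and_dc_monotone(self, rng):
        grid = ScaleGrid(10, 5, 90)
        for _ in range(5):
            pts = rng.uniform(0, 80, size=(12, 3))
            from sddam import build_filtration

            filt = build_filtration(pts, grid)
            prev_dc = None
            for g in filt:
                dc = degree_centrality(g)
                ec = eigenvector_centrality(g)
                cc = clustering_coefficient(g)
                for arr in (dc, ec, cc):
                    assert np.all((arr >= -1e-12) & (arr <= 1 + 1e-12))
                if prev_dc is not None:
                    assert np.all(dc >= prev_dc - 1e-12)
                prev_dc = dc


def make_record(ci, cc, lesion_id="L0"):
    n = len(ci)
    return TrajectoryRecord(
        lesion_id=lesion_id,
        patient_id="P0",
        scales=np.arange(n, dtype=float),
        ci=np.asarray(ci, dtype=float),
        cc=np.asarray(cc, dtype=float),
    )


class TestSummaryAndFilter:
    def test_constant_trajectory_same_under_both_modes(self):
        rec = make_record([0.3] * 4, [0.7] * 4)
        for mode in ("mean", "max"):
            assert summarize(rec, SummarySpec(mode=mode)) == (0.3, 0.7)

    def test_mean_and_max(self):
        rec = make_record([0.2, 0.8], [0.1, 0.5])
        assert summarize(rec, SummarySpec(mode="mean")) == (0.5, 0.3)
        assert summarize(rec, SummarySpec(mode="max")) == (0.8, 0.5)

    def test_filter_is_strict_exceedance(self):
        recs = [make_record([0.80], [0.0], "at"), make_record([0.81], [0.0], "above")]
        high_cc, high_ci = filter_high_level(recs, SummarySpec(mode="max", ci_threshold=0.8))
        assert [r.lesion_id for r in high_ci] == ["above"]
        assert high_cc == []

    def test_all_zero_trajectories_filter_to_empty(self):
        recs = [make_record([0.0] * 3, [0.0] * 3)] * 4
        high_cc, high_ci = filter_high_level(recs)
        assert high_cc == [] and high_ci == []

    def test_high_cc_lesion_selected_in_max_mode(self):
        recs = [make_record([0.0, 0.0], [0.0, 1.0])]
        high_cc, _ = filter_high_level(recs, SummarySpec(mode="max"))
        assert len(high_cc) == 1


class TestBinTenRanges:
    def test_value_one_goes_to_last_bin(self):
        counts = bin_ten_ranges([1.0])
        assert counts[-1] == 1 and counts.sum() == 1

    def test_two_values_in_adjacent_bins(self):
        counts = bin_ten_ranges([0.05, 0.15])
        assert counts[0] == 1 and counts[1] == 1

    def test_counts_conserve_input_size(self, rng):
        v = rng.uniform(0, 1, size=137)
        assert bin_ten_ranges(v).sum() == 137

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_ten_ranges([1.2])
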