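"""Graph metrics against analytic fixtures and brute-force oracles."""

import numpy as np
import pytest

from restconn.connectome import ConnectivityMatrix, SparsityGrid, build_network_family
from restconn.metrics import (
    MetricError,
    characteristic_path_length,
    compute_metric_curves,
    distance_matrix,
    global_efficiency,
    global_metrics,
    local_efficiency,
    nodal_clustering,
    shortest_path_lengths,
)

from _oracles import (
    clustering_brute,
    floyd_warshall,
    global_eff_brute,
    local_eff_brute,
    lp_brute,
    random_graph,
)
from conftest import make_network


def complete(n):
    return make_network(np.ones((n, n), dtype=np.uint8) - np.eye(n, dtype=np.uint8))


def path3():
    return make_network([[0, 1, 0], [1, 0, 1], [0, 1, 0]])


def star(n):
    a = np.zeros((n, n), dtype=np.uint8)
    a[0, 1:] = a[1:, 0] = 1
    return make_network(a)


def two_triangles():
    a = np.zeros((6, 6), dtype=np.uint8)
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        a[i, j] = a[j, i] = 1
    return make_network(a)


class TestAnalyticFixtures:
    def test_triangle_clustering(self):
        g = complete(3)
        assert all(nodal_clustering(g, i) == 1.0 for i in range(3))

    def test_star_clustering_zero(self):
        g = star(5)
        assert np.all(nodal_clustering(g) == 0.0)

    def test_chorded_cycle_clustering(self, chorded_cycle):
        # A-B-C-D cycle with chord A-C: (A, B, C, D) = (2/3, 1, 2/3, 1)
        assert np.allclose(nodal_clustering(chorded_cycle), [2 / 3, 1.0, 2 / 3, 1.0])
        assert nodal_clustering(chorded_cycle).mean() == pytest.approx(5 / 6)

    def test_path_graph_distances_and_lp(self):
        g = path3()
        d = shortest_path_lengths(g)
        assert d[0, 2] == 2
        lp, unreachable = characteristic_path_length(g)
        assert lp == pytest.approx(4 / 3)
        assert unreachable == 0

    def test_complete_graph_metrics_all_one(self):
        gm = global_metrics(complete(6))
        assert (gm.Cp, gm.Lp, gm.Eglob, gm.Eloc) == (1.0, 1.0, 1.0, 1.0)

    def test_disjoint_triangles_lp_and_unreachable(self):
        lp, unreachable = characteristic_path_length(two_triangles())
        assert lp == pytest.approx(1.0)
        assert unreachable == 9

    def test_path_graph_efficiency(self):
        assert global_efficiency(path3()) == pytest.approx(5 / 6)

    def test_edgeless_graph_efficiency_zero(self):
        assert global_efficiency(make_network(np.zeros((4, 4)))) == 0.0

    def test_edgeless_graph_lp_undefined(self):
        with pytest.raises(MetricError):
            characteristic_path_length(make_network(np.zeros((4, 4))))

    def test_local_efficiency_k4(self):
        assert local_efficiency(complete(4), 0) == pytest.approx(1.0)

    def test_local_efficiency_star_zero(self):
        g = star(5)
        assert np.all(local_efficiency(g) == 0.0)

    def test_local_efficiency_chorded_cycle(self, chorded_cycle):
        # neighbours of A = {B, C, D} with edges B-C, C-D: a path graph
        assert local_efficiency(chorded_cycle, 0) == pytest.approx(5 / 6)

    def test_unknown_node_rejected(self, chorded_cycle):
        with pytest.raises(MetricError):
            nodal_clustering(chorded_cycle, "nope")
        with pytest.raises(MetricError):
            local_efficiency(chorded_cycle, 99)


def test_all_metrics_match_brute_force_oracles():
    """On 100 random graphs (N <= 25), every metric matches independent
    neighbour-pair-enumeration / Floyd-Warshall implementations to 1e-12."""
    rng = np.random.default_rng(2024)
    for trial in range(100):
        n = int(rng.integers(4, 26))
        p = float(rng.uniform(0.1, 0.7))
        adj = random_graph(n, p, rng)
        if adj.sum() == 0:
            continue
        g = make_network(adj)
        d_oracle = floyd_warshall(adj)
        d = distance_matrix(adj)
        assert np.array_equal(np.isinf(d), np.isinf(d_oracle))
        finite = np.isfinite(d)
        assert np.allclose(d[finite], d_oracle[finite], atol=1e-12)
        cp = nodal_clustering(g)
        for i in range(n):
            assert cp[i] == pytest.approx(clustering_brute(adj, i), abs=1e-12)
            assert local_efficiency(g, i) == pytest.approx(local_eff_brute(adj, i), abs=1e-12)
        assert global_efficiency(g) == pytest.approx(global_eff_brute(adj), abs=1e-12)
        lp, unreachable = characteristic_path_length(g)
        lp_o, unreachable_o = lp_brute(adj)
        assert lp == pytest.approx(lp_o, abs=1e-12)
        assert unreachable == unreachable_o


def test_metrics_invariant_under_relabeling():
    rng = np.random.default_rng(8)
    adj = random_graph(15, 0.3, rng)
    perm = rng.permutation(15)
    g = make_network(adj)
    g_p = make_network(adj[np.ix_(perm, perm)])
    gm, gm_p = global_metrics(g), global_metrics(g_p)
    assert gm_p.Cp == pytest.approx(gm.Cp, abs=1e-12)
    assert gm_p.Lp == pytest.approx(gm.Lp, abs=1e-12)
    assert gm_p.Eglob == pytest.approx(gm.Eglob, abs=1e-12)
    assert gm_p.Eloc == pytest.approx(gm.Eloc, abs=1e-12)


def test_lp_is_not_inverse_efficiency_on_incomplete_graph():
    """Guard against conflating the finite-pair mean Lp with 1/E_glob:
    they agree only on complete graphs."""
    g = path3()
    lp, _ = characteristic_path_length(g)
    assert lp != pytest.approx(1.0 / global_efficiency(g))
    lp_h, _ = characteristic_path_length(g, convention="harmonic")
    assert lp_h == pytest.approx(1.0 / global_efficiency(g))


def test_eglob_monotone_and_cp_trend_on_nested_families():
    """E_glob never decreases when edges are added (a theorem: new edges never
    lengthen distances). The Cp trend is statistical only — individual edge
    additions can dilute clustering — so it is checked as a tendency over 50
    random nested families: densifying raises Cp overall in nearly every
    family and the average per-step change is upward."""
    rng = np.random.default_rng(3)
    grid = SparsityGrid(0.1, 0.5, 0.1)
    cp_rises_overall = 0
    step_changes = []
    for _ in range(50):
        r = np.corrcoef(rng.standard_normal((15, 60)))
        np.fill_diagonal(r, 0)
        fam = build_network_family(ConnectivityMatrix("s", r), grid, edge_sign="absolute")
        gdf, _ = compute_metric_curves(fam, grid, nodal=False)
        eg = gdf["Eglob"].to_numpy()
        assert np.all(np.diff(eg) >= -1e-12)
        cp = gdf["Cp"].to_numpy()
        cp_rises_overall += cp[-1] > cp[0]
        step_changes.extend(np.diff(cp))
    assert cp_rises_overall >= 45
    assert np.mean(step_changes) > 0


def test_curves_at_complete_graph_sparsity():
    rng = np.random.default_rng(4)
    r = np.abs(np.corrcoef(rng.standard_normal((8, 40))))
    np.fill_diagonal(r, 0)
    grid = SparsityGrid(0.999, 0.999, 0.01)
    fam = build_network_family(ConnectivityMatrix("s", r), grid)
    gdf, _ = compute_metric_curves(fam, grid, nodal=False)
    row = gdf.iloc[0]
    assert (row.Cp, row.Lp, row.Eglob, row.Eloc) == (1.0, 1.0, 1.0, 1.0)


def test_curves_missing_grid_value_rejected():
    rng = np.random.default_rng(4)
    r = np.corrcoef(rng.standard_normal((8, 40)))
    np.fill_diagonal(r, 0)
    grid = SparsityGrid(0.2, 0.4, 0.1)
    fam = build_network_family(ConnectivityMatrix("s", r), grid)[:-1]
    with pytest.raises(MetricError, match="cover"):
        compute_metric_curves(fam, grid)


def test_nodal_table_consistent_with_global(chorded_cycle):
    from restconn.metrics import nodal_metric_table

    t = nodal_metric_table(chorded_cycle)
    gm = global_metrics(chorded_cycle)
    assert t["clustering"].mean() == pytest.approx(gm.Cp)
    assert t["efficiency"].mean() == pytest.approx(gm.Eglob)
    assert t["local_efficiency"].mean() == pytest.approx(gm.Eloc)
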