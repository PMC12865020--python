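"""Cluster-based permutation statistics: graph construction, clustering
correctness against brute-force and library oracles, validity and
sensitivity, the minimum-neighbor rule and the two-stage procedure."""

import numpy as np
import pytest

from tepkit.cluster import (
    ClusterParams,
    NeighborGraph,
    build_neighbors,
    cluster_anova,
    cluster_ttest,
    two_stage_test,
)

WIDE = (-np.inf, np.inf)


def params(**kw):
    base = dict(test_window_ms=WIDE, n_permutations=500)
    base.update(kw)
    return ClusterParams(**base)


# -------------------------------------------------------------- neighbors

def test_collinear_sensors_form_path_graph():
    labels = ["a", "b", "c"]
    pos = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
    g = build_neighbors(labels, positions=pos, rule="distance",
                        distance_threshold=1.5)
    assert g.adjacency == [{1}, {0, 2}, {1}]


def test_knn_with_k_all_is_complete():
    rng = np.random.default_rng(0)
    pos = rng.standard_normal((5, 2))
    g = build_neighbors([f"s{i}" for i in range(5)], positions=pos,
                        rule="knn", k=4)
    assert all(len(nb) == 4 for nb in g.adjacency)


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_graph_symmetry_random_layouts(seed):
    rng = np.random.default_rng(seed)
    pos = rng.standard_normal((12, 2))
    g = build_neighbors([f"s{i}" for i in range(12)], positions=pos,
                        rule="knn", k=3)
    for i, nbrs in enumerate(g.adjacency):
        assert i not in nbrs
        for j in nbrs:
            assert i in g.adjacency[j]


def test_empty_layout_rejected():
    with pytest.raises(ValueError):
        build_neighbors([], positions=np.empty((0, 2)), rule="knn", k=1)


def test_isolated_nodes_reported():
    pos = np.array([[0.0, 0.0], [1.0, 0.0], [50.0, 0.0]])
    g = build_neighbors(["a", "b", "far"], positions=pos, rule="distance",
                        distance_threshold=2.0)
    assert g.isolated_nodes() == ["far"]


# ----------------------------------------------------- clustering oracle

def test_cluster_masses_match_brute_force_components(ring_graph):
    """Cluster decomposition against an independent connected-components
    oracle (networkx) on a product graph of spatial + temporal edges."""
    import networkx as nx
    from scipy import stats

    rng = np.random.default_rng(7)
    n = 10
    a = rng.standard_normal((n, 6, 20))
    b = rng.standard_normal((n, 6, 20))
    a[:, 2:5, 5:12] += 1.2  # force some suprathreshold structure
    res = cluster_ttest(a, b, ring_graph, params(), seed=0)

    tmap = res.stat_map
    thr = stats.t.ppf(1 - 0.05 / 2, n - 1)
    expected = []
    for sign in (1, -1):
        mask = sign * tmap > thr
        gx = nx.Graph()
        pts = [tuple(p) for p in np.argwhere(mask)]
        gx.add_nodes_from(pts)
        for (i, s) in pts:
            for j in ring_graph.adjacency[i]:
                if mask[j, s]:
                    gx.add_edge((i, s), (j, s))
            if s + 1 < 20 and mask[i, s + 1]:
                gx.add_edge((i, s), (i, s + 1))
        for comp in nx.connected_components(gx):
            expected.append(sum(tmap[p] for p in comp))
    np.testing.assert_allclose(
        sorted(c.mass for c in res.clusters), sorted(expected), atol=1e-9
    )


def test_observed_clusters_match_mne_oracle(ring_graph):
    """Observed cluster masses agree with the independent implementation in
    MNE given the same threshold and adjacency."""
    import mne
    from scipy import sparse, stats

    rng = np.random.default_rng(3)
    n = 15
    diff = rng.standard_normal((n, 6, 25))
    diff[:, 0:3, 8:15] += 0.9
    res = cluster_ttest(diff, np.zeros_like(diff), ring_graph, params(), seed=0)

    adj = sparse.lil_matrix((6, 6))
    for i, nbrs in enumerate(ring_graph.adjacency):
        for j in nbrs:
            adj[i, j] = 1
    thr = stats.t.ppf(1 - 0.05 / 2, n - 1)
    # MNE wants (obs, times, vertices)
    _, clusters, _, _ = mne.stats.permutation_cluster_1samp_test(
        diff.transpose(0, 2, 1), threshold=thr, n_permutations=100,
        adjacency=sparse.csr_matrix(adj), tail=0, out_type="mask", seed=1,
        verbose="error",
    )
    tmap = res.stat_map
    mne_masses = sorted(
        float(tmap.T[c].sum()) for c in clusters
    )
    ours = sorted(c.mass for c in res.clusters)
    np.testing.assert_allclose(ours, mne_masses, atol=1e-8)


# ------------------------------------------------------------- t-test

def test_identical_conditions_give_no_clusters(ring_graph):
    rng = np.random.default_rng(1)
    a = rng.standard_normal((8, 6, 15))
    res = cluster_ttest(a, a.copy(), ring_graph, params(), seed=0)
    assert np.abs(res.stat_map).max() == 0.0
    assert res.clusters == []


def test_injected_patch_detected_with_coverage(ring_graph):
    rng = np.random.default_rng(2)
    a = rng.standard_normal((20, 6, 30))
    b = rng.standard_normal((20, 6, 30))
    a[:, 1:4, 10:20] += 2.0
    res = cluster_ttest(a, b, ring_graph, params(n_permutations=1000), seed=4)
    sig = [c for c in res.clusters if c.p_value <= 0.01 and c.sign > 0]
    assert sig
    patch = {(n, s) for n in (1, 2, 3) for s in range(10, 20)}
    best = max(sig, key=lambda c: len(patch & set(c.members)))
    assert len(patch & set(best.members)) / len(patch) >= 0.8


def test_pvalues_bounded_below(ring_graph):
    rng = np.random.default_rng(3)
    a = rng.standard_normal((15, 6, 20))
    b = rng.standard_normal((15, 6, 20))
    a += 3.0  # huge global effect
    res = cluster_ttest(a, b, ring_graph, params(), seed=0)
    assert res.clusters
    for c in res.clusters:
        assert 1 / 501 <= c.p_value <= 1.0
    assert min(c.p_value for c in res.clusters) == pytest.approx(1 / 501)


def test_seed_determinism(ring_graph):
    rng = np.random.default_rng(4)
    a = rng.standard_normal((10, 6, 20))
    b = rng.standard_normal((10, 6, 20))
    r1 = cluster_ttest(a, b, ring_graph, params(), seed=11)
    r2 = cluster_ttest(a, b, ring_graph, params(), seed=11)
    assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]
    assert np.array_equal(r1.null_max, r2.null_max)


def test_subject_mismatch_rejected(ring_graph):
    with pytest.raises(ValueError):
        cluster_ttest(np.zeros((10, 6, 5)), np.zeros((9, 6, 5)), ring_graph,
                      params(), seed=0)


def test_min_neighbor_rule_excludes_lonely_nodes():
    """With min_neighbors=3, a suprathreshold node with fewer than three
    suprathreshold neighbors never enters a cluster."""
    # star graph: hub 0 connected to 1..4; leaves unconnected to each other
    g = NeighborGraph(
        labels=[f"p{i}" for i in range(5)],
        adjacency=[{1, 2, 3, 4}, {0}, {0}, {0}, {0}],
        min_neighbors=3,
    )
    rng = np.random.default_rng(5)
    n = 12
    a = rng.standard_normal((n, 5, 10))
    b = rng.standard_normal((n, 5, 10))
    # huge effect on hub + 2 leaves only: hub has 2 suprathreshold
    # neighbors, leaves have 1 -> everything must be pruned
    a[:, [0, 1, 2], :] += 5.0
    res = cluster_ttest(a, b, g, params(), seed=0)
    member_nodes = set().union(*(c.nodes for c in res.clusters)) if res.clusters else set()
    assert 0 not in member_nodes and 1 not in member_nodes
    # with 3 leaves active the hub qualifies
    a[:, 3, :] += 5.0
    res2 = cluster_ttest(a, b, g, params(), seed=0)
    assert any(0 in c.nodes for c in res2.clusters)


# --------------------------------------------------------------- ANOVA

def test_anova_identical_conditions_no_clusters(ring_graph):
    rng = np.random.default_rng(6)
    a = rng.standard_normal((8, 6, 15))
    res = cluster_anova([a, a.copy(), a.copy(), a.copy()], ring_graph,
                        params(), seed=0)
    assert res.clusters == []


def test_anova_detects_shifted_condition(ring_graph):
    rng = np.random.default_rng(7)
    conds = [rng.standard_normal((15, 6, 30)) for _ in range(4)]
    conds[2][:, 2:5, 10:20] += 1.5
    res = cluster_anova(conds, ring_graph, params(), seed=1)
    sig = [c for c in res.clusters if c.p_value < 0.05]
    assert sig
    patch = {(n, s) for n in (2, 3, 4) for s in range(10, 20)}
    best = max(sig, key=lambda c: len(patch & set(c.members)))
    assert len(patch & set(best.members)) / len(patch) > 0.5


def test_anova_unequal_shapes_rejected(ring_graph):
    conds = [np.zeros((8, 6, 10)), np.zeros((8, 6, 10)), np.zeros((7, 6, 10))]
    with pytest.raises(ValueError):
        cluster_anova(conds, ring_graph, params(), seed=0)


# ----------------------------------------------------------- two-stage

def test_two_stage_no_effect_is_empty(ring_graph):
    rng = np.random.default_rng(8)
    times = np.arange(0.0, 300.0, 10.0)
    a = rng.standard_normal((10, 6, times.size))
    b = rng.standard_normal((10, 6, times.size))
    res = two_stage_test([a, b], ring_graph,
                         ClusterParams(test_window_ms=(20, 300),
                                       n_permutations=500),
                         seed=0, times=times)
    if not res.stage1.significant(0.05):  # typical case under the null
        assert res.windows == [] and res.stage2 == []


def test_two_stage_finds_window_then_channels(ring_graph):
    rng = np.random.default_rng(9)
    times = np.arange(0.0, 300.0, 5.0)
    a = rng.standard_normal((20, 6, times.size))
    b = rng.standard_normal((20, 6, times.size))
    effect_t = (times >= 100) & (times <= 200)
    for ch in (1, 2, 3, 4):
        a[:, ch, effect_t] += 1.5
    res = two_stage_test([a, b], ring_graph,
                         ClusterParams(test_window_ms=(20, 300),
                                       n_permutations=500),
                         seed=1, times=times)
    assert res.windows
    lo, hi = res.windows[0]
    assert lo <= 200 and hi >= 100  # overlaps the injected interval
    stage2_sig = res.stage2[0].significant(0.05)
    assert stage2_sig
    found = set().union(*(c.nodes for c in stage2_sig))
    assert len(found & {1, 2, 3, 4}) >= 3


def test_two_stage_window_average_bookkeeping(ring_graph):
    """The stage-2 statistic map equals the t-map of data averaged over the
    stage-1 window, computed directly."""
    from scipy import stats as sps

    rng = np.random.default_rng(10)
    times = np.arange(0.0, 300.0, 5.0)
    a = rng.standard_normal((20, 6, times.size))
    b = rng.standard_normal((20, 6, times.size))
    a[:, 1:5, (times >= 100) & (times <= 200)] += 1.5
    res = two_stage_test([a, b], ring_graph,
                         ClusterParams(test_window_ms=(20, 300),
                                       n_permutations=500),
                         seed=2, times=times)
    assert res.windows
    lo, hi = res.windows[0]
    m = (times >= lo) & (times <= hi)
    d = (a - b)[:, :, m].mean(axis=2)
    t_direct = sps.ttest_1samp(d, 0.0, axis=0).statistic
    np.testing.assert_allclose(res.stage2[0].stat_map[:, 0], t_direct, atol=1e-9)
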