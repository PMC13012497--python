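"""Cluster formation, adjacency, and the permutation machinery."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import dreamdepth as dd
from dreamdepth.clusters import (_stratified_permutation, form_clusters,
                                 significant_clusters)
from dreamdepth.glme import BRAIN, ChannelwiseWaldEngine, ModelSpec


def _stats(labels, pvals, signs, wald=None, ok=None):
    wald = wald if wald is not None else 10.0 * (1 - np.asarray(pvals))
    return pd.DataFrame(
        {"wald": wald, "pvalue": pvals, "sign": signs,
         "ok": ok if ok is not None else [True] * len(labels)},
        index=pd.Index(labels, name="channel"),
    )


def _brute_force_clusters(stats, graph, p_thresh, min_size):
    """Exhaustive connected-component enumeration (independent oracle)."""
    out = []
    for s in (1, -1):
        active = {
            ch for ch in stats.index
            if stats.loc[ch, "ok"] and stats.loc[ch, "pvalue"] < p_thresh
            and stats.loc[ch, "sign"] == s
        }
        seen = set()
        for ch in active:
            if ch in seen:
                continue
            comp, frontier = {ch}, [ch]
            while frontier:
                cur = frontier.pop()
                for nb in graph.neighbors(cur):
                    if nb in active and nb not in comp:
                        comp.add(nb)
                        frontier.append(nb)
            seen |= comp
            if len(comp) >= min_size:
                out.append((tuple(sorted(comp)), s,
                            float(stats.loc[list(comp), "wald"].sum())))
    return sorted(out, key=lambda c: -c[2])


class TestBuildAdjacency:
    def test_collinear_chain_with_distance_method(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        sens = dd.SensorArray(("a", "b", "c"), pos)
        g = dd.build_adjacency(sens, method="distance", threshold=1.0)
        assert set(map(frozenset, g.edges())) == {frozenset("ab"),
                                                  frozenset("bc")}

    def test_grid_rook_adjacency(self, grid4x4):
        g = dd.build_adjacency(grid4x4, method="distance", threshold=1.0)
        assert g.number_of_edges() == 24
        # oracle: brute-force pairwise distances
        pos, labels = grid4x4.positions, grid4x4.channel_labels
        expect = {
            frozenset((labels[i], labels[j]))
            for i, j in itertools.combinations(range(16), 2)
            if np.linalg.norm(pos[i] - pos[j]) <= 1.0
        }
        assert set(map(frozenset, g.edges())) == expect

    def test_symmetry(self, sensors16):
        g = dd.build_adjacency(sensors16)
        for a, b in g.edges():
            assert g.has_edge(b, a)
        assert not any(a == b for a, b in g.edges())

    def test_duplicate_positions_rejected(self):
        pos = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0]], float)
        with pytest.raises(ValueError, match="duplicate"):
            dd.build_adjacency(dd.SensorArray(("a", "b", "c"), pos),
                               method="distance", threshold=1.0)

    def test_delaunay_connected_on_cap(self):
        g = dd.build_adjacency(dd.spherical_cap_grid(64))
        assert nx.is_connected(g)


class TestFormClusters:
    def test_no_suprathreshold_gives_empty_list(self, grid4x4):
        g = dd.build_adjacency(grid4x4, method="distance", threshold=1.0)
        stats = _stats(grid4x4.channel_labels, [0.5] * 16, [1] * 16)
        assert form_clusters(stats, g) == []

    def test_pair_below_min_size_dropped(self, grid4x4):
        g = dd.build_adjacency(grid4x4, method="distance", threshold=1.0)
        p = [0.5] * 16
        p[0] = p[1] = 0.001  # G00-G01 adjacent, but only two electrodes
        stats = _stats(grid4x4.channel_labels, p, [1] * 16)
        assert form_clusters(stats, g, min_size=3) == []

    def test_two_disjoint_patches_match_brute_force(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("c", "d"),  # patch 1
                          ("e", "f"), ("f", "g"),              # patch 2
                          ("d", "h"), ("h", "e"), ("i", "j")])
        labels = list("abcdefghij")
        p = {ch: 0.001 if ch in "abcdefg" else 0.9 for ch in labels}
        p["h"] = 0.9  # separates the patches
        stats = _stats(labels, [p[c] for c in labels], [1] * 10,
                       wald=np.arange(10, 20.0))
        found = form_clusters(stats, g, min_size=3)
        oracle = _brute_force_clusters(stats, g, 0.005, 3)
        assert [(c.members, c.sign, c.mass) for c in found] == oracle
        assert {c.members for c in found} == {("a", "b", "c", "d"),
                                              ("e", "f", "g")}

    def test_sign_homogeneity_splits_clusters(self):
        g = nx.path_graph(6)
        g = nx.relabel_nodes(g, {i: f"c{i}" for i in range(6)})
        labels = [f"c{i}" for i in range(6)]
        stats = _stats(labels, [0.001] * 6, [1, 1, 1, -1, -1, -1])
        found = form_clusters(stats, g, min_size=3)
        assert {c.members for c in found} == {("c0", "c1", "c2"),
                                              ("c3", "c4", "c5")}
        assert {c.sign for c in found} == {1, -1}

    def test_not_ok_channels_cannot_join(self):
        g = nx.path_graph(4)
        g = nx.relabel_nodes(g, {i: f"c{i}" for i in range(4)})
        labels = [f"c{i}" for i in range(4)]
        stats = _stats(labels, [0.001] * 4, [1] * 4,
                       ok=[True, True, False, True])
        found = form_clusters(stats, g, min_size=2)
        assert {c.members for c in found} == {("c0", "c1")}

    @pytest.mark.parametrize("seed", range(12))
    def test_random_small_graphs_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        labels = [f"n{i}" for i in range(n)]
        g = nx.gnp_random_graph(n, 0.35, seed=seed)
        g = nx.relabel_nodes(g, {i: labels[i] for i in range(n)})
        g.add_nodes_from(labels)
        stats = _stats(
            labels,
            rng.uniform(0, 0.02, n),
            rng.choice([1, -1], n),
            wald=rng.uniform(5, 30, n),
        )
        found = [(c.members, c.sign, c.mass)
                 for c in form_clusters(stats, g, min_size=2)]
        assert found == _brute_force_clusters(stats, g, 0.005, 2)

    def test_threshold_monotonicity(self, grid4x4):
        g = dd.build_adjacency(grid4x4, method="distance", threshold=1.0)
        rng = np.random.default_rng(1)
        stats = _stats(grid4x4.channel_labels, rng.uniform(0, 0.01, 16),
                       [1] * 16)
        loose = form_clusters(stats, g, p_thresh=0.01, min_size=1)
        tight = form_clusters(stats, g, p_thresh=0.002, min_size=1)
        loose_members = set().union(*[set(c.members) for c in loose]) if loose else set()
        tight_members = set().union(*[set(c.members) for c in tight]) if tight else set()
        assert tight_members <= loose_members

    def test_relabeling_invariance(self, grid4x4):
        g = dd.build_adjacency(grid4x4, method="distance", threshold=1.0)
        rng = np.random.default_rng(2)
        p = rng.uniform(0, 0.02, 16)
        w = rng.uniform(5, 20, 16)
        stats = _stats(grid4x4.channel_labels, p, [1] * 16, wald=w)
        found = form_clusters(stats, g, min_size=2)
        mapping = {l: f"X{l}" for l in grid4x4.channel_labels}
        g2 = nx.relabel_nodes(g, mapping)
        stats2 = stats.copy()
        stats2.index = [mapping[l] for l in stats.index]
        found2 = form_clusters(stats2, g2, min_size=2)
        assert [(tuple(mapping[m] for m in c.members), c.sign, c.mass)
                for c in found] == [(c.members, c.sign, c.mass) for c in found2]


class TestPermutation:
    def test_stratified_permutation_preserves_stratum_multisets(self):
        rng = np.random.default_rng(0)
        codes = np.repeat(np.arange(5), [3, 4, 5, 2, 6])
        y = rng.normal(size=len(codes))
        groups = [np.flatnonzero(codes == c) for c in range(5)]
        for _ in range(20):
            perm = _stratified_permutation(rng, groups, len(codes))
            for idx in groups:
                assert sorted(y[perm][idx]) == pytest.approx(sorted(y[idx]))
            # and nothing leaks across strata
            assert np.array_equal(codes[perm], codes)

    def test_identity_permutation_reproduces_observed(self, small_cohort):
        spec = ModelSpec(outcome="sleep_depth", predictors=(BRAIN,))
        feats = small_cohort.features["ratio"].iloc[:, :6]
        eng = ChannelwiseWaldEngine(small_cohort.records, feats, spec)
        obs = eng.wald_table()
        ident = eng.wald_table(np.arange(len(small_cohort.records)))
        pd.testing.assert_frame_equal(obs, ident)

    def test_null_deterministic_given_seed(self, small_cohort):
        spec = ModelSpec(outcome="sleep_depth", predictors=(BRAIN,))
        feats = small_cohort.features["ratio"].iloc[:, :6]
        g = dd.build_adjacency(dd.spherical_cap_grid(16))
        sub = g.subgraph(feats.columns).copy()
        n1 = dd.permutation_null(small_cohort.records, feats, spec, sub,
                                 n_perm=120, seed=5)
        n2 = dd.permutation_null(small_cohort.records, feats, spec, sub,
                                 n_perm=120, seed=5)
        np.testing.assert_array_equal(n1.values, n2.values)

    def test_low_n_perm_warns(self, small_cohort):
        spec = ModelSpec(outcome="sleep_depth", predictors=(BRAIN,))
        feats = small_cohort.features["ratio"].iloc[:, :4]
        g = dd.build_adjacency(dd.spherical_cap_grid(16)).subgraph(
            feats.columns
        ).copy()
        with pytest.warns(UserWarning, match="unstable"):
            dd.permutation_null(small_cohort.records, feats, spec, g,
                                n_perm=50, seed=0)


class TestSignificantClusters:
    def test_mass_below_every_null_value(self):
        null = dd.PermutationNull(values=np.linspace(10, 50, 200),
                                  n_permutations=200, seed=0, strata="p")
        cands = [dd.ClusterResult(("a", "b", "c"), 1, 5.0)]
        sig = significant_clusters(cands, null)
        assert sig == []
        # corrected p of that cluster is ~1
        p = (1 + (null.values >= 5.0).sum()) / 201
        assert p == pytest.approx(1.0, abs=0.01)

    def test_mass_above_every_null_value_closed_form(self):
        null = dd.PermutationNull(values=np.zeros(5000), n_permutations=5000,
                                  seed=0, strata="p")
        cands = [dd.ClusterResult(("a", "b", "c"), -1, 99.0)]
        sig = significant_clusters(cands, null)
        assert len(sig) == 1
        assert sig[0].corrected_p == pytest.approx(1 / 5001)

    def test_empty_null_rejected(self):
        null = dd.PermutationNull(values=np.array([]), n_permutations=0,
                                  seed=0, strata="p")
        with pytest.raises(ValueError, match="empty"):
            significant_clusters([dd.ClusterResult(("a",), 1, 1.0)], null)


def test_injected_effect_detected_and_localized():
    """A strong 8-electrode effect yields one significant, well-localized
    cluster and no spurious ones."""
    sens = dd.spherical_cap_grid(32)
    ci = sens.index_of("E005")
    d = np.linalg.norm(sens.positions - sens.positions[ci], axis=1)
    r8 = np.sort(d)[7] + 1e-9
    topo = dd.inject_cluster_effect(sens, "E005", r8, 1.0)
    region = set(np.array(sens.channel_labels)[topo != 0])
    graph = dd.build_adjacency(sens)
    spec = ModelSpec(outcome="sleep_depth", predictors=(BRAIN,))
    cfg = dd.SimConfig(n_participants=16, n_channels=32,
                       effect_topography=topo,
                       fixed_effects={"depth_brain": -0.35}, seed=77)
    ds = dd.generate_cohort(cfg)
    sig, _, _, _ = dd.cluster_permutation_test(
        ds.records, ds.features["gamma"], spec, graph, n_perm=200, seed=1
    )
    assert len(sig) == 1
    inside = len(set(sig[0].members) & region) / sig[0].size
    assert inside >= 0.9
    assert sig[0].sign == -1
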