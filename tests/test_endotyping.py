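"""K-S characterization, cluster extraction, and cross-cohort replication."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endomapper.endotyping import (
    ClusterDefinition,
    TestResult,
    characterize,
    compare_clusters,
    extract_clusters,
    ks_two_sample,
    match_replication,
)
from endomapper.errors import TestError as StatTestError
from endomapper.mapper import MapperConfig, MapperGraph, MapperNode, run_mapper
from tests.conftest import make_table


def brute_force_ks_d(x, y):
    """Independent oracle: sup |F_x - F_y| evaluated at every pooled point."""
    x, y = np.sort(x), np.sort(y)
    best = 0.0
    for t in np.concatenate([x, y]):
        fx = np.mean(x <= t)
        fy = np.mean(y <= t)
        best = max(best, abs(fx - fy))
    return best


class TestKsTwoSample:
    def test_identical_samples_give_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        D, p = ks_two_sample(x, x)
        assert D == 0.0

    def test_disjoint_supports_give_one(self):
        D, _ = ks_two_sample(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0]))
        assert D == 1.0

    def test_interleaved_example(self):
        D, _ = ks_two_sample(np.array([1.0, 2.0, 3.0, 4.0]),
                             np.array([2.0, 3.0, 4.0, 5.0]))
        assert D == pytest.approx(0.25)

    def test_matches_brute_force_on_random_samples(self, rng):
        for _ in range(50):
            x = rng.choice(np.arange(6.0), size=rng.integers(2, 9))
            y = rng.choice(np.arange(6.0), size=rng.integers(2, 9))
            D, _ = ks_two_sample(x, y)
            assert D == pytest.approx(brute_force_ks_d(x, y), abs=1e-12)

    def test_empty_sample_is_error(self):
        with pytest.raises(StatTestError):
            ks_two_sample(np.array([1.0]), np.array([1.0, 2.0]))

    @given(st.lists(st.integers(-50, 50), min_size=3, max_size=12),
           st.lists(st.integers(-50, 50), min_size=3, max_size=12))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_invariant_under_monotone_transform(self, xs, ys):
        x, y = np.array(xs, dtype=float), np.array(ys, dtype=float)
        d1, _ = ks_two_sample(x, y)
        d2, _ = ks_two_sample(np.exp(x / 25), np.exp(y / 25))
        assert d1 == pytest.approx(d2, abs=1e-12)


def _toy_graph(node_subjects, n_subjects):
    import networkx as nx
    nodes = [MapperNode(node_id=i, subjects=frozenset(s), cell=(i, None),
                        size=len(s), mean_lens=(0.0,))
             for i, s in enumerate(node_subjects)]
    G = nx.Graph()
    G.add_nodes_from(range(len(nodes)))
    for a, b in itertools.combinations(range(len(nodes)), 2):
        shared = len(nodes[a].subjects & nodes[b].subjects)
        if shared:
            G.add_edge(a, b, shared=shared)
    return MapperGraph(nodes=nodes, graph=G,
                       lens_values=np.zeros((n_subjects, 1)),
                       subjects=[f"s{i}" for i in range(n_subjects)])


class TestExtractClusters:
    def test_two_components_give_two_clusters(self):
        g = _toy_graph([range(0, 40), range(40, 75)], 75)
        clusters = extract_clusters(g, min_size=5, split_fraction=0.9)
        assert sorted(len(c) for c in clusters) == [35, 40]

    def test_fully_overlapping_nodes_one_cluster(self):
        g = _toy_graph([{0, 1, 2, 3, 4}, {0, 1, 2, 3, 4, 5}], 6)
        clusters = extract_clusters(g, min_size=2, split_fraction=0.95)
        assert len(clusters) == 1
        assert clusters[0] == set(range(6))

    def test_manual_node_lists_override(self):
        g = _toy_graph([{0, 1}, {2, 3}, {4, 5}], 6)
        clusters = extract_clusters(g, min_size=1,
                                    manual_node_lists=[[0, 1], [2]])
        assert clusters == [{0, 1, 2, 3}, {4, 5}]

    def test_planted_three_blobs_recovered(self):
        # three Gaussian blobs separated by ~6 within-SDs, full pipeline
        from sklearn.metrics import adjusted_rand_score
        from endomapper.preprocess import variance_normalize
        aris = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            centers = np.array([[0, 0, 0], [6, 0, 3], [0, 6, -3]], dtype=float)
            labels = np.repeat([0, 1, 2], 30)
            pts = centers[labels] + r.normal(size=(90, 3))
            t = make_table(pts)
            X, _ = variance_normalize(t.values)
            g = run_mapper(t, MapperConfig(resolution=10, gain=2.5,
                                           stratify_on_asthma=False), features=X)
            clusters = extract_clusters(g, min_size=4, features=X)
            pred = {s: i for i, c in enumerate(clusters) for s in c}
            idx = sorted(pred)
            aris.append(adjusted_rand_score(labels[idx], [pred[s] for s in idx]))
        assert np.mean(aris) >= 0.9


class TestCharacterize:
    def test_planted_shift_is_detected_with_direction(self, rng):
        n, p = 145, 10
        vals = rng.normal(size=(n, p))
        cluster = set(range(20))
        vals[list(cluster), 3] += 1.5
        t = make_table(vals)
        d = characterize(cluster, t, label="planted")
        hits = {f.feature: f.direction for f in d.defining_features}
        assert hits.get("v3") == "higher"
        assert d.defining_features[0].ks_score <= 1.0
        assert d.size == 20

    def test_null_false_positive_rate_matches_alpha(self):
        n_feat, per_seed = 40, []
        for seed in range(50):
            r = np.random.default_rng(seed)
            vals = r.normal(size=(60, n_feat))
            t = make_table(vals)
            d = characterize(set(range(25)), t)
            per_seed.append(len(d.defining_features))
        rate = np.mean(per_seed) / n_feat
        assert 0.01 < rate < 0.09   # nominal 0.05

    def test_identical_empirical_distributions_give_zero_d(self, rng):
        block = rng.normal(size=50)
        vals = np.concatenate([block, block])[:, None]   # cluster == complement
        t = make_table(vals)
        d = characterize(set(range(50)), t)
        assert d.defining_features == []

    def test_features_sorted_by_descending_ks_score(self, rng):
        vals = rng.normal(size=(100, 5))
        cluster = set(range(30))
        vals[list(cluster), 0] += 2.5
        vals[list(cluster), 1] += 1.0
        t = make_table(vals)
        d = characterize(cluster, t)
        scores = [f.ks_score for f in d.defining_features]
        assert scores == sorted(scores, reverse=True)


class TestCompareClusters:
    def test_null_f_statistic_near_one(self):
        fs = []
        for seed in range(60):
            r = np.random.default_rng(seed)
            t = make_table(r.normal(size=(60, 1)))
            res = compare_clusters(t, [set(range(20)), set(range(20, 40)),
                                       set(range(40, 60))], "v0")
            fs.append(res["F"])
        assert 0.6 < np.mean(fs) < 1.5

    def test_shifted_group_detected_with_bonferroni_posthocs(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            vals = r.normal(size=(90, 1))
            vals[60:, 0] += 2.0
            t = make_table(vals)
            res = compare_clusters(t, [set(range(30)), set(range(30, 60)),
                                       set(range(60, 90))], "v0")
            ok = (res["p"] < 0.05 and res["posthoc"][(0, 2)] < 0.05
                  and res["posthoc"][(1, 2)] < 0.05)
            hits += ok
        assert hits >= 95

    def test_identical_groups_capped_at_one(self, rng):
        vals = rng.normal(size=(30, 1))
        dup = np.vstack([vals, vals, vals])
        t = make_table(dup)
        res = compare_clusters(t, [set(range(30)), set(range(30, 60)),
                                   set(range(60, 90))], "v0")
        assert all(p == 1.0 for p in res["posthoc"].values())


def _definition(label, signed):
    feats = [TestResult(f, 0.5, 0.01, d) for f, d in signed]
    return ClusterDefinition(label=label, subjects={0, 1}, defining_features=feats)


class TestMatchReplication:
    def test_identical_signed_sets_match_perfectly(self):
        d = [_definition("A", [("p", "lower"), ("g", "lower")])]
        v = [_definition("a", [("p", "lower"), ("g", "lower")])]
        rep = match_replication(d, v)
        assert rep.matched[0][:2] == ("A", "a")
        assert rep.matched[0][2] == 1.0
        assert rep.replicated == [("A", "a")]

    def test_disjoint_sets_do_not_match(self):
        d = [_definition("A", [("p", "lower")])]
        v = [_definition("a", [("q", "higher")])]
        rep = match_replication(d, v)
        assert rep.replicated_count == 0
        assert rep.unmatched_derivation == ["A"]

    def test_partial_overlap_jaccard_two_thirds(self):
        d = [_definition("A", [("periostin", "lower"), ("gina", "lower"),
                               ("age", "lower")])]
        v = [_definition("a", [("periostin", "lower"), ("gina", "lower")])]
        rep = match_replication(d, v)
        assert rep.matched[0][2] == pytest.approx(2 / 3)
        assert rep.matched[0][3] == 2
        assert rep.replicated_count == 1

    def test_opposite_direction_does_not_count_as_shared(self):
        d = [_definition("A", [("p", "lower"), ("q", "higher")])]
        v = [_definition("a", [("p", "higher"), ("q", "higher")])]
        rep = match_replication(d, v)
        assert rep.matched[0][3] == 1   # only q shared
        assert rep.replicated_count == 0

    def test_symmetric_in_cohort_roles(self):
        d = [_definition("A", [("p", "lower"), ("q", "higher")]),
             _definition("B", [("r", "lower"), ("s", "lower"), ("q", "higher")])]
        v = [_definition("a", [("p", "lower"), ("q", "higher"), ("t", "lower")]),
             _definition("b", [("r", "lower"), ("s", "lower")])]
        fwd = match_replication(d, v)
        rev = match_replication(v, d)
        assert {(a, b) for a, b, *_ in fwd.matched} == \
            {(b, a) for a, b, *_ in rev.matched}
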