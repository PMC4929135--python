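"""Mapper construction: lenses, cover, preimage clustering, nerve, invariants."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from endomapper.mapper import (
    MapperConfig,
    build_cover,
    build_nerve,
    cluster_preimage,
    equalize_lens,
    mds_lens,
    run_mapper,
)
from tests.conftest import make_table


class TestMdsLens:
    def test_two_points_at_unit_distance(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        coords = mds_lens(D, k=1)
        assert sorted(coords.ravel().tolist()) == pytest.approx([-0.5, 0.5])

    def test_collinear_points_have_rank_one(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        D = squareform(pdist(pts))
        with pytest.warns(UserWarning, match="rank"):
            coords = mds_lens(D, k=2)
        assert coords.shape[1] == 1
        d_emb = squareform(pdist(coords))
        assert np.allclose(d_emb, D, atol=1e-10)

    def test_full_rank_embedding_reproduces_distances(self, rng):
        pts = rng.normal(size=(20, 5))
        D = squareform(pdist(pts))
        coords = mds_lens(D, k=19)
        assert np.allclose(squareform(pdist(coords)), D, atol=1e-8)

    def test_deterministic_sign_convention(self, rng):
        pts = rng.normal(size=(15, 3))
        D = squareform(pdist(pts))
        coords = mds_lens(D, k=2)
        for j in range(2):
            assert coords[np.argmax(np.abs(coords[:, j])), j] > 0


class TestEqualizeLens:
    def test_three_values_formula(self):
        out = equalize_lens(np.array([10.0, 20.0, 30.0]))
        assert np.allclose(out.ravel(), [1 / 6, 3 / 6, 5 / 6])

    def test_all_ties_map_to_half(self):
        out = equalize_lens(np.array([7.0, 7.0, 7.0, 7.0]))
        assert np.allclose(out, 0.5)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=40)
        assert np.allclose(equalize_lens(x), equalize_lens(np.exp(x)))


class TestBuildCover:
    def test_resolution_two_gain_one_has_no_overlap(self):
        lens = np.array([[0.25], [0.75]])
        cells = build_cover(lens, MapperConfig(resolution=2, gain=1.0))
        members = {c.intervals: set(c.members) for c in cells}
        assert members == {(0,): {0}, (1,): {1}}

    def test_resolution_two_gain_two_overlap_region(self):
        lens = np.array([[0.4], [0.05], [0.95]])
        cells = build_cover(lens, MapperConfig(resolution=2, gain=2.0))
        members = {c.intervals: set(c.members) for c in cells}
        # intervals clip to [0, 0.75] and [0.25, 1]; 0.4 belongs to both
        assert members[(0,)] == {0, 1}
        assert members[(1,)] == {0, 2}

    def test_study_cover_interior_point_in_nine_cells(self):
        lens = np.array([[0.5171, 0.5171]])
        cells = build_cover(lens, MapperConfig(resolution=30, gain=3.0))
        assert len(cells) == 9   # 3 intervals per axis

    def test_strata_never_mix(self, rng):
        lens = rng.random((40, 2))
        strata = np.array([0, 1] * 20)
        cells = build_cover(lens, MapperConfig(resolution=5, gain=2.0), strata=strata)
        for c in cells:
            assert len(set(strata[c.members])) == 1


class TestClusterPreimage:
    def test_singleton_is_one_cluster(self):
        parts = cluster_preimage(np.array([[1.0, 2.0]]))
        assert [p.tolist() for p in parts] == [[0]]

    def test_histogram_gap_splits_clusters(self):
        # 1-D points with single-linkage merge heights 0.10, 0.12, 0.90
        rows = np.array([[0.0], [0.10], [0.22], [1.12]])
        parts = cluster_preimage(rows)
        groups = sorted(sorted(p.tolist()) for p in parts)
        assert groups == [[0, 1, 2], [3]]

    def test_uniform_distances_stay_together(self):
        # equilateral triangle: no empty histogram bin
        rows = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        parts = cluster_preimage(rows)
        assert len(parts) == 1


class TestBuildNerve:
    def _cells(self, membership):
        from endomapper.mapper import CoverCell
        return [
            (CoverCell(intervals=(i,), stratum=None, members=np.array(m)),
             [np.arange(len(m))])
            for i, m in enumerate(membership)
        ]

    def test_shared_subject_makes_edge(self):
        lens = np.zeros((3, 1))
        g = build_nerve(self._cells([[0, 1], [1, 2]]), lens, ["a", "b", "c"])
        assert g.graph.number_of_edges() == 1
        assert g.graph.edges[0, 1]["shared"] == 1

    def test_disjoint_clusters_no_edge(self):
        lens = np.zeros((4, 1))
        g = build_nerve(self._cells([[0, 1], [2, 3]]), lens, list("abcd"))
        assert g.graph.number_of_edges() == 0

    def test_chain_of_overlaps_is_path_graph(self):
        lens = np.zeros((4, 1))
        g = build_nerve(self._cells([[0, 1], [1, 2], [2, 3]]), lens, list("abcd"))
        assert sorted(g.graph.edges) == [(0, 1), (1, 2)]


class TestRunMapper:
    def _blob_table(self, rng, n=60, separation=12.0, spread=0.5):
        half = n // 2
        pts = np.vstack([
            rng.normal([0, 0], spread, size=(half, 2)),
            rng.normal([separation, separation], spread, size=(n - half, 2)),
        ])
        return make_table(pts), np.array([0] * half + [1] * (n - half))

    def test_two_separated_blobs_give_two_components(self, rng):
        # a couple of outlier subjects may form singleton nodes (as in any
        # Mapper network); the macroscopic structure must be the two blobs
        import networkx as nx
        t, truth = self._blob_table(rng)
        g = run_mapper(t, MapperConfig(resolution=10, gain=2.0, equalize=False,
                                       stratify_on_asthma=False))
        node_by = {n.node_id: n for n in g.nodes}
        comps = []
        for comp in nx.connected_components(g.graph):
            subs = set().union(*(node_by[i].subjects for i in comp))
            if len(subs) >= 2:
                comps.append(subs)
        assert len(comps) == 2
        for subs in comps:
            assert len({truth[i] for i in subs}) == 1   # blob-pure

    def test_identical_subjects_collapse_to_single_node(self):
        t = make_table(np.ones((6, 3)))
        with pytest.warns(UserWarning):
            g = run_mapper(t, MapperConfig(resolution=5, gain=2.0,
                                           stratify_on_asthma=False))
        assert len(g.nodes) == 1
        assert g.nodes[0].subjects == frozenset(range(6))

    def test_every_subject_is_covered(self, rng):
        t = make_table(rng.normal(size=(40, 4)))
        g = run_mapper(t, MapperConfig(resolution=8, gain=2.5,
                                       stratify_on_asthma=False))
        assert g.covered_subjects() == set(range(40))

    def test_edge_count_monotone_in_gain(self, rng):
        t = make_table(rng.normal(size=(50, 3)))
        edges = []
        for gain in (1.5, 2.5, 3.5):
            g = run_mapper(t, MapperConfig(resolution=10, gain=gain,
                                           stratify_on_asthma=False))
            edges.append(g.graph.number_of_edges())
        assert edges[0] <= edges[1] <= edges[2]

    def test_resolution_one_reduces_to_whole_cohort_clustering(self, rng):
        from endomapper.preprocess import variance_normalize
        t = make_table(rng.normal(size=(25, 3)))
        g = run_mapper(t, MapperConfig(resolution=1, gain=1.0,
                                       stratify_on_asthma=False))
        X, _ = variance_normalize(t.values)
        parts = cluster_preimage(X)
        assert sorted(sorted(n.subjects) for n in g.nodes) == \
            sorted(sorted(p.tolist()) for p in parts)

    def test_subject_permutation_gives_isomorphic_graph(self, rng):
        t = make_table(rng.normal(size=(30, 3)))
        g1 = run_mapper(t, MapperConfig(resolution=6, gain=2.0,
                                        stratify_on_asthma=False))
        perm = rng.permutation(30)
        t2 = t.subset_subjects(perm)
        g2 = run_mapper(t2, MapperConfig(resolution=6, gain=2.0,
                                         stratify_on_asthma=False))
        part1 = sorted(sorted(n.subjects) for n in g1.nodes)
        inv = np.argsort(np.argsort(perm))  # position of original row in t2
        mapped = sorted(sorted(int(perm[i]) for i in n.subjects) for n in g2.nodes)
        assert part1 == mapped

    def test_strata_separate_healthy_from_asthma_nodes(self, rng):
        vals = rng.normal(size=(40, 3))
        asthma = np.array([True] * 30 + [False] * 10)
        t = make_table(vals, asthma=asthma)
        g = run_mapper(t, MapperConfig(resolution=6, gain=2.0))
        for node in g.nodes:
            flags = {bool(asthma[i]) for i in node.subjects}
            assert len(flags) == 1
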