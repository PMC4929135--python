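"""Discretization, BDeu scoring vs brute force, structure search, edge annotation."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.special import gammaln

from endomapper.bayesnet import (
    DiscreteTable,
    DiscretizationConfig,
    ScoreConfig,
    annotate_edges,
    bdeu_score,
    discretize,
    learn_structure,
    spearman,
)
from endomapper.errors import TestError as StatTestError
from tests.conftest import make_table


# ---------------------------------------------------------------------------
# independent BDeu oracle (naive, no caching, direct counting)

def naive_bdeu(codes, cards, dag_edges, n_nodes, ess=1.0):
    total = 0.0
    for child in range(n_nodes):
        parents = sorted(a for a, b in dag_edges if b == child)
        r = cards[child]
        q = int(np.prod([cards[p] for p in parents])) if parents else 1
        counts = {}
        for row in codes:
            j = tuple(row[p] for p in parents)
            counts.setdefault(j, np.zeros(r))[row[child]] += 1
        a_j, a_jk = ess / q, ess / (q * r)
        for njk in counts.values():
            nj = njk.sum()
            total += gammaln(a_j) - gammaln(a_j + nj)
            total += sum(gammaln(a_jk + c) - gammaln(a_jk) for c in njk)
    return total


def all_three_node_dags():
    edges_all = [(a, b) for a in range(3) for b in range(3) if a != b]
    for mask in range(1 << 6):
        es = [edges_all[i] for i in range(6) if mask >> i & 1]
        g = nx.DiGraph()
        g.add_nodes_from(range(3))
        g.add_edges_from(es)
        if nx.is_directed_acyclic_graph(g):
            yield g


def _dt(codes, names=None):
    codes = np.asarray(codes, dtype=np.int64)
    return DiscreteTable(
        names=names or [f"n{j}" for j in range(codes.shape[1])],
        codes=codes,
        cardinality=codes.max(axis=0).astype(int) + 1,
    )


class TestDiscretize:
    def test_octave_into_four_equal_bins(self):
        t = make_table(np.arange(1.0, 9.0)[:, None])
        d = discretize(t, DiscretizationConfig(continuous_bins=4))
        assert d.codes.ravel().tolist() == [0, 0, 1, 1, 2, 2, 3, 3]
        assert d.cardinality.tolist() == [4]

    def test_binary_passthrough(self):
        t = make_table(np.array([[0.0], [1.0], [0.0], [1.0]]), scales=["binary"])
        d = discretize(t)
        assert d.codes.ravel().tolist() == [0, 1, 0, 1]
        assert d.cardinality.tolist() == [2]

    def test_constant_variable_dropped_with_warning(self):
        t = make_table(np.column_stack([np.ones(6), np.arange(6.0)]))
        with pytest.warns(UserWarning, match="v0"):
            d = discretize(t)
        assert d.names == ["v1"]
        assert d.dropped_variables == ["v0"]

    def test_incomplete_rows_dropped_and_counted(self):
        vals = np.arange(20.0).reshape(10, 2)
        vals[3, 1] = np.nan
        t = make_table(vals)
        d = discretize(t)
        assert d.n_dropped_rows == 1
        assert d.codes.shape[0] == 9

    def test_heavy_ties_shrink_realized_bins(self):
        x = np.array([1.0] * 6 + [2.0, 3.0])
        d = discretize(make_table(x[:, None]), DiscretizationConfig(continuous_bins=4))
        assert d.cardinality[0] < 4
        assert d.codes.max() == d.cardinality[0] - 1


class TestBdeuScore:
    def test_independence_prefers_empty_graph(self, rng):
        codes = np.column_stack([np.repeat([0, 1], 50), np.tile([0, 1], 50)])
        dt = _dt(codes)
        empty = nx.DiGraph()
        empty.add_nodes_from([0, 1])
        edge = nx.DiGraph()
        edge.add_nodes_from([0, 1])
        edge.add_edge(0, 1)
        assert bdeu_score(dt, empty) > bdeu_score(dt, edge)

    def test_deterministic_copy_prefers_edge(self):
        a = np.tile([0, 1], 50)
        dt = _dt(np.column_stack([a, a]))
        empty = nx.DiGraph(); empty.add_nodes_from([0, 1])
        edge = nx.DiGraph(); edge.add_nodes_from([0, 1]); edge.add_edge(0, 1)
        assert bdeu_score(dt, edge) > bdeu_score(dt, empty)

    def test_matches_naive_oracle_on_all_three_node_dags(self, rng):
        codes = rng.integers(0, 3, size=(40, 3))
        codes[:, 2] = (codes[:, 0] + rng.integers(0, 2, 40)) % 3
        dt = _dt(codes)
        for dag in all_three_node_dags():
            mine = bdeu_score(dt, dag, ess=1.0)
            oracle = naive_bdeu(dt.codes, dt.cardinality, list(dag.edges), 3)
            assert mine == pytest.approx(oracle, abs=1e-9)

    def test_cyclic_graph_rejected(self):
        dt = _dt(np.zeros((30, 2), dtype=int) + np.arange(2))
        g = nx.DiGraph([(0, 1), (1, 0)])
        with pytest.raises(StatTestError):
            bdeu_score(dt, g)


class TestLearnStructure:
    def _chain_data(self, seed, n=500, flip=0.2):
        r = np.random.default_rng(seed)
        x = r.integers(0, 2, n)
        y = (x + (r.random(n) < flip)) % 2
        z = (y + (r.random(n) < flip)) % 2
        return _dt(np.column_stack([x, y, z]), names=["x", "y", "z"])

    def test_chain_matches_exhaustive_search(self):
        dt = self._chain_data(seed=5)
        learned = learn_structure(dt, ScoreConfig(restarts=5, seed=0))
        best = max(all_three_node_dags(), key=lambda g: bdeu_score(dt, g))
        skel = lambda g, names: sorted(
            tuple(sorted((names.index(a) if isinstance(a, str) else a,
                          names.index(b) if isinstance(b, str) else b)))
            for a, b in g.edges)
        assert skel(learned, dt.names) == skel(best, dt.names)
        assert skel(learned, dt.names) == [(0, 1), (1, 2)]

    def test_independent_variables_yield_empty_graph(self):
        empty = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            dt = _dt(r.integers(0, 2, size=(500, 3)))
            dag = learn_structure(dt, ScoreConfig(restarts=1, seed=seed))
            empty += dag.number_of_edges() == 0
        assert empty >= 48   # >= 95%

    def test_single_variable_gives_empty_graph(self):
        dt = _dt(np.tile([0, 1], 30)[:, None])
        dag = learn_structure(dt, ScoreConfig())
        assert dag.number_of_edges() == 0

    def test_deterministic_given_seed(self):
        dt = self._chain_data(seed=9)
        g1 = learn_structure(dt, ScoreConfig(restarts=4, seed=3))
        g2 = learn_structure(dt, ScoreConfig(restarts=4, seed=3))
        assert sorted(g1.edges) == sorted(g2.edges)

    def test_six_node_edge_recovery_within_shd_two(self):
        # known DAG with strong conditional dependencies
        true_edges = [(0, 1), (1, 2), (2, 3), (0, 4), (4, 5)]
        good = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 300
            cols = [r.integers(0, 2, n)]
            data = {0: cols[0]}
            for (a, b) in true_edges:
                data[b] = (data[a] + (r.random(n) < 0.15)) % 2
            codes = np.column_stack([data[i] for i in range(6)])
            dt = _dt(codes)
            dag = learn_structure(dt, ScoreConfig(restarts=3, seed=seed))
            idx = {name: i for i, name in enumerate(dt.names)}
            learned = {tuple(sorted((idx[a], idx[b]))) for a, b in dag.edges}
            truth = {tuple(sorted(e)) for e in true_edges}
            shd = len(learned ^ truth)
            good += shd <= 2
        assert good >= 16   # >= 80% of seeds


class TestAnnotateEdges:
    def _annotated(self, y_of_x, rng, n=200):
        x = rng.normal(size=n)
        y = y_of_x(x) + rng.normal(scale=0.05, size=n)
        t = make_table(np.column_stack([x, y]), names=["x", "y"])
        d = discretize(t, DiscretizationConfig(continuous_bins=4))
        dag = nx.DiGraph()
        dag.add_nodes_from(d.names)
        dag.add_edge("x", "y")
        return annotate_edges(dag, d, t)

    def test_monotone_increasing_is_positive(self, rng):
        net = self._annotated(lambda x: x, rng)
        assert net.graph.edges["x", "y"]["sign"] == "positive"

    def test_monotone_decreasing_is_negative(self, rng):
        net = self._annotated(lambda x: -x, rng)
        assert net.graph.edges["x", "y"]["sign"] == "negative"

    def test_symmetric_quadratic_is_nonlinear(self, rng):
        net = self._annotated(lambda x: (x - np.median(x)) ** 2, rng)
        assert net.graph.edges["x", "y"]["sign"] == "nonlinear"

    def test_strengths_positive_and_isolated_nodes_excluded(self, rng):
        x = rng.integers(0, 2, 200).astype(float)
        y = (x + (rng.random(200) < 0.1)) % 2
        z = rng.normal(size=200)
        t = make_table(np.column_stack([x, y, z]), names=["x", "y", "z"],
                       scales=["binary", "binary", "continuous"])
        d = discretize(t)
        dag = learn_structure(d, ScoreConfig(restarts=2, seed=1))
        net = annotate_edges(dag, d, t)
        assert all(attrs["strength"] > 0 for *_, attrs in net.graph.edges(data=True))
        assert "z" in net.excluded
        assert set(net.included) | set(net.excluded) == {"x", "y", "z"}


class TestSpearman:
    def test_perfectly_increasing(self):
        rho, _ = spearman(np.arange(10.0), np.arange(10.0) ** 3)
        assert rho == pytest.approx(1.0)

    def test_perfectly_decreasing(self):
        rho, _ = spearman(np.arange(10.0), -np.arange(10.0))
        assert rho == pytest.approx(-1.0)

    def test_textbook_rank_example(self):
        rho, _ = spearman(np.array([1, 2, 3, 4, 5.0]), np.array([1, 3, 2, 5, 4.0]))
        assert rho == pytest.approx(0.8)   # 1 - 6*4/(5*24)

    def test_constant_input_is_error(self):
        with pytest.raises(StatTestError):
            spearman(np.ones(5), np.arange(5.0))

    def test_pairwise_deletion_of_missing(self):
        x = np.array([1, 2, 3, 4, np.nan])
        y = np.array([2, 4, 6, 8, 100.0])
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(1.0)
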