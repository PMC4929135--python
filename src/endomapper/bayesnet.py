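"""Bayesian network over discretized inflammatory and clinical parameters.

The network stage quantile-discretizes the 74-parameter set on complete cases,
learns a directed acyclic structure by BDeu-scored greedy hill climbing with
random restarts, and annotates each retained edge with a strength (score drop
when the edge is removed, normalized over edges) and a sign from the Spearman
correlation of the endpoints on the original scale: positive (green in the
figure convention), negative (red) or nonlinear (black, when the monotone
correlation is not significant despite the probabilistic dependence).

The BDeu score is the Dirichlet-multinomial marginal likelihood with the
equivalent-sample-size prior spread uniformly over parent configurations; it is
decomposable, so family scores are cached across search moves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from scipy.special import gammaln

from .cohort import CohortTable
from .errors import TestError


@dataclass
class DiscretizationConfig:
    """Quantile binning: 4 or 5 bins for continuous variables, binary passthrough."""

    continuous_bins: int = 4
    binary_passthrough: bool = True

    def __post_init__(self) -> None:
        if self.continuous_bins < 2:
            raise ValueError("continuous_bins must be >= 2")


@dataclass
class ScoreConfig:
    """BDeu hill-climbing search parameters."""

    equivalent_sample_size: float = 1.0
    max_parents: int = 4
    restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.equivalent_sample_size <= 0:
            raise ValueError("equivalent_sample_size must be > 0")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")


@dataclass
class DiscreteTable:
    """Complete-case discrete data: n x p integer codes with per-column cardinality."""

    names: list[str]
    codes: np.ndarray
    cardinality: np.ndarray
    n_dropped_rows: int = 0
    dropped_variables: list[str] = field(default_factory=list)


@dataclass
class BayesNet:
    """Learned structure with per-edge strength and sign, plus excluded nodes."""

    graph: nx.DiGraph          # edges carry "strength" (0, 1] and "sign"
    included: list[str]
    excluded: list[str]
    score: float
    n_rows: int

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def to_dot(self, path) -> None:
        colors = {"positive": "green", "negative": "red", "nonlinear": "black"}
        with open(path, "w") as fh:
            fh.write("digraph bayesnet {\n")
            for node in self.graph.nodes:
                fh.write(f'  "{node}";\n')
            for u, v, d in self.graph.edges(data=True):
                width = 0.5 + 4.5 * d["strength"]
                fh.write(
                    f'  "{u}" -> "{v}" [penwidth={width:.2f}, '
                    f'color={colors[d["sign"]]}];\n'
                )
            fh.write("}\n")

    def undirected_view(self) -> nx.Graph:
        """Association view: edge directions dropped, attributes kept."""
        G = nx.Graph()
        G.add_nodes_from(self.graph.nodes)
        for u, v, d in self.graph.edges(data=True):
            G.add_edge(u, v, **d)
        return G


# ---------------------------------------------------------------------------
# discretization

def discretize(
    table: CohortTable, config: DiscretizationConfig | None = None,
    *, variables: list[str] | None = None,
) -> DiscreteTable:
    """Quantile-bin the (complete-case) rows of the selected variables.

    Rows with any missing value among the selected variables are dropped and
    counted. Continuous variables are quantile-binned into
    ``continuous_bins`` bins with ties sharing the lower bin (the realized bin
    count may shrink and is re-coded to consecutive integers); binary and
    categorical variables pass through as observed codes. Variables with a
    single distinct value are dropped with a warning.
    """
    config = config or DiscretizationConfig()
    if variables is None:
        variables = [v.name for v in table.variables]
    idx = [table.variable_names.index(n) for n in variables]
    sub = table.values[:, idx]
    complete = ~np.isnan(sub).any(axis=1)
    n_dropped = int((~complete).sum())
    data = sub[complete]
    names, cols, cards, dropped = [], [], [], []
    for k, name in enumerate(variables):
        spec = table.variables[idx[k]]
        x = data[:, k]
        uniq = np.unique(x)
        if uniq.size < 2:
            warnings.warn(f"variable {name!r} is constant on complete cases; dropped")
            dropped.append(name)
            continue
        if spec.scale in ("binary", "categorical") and config.binary_passthrough:
            codes = np.searchsorted(uniq, x)
        else:
            b = config.continuous_bins
            edges = np.quantile(x, [i / b for i in range(1, b)])
            codes = np.searchsorted(edges, x, side="left")
            # ties at an edge share the lower bin by construction of side="left"
            used = np.unique(codes)
            codes = np.searchsorted(used, codes)
        names.append(name)
        cols.append(codes.astype(np.int64))
        cards.append(int(codes.max()) + 1)
    return DiscreteTable(
        names=names,
        codes=np.column_stack(cols) if cols else np.empty((data.shape[0], 0), int),
        cardinality=np.array(cards, dtype=int),
        n_dropped_rows=n_dropped,
        dropped_variables=dropped,
    )


# ---------------------------------------------------------------------------
# BDeu scoring

def _family_score(
    codes: np.ndarray, cards: np.ndarray, child: int, parents: tuple[int, ...],
    ess: float,
) -> float:
    r = int(cards[child])
    if parents:
        q = int(np.prod(cards[list(parents)]))
        pa_index = np.zeros(codes.shape[0], dtype=np.int64)
        for p in parents:
            pa_index = pa_index * cards[p] + codes[:, p]
    else:
        q = 1
        pa_index = np.zeros(codes.shape[0], dtype=np.int64)
    joint = pa_index * r + codes[:, child]
    njk = np.bincount(joint, minlength=q * r).reshape(q, r)
    nj = njk.sum(axis=1)
    a_j, a_jk = ess / q, ess / (q * r)
    occupied = nj > 0
    score = float(
        np.sum(gammaln(a_j) - gammaln(a_j + nj[occupied]))
        + np.sum(gammaln(a_jk + njk[occupied]) - gammaln(a_jk))
    )
    return score


class _Scorer:
    """Cached decomposable BDeu family scores for one discrete table."""

    def __init__(self, table: DiscreteTable, ess: float):
        self.codes = table.codes
        self.cards = table.cardinality
        self.ess = float(ess)
        self.p = len(table.names)
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def family(self, child: int, parents) -> float:
        key = (child, tuple(sorted(parents)))
        if key not in self._cache:
            self._cache[key] = _family_score(
                self.codes, self.cards, child, key[1], self.ess
            )
        return self._cache[key]

    def total(self, dag: "nx.DiGraph") -> float:
        return sum(self.family(c, tuple(dag.predecessors(c))) for c in dag.nodes)


def bdeu_score(
    table: DiscreteTable, dag: nx.DiGraph, ess: float = 1.0
) -> float:
    """BDeu log marginal likelihood of a DAG (nodes are column indices or names)."""
    if not nx.is_directed_acyclic_graph(dag):
        raise TestError("graph must be acyclic")
    name_to_idx = {n: i for i, n in enumerate(table.names)}
    scorer = _Scorer(table, ess)
    total = 0.0
    for node in dag.nodes:
        c = name_to_idx.get(node, node)
        parents = [name_to_idx.get(p, p) for p in dag.predecessors(node)]
        total += scorer.family(c, parents)
    return total


# ---------------------------------------------------------------------------
# structure search

def _reachable(adj: list[set[int]], src: int, dst: int) -> bool:
    seen = {src}
    stack = [src]
    while stack:
        u = stack.pop()
        if u == dst:
            return True
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


def learn_structure(
    table: DiscreteTable, config: ScoreConfig | None = None
) -> nx.DiGraph:
    """Greedy hill climbing over add/delete/reverse moves maximizing BDeu.

    Acyclicity and the parent limit are enforced for every move; ties are
    broken by lexicographic move order, and ``restarts`` additional climbs
    start from seeded random DAGs. Deterministic given the seed.
    """
    config = config or ScoreConfig()
    p = len(table.names)
    if p == 0:
        return nx.DiGraph()
    if table.codes.shape[0] < 20 and p >= 2:
        raise TestError("need >= 20 complete rows to learn a structure")
    scorer = _Scorer(table, config.equivalent_sample_size)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB0]))

    def climb(parents: list[set[int]]) -> tuple[float, list[set[int]]]:
        children = [set() for _ in range(p)]
        for c in range(p):
            for a in parents[c]:
                children[a].add(c)
        fam = [scorer.family(c, parents[c]) for c in range(p)]
        while True:
            best_delta, best_move = 1e-9, None
            for i in range(p):
                for j in range(p):
                    if i == j:
                        continue
                    if i in parents[j]:
                        # delete i -> j
                        d = scorer.family(j, parents[j] - {i}) - fam[j]
                        if d > best_delta:
                            best_delta, best_move = d, ("del", i, j)
                        # reverse i -> j: adding j -> i cycles iff i still
                        # reaches j once the original edge is removed
                        if len(parents[i]) < config.max_parents:
                            children[i].discard(j)
                            ok = not _reachable(children, i, j)
                            children[i].add(j)
                            if ok:
                                d = (
                                    scorer.family(j, parents[j] - {i}) - fam[j]
                                    + scorer.family(i, parents[i] | {j}) - fam[i]
                                )
                                if d > best_delta:
                                    best_delta, best_move = d, ("rev", i, j)
                    elif j not in parents[i] and len(parents[j]) < config.max_parents:
                        # add i -> j: cycle iff i reachable from j
                        if not _reachable(children, j, i):
                            d = scorer.family(j, parents[j] | {i}) - fam[j]
                            if d > best_delta:
                                best_delta, best_move = d, ("add", i, j)
            if best_move is None:
                break
            op, i, j = best_move
            if op == "add":
                parents[j].add(i)
                children[i].add(j)
            elif op == "del":
                parents[j].discard(i)
                children[i].discard(j)
            else:
                parents[j].discard(i)
                children[i].discard(j)
                parents[i].add(j)
                children[j].add(i)
            fam = [scorer.family(c, parents[c]) for c in range(p)]
        return sum(fam), parents

    best_score, best_parents = climb([set() for _ in range(p)])
    for _ in range(config.restarts):
        order = rng.permutation(p)
        parents = [set() for _ in range(p)]
        pos = np.empty(p, dtype=int)
        pos[order] = np.arange(p)
        for j in range(p):
            earlier = [i for i in range(p) if pos[i] < pos[j]]
            if earlier:
                k = int(rng.integers(0, min(len(earlier), config.max_parents) + 1))
                if k:
                    parents[j] = set(rng.choice(earlier, size=k, replace=False).tolist())
        score, parents = climb(parents)
        if score > best_score + 1e-9:
            best_score, best_parents = score, parents
    dag = nx.DiGraph()
    dag.add_nodes_from(table.names)
    for j in range(p):
        for i in best_parents[j]:
            dag.add_edge(table.names[i], table.names[j])
    return dag


# ---------------------------------------------------------------------------
# correlation and edge annotation

def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with pairwise deletion; p via the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise TestError("spearman needs >= 3 paired observed values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise TestError("spearman undefined for constant input")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def annotate_edges(
    dag: nx.DiGraph,
    discrete: DiscreteTable,
    original: CohortTable,
    *,
    ess: float = 1.0,
    alpha: float = 0.05,
) -> BayesNet:
    """Attach strength and sign to every edge; move isolated nodes to excluded.

    Strength is the BDeu score drop when the edge alone is removed, scaled by
    the largest drop so values lie in (0, 1]. Sign comes from the Spearman
    correlation of the endpoints on the original measurement scale: positive or
    negative when significant at ``alpha``, nonlinear otherwise.
    """
    name_to_idx = {n: i for i, n in enumerate(discrete.names)}
    scorer = _Scorer(discrete, ess)
    drops = {}
    for u, v in dag.edges:
        pv = [name_to_idx[p] for p in dag.predecessors(v)]
        with_e = scorer.family(name_to_idx[v], pv)
        without = scorer.family(name_to_idx[v], [p for p in pv if p != name_to_idx[u]])
        drops[(u, v)] = with_e - without
    max_drop = max(drops.values()) if drops else 1.0
    G = nx.DiGraph()
    for u, v in dag.edges:
        try:
            rho, p = spearman(original.column(u), original.column(v))
            sign = ("positive" if rho > 0 else "negative") if p < alpha else "nonlinear"
        except TestError:
            sign = "nonlinear"
        strength = drops[(u, v)] / max_drop if max_drop > 0 else 1.0
        G.add_edge(u, v, strength=float(max(strength, 1e-9)), sign=sign)
    included = sorted(G.nodes)
    excluded = sorted(set(dag.nodes) - set(G.nodes))
    total = scorer.total(nx.relabel_nodes(dag, name_to_idx, copy=True))
    return BayesNet(graph=G, included=included, excluded=excluded,
                    score=float(total), n_rows=discrete.codes.shape[0])
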