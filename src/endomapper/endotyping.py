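"""Candidate clusters from the Mapper graph, K-S characterization, replication.

The study's procedure is: pick subject groups off the topological network,
find the parameters whose distribution inside the group differs from the rest
of the structure (two-sample Kolmogorov-Smirnov tests, direction by median
difference), and call a cluster replicated when an independent cohort yields a
cluster with the same signed defining features. The original analyses of this
kind selected groups visually; here extraction is automatic (connected components, with oversized
components split by greedy modularity communities) but a manual node-list
override is supported so a visual selection can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .cohort import CohortTable
from .errors import TestError
from .mapper import MapperGraph


# ---------------------------------------------------------------------------
# K-S machinery

@dataclass
class TestResult:
    """One feature's two-sample K-S comparison: D statistic, p, direction."""

    feature: str
    ks_score: float
    p_value: float
    direction: str  # "higher" | "lower" | "tied"
    bonferroni_significant: bool = False


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample K-S: D = sup |F_x - F_y|, asymptotic two-sided p.

    Both samples need at least 2 observed (non-NaN) values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise TestError("ks_two_sample needs >= 2 observed values per sample")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# cluster extraction

def extract_clusters(
    graph: MapperGraph,
    min_size: int = 4,
    *,
    features: np.ndarray | None = None,
    split_fraction: float = 0.25,
    resolution: float = 1.0,
    merge_radii: tuple[float, ...] = (0.42, 0.51),
    manual_node_lists: list[list[int]] | None = None,
) -> list[set[int]]:
    """Subject clusters from the nerve graph (row-index sets, largest first).

    Stage 1 (graph): connected components are candidate groups; any component
    holding more than ``split_fraction`` of all subjects is split by greedy
    modularity-based communities (edge weight = shared-subject count,
    deterministic tie-breaking via sorted node order). Subjects spanning several
    node groups go to the group containing most of their nodes, ties to the
    lexicographically first label.

    Stage 2 (feature space, only when ``features`` — the variance-normalized
    matrix the graph was built from — is supplied): group centroids are merged
    by average-linkage agglomeration at each radius in ``merge_radii`` (radii
    are multiples of sqrt(n_features), the scale of unit-variance noise), with
    a nearest-centroid reassignment of all subjects between merges; strata (the
    cover's categorical filter) are never mixed. This consolidates the
    fine-grained nerve communities into the coherent subgroups a reader would
    select off the network by eye.

    Groups smaller than ``min_size`` are dropped (background).
    ``manual_node_lists`` bypasses detection and turns explicit node-id lists
    into clusters directly.
    """
    n_total = len(graph.subjects)
    node_by_id = {n.node_id: n for n in graph.nodes}

    if manual_node_lists is not None:
        groups = [set(ids) for ids in manual_node_lists]
    else:
        G = graph.graph
        groups = []
        for comp in sorted(nx.connected_components(G), key=lambda c: (-len(c), min(c))):
            comp_subjects = set().union(*(node_by_id[i].subjects for i in comp))
            if len(comp_subjects) > split_fraction * n_total and len(comp) > 1:
                sub = G.subgraph(sorted(comp))
                communities = nx.community.greedy_modularity_communities(
                    sub, weight="shared", resolution=resolution
                )
                groups.extend(set(c) for c in communities)
            else:
                groups.append(set(comp))

    # deterministic group labels: by (size desc, smallest node id)
    groups = sorted(groups, key=lambda g: (-len(g), min(g) if g else -1))
    # assign each subject to the group holding most of its nodes
    membership: dict[int, np.ndarray] = {}
    for gi, g in enumerate(groups):
        for node_id in g:
            for s in node_by_id[node_id].subjects:
                membership.setdefault(s, np.zeros(len(groups), dtype=int))[gi] += 1
    assignment: dict[int, int] = {}
    for s, counts in membership.items():
        assignment[s] = int(np.argmax(counts))  # argmax takes first max: lexicographic
    clusters: list[set[int]] = [set() for _ in groups]
    for s, gi in assignment.items():
        clusters[gi].add(s)
    clusters = [c for c in clusters if c]

    if features is not None and manual_node_lists is None and clusters:
        strata = (graph.strata if graph.strata is not None
                  else np.zeros(n_total, dtype=int))
        clusters = _refine_in_feature_space(
            clusters, np.asarray(features, dtype=float), np.asarray(strata),
            merge_radii,
        )

    clusters = [c for c in clusters if len(c) >= min_size]
    return sorted(clusters, key=lambda c: (-len(c), min(c)))


def _refine_in_feature_space(
    clusters: list[set[int]],
    X: np.ndarray,
    strata: np.ndarray,
    merge_radii: tuple[float, ...],
    max_iter: int = 25,
) -> list[set[int]]:
    """Centroid merge + nearest-centroid reassignment rounds (stratum-pure)."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist

    C = np.array([X[np.array(sorted(c))].mean(axis=0) for c in clusters])
    Cs = np.array([strata[next(iter(c))] for c in clusters])
    sizes = np.array([len(c) for c in clusters], dtype=float)
    assign = None
    scale = float(np.sqrt(X.shape[1]))
    for tau in (r * scale for r in merge_radii):
        merged: list[list[int]] = []
        for s in np.unique(Cs):
            sel = np.flatnonzero(Cs == s)
            if len(sel) == 1:
                merged.append(list(sel))
                continue
            lab = fcluster(linkage(pdist(C[sel]), method="average"),
                           t=tau, criterion="distance")
            for l in np.unique(lab):
                merged.append(list(sel[lab == l]))
        C = np.array([np.average(C[m], axis=0, weights=sizes[m]) for m in merged])
        Cs = np.array([Cs[m[0]] for m in merged])
        assign = None
        for _ in range(max_iter):
            d = ((X[:, None, :] - C[None, :, :]) ** 2).sum(-1)
            d[strata[:, None] != Cs[None, :]] = np.inf
            new = d.argmin(1)
            if assign is not None and (new == assign).all():
                break
            assign = new
            for k in range(len(C)):
                sel = assign == k
                if sel.any():
                    C[k] = X[sel].mean(0)
        keep = [k for k in range(len(C)) if (assign == k).any()]
        C, Cs = C[keep], Cs[keep]
        assign = np.searchsorted(keep, assign)
        sizes = np.array([(assign == k).sum() for k in range(len(C))], dtype=float)
    return [set(np.flatnonzero(assign == k).tolist()) for k in range(len(C))]


# ---------------------------------------------------------------------------
# characterization

@dataclass
class ClusterDefinition:
    """A subject set plus its signed, K-S-tested defining features."""

    label: str
    subjects: set[int]
    defining_features: list[TestResult]
    size: int = 0

    def __post_init__(self) -> None:
        if not self.subjects:
            raise TestError(f"cluster {self.label!r} is empty")
        self.size = len(self.subjects)
        self.defining_features.sort(key=lambda t: (-t.ks_score, t.feature))

    @property
    def signed_features(self) -> set[tuple[str, str]]:
        return {(t.feature, t.direction) for t in self.defining_features
                if t.direction != "tied"}

    def to_rows(self) -> list[dict]:
        return [
            {"cluster": self.label, "feature": t.feature,
             "ks_score": round(t.ks_score, 4), "p_value": t.p_value,
             "direction": t.direction,
             "bonferroni_significant": t.bonferroni_significant}
            for t in self.defining_features
        ]


def characterize(
    cluster: set[int],
    table: CohortTable,
    alpha: float = 0.05,
    *,
    label: str = "cluster",
    complement: set[int] | None = None,
    asthma_only_complement: bool = False,
) -> ClusterDefinition:
    """K-S-test every non-label variable, cluster vs the rest of the structure.

    All variables are tested (not only the clustering set). Features with
    ``p < alpha`` are kept, with direction from the median difference; a
    Bonferroni-adjusted significance flag is reported alongside but does not
    gate inclusion. ``asthma_only_complement`` restricts the comparison group
    to asthmatic subjects.
    """
    n = table.n_subjects
    idx = np.array(sorted(cluster), dtype=int)
    if complement is None:
        rest_mask = np.ones(n, dtype=bool)
        rest_mask[idx] = False
        if asthma_only_complement:
            rest_mask &= table.asthma_flag
        rest = np.flatnonzero(rest_mask)
    else:
        rest = np.array(sorted(complement - cluster), dtype=int)
    if idx.size < 2 or rest.size < 2:
        raise TestError("cluster and complement must each hold >= 2 subjects")
    tested = 0
    results = []
    for j, spec in enumerate(table.variables):
        if spec.role == "label":
            continue
        col = table.values[:, j]
        x = col[idx]
        y = col[rest]
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if x.size < 2 or y.size < 2:
            continue
        tested += 1
        D, p = ks_two_sample(x, y)
        if p >= alpha:
            continue
        mx, my = float(np.median(x)), float(np.median(y))
        direction = "higher" if mx > my else ("lower" if mx < my else "tied")
        results.append(TestResult(spec.name, D, p, direction))
    for t in results:
        t.bonferroni_significant = t.p_value * max(tested, 1) < alpha
    return ClusterDefinition(label=label, subjects=set(cluster),
                             defining_features=results)


def compare_clusters(
    table: CohortTable, clusters: list[set[int]], feature: str
) -> dict:
    """One-way ANOVA on a feature across clusters, Bonferroni post hoc t tests.

    The feature is log10-transformed first when its dictionary hint says so.
    Clusters with fewer than 2 observed values are dropped with a warning entry.
    """
    j = table.variable_names.index(feature)
    hint = table.variables[j].transform_hint
    col = table.values[:, j].copy()
    if hint == "log":
        obs = col[~np.isnan(col)]
        offset = 0.0
        if (obs <= 0).any():
            pos = obs[obs > 0]
            offset = float(pos.min()) / 2.0 if pos.size else 1.0
        col = np.log10(col + offset)
    samples, kept, dropped = [], [], []
    for ci, c in enumerate(clusters):
        vals = col[np.array(sorted(c), dtype=int)]
        vals = vals[~np.isnan(vals)]
        if vals.size < 2:
            dropped.append(ci)
            continue
        samples.append(vals)
        kept.append(ci)
    if len(samples) < 2:
        raise TestError("need >= 2 clusters with >= 2 observed values")
    F, p = stats.f_oneway(*samples)
    n_pairs = len(samples) * (len(samples) - 1) // 2
    posthoc = {}
    for a in range(len(samples)):
        for b in range(a + 1, len(samples)):
            t, pp = stats.ttest_ind(samples[a], samples[b])
            posthoc[(kept[a], kept[b])] = min(float(pp) * n_pairs, 1.0)
    return {"F": float(F), "p": float(p), "posthoc": posthoc, "dropped": dropped}


# ---------------------------------------------------------------------------
# replication

@dataclass
class ReplicationReport:
    """One-to-one matching of clusters across cohorts by signed-feature overlap."""

    matched: list[tuple[str, str, float, int]]  # (derivation, validation, jaccard, shared)
    replicated: list[tuple[str, str]] = field(default_factory=list)
    unmatched_derivation: list[str] = field(default_factory=list)
    unmatched_validation: list[str] = field(default_factory=list)

    @property
    def replicated_count(self) -> int:
        return len(self.replicated)

    def to_json_dict(self) -> dict:
        return {
            "matched": [
                {"derivation": a, "validation": b,
                 "jaccard": round(j, 4), "shared_signed_features": s}
                for a, b, j, s in self.matched
            ],
            "replicated": [list(p) for p in self.replicated],
            "replicated_count": self.replicated_count,
            "unmatched_derivation": self.unmatched_derivation,
            "unmatched_validation": self.unmatched_validation,
        }


def match_replication(
    derivation: list[ClusterDefinition],
    validation: list[ClusterDefinition],
    *,
    jaccard_threshold: float = 0.2,
    min_shared: int = 2,
) -> ReplicationReport:
    """Optimal one-to-one matching of clusters by signed-feature Jaccard.

    A matched pair counts as replicated iff its Jaccard similarity reaches
    ``jaccard_threshold`` AND it shares at least ``min_shared`` signed features.
    The matching maximizes total similarity (assignment problem) and is
    symmetric in the two cohorts.
    """
    if not derivation or not validation:
        raise TestError("both cluster lists must be non-empty")
    sets_d = [c.signed_features for c in derivation]
    sets_v = [c.signed_features for c in validation]
    S = np.zeros((len(sets_d), len(sets_v)))
    shared = np.zeros_like(S, dtype=int)
    for i, a in enumerate(sets_d):
        for j, b in enumerate(sets_v):
            inter = len(a & b)
            union = len(a | b)
            S[i, j] = inter / union if union else 0.0
            shared[i, j] = inter
    rows, cols = linear_sum_assignment(-S)
    matched, replicated = [], []
    used_d, used_v = set(), set()
    for i, j in zip(rows, cols):
        if S[i, j] <= 0:
            continue
        matched.append((derivation[i].label, validation[j].label,
                        float(S[i, j]), int(shared[i, j])))
        used_d.add(i)
        used_v.add(j)
        if S[i, j] >= jaccard_threshold and shared[i, j] >= min_shared:
            replicated.append((derivation[i].label, validation[j].label))
    return ReplicationReport(
        matched=matched,
        replicated=replicated,
        unmatched_derivation=[c.label for i, c in enumerate(derivation)
                              if i not in used_d],
        unmatched_validation=[c.label for j, c in enumerate(validation)
                              if j not in used_v],
    )
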