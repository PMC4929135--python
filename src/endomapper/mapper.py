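"""Mapper topological clustering: metric, lenses, cover, preimage clusters, nerve.

The construction summarizes a cohort as a graph: subjects are embedded by two
lens coordinates (classical metric scaling of the variance-normalized Euclidean
distance matrix), the lens plane is covered by overlapping rectangles
(``resolution`` intervals per axis, overlap controlled by ``gain``, optionally
rank-equalized), each rectangle's subjects are clustered in the full feature
space, and clusters sharing subjects are joined by edges. An optional binary
per-subject stratifier (asthma presence/absence in the study design) splits the
cover so no node mixes strata.

Conventions made explicit because vendor tools differ: interval half-width is
``gain / (2 * resolution)`` so adjacent intervals overlap by a fraction
``1 - 1/gain``; eigenvector signs are fixed by making the largest-magnitude
loading positive; the within-cell clusterer is single linkage cut at the first
empty bin of a 10-bin histogram of merge heights.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .cohort import CohortTable
from .preprocess import ImputationConfig, auto_log_transform, impute_mean_of_multiple, variance_normalize


@dataclass
class MapperConfig:
    """Cover and clustering parameters for one Mapper run."""

    resolution: int = 30
    gain: float = 3.0
    equalize: bool = True
    stratify_on_asthma: bool = True
    lens: str = "mds"             # "mds" (metric scaling) or "pca"
    histogram_bins: int = 10
    gap_dominance: float = 1.0    # few-merge cells split only if the largest
                                  # inter-height gap exceeds this multiple of
                                  # the remaining gaps combined
    min_cluster_size: int = 1
    imputation: ImputationConfig = field(default_factory=ImputationConfig)

    def __post_init__(self) -> None:
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1")
        if self.gain < 1:
            raise ValueError("gain must be >= 1")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")


@dataclass
class MapperNode:
    node_id: int
    subjects: frozenset[int]      # row indices into the input table
    cell: tuple                   # (axis interval indices..., stratum)
    size: int
    mean_lens: tuple[float, ...]


@dataclass
class MapperGraph:
    """Nerve of the cover: nodes are within-cell clusters, edges share subjects."""

    nodes: list[MapperNode]
    graph: nx.Graph               # node_id -> node_id, edge attr "shared"
    lens_values: np.ndarray       # n x k, retained for audit
    subjects: list[str]
    strata: np.ndarray | None = None

    def subject_nodes(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for node in self.nodes:
            for s in node.subjects:
                out.setdefault(s, []).append(node.node_id)
        return out

    def covered_subjects(self) -> set[int]:
        return set().union(*(n.subjects for n in self.nodes)) if self.nodes else set()

    # -- export -----------------------------------------------------------
    def to_networkx(self, *, node_color: np.ndarray | None = None) -> nx.Graph:
        G = self.graph.copy()
        for node in self.nodes:
            attrs = {
                "size": node.size,
                "subjects": ",".join(self.subjects[i] for i in sorted(node.subjects)),
                "mean_lens_1": node.mean_lens[0],
                "mean_lens_2": node.mean_lens[1] if len(node.mean_lens) > 1 else 0.0,
            }
            if node_color is not None:
                vals = [node_color[i] for i in node.subjects if np.isfinite(node_color[i])]
                attrs["color_value"] = float(np.mean(vals)) if vals else float("nan")
            G.nodes[node.node_id].update(attrs)
        return G

    def write_graphml(self, path, **kw) -> None:
        nx.write_graphml(self.to_networkx(**kw), path)

    def write_json(self, path, **kw) -> None:
        data = nx.node_link_data(self.to_networkx(**kw), edges="links")
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


# ---------------------------------------------------------------------------
# lenses

def mds_lens(distances: np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) metric scaling of a distance matrix.

    Double-center ``-D**2/2``, eigendecompose, and return the top-``k``
    coordinates scaled by the square root of their eigenvalues. The sign of each
    axis is fixed by making its largest-magnitude loading positive; columns are
    ordered by descending eigenvalue. If fewer than ``k`` positive eigenvalues
    exist, a reduced-rank embedding is returned with a warning.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.abs(np.diag(D)).max() > 1e-8:
        raise ValueError("distance matrix must have zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = w > max(w.max(), 0) * 1e-12
    n_pos = int(pos.sum())
    if n_pos < k:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning a rank-{n_pos} lens"
        )
    k_eff = min(k, max(n_pos, 1))
    coords = V[:, :k_eff] * np.sqrt(np.clip(w[:k_eff], 0, None))
    for j in range(k_eff):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def pca_lens(normalized: np.ndarray, k: int = 2) -> np.ndarray:
    """Principal-component lens on an already variance-normalized matrix."""
    X = np.asarray(normalized, dtype=float)
    X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :k] * s[:k]
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def equalize_lens(lens: np.ndarray) -> np.ndarray:
    """Rank-equalize each lens axis to (0, 1): ``(rank - 0.5) / n``, mean ranks for ties."""
    lens = np.asarray(lens, dtype=float)
    if lens.ndim == 1:
        lens = lens[:, None]
    n = lens.shape[0]
    out = np.empty_like(lens)
    for j in range(lens.shape[1]):
        out[:, j] = (rankdata(lens[:, j], method="average") - 0.5) / n
    return out


def minmax_lens(lens: np.ndarray) -> np.ndarray:
    """Affine rescale of each axis to [0, 1] (used when equalization is off)."""
    lens = np.asarray(lens, dtype=float)
    lo, hi = lens.min(axis=0), lens.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (lens - lo) / span


# ---------------------------------------------------------------------------
# cover

@dataclass
class CoverCell:
    intervals: tuple[int, ...]
    stratum: object
    members: np.ndarray  # row indices


def build_cover(
    lens01: np.ndarray,
    config: MapperConfig,
    strata: np.ndarray | None = None,
) -> list[CoverCell]:
    """Overlapping rectangular cover of lens values in [0, 1].

    Per axis there are ``resolution`` intervals with centers ``(i + 0.5) / R``
    and half-width ``gain / (2R)``, clipped to [0, 1]; a subject belongs to a
    cell iff every axis interval contains it and the stratum matches.
    """
    lens01 = np.asarray(lens01, dtype=float)
    if lens01.ndim == 1:
        lens01 = lens01[:, None]
    n, k = lens01.shape
    R, half = config.resolution, config.gain / (2.0 * config.resolution)
    axis_membership = []
    for a in range(k):
        M = np.zeros((n, R), dtype=bool)
        for i in range(R):
            lo = max((i + 0.5) / R - half, 0.0)
            hi = min((i + 0.5) / R + half, 1.0)
            M[:, i] = (lens01[:, a] >= lo) & (lens01[:, a] <= hi)
        axis_membership.append(M)
    strata_levels = [None] if strata is None else sorted(set(np.asarray(strata).tolist()))
    cells = []
    for combo in itertools.product(range(R), repeat=k):
        members = axis_membership[0][:, combo[0]].copy()
        for a in range(1, k):
            members &= axis_membership[a][:, combo[a]]
        if not members.any():
            continue
        for s in strata_levels:
            sel = members if s is None else members & (np.asarray(strata) == s)
            if sel.any():
                cells.append(CoverCell(intervals=combo, stratum=s,
                                       members=np.flatnonzero(sel)))
    return cells


# ---------------------------------------------------------------------------
# preimage clustering and nerve

def cluster_preimage(
    rows: np.ndarray, config: MapperConfig | None = None
) -> list[np.ndarray]:
    """Partition the subjects of one cover cell by single linkage.

    The merge tree is cut at the left edge of the first empty bin of a
    ``histogram_bins``-bin histogram of merge heights (the classic Mapper
    heuristic); with no empty bin, or fewer than three merges, the cell stays a
    single cluster. Returns local index arrays into ``rows``.
    """
    config = config or MapperConfig()
    rows = np.asarray(rows, dtype=float)
    m = rows.shape[0]
    if m <= 1:
        return [np.arange(m)]
    d = pdist(rows)
    Z = linkage(d, method="single")
    heights = Z[:, 2]
    if m == 2 or np.ptp(heights) <= 0:
        return [np.arange(m)]
    if heights.size >= config.histogram_bins:
        counts, edges = np.histogram(heights, bins=config.histogram_bins)
        empty = np.flatnonzero(counts == 0)
        if empty.size == 0:
            return [np.arange(m)]
        threshold = edges[empty[0]]
    else:
        # few merges: a histogram is mostly empty bins, so demand a dominant
        # gap (larger than all other inter-height gaps combined) before cutting
        srt = np.sort(heights)
        gaps = np.diff(srt)
        if gaps.size == 0:
            return [np.arange(m)]
        k = int(np.argmax(gaps))
        others = float(gaps.sum() - gaps[k])
        if gaps[k] <= config.gap_dominance * others:
            return [np.arange(m)]
        threshold = float((srt[k] + srt[k + 1]) / 2.0)
    assign = fcluster(Z, t=threshold, criterion="distance")
    return [np.flatnonzero(assign == c) for c in np.unique(assign)]


def build_nerve(
    cell_partitions: list[tuple[CoverCell, list[np.ndarray]]],
    lens01: np.ndarray,
    subjects: list[str],
    strata: np.ndarray | None = None,
    min_cluster_size: int = 1,
) -> MapperGraph:
    """One node per within-cell cluster; edges join nodes sharing subjects."""
    lens01 = np.asarray(lens01, dtype=float)
    if lens01.ndim == 1:
        lens01 = lens01[:, None]
    # identical subject sets arising in overlapping cells collapse to one node
    nodes: list[MapperNode] = []
    seen: dict[frozenset, int] = {}
    for cell, parts in cell_partitions:
        for local in parts:
            subj = cell.members[local]
            if subj.size < min_cluster_size:
                continue
            key = frozenset(int(i) for i in subj)
            if key in seen:
                continue
            seen[key] = len(nodes)
            nodes.append(
                MapperNode(
                    node_id=len(nodes),
                    subjects=key,
                    cell=(*cell.intervals, cell.stratum),
                    size=int(subj.size),
                    mean_lens=tuple(float(x) for x in lens01[subj].mean(axis=0)),
                )
            )
    G = nx.Graph()
    G.add_nodes_from(n.node_id for n in nodes)
    by_subject: dict[int, list[int]] = {}
    for node in nodes:
        for s in node.subjects:
            by_subject.setdefault(s, []).append(node.node_id)
    shared: dict[tuple[int, int], int] = {}
    for ids in by_subject.values():
        for a, b in itertools.combinations(sorted(ids), 2):
            shared[(a, b)] = shared.get((a, b), 0) + 1
    for (a, b), cnt in shared.items():
        G.add_edge(a, b, shared=cnt)
    graph = MapperGraph(nodes=nodes, graph=G, lens_values=lens01,
                        subjects=list(subjects), strata=strata)
    covered = graph.covered_subjects()
    if len(covered) != len(subjects):
        missing = sorted(set(range(len(subjects))) - covered)
        raise AssertionError(f"subjects not covered by any node: {missing}")
    return graph


# ---------------------------------------------------------------------------
# full run

def run_mapper(
    table: CohortTable,
    config: MapperConfig | None = None,
    *,
    features: np.ndarray | None = None,
) -> MapperGraph:
    """The full construction on a cohort table (clustering-set columns expected).

    Composition: automatic log transform -> imputation (if any cell is missing)
    -> variance normalization -> distance matrix -> lens -> equalization (or
    min-max) -> stratified cover -> per-cell single-linkage clustering on the
    normalized rows -> nerve. Deterministic given table and config.
    ``features`` short-circuits the preprocessing with an already
    variance-normalized matrix.
    """
    config = config or MapperConfig()
    if features is not None:
        X = np.asarray(features, dtype=float)
    else:
        work, _ = auto_log_transform(table)
        if work.missing_mask.any():
            work = impute_mean_of_multiple(work, config.imputation)
        X, _ = variance_normalize(work.values)
    if config.lens == "pca":
        lens = pca_lens(X, k=2)
    else:
        D = squareform(pdist(X))
        lens = mds_lens(D, k=2)
    lens01 = equalize_lens(lens) if config.equalize else minmax_lens(lens)
    strata = table.asthma_flag.astype(int) if config.stratify_on_asthma else None
    cells = build_cover(lens01, config, strata=strata)
    partitions = [(cell, cluster_preimage(X[cell.members], config)) for cell in cells]
    return build_nerve(partitions, lens01, table.subjects, strata=strata,
                       min_cluster_size=config.min_cluster_size)
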