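"""Two-cohort synthetic data with planted endotype clusters.

The generator emulates the statistical structure of a severe-asthma study pair
(derivation and validation cohorts) so the full pipeline is testable without any
patient-level download:

* subjects belong to latent clusters (prototypes) with per-variable location
  shifts on a latent Gaussian scale, in SD units;
* continuous variables are a Gaussian copula: a cluster-shifted multivariate
  normal pushed through each variable's marginal quantile function, so rank
  correlations are controlled exactly and cluster shifts survive monotone
  transforms;
* sputum differential percentages are Dirichlet within each cluster (normalized
  Gammas) whose underlying uniforms come from the same copula, so cell
  percentages can carry rank correlations with mediators while staying
  marginally Dirichlet and summing to 100;
* missingness is MCAR at a configurable overall rate, concentrated by default
  on subjects outside the high-quality sputum subset so that complete-case
  stages remain feasible;
* ground-truth cluster labels travel in a sidecar, never inside the table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import CohortTable, VariableSpec
from .errors import ConfigurationError, GenerationError

DIFFERENTIAL_CELLS = ("macrophage", "neutrophil", "eosinophil", "lymphocyte", "epithelial")
DIFFERENTIAL_VARS = {f"sputum_{c}_pct": c for c in DIFFERENTIAL_CELLS}


def _driver(cell: str) -> str:
    return f"_diff_{cell}"


# ---------------------------------------------------------------------------
# domain types

@dataclass
class Marginal:
    """Marginal family for one variable: normal(loc, scale) or lognormal(mu, sigma)."""

    family: str
    params: dict

    def quantile_from_standard_normal(self, t: np.ndarray) -> np.ndarray:
        if self.family == "normal":
            return self.params["loc"] + self.params["scale"] * t
        if self.family == "lognormal":
            return np.exp(self.params["mu"] + self.params["sigma"] * t)
        raise ConfigurationError(f"unknown marginal family {self.family!r}")


@dataclass
class ClusterPrototype:
    """One planted cluster: mixing weight, latent shifts, differential, discrete probs."""

    label: str
    mixing_weight: float
    asthma: bool = True
    location_shifts: dict[str, float] = field(default_factory=dict)
    differential_concentration: dict[str, float] = field(default_factory=dict)
    categorical_probs: dict[str, dict] = field(default_factory=dict)
    differential_medians: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for cell, a in self.differential_concentration.items():
            if a <= 0:
                raise ConfigurationError(
                    f"prototype {self.label!r}: concentration for {cell!r} must be > 0"
                )
        for name in self.location_shifts:
            if name in DIFFERENTIAL_VARS:
                raise ConfigurationError(
                    f"prototype {self.label!r}: shift cluster differentials via "
                    f"concentrations, not location_shifts ({name!r})"
                )


@dataclass
class CorrelationSpec:
    """Target rank correlations between named variable pairs.

    ``pairs`` holds (name_a, name_b, target Spearman rho). ``ratio_pairs`` holds
    (numerator, denominator, other, rho) targets for a ratio of two log-normal
    variables against a third variable. ``completion_rule`` fills unlisted pairs:
    ``"zero"`` (independent) or ``"path"`` (product of listed correlations along
    the shortest path in the pair graph, exact and positive definite when the
    listed pairs form a forest).
    """

    pairs: list[tuple[str, str, float]] = field(default_factory=list)
    ratio_pairs: list[tuple[str, str, str, float]] = field(default_factory=list)
    completion_rule: str = "path"

    def __post_init__(self) -> None:
        seen: dict[frozenset, float] = {}
        for a, b, r in self.pairs:
            if abs(r) > 1:
                raise ConfigurationError(f"|rho| > 1 for pair ({a}, {b})")
            key = frozenset((a, b))
            if key in seen and seen[key] != r:
                raise ConfigurationError(f"contradictory duplicate pair ({a}, {b})")
            seen[key] = r
        if self.completion_rule not in ("zero", "path"):
            raise ConfigurationError(f"unknown completion_rule {self.completion_rule!r}")


@dataclass
class SyntheticConfig:
    """Everything needed to draw the two study cohorts."""

    variables: list[VariableSpec]
    cohort_sizes: dict[str, int]
    prototypes: dict[str, list[ClusterPrototype]]
    marginals: dict[str, Marginal]
    correlation: CorrelationSpec = field(default_factory=CorrelationSpec)
    quality_sizes: dict[str, int] = field(default_factory=dict)
    missing_rate: float = 0.061
    concentrate_missing_outside_quality: bool = True
    seed: int = 0
    # optional pre-calibrated latent correlation (names must equal latent_columns)
    latent_names: list[str] | None = None
    latent_corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        for cid, protos in self.prototypes.items():
            w = sum(p.mixing_weight for p in protos)
            if abs(w - 1.0) > 1e-6:
                raise ConfigurationError(f"cohort {cid!r}: mixing weights sum to {w}, not 1")
            if self.cohort_sizes.get(cid, 0) < len(protos):
                raise ConfigurationError(
                    f"cohort {cid!r}: size smaller than number of prototypes"
                )


# ---------------------------------------------------------------------------
# rank-correlation plumbing

def spearman_to_latent(rho_s: float) -> float:
    """Gaussian-copula conversion from a Spearman target to the latent Pearson r.

    ``r = 2 sin(pi * rho_s / 6)``; ``|r| >= |rho_s|`` with the same sign.
    """
    if abs(rho_s) > 1:
        raise ConfigurationError(f"Spearman rho must be in [-1, 1], got {rho_s}")
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def nearest_positive_definite(A: np.ndarray, *, eps: float = 1e-8) -> np.ndarray:
    """Higham-style projection to the nearest correlation-like PD matrix."""
    B = (A + A.T) / 2.0
    for _ in range(100):
        w, V = np.linalg.eigh(B)
        if w.min() > eps:
            break
        w = np.clip(w, eps, None)
        B = (V * w) @ V.T
        d = np.sqrt(np.diag(B))
        B = B / np.outer(d, d)
        B = (B + B.T) / 2.0
    np.fill_diagonal(B, 1.0)
    return B


def is_positive_definite(A: np.ndarray, *, eps: float = 1e-10) -> bool:
    return bool(np.linalg.eigvalsh((A + A.T) / 2.0).min() > eps)


def complete_correlation(
    spec: CorrelationSpec,
    variables: list[str],
    *,
    convert: bool = True,
) -> np.ndarray:
    """Build a latent correlation matrix honoring the listed pairs.

    Listed Spearman targets are converted via :func:`spearman_to_latent` (unless
    ``convert=False``, in which case values are taken as latent correlations
    directly). Unlisted pairs are filled by the completion rule, and a
    nearest-PD repair is applied (and warned about) if the result is not
    positive definite.
    """
    idx = {name: i for i, name in enumerate(variables)}
    p = len(variables)
    R = np.eye(p)
    edges: dict[tuple[int, int], float] = {}
    for a, b, r in spec.pairs:
        if a not in idx or b not in idx:
            raise ConfigurationError(f"pair ({a}, {b}) references unknown variables")
        val = spearman_to_latent(r) if convert else float(r)
        i, j = idx[a], idx[b]
        edges[(min(i, j), max(i, j))] = val
        R[i, j] = R[j, i] = val

    if spec.completion_rule == "path":
        # product of edge correlations along shortest paths (exact PD on forests)
        adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(p)}
        for (i, j), val in edges.items():
            adj[i].append((j, val))
            adj[j].append((i, val))
        for s in range(p):
            prod = {s: 1.0}
            frontier = [s]
            while frontier:
                nxt = []
                for u in frontier:
                    for v, val in adj[u]:
                        if v not in prod:
                            prod[v] = prod[u] * val
                            nxt.append(v)
                frontier = nxt
            for t, val in prod.items():
                if t != s and (min(s, t), max(s, t)) not in edges:
                    R[s, t] = R[t, s] = val

    if not is_positive_definite(R):
        warnings.warn("latent correlation matrix repaired to nearest positive definite")
        R = nearest_positive_definite(R)
    return R


# ---------------------------------------------------------------------------
# latent layout

def latent_columns(config: SyntheticConfig) -> list[str]:
    """Ordered names of latent Gaussian columns: copula variables then drivers."""
    cols = [
        v.name
        for v in config.variables
        if v.name in config.marginals and v.name not in DIFFERENTIAL_VARS
    ]
    cols += [_driver(c) for c in DIFFERENTIAL_CELLS]
    return cols


def _latent_matrix(config: SyntheticConfig, names: list[str]) -> np.ndarray:
    if config.latent_corr is not None:
        if config.latent_names != names:
            raise GenerationError("latent_corr does not match the latent column layout")
        R = np.asarray(config.latent_corr)
    else:
        spec = CorrelationSpec(
            pairs=[
                (_map_latent(a), _map_latent(b), r) for a, b, r in config.correlation.pairs
            ],
            completion_rule=config.correlation.completion_rule,
        )
        R = complete_correlation(spec, names)
    if not is_positive_definite(R):
        R = nearest_positive_definite(R)
        if not is_positive_definite(R):
            raise GenerationError("latent correlation matrix not repairable")
    return R


def _map_latent(name: str) -> str:
    return _driver(DIFFERENTIAL_VARS[name]) if name in DIFFERENTIAL_VARS else name


# ---------------------------------------------------------------------------
# sampling

def _allocate(weights: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder allocation of n subjects to clusters (deterministic)."""
    raw = weights * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def sample_cohort(
    config: SyntheticConfig, cohort_id: str, seed: int | None = None
) -> tuple[CohortTable, np.ndarray]:
    """Draw one cohort; returns the table and the ground-truth label array.

    Identical seeds give bit-identical output. The labels are deliberately NOT
    stored in the table (write them with :func:`write_truth_labels`).
    """
    if cohort_id not in config.prototypes:
        raise ConfigurationError(f"no prototypes defined for cohort {cohort_id!r}")
    seed = config.seed if seed is None else seed
    protos = config.prototypes[cohort_id]
    n = config.cohort_sizes[cohort_id]
    cohort_index = sorted(config.cohort_sizes).index(cohort_id)
    ss = np.random.SeedSequence([int(seed) % (2**31), cohort_index])
    rng_latent, rng_disc, rng_quality, rng_miss, rng_perm = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    weights = np.array([p.mixing_weight for p in protos])
    counts = _allocate(weights, n)
    labels_block = np.repeat(np.arange(len(protos)), counts)
    perm = rng_perm.permutation(n)
    labels = labels_block[perm]

    names = latent_columns(config)
    m = len(names)
    R = _latent_matrix(config, names)
    L = np.linalg.cholesky(R)
    Z = rng_latent.standard_normal((n, m)) @ L.T

    # cluster shifts in latent SD units (drivers never shifted)
    delta = np.zeros((len(protos), m))
    col = {name: k for k, name in enumerate(names)}
    for c, proto in enumerate(protos):
        for name, s in proto.location_shifts.items():
            if name not in col:
                raise ConfigurationError(
                    f"prototype {proto.label!r}: shift on unknown variable {name!r}"
                )
            delta[c, col[name]] = s
    X = Z + delta[labels]

    var_names = [v.name for v in config.variables]
    values = np.full((n, len(var_names)), np.nan)
    vcol = {name: j for j, name in enumerate(var_names)}

    # continuous copula variables: the marginal quantile map is applied to the
    # cluster-shifted latent, so marginal params describe within-cluster spread
    # and a shift of s moves the cluster median by s within-cluster SDs
    for name, marg in config.marginals.items():
        if name in DIFFERENTIAL_VARS or name not in vcol:
            continue
        values[:, vcol[name]] = marg.quantile_from_standard_normal(X[:, col[name]])

    # sputum differential: per-cluster Dirichlet via copula-driven Gammas
    alphas = np.zeros((len(protos), len(DIFFERENTIAL_CELLS)))
    for c, proto in enumerate(protos):
        for k, cell in enumerate(DIFFERENTIAL_CELLS):
            alphas[c, k] = proto.differential_concentration.get(cell, 1.0)
    U = stats.norm.cdf(
        np.column_stack([X[:, col[_driver(cell)]] for cell in DIFFERENTIAL_CELLS])
    )
    U = np.clip(U, 1e-12, 1 - 1e-12)
    G = stats.gamma.ppf(U, a=alphas[labels])
    G = np.clip(G, 1e-300, None)
    pct = 100.0 * G / G.sum(axis=1, keepdims=True)
    for k, cell in enumerate(DIFFERENTIAL_CELLS):
        name = f"sputum_{cell}_pct"
        if name in vcol:
            values[:, vcol[name]] = pct[:, k]

    # discrete variables from per-cluster probabilities
    asthma = np.array([protos[c].asthma for c in labels])
    for spec in config.variables:
        if spec.name not in vcol or spec.scale not in ("binary", "categorical"):
            continue
        j = vcol[spec.name]
        if spec.role == "label":
            values[:, j] = asthma.astype(float)
            continue
        out = np.zeros(n)
        u = rng_disc.random(n)
        for c, proto in enumerate(protos):
            sel = labels == c
            if not sel.any():
                continue
            probs = proto.categorical_probs.get(spec.name)
            if probs is None:
                out[sel] = 0.0
            elif isinstance(probs, dict):
                levels = np.array(sorted(probs), dtype=float)
                pvec = np.array([probs[k] for k in sorted(probs)], dtype=float)
                pvec = pvec / pvec.sum()
                out[sel] = levels[np.searchsorted(np.cumsum(pvec), u[sel], side="right")]
            else:  # scalar probability of level 1
                out[sel] = (u[sel] < float(probs)).astype(float)
        values[:, j] = out

    unfilled = [name for name, j in vcol.items() if np.isnan(values[:, j]).all()]
    if unfilled:
        raise GenerationError(f"no marginal or rule for variables: {unfilled}")

    # quality subset
    nq = config.quality_sizes.get(cohort_id, n)
    quality = np.zeros(n, dtype=bool)
    quality[rng_quality.choice(n, size=min(nq, n), replace=False)] = True

    # MCAR missingness on non-label variables
    eligible = np.array([v.role != "label" for v in config.variables])
    mask = np.zeros_like(values, dtype=bool)
    if config.missing_rate > 0:
        if config.concentrate_missing_outside_quality and 0 < nq < n:
            cell_rate = min(config.missing_rate * n / (n - nq), 0.95)
            rows = ~quality
        else:
            cell_rate = config.missing_rate
            rows = np.ones(n, dtype=bool)
        draw = rng_miss.random(values.shape)
        mask[np.ix_(rows, eligible)] = draw[np.ix_(rows, eligible)] < cell_rate
        # keep every variable estimable
        for j in range(values.shape[1]):
            if (~mask[:, j]).sum() < 2:
                keep = rng_miss.choice(np.flatnonzero(mask[:, j]), size=2, replace=False)
                mask[keep, j] = False

    table = CohortTable(
        cohort_id=cohort_id,
        subjects=[f"{cohort_id[:3].upper()}{i + 1:04d}" for i in range(n)],
        variables=list(config.variables),
        values=np.where(mask, np.nan, values),
        missing_mask=mask,
        asthma_flag=asthma,
        quality_flag=quality,
    )
    return table, np.array([protos[c].label for c in labels])


def sample_study(
    config: SyntheticConfig, seed: int | None = None
) -> dict[str, tuple[CohortTable, np.ndarray]]:
    """Draw every configured cohort with one call."""
    return {cid: sample_cohort(config, cid, seed=seed) for cid in config.cohort_sizes}


def sample_combined_quality(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[CohortTable, np.ndarray]:
    """Both cohorts drawn, restricted to the high-quality subsets and stacked.

    This is the population the network stage analyzes (complete high-quality
    sputum data, both cohorts combined).
    """
    tables, labels = [], []
    for cid in sorted(config.cohort_sizes):
        t, lab = sample_cohort(config, cid, seed=seed)
        keep = np.flatnonzero(t.quality_flag)
        tables.append(t.subset_subjects(keep))
        labels.append(lab[keep])
    combined = CohortTable(
        cohort_id="combined",
        subjects=[s for t in tables for s in t.subjects],
        variables=list(config.variables),
        values=np.vstack([t.values for t in tables]),
        missing_mask=np.vstack([t.missing_mask for t in tables]),
        asthma_flag=np.concatenate([t.asthma_flag for t in tables]),
        quality_flag=np.concatenate([t.quality_flag for t in tables]),
    )
    return combined, np.concatenate(labels)


def write_truth_labels(subjects: list[str], labels: np.ndarray, path) -> None:
    """Sidecar ground-truth file: two-column CSV (subject, cluster)."""
    with open(path, "w") as fh:
        fh.write("subject,cluster\n")
        for s, lab in zip(subjects, labels):
            fh.write(f"{s},{lab}\n")
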