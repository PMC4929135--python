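"""End-to-end orchestration: run the two-cohort study and emit every artifact.

Stage order mirrors the study: per cohort, the clustering-set variables are
log-transformed, imputed (mean of 5 chained imputations) and variance
normalized; the Mapper graph is built (gain 3 for the derivation cohort, 4 for
validation, stratified on asthma presence); candidate clusters are extracted
and characterized by K-S tests against the rest of the cohort on all
parameters. Clusters are then matched across cohorts to count replicated
endotypes. Separately, a severe-vs-healthy K-S comparison is computed per
cohort and intersected, and a Bayesian network is learned on the pooled
complete-case high-quality subset of the 74-parameter set.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import bayesnet as bn
from .calibration import default_study_config
from .cohort import CohortTable, select_variables
from .endotyping import (
    ClusterDefinition,
    ReplicationReport,
    TestResult,
    characterize,
    extract_clusters,
    ks_two_sample,
    match_replication,
)
from .errors import TestError
from .mapper import MapperConfig, MapperGraph, run_mapper
from .preprocess import ImputationConfig, auto_log_transform, impute_mean_of_multiple, variance_normalize
from .synthetic import sample_cohort, write_truth_labels


@dataclass
class EndotypingConfig:
    """Extraction and replication thresholds."""

    min_cluster_size: int = 4
    split_fraction: float = 0.25
    modularity_resolution: float = 1.0
    merge_radii: tuple[float, ...] = (0.42, 0.51)
    alpha: float = 0.05
    jaccard_threshold: float = 0.2
    min_shared_features: int = 2
    asthma_only_complement: bool = False


@dataclass
class RunConfig:
    """Everything one study run needs; defaults follow the study settings."""

    seed: int = 1
    cohort_tables: dict[str, CohortTable] | None = None  # None -> synthetic
    mapper: dict[str, MapperConfig] = field(default_factory=lambda: {
        "derivation": MapperConfig(resolution=30, gain=3.0),
        "validation": MapperConfig(resolution=30, gain=4.0),
    })
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    discretization: bn.DiscretizationConfig = field(default_factory=bn.DiscretizationConfig)
    score: bn.ScoreConfig = field(default_factory=bn.ScoreConfig)
    endotyping: EndotypingConfig = field(default_factory=EndotypingConfig)
    run_bayesnet: bool = True
    output_dir: str | None = None


@dataclass
class CohortResult:
    table: CohortTable
    graph: MapperGraph
    clusters: list[set[int]]
    definitions: list[ClusterDefinition]          # asthma-majority clusters only
    healthy_clusters: list[set[int]]


@dataclass
class StudyReport:
    cohorts: dict[str, CohortResult]
    replication: ReplicationReport
    severe_vs_healthy_both: dict[str, list[str]]  # increased / decreased
    severe_tables: dict[str, list[TestResult]]
    network: bn.BayesNet | None
    manifest: dict


def prepare_features(table: CohortTable, imputation: ImputationConfig):
    """Log-transform, impute, and variance-normalize the table (Mapper input)."""
    work, record = auto_log_transform(table)
    if work.missing_mask.any():
        work = impute_mean_of_multiple(work, imputation)
    X, degenerate = variance_normalize(work.values)
    return X, record, degenerate


def severe_vs_healthy(table: CohortTable, alpha: float = 0.05) -> list[TestResult]:
    """Per-feature K-S comparison of severe asthma (GINA step >= 4) vs healthy."""
    if "gina_step" not in table.variable_names:
        raise TestError("severe_vs_healthy requires a gina_step variable")
    gina = table.column("gina_step")
    severe = table.asthma_flag & (gina >= 4)
    healthy = ~table.asthma_flag
    if severe.sum() < 2 or healthy.sum() < 2:
        raise TestError("severe and healthy groups must each hold >= 2 subjects")
    out = []
    for j, spec in enumerate(table.variables):
        if spec.role == "label" or spec.name == "gina_step":
            continue
        col = table.values[:, j]
        x = col[severe]
        y = col[healthy]
        x, y = x[~np.isnan(x)], y[~np.isnan(y)]
        if x.size < 2 or y.size < 2:
            continue
        D, p = ks_two_sample(x, y)
        if p < alpha:
            mx, my = float(np.median(x)), float(np.median(y))
            direction = "higher" if mx > my else ("lower" if mx < my else "tied")
            out.append(TestResult(spec.name, D, p, direction))
    out.sort(key=lambda t: (-t.ks_score, t.feature))
    return out


def _run_cohort(table: CohortTable, mapper_cfg: MapperConfig,
                imputation: ImputationConfig, endo: EndotypingConfig) -> CohortResult:
    clustering = select_variables(table, "clustering")
    X, _, _ = prepare_features(clustering, imputation)
    graph = run_mapper(clustering, mapper_cfg, features=X)
    clusters = extract_clusters(
        graph,
        min_size=endo.min_cluster_size,
        features=X,
        split_fraction=endo.split_fraction,
        resolution=endo.modularity_resolution,
        merge_radii=endo.merge_radii,
    )
    asthma_clusters, healthy_clusters = [], []
    for c in clusters:
        members = np.array(sorted(c))
        (asthma_clusters if table.asthma_flag[members].mean() > 0.5
         else healthy_clusters).append(c)
    definitions = [
        characterize(c, table, alpha=endo.alpha, label=f"{table.cohort_id[:1].upper()}{i + 1}",
                     asthma_only_complement=endo.asthma_only_complement)
        for i, c in enumerate(asthma_clusters)
    ]
    return CohortResult(table=table, graph=graph, clusters=clusters,
                        definitions=definitions, healthy_clusters=healthy_clusters)


def run_study(config: RunConfig | None = None) -> StudyReport:
    """Execute the full derivation + validation analysis; see the module docstring."""
    config = config or RunConfig()
    t_start = time.time()
    manifest: dict = {"seed": config.seed, "stages": {}, "warnings": []}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- load or generate cohorts
        t0 = time.time()
        truth: dict[str, np.ndarray] = {}
        if config.cohort_tables is None:
            synth = default_study_config(seed=config.seed)
            tables = {}
            for cid in sorted(synth.cohort_sizes):
                tables[cid], truth[cid] = sample_cohort(synth, cid, seed=config.seed)
            manifest["source"] = "synthetic"
        else:
            tables = dict(config.cohort_tables)
            manifest["source"] = "user"
        manifest["stages"]["load"] = round(time.time() - t0, 3)
        manifest["cohort_sizes"] = {cid: t.n_subjects for cid, t in tables.items()}

        # --- per-cohort Mapper + endotyping
        results: dict[str, CohortResult] = {}
        for cid, table in tables.items():
            t0 = time.time()
            mcfg = config.mapper.get(cid, MapperConfig())
            mcfg.imputation = ImputationConfig(
                n_imputations=config.imputation.n_imputations,
                max_iterations=config.imputation.max_iterations,
                seed=config.seed,
            )
            results[cid] = _run_cohort(table, mcfg, mcfg.imputation, config.endotyping)
            manifest["stages"][f"mapper+endotype:{cid}"] = round(time.time() - t0, 3)
            manifest[f"clusters:{cid}"] = [len(c) for c in results[cid].clusters]

        # --- replication across cohorts
        t0 = time.time()
        cids = sorted(results)
        if len(cids) >= 2:
            replication = match_replication(
                results[cids[0]].definitions, results[cids[1]].definitions,
                jaccard_threshold=config.endotyping.jaccard_threshold,
                min_shared=config.endotyping.min_shared_features,
            )
        else:
            replication = ReplicationReport(matched=[])
        manifest["stages"]["replication"] = round(time.time() - t0, 3)
        manifest["replicated_count"] = replication.replicated_count

        # --- severe vs healthy, intersected across cohorts
        t0 = time.time()
        severe_tables = {cid: severe_vs_healthy(t) for cid, t in tables.items()}
        both: dict[str, list[str]] = {"increased": [], "decreased": []}
        if len(cids) >= 2:
            sets = []
            for cid in cids[:2]:
                sets.append({(r.feature, r.direction) for r in severe_tables[cid]})
            common = sets[0] & sets[1]
            both["increased"] = sorted(f for f, d in common if d == "higher")
            both["decreased"] = sorted(f for f, d in common if d == "lower")
        manifest["stages"]["severe_vs_healthy"] = round(time.time() - t0, 3)

        # --- pooled Bayesian network on the high-quality complete-case 74-set
        network = None
        if config.run_bayesnet:
            t0 = time.time()
            quality_parts = []
            for cid in cids:
                t = tables[cid]
                keep = (np.flatnonzero(t.quality_flag)
                        if t.quality_flag is not None else np.arange(t.n_subjects))
                quality_parts.append(t.subset_subjects(keep))
            pooled = CohortTable(
                cohort_id="combined",
                subjects=[s for t in quality_parts for s in t.subjects],
                variables=list(tables[cids[0]].variables),
                values=np.vstack([t.values for t in quality_parts]),
                missing_mask=np.vstack([t.missing_mask for t in quality_parts]),
                asthma_flag=np.concatenate([t.asthma_flag for t in quality_parts]),
            )
            bayes_vars = [v.name for v in pooled.variables if v.in_bayes_set]
            cfg_d = config.discretization
            discrete = bn.discretize(pooled, cfg_d, variables=bayes_vars)
            manifest["bayes_dropped_rows"] = discrete.n_dropped_rows
            manifest["bayes_rows"] = int(discrete.codes.shape[0])
            score_cfg = bn.ScoreConfig(
                equivalent_sample_size=config.score.equivalent_sample_size,
                max_parents=config.score.max_parents,
                restarts=config.score.restarts,
                seed=config.seed,
            )
            dag = bn.learn_structure(discrete, score_cfg)
            network = bn.annotate_edges(dag, discrete, pooled,
                                        ess=score_cfg.equivalent_sample_size)
            manifest["stages"]["bayesnet"] = round(time.time() - t0, 3)
            manifest["bayes_included"] = len(network.included)
            manifest["bayes_excluded"] = len(network.excluded)

        manifest["warnings"] = sorted({str(w.message) for w in caught})

    manifest["total_seconds"] = round(time.time() - t_start, 3)
    report = StudyReport(
        cohorts=results,
        replication=replication,
        severe_vs_healthy_both=both,
        severe_tables=severe_tables,
        network=network,
        manifest=manifest,
    )
    if config.output_dir is not None:
        _write_outputs(report, truth, Path(config.output_dir))
    return report


def _write_outputs(report: StudyReport, truth: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for cid, res in report.cohorts.items():
        res.graph.write_graphml(outdir / f"mapper_{cid}.graphml")
        res.graph.write_json(outdir / f"mapper_{cid}.json")
        rows = [row for d in res.definitions for row in d.to_rows()]
        _write_csv(outdir / f"clusters_{cid}.csv",
                   ["cluster", "feature", "ks_score", "p_value", "direction",
                    "bonferroni_significant"], rows)
        sev = [{"feature": r.feature, "ks_score": round(r.ks_score, 4),
                "p_value": r.p_value, "direction": r.direction}
               for r in report.severe_tables[cid]]
        _write_csv(outdir / f"severe_vs_healthy_{cid}.csv",
                   ["feature", "ks_score", "p_value", "direction"], sev)
        if cid in truth:
            write_truth_labels(res.table.subjects, truth[cid],
                               outdir / f"truth_{cid}.csv")
    with open(outdir / "replication.json", "w") as fh:
        json.dump(report.replication.to_json_dict(), fh, indent=1, sort_keys=True)
    with open(outdir / "severe_vs_healthy_both.json", "w") as fh:
        json.dump(report.severe_vs_healthy_both, fh, indent=1, sort_keys=True)
    if report.network is not None:
        report.network.to_graphml(outdir / "bayesnet.graphml")
        report.network.to_dot(outdir / "bayesnet.dot")
    # wall-times live only in the in-memory report so the written manifest is
    # byte-identical across reruns of the same config
    stable = {k: v for k, v in report.manifest.items()
              if k not in ("stages", "total_seconds")}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(stable, fh, indent=1, sort_keys=True)


def _write_csv(path, header, rows) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(str(row[h]) for h in header) + "\n")
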