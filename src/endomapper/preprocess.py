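"""Transformations applied before clustering and network learning.

Three steps, in the order the pipeline uses them: an automatic log10 transform of
skewed continuous variables, mean-of-multiple-imputations missing-data handling,
and variance normalization (so Euclidean distance on the output equals the
variance-normalized Euclidean distance the topological stage requires).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .cohort import CohortTable
from .errors import ImputationError, TransformError


@dataclass
class ImputationConfig:
    """Chained-equations imputation settings: mean of ``n_imputations`` rounds."""

    n_imputations: int = 5
    max_iterations: int = 5
    seed: int = 0
    ridge: float = 1e-3  # regularization for p ~ n regressions

    def __post_init__(self) -> None:
        if self.n_imputations < 1:
            raise ValueError("n_imputations must be >= 1")


@dataclass
class TransformRecord:
    """Per-variable audit of the automatic log-transform decision."""

    transform: dict[str, str] = field(default_factory=dict)  # name -> none|log
    offset: dict[str, float] = field(default_factory=dict)
    skewness: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            name: {
                "transform": self.transform[name],
                "offset": self.offset.get(name, 0.0),
                "skewness_before": self.skewness.get(name, float("nan")),
            }
            for name in self.transform
        }


def auto_log_transform(
    table: CohortTable, *, skew_threshold: float = 1.0
) -> tuple[CohortTable, TransformRecord]:
    """Log10-transform continuous variables whose observed skewness exceeds the threshold.

    Variables on a binary or categorical scale are never candidates. When zeros
    (or negatives clipped at zero) are present the transform is ``log10(x + c)``
    with offset ``c`` = half the smallest positive observed value; a candidate
    with no positive values at all raises :class:`TransformError`.
    """
    values = table.values.copy()
    out_specs = list(table.variables)
    record = TransformRecord()
    for j, spec in enumerate(table.variables):
        name = spec.name
        if spec.scale in ("binary", "categorical"):
            record.transform[name] = "none"
            continue
        obs_mask = ~table.missing_mask[:, j]
        obs = values[obs_mask, j]
        if obs.size < 3:
            record.transform[name] = "none"
            continue
        skew = float(stats.skew(obs, bias=False)) if np.ptp(obs) > 0 else 0.0
        record.skewness[name] = skew
        if skew <= skew_threshold:
            record.transform[name] = "none"
            continue
        positive = obs[obs > 0]
        if positive.size == 0:
            raise TransformError(f"variable {name!r} is skewed but has no positive values")
        offset = 0.0
        if obs.min() <= 0:
            offset = float(positive.min()) / 2.0
        values[obs_mask, j] = np.log10(obs + offset)
        record.transform[name] = "log"
        record.offset[name] = offset
        if spec.scale == "percentage":  # log scale leaves the [0, 100] range
            out_specs[j] = replace(spec, scale="continuous")
    out = CohortTable(
        cohort_id=table.cohort_id,
        subjects=list(table.subjects),
        variables=out_specs,
        values=values,
        missing_mask=table.missing_mask.copy(),
        asthma_flag=table.asthma_flag,
        quality_flag=table.quality_flag,
    )
    return out, record


def variance_normalize(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center each column to mean 0 and scale to sample (n-1) SD 1.

    Returns ``(normalized, degenerate)`` where ``degenerate`` flags zero-variance
    columns, which are set to all-zeros rather than raising.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    degenerate = ~(sd > 0)
    safe_sd = np.where(degenerate, 1.0, sd)
    out = (X - mean) / safe_sd
    out[:, degenerate] = 0.0
    return out, degenerate


def impute_mean_of_multiple(
    table: CohortTable, config: ImputationConfig | None = None
) -> CohortTable:
    """Fill missing cells with the mean of several chained-equations imputations.

    Each round initializes missing cells from observed-value draws, then cycles
    through variables filling each from a ridge regression on all other
    (currently filled) variables plus Gaussian noise at the residual SD. The
    final value is the mean across rounds; observed cells are never touched.
    Binary/categorical columns are rounded to the nearest observed level at the
    end so imputed codes stay on the code scale.
    """
    config = config or ImputationConfig()
    mask = table.missing_mask
    if not mask.any():
        return table
    X = table.values
    n, p = X.shape
    for j, spec in enumerate(table.variables):
        if (~mask[:, j]).sum() < 2:
            raise ImputationError(
                f"variable {spec.name!r} has fewer than 2 observed values"
            )

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x1A7]))
    fills = np.zeros((config.n_imputations, n, p))
    order = [j for j in range(p) if mask[:, j].any()]
    col_obs = {j: X[~mask[:, j], j] for j in range(p)}
    for m in range(config.n_imputations):
        Xm = X.copy()
        # initialize by resampling observed values
        for j in order:
            miss = mask[:, j]
            Xm[miss, j] = rng.choice(col_obs[j], size=int(miss.sum()), replace=True)
        for _ in range(config.max_iterations):
            for j in order:
                miss = mask[:, j]
                others = [k for k in range(p) if k != j]
                Z = Xm[:, others]
                mu, sd = Z.mean(axis=0), Z.std(axis=0, ddof=1)
                sd[sd == 0] = 1.0
                Z = (Z - mu) / sd
                Z = np.column_stack([np.ones(n), Z])
                obs = ~miss
                A = Z[obs].T @ Z[obs] + config.ridge * n * np.eye(Z.shape[1])
                beta = np.linalg.solve(A, Z[obs].T @ Xm[obs, j])
                resid = Xm[obs, j] - Z[obs] @ beta
                dof = max(int(obs.sum()) - 1, 1)
                sigma = float(np.sqrt((resid @ resid) / dof))
                Xm[miss, j] = Z[miss] @ beta + rng.normal(0.0, sigma, size=int(miss.sum()))
        fills[m] = Xm
    filled = fills.mean(axis=0)
    filled[~mask] = X[~mask]
    # snap discrete columns back onto their observed code levels
    for j, spec in enumerate(table.variables):
        if spec.scale in ("binary", "categorical") and mask[:, j].any():
            levels = np.unique(col_obs[j])
            vals = filled[mask[:, j], j]
            filled[mask[:, j], j] = levels[
                np.argmin(np.abs(vals[:, None] - levels[None, :]), axis=1)
            ]
        if spec.scale == "percentage" and mask[:, j].any():
            filled[mask[:, j], j] = np.clip(filled[mask[:, j], j], 0.0, 100.0)
    return CohortTable(
        cohort_id=table.cohort_id,
        subjects=list(table.subjects),
        variables=list(table.variables),
        values=filled,
        missing_mask=np.zeros_like(mask),
        asthma_flag=table.asthma_flag,
        quality_flag=table.quality_flag,
    )
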