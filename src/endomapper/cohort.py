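"""Cohort feature tables and the variable dictionary.

A cohort is a rectangular subject x variable matrix with an explicit missingness
mask and a companion dictionary describing every variable: its role (demographic,
physiology, questionnaire, sputum cell, mediator, treatment, label), measurement
scale, units, transform hint, and whether it belongs to the clustering set (the
29 clinical/physiologic/cellular parameters used to build the topological
network) or the network set (the 74 parameters entering the Bayesian network).

The packaged default dictionary (``data/variables.yaml``) is a reconstruction of
the study roster of 103 parameters; it is data, not code, and can be swapped for
any user-supplied dictionary with the same schema.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ParseError, SchemaError

ROLES = {
    "demographic",
    "physiology",
    "questionnaire",
    "sputum_cell",
    "mediator_sputum",
    "mediator_serum",
    "treatment",
    "label",
}
SCALES = {"binary", "categorical", "continuous", "percentage"}

#: cell spellings accepted as missing in delimited tables (case-insensitive)
MISSING_TOKENS = {"", "na", "nan"}


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of a single variable in the dictionary."""

    name: str
    role: str
    scale: str = "continuous"
    units: str = ""
    transform_hint: str = "none"
    in_clustering_set: bool = False
    in_bayes_set: bool = False
    levels: tuple[str, ...] | None = None  # labels for categorical codes

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemaError(f"variable {self.name!r}: unknown role {self.role!r}")
        if self.scale not in SCALES:
            raise SchemaError(f"variable {self.name!r}: unknown scale {self.scale!r}")
        if self.transform_hint not in {"none", "log"}:
            raise SchemaError(
                f"variable {self.name!r}: unknown transform_hint {self.transform_hint!r}"
            )


@dataclass
class CohortTable:
    """Subject x variable matrix with missingness mask and variable dictionary.

    ``values`` is float64; masked entries hold NaN. ``asthma_flag`` and
    ``quality_flag`` are per-subject booleans (quality marks the highest-quality
    sputum subset used, without imputation, by the network stage).
    """

    cohort_id: str
    subjects: list[str]
    variables: list[VariableSpec]
    values: np.ndarray
    missing_mask: np.ndarray
    asthma_flag: np.ndarray
    quality_flag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.values.shape
        if n < 2:
            raise SchemaError("a cohort needs at least 2 subjects")
        if len(self.subjects) != n or len(self.variables) != p:
            raise SchemaError("values shape does not match subjects/variables")
        if self.missing_mask.shape != (n, p):
            raise SchemaError("missing_mask shape does not match values")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("variable names are not unique")
        self.asthma_flag = np.asarray(self.asthma_flag, dtype=bool)
        if self.asthma_flag.shape != (n,):
            raise SchemaError("asthma_flag must be per-subject")
        if self.quality_flag is not None:
            self.quality_flag = np.asarray(self.quality_flag, dtype=bool)
        # mask true <=> value absent (stored as NaN)
        self.values = np.where(self.missing_mask, np.nan, self.values)
        for j, v in enumerate(self.variables):
            if v.scale == "percentage":
                obs = self.values[~self.missing_mask[:, j], j]
                if obs.size and (obs.min() < -1e-9 or obs.max() > 100 + 1e-9):
                    raise SchemaError(f"percentage variable {v.name!r} outside [0, 100]")

    # -- convenience -------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def column(self, name: str, observed_only: bool = False) -> np.ndarray:
        j = self.variable_names.index(name)
        col = self.values[:, j]
        return col[~self.missing_mask[:, j]] if observed_only else col

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subjects, columns=self.variable_names)

    def subset_subjects(self, index: np.ndarray) -> "CohortTable":
        index = np.asarray(index)
        return CohortTable(
            cohort_id=self.cohort_id,
            subjects=[self.subjects[i] for i in index],
            variables=list(self.variables),
            values=self.values[index],
            missing_mask=self.missing_mask[index],
            asthma_flag=self.asthma_flag[index],
            quality_flag=None if self.quality_flag is None else self.quality_flag[index],
        )


# ---------------------------------------------------------------------------
# dictionary I/O

def read_dictionary(path) -> list[VariableSpec]:
    """Load a variable dictionary from YAML (list of mappings, one per variable)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _specs_from_raw(raw)


def _specs_from_raw(raw) -> list[VariableSpec]:
    specs = []
    for entry in raw:
        entry = dict(entry)
        if "levels" in entry and entry["levels"] is not None:
            entry["levels"] = tuple(str(x) for x in entry["levels"])
        specs.append(VariableSpec(**entry))
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate variable names in dictionary")
    return specs


def write_dictionary(specs: list[VariableSpec], path) -> None:
    raw = []
    for s in specs:
        d = {
            "name": s.name,
            "role": s.role,
            "scale": s.scale,
            "units": s.units,
            "transform_hint": s.transform_hint,
            "in_clustering_set": s.in_clustering_set,
            "in_bayes_set": s.in_bayes_set,
        }
        if s.levels is not None:
            d["levels"] = list(s.levels)
        raw.append(d)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def default_dictionary() -> list[VariableSpec]:
    """The packaged 103-variable roster with clustering-set and network-set flags."""
    ref = importlib.resources.files("endomapper.data").joinpath("variables.yaml")
    return _specs_from_raw(yaml.safe_load(ref.read_text()))


# ---------------------------------------------------------------------------
# table I/O

def read_cohort(
    table_path,
    dictionary_path=None,
    *,
    cohort_id: str | None = None,
    delimiter: str | None = None,
    variables: list[VariableSpec] | None = None,
) -> CohortTable:
    """Read a delimited table (first column = subject id) against a dictionary.

    The delimiter is inferred from the extension (``.tsv`` -> tab, else comma)
    unless given. Empty cells and the spellings NA / NaN (case-insensitive) are
    missing; anything else non-numeric in a numeric column is a :class:`ParseError`.
    """
    if variables is None:
        if dictionary_path is None:
            raise ConfigurationError("either dictionary_path or variables is required")
        variables = read_dictionary(dictionary_path)
    if delimiter is None:
        delimiter = "\t" if str(table_path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(table_path, sep=delimiter, dtype=str, keep_default_na=False)
    id_col = df.columns[0]
    declared = {v.name for v in variables}
    table_cols = [c for c in df.columns[1:]]
    undeclared = [c for c in table_cols if c not in declared]
    if undeclared:
        raise SchemaError(f"columns not in dictionary: {undeclared}")
    missing_cols = [v.name for v in variables if v.name not in table_cols]
    if missing_cols:
        raise SchemaError(f"dictionary variables absent from table: {missing_cols}")

    subjects = df[id_col].astype(str).tolist()
    n, p = len(subjects), len(variables)
    values = np.full((n, p), np.nan)
    mask = np.zeros((n, p), dtype=bool)
    for j, spec in enumerate(variables):
        col = df[spec.name].astype(str).str.strip()
        is_missing = col.str.lower().isin(MISSING_TOKENS)
        mask[:, j] = is_missing.to_numpy()
        for i, (miss, cell) in enumerate(zip(is_missing, col)):
            if miss:
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric value {cell!r} at row {i} (subject {subjects[i]!r}), "
                    f"column {spec.name!r}"
                ) from None

    asthma = _flag_from(values, mask, variables, "asthma", default=np.ones(n, bool))
    quality = _flag_from(values, mask, variables, "sputum_quality", default=None)
    return CohortTable(
        cohort_id=cohort_id or str(table_path),
        subjects=subjects,
        variables=variables,
        values=values,
        missing_mask=mask,
        asthma_flag=asthma,
        quality_flag=quality,
    )


def _flag_from(values, mask, variables, name, default):
    names = [v.name for v in variables]
    if name in names:
        j = names.index(name)
        col = np.where(mask[:, j], 0.0, values[:, j])
        return col > 0.5
    return default


def write_cohort(table: CohortTable, path, *, delimiter: str | None = None) -> None:
    """Write a table readable back by :func:`read_cohort` (lossless round trip)."""
    if delimiter is None:
        delimiter = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = table.to_dataframe().copy()
    df.insert(0, "subject_id", table.subjects)
    df.to_csv(path, sep=delimiter, index=False, na_rep="NA", float_format="%.17g")


# ---------------------------------------------------------------------------
# selection

def select_variables(table: CohortTable, which: str) -> CohortTable:
    """Column-subset a cohort by flag: ``"clustering"``, ``"bayes"`` or ``"all"``.

    Subject order and the missingness mask are preserved; an empty selection is
    a configuration error.
    """
    if which == "all":
        keep = [True] * table.n_variables
    elif which == "clustering":
        keep = [v.in_clustering_set for v in table.variables]
    elif which == "bayes":
        keep = [v.in_bayes_set for v in table.variables]
    else:
        raise ConfigurationError(f"unknown selection {which!r}")
    idx = [j for j, k in enumerate(keep) if k]
    if not idx:
        raise ConfigurationError(f"selection {which!r} matched no variables")
    return CohortTable(
        cohort_id=table.cohort_id,
        subjects=list(table.subjects),
        variables=[table.variables[j] for j in idx],
        values=table.values[:, idx],
        missing_mask=table.missing_mask[:, idx],
        asthma_flag=table.asthma_flag,
        quality_flag=table.quality_flag,
    )


def select_named(table: CohortTable, names: list[str]) -> CohortTable:
    """Column-subset by explicit variable names (order follows ``names``)."""
    pos = {v.name: j for j, v in enumerate(table.variables)}
    missing = [n for n in names if n not in pos]
    if missing:
        raise ConfigurationError(f"unknown variables: {missing}")
    idx = [pos[n] for n in names]
    if not idx:
        raise ConfigurationError("empty selection")
    return CohortTable(
        cohort_id=table.cohort_id,
        subjects=list(table.subjects),
        variables=[table.variables[j] for j in idx],
        values=table.values[:, idx],
        missing_mask=table.missing_mask[:, idx],
        asthma_flag=table.asthma_flag,
        quality_flag=table.quality_flag,
    )
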