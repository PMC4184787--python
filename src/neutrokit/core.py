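"""Expression-matrix data model, I/O, and population-level summary primitives.

The package's currency is a genes x samples matrix of normalized,
linear-scale microarray intensities together with a map from each sample to
the cell population it profiles (e.g. bone-marrow neutrophils, blood
neutrophils, or one of ~200 non-neutrophil immune populations).  All
downstream screens operate on *population means* -- the mean intensity over
the replicate samples of each population -- and log2 transforms are applied
only where a specific analysis calls for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NEUTROPHIL = "neutrophil"
NON_NEUTROPHIL = "non_neutrophil"

#: Activation/source condition labels used for neutrophil populations.
CONDITIONS = ("BM", "BL", "SF", "UA", "TG")


class ValidationError(ValueError):
    """Raised when an input matrix or population map violates an invariant."""


@dataclass(frozen=True)
class PopulationGroup:
    """One profiled cell population.

    Parameters
    ----------
    population_id
        Unique identifier of the population.
    group_class
        Either ``"neutrophil"`` or ``"non_neutrophil"``.
    condition
        Optional condition label (``BM``, ``BL``, ``SF``, ``UA``, ``TG`` for
        the neutrophil populations; free-form or empty otherwise).
    """

    population_id: str
    group_class: str
    condition: str = ""

    def __post_init__(self) -> None:
        if self.group_class not in (NEUTROPHIL, NON_NEUTROPHIL):
            raise ValidationError(
                f"population {self.population_id!r}: class must be "
                f"{NEUTROPHIL!r} or {NON_NEUTROPHIL!r}, got {self.group_class!r}"
            )


@dataclass
class AnalysisConfig:
    """Thresholds and sizes shared across the pipeline stages.

    Defaults are the values routinely used for this microarray platform:
    intensity 120 as the reliable-expression cut-off (associated with ~95%
    probability of detectable protein), ANOVA P<0.01 and fold >=2 for the
    between-condition variation filter, within-group CV<0.5 for replicate
    consistency, K-means with k=32, an 81-bin regulatory model with 10,000
    permutations, FDR cut-offs Q<0.05 (modules) and Q<0.01 (regulator
    pairs), and an 8-fold heatmap color span.
    """

    presence_threshold: float = 120.0
    anova_p: float = 0.01
    min_fold: float = 2.0
    relaxed_fold: float = 1.5
    max_cv: float = 0.5
    k_clusters: int = 32
    n_modules: int = 81
    n_permutations: int = 10_000
    q_module: float = 0.05
    q_pair: float = 0.01
    heatmap_fold_span: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("presence_threshold", "min_fold", "relaxed_fold", "max_cv",
                     "heatmap_fold_span"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("anova_p", "q_module", "q_pair"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1)")
        for name in ("k_clusters", "n_modules", "n_permutations"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")


@dataclass
class ExpressionMatrix:
    """Validated genes x samples intensity matrix with its population map.

    ``values`` is a float DataFrame indexed by gene id with one column per
    sample; ``populations`` is indexed by sample id with columns
    ``population_id``, ``group_class`` and ``condition``.  Every sample in
    the matrix must be mapped, values must be finite and non-negative, and
    gene/sample ids must be unique.
    """

    values: pd.DataFrame
    populations: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        arr = v.to_numpy(dtype=float, copy=False)
        if not np.isfinite(arr).all():
            bad = v.index[np.where(~np.isfinite(arr))[0][0]]
            raise ValidationError(f"non-finite or missing value in gene {bad!r}")
        if (arr < 0).any():
            bad = v.index[np.where((arr < 0).any(axis=1))[0][0]]
            raise ValidationError(f"negative intensity in gene {bad!r}")
        missing = v.columns.difference(self.populations.index)
        if len(missing):
            raise ValidationError(f"sample not in population map: {missing[0]!r}")
        self.populations = self.populations.loc[v.columns]
        for sid, cls in self.populations["group_class"].items():
            if cls not in (NEUTROPHIL, NON_NEUTROPHIL):
                raise ValidationError(
                    f"sample {sid!r}: invalid class {cls!r}"
                )

    # -- convenience accessors -------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def sample_to_population(self) -> pd.Series:
        return self.populations["population_id"]

    def population_ids(self) -> list[str]:
        """Population ids in order of first appearance among the samples."""
        return list(dict.fromkeys(self.sample_to_population))

    def populations_of_class(self, group_class: str) -> list[str]:
        mask = self.populations["group_class"] == group_class
        return list(dict.fromkeys(self.populations.loc[mask, "population_id"]))

    def samples_of(self, population_id: str) -> list[str]:
        mask = self.sample_to_population == population_id
        return list(self.sample_ids[mask])

    def condition_of(self, population_id: str) -> str:
        mask = self.sample_to_population == population_id
        return str(self.populations.loc[mask, "condition"].iloc[0])

    # -- I/O --------------------------------------------------------------

    def save(self, matrix_path: str | Path, popmap_path: str | Path) -> None:
        """Write the tab-delimited matrix and the CSV population map."""
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(matrix_path, sep="\t", lineterminator="\n")
        pop = self.populations.copy()
        pop.index.name = "sample_id"
        pop.to_csv(popmap_path, lineterminator="\n")


def load_expression(matrix_path: str | Path,
                    popmap_path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix and its population map.

    The matrix file has a header row of sample ids with first cell
    ``gene_id``; the map is a CSV with columns ``sample_id``,
    ``population_id``, ``group_class`` (``neutrophil``/``non_neutrophil``)
    and ``condition``.  Duplicated ids, negative or non-numeric values and
    unmapped samples are rejected with the offending identifier.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0,
                         float_precision="round_trip")
    if values.index.name != "gene_id":
        raise ValidationError(
            f"first header cell must be 'gene_id', got {values.index.name!r}"
        )
    for col in values.columns:
        if not pd.api.types.is_numeric_dtype(values[col]):
            bad = values.index[pd.to_numeric(values[col], errors="coerce").isna()]
            raise ValidationError(
                f"non-numeric value in sample {col!r}"
                + (f", gene {bad[0]!r}" if len(bad) else "")
            )
    values.index = values.index.astype(str)
    pop = pd.read_csv(popmap_path, dtype=str).fillna("")
    required = {"sample_id", "population_id", "group_class", "condition"}
    if not required.issubset(pop.columns):
        raise ValidationError(
            f"population map missing columns: {sorted(required - set(pop.columns))}"
        )
    if pop["sample_id"].duplicated().any():
        dup = pop.loc[pop["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample id in population map: {dup!r}")
    pop = pop.set_index("sample_id")
    return ExpressionMatrix(values.astype(float), pop)


def load_expression_long(long_path: str | Path,
                         popmap_path: str | Path) -> ExpressionMatrix:
    """Read a 3-column long-format table (gene_id, sample_id, value)."""
    long = pd.read_csv(long_path, sep="\t",
                       dtype={"gene_id": str, "sample_id": str},
                       float_precision="round_trip")
    required = {"gene_id", "sample_id", "value"}
    if not required.issubset(long.columns):
        raise ValidationError(
            f"long format missing columns: {sorted(required - set(long.columns))}"
        )
    if long.duplicated(["gene_id", "sample_id"]).any():
        bad = long.loc[long.duplicated(["gene_id", "sample_id"]), "gene_id"]
        raise ValidationError(f"duplicate (gene, sample) entry: {bad.iloc[0]!r}")
    values = long.pivot(index="gene_id", columns="sample_id", values="value")
    if values.isna().any().any():
        bad = values.index[values.isna().any(axis=1)][0]
        raise ValidationError(f"missing value for gene {bad!r}")
    pop = pd.read_csv(popmap_path, dtype=str).fillna("").set_index("sample_id")
    return ExpressionMatrix(values.astype(float), pop)


def population_means(m: ExpressionMatrix) -> pd.DataFrame:
    """Mean intensity over the replicate samples of each population.

    Returns a genes x populations DataFrame on the linear scale, columns in
    order of first appearance of each population among the samples.
    """
    order = m.population_ids()
    grouped = m.values.T.groupby(m.sample_to_population, sort=False).mean().T
    return grouped[order]


def summarize_populations(means: pd.DataFrame,
                          popset: Sequence[str],
                          threshold: float) -> pd.DataFrame:
    """Median, min, max, and strict count-above-threshold over a population set.

    The median of an even-sized set is the mean of the two central values.
    ``count_above`` counts populations whose mean is strictly greater than
    ``threshold``.
    """
    popset = list(popset)
    if not popset:
        raise ValidationError("population set is empty")
    sub = means[popset].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "median": np.median(sub, axis=1),
            "min": sub.min(axis=1),
            "max": sub.max(axis=1),
            "count_above": (sub > threshold).sum(axis=1),
        },
        index=means.index,
    )


def log2_mean_center(means: pd.DataFrame,
                     popset: Sequence[str] | None = None) -> pd.DataFrame:
    """log2-transform and mean-center each gene across a population set.

    No pseudocount is added: normalized intensities on this platform are
    bounded well above zero, so a non-positive mean indicates corrupt input
    and raises.
    """
    sub = means if popset is None else means[list(popset)]
    arr = sub.to_numpy(dtype=float)
    if (arr <= 0).any():
        bad = sub.index[np.where((arr <= 0).any(axis=1))[0][0]]
        raise ValidationError(f"non-positive mean for gene {bad!r}")
    logs = np.log2(arr)
    centered = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=sub.index, columns=sub.columns)
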