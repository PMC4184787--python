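"""Regulator inference from a gene-module regulatory model.

The model assigns every target gene to exactly one coarse co-expression
module (up to 81 bins) and links each module to several candidate
regulators with regression-derived weights (weights are comparable only
within a module and are never combined arithmetically across modules; the
tests here use them only to define which regulator-module associations
exist).

Two complementary enrichment analyses identify regulators of a gene list:

* **module-bin permutation** -- the list's X model-target genes are compared
  with 10,000 random draws of X distinct targets; a module whose observed
  gene count is rarely reached by chance is enriched (BH across modules,
  Q<0.05), and its associated regulators are candidates;
* **regulator-target-pair over-representation** -- each listed gene
  contributes one pair per regulator associated with its module; a 2x2
  chi-square compares a regulator's pairs in the list against its maximum
  pairs in the model (BH across regulators, Q<0.01).

A regulator is *selected* when it passes the pair test in some cluster pool
and is associated with an enriched module in some pool.  Per-cluster raw
pair p-values form a regulator x cluster matrix, hierarchically clustered
on both axes to reveal related regulators and related expression patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core import ValidationError
from .stats import bh_adjust, enrichment_2x2


@dataclass
class RegulatoryModel:
    """Gene -> coarse-module assignment plus regulator-module associations.

    ``targets``: Series mapping gene id to module id (each gene in exactly
    one module).  ``associations``: DataFrame with columns ``regulator_id``,
    ``module_id``, ``weight`` (one row per association; zero-weight rows are
    dropped at validation).  Every module must have at least one target and
    one associated regulator.
    """

    targets: pd.Series
    associations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.targets.index.has_duplicates:
            dup = self.targets.index[self.targets.index.duplicated()][0]
            raise ValidationError(f"gene assigned to multiple modules: {dup!r}")
        required = {"regulator_id", "module_id", "weight"}
        if not required.issubset(self.associations.columns):
            raise ValidationError(
                f"associations missing columns: "
                f"{sorted(required - set(self.associations.columns))}"
            )
        self.associations = self.associations.loc[
            self.associations["weight"] != 0
        ].reset_index(drop=True)
        target_modules = set(self.targets.unique())
        assoc_modules = set(self.associations["module_id"].unique())
        if target_modules - assoc_modules:
            bad = sorted(target_modules - assoc_modules)[0]
            raise ValidationError(f"module {bad!r} has no associated regulator")
        if assoc_modules - target_modules:
            bad = sorted(assoc_modules - target_modules)[0]
            raise ValidationError(f"module {bad!r} has no target gene")

    # -- derived quantities ----------------------------------------------

    @property
    def module_sizes(self) -> pd.Series:
        return self.targets.value_counts().sort_index()

    @property
    def regulator_ids(self) -> list:
        return sorted(self.associations["regulator_id"].unique())

    def modules_of_regulator(self, regulator_id) -> list:
        mask = self.associations["regulator_id"] == regulator_id
        return sorted(self.associations.loc[mask, "module_id"].unique())

    def regulators_of_module(self, module_id) -> list:
        mask = self.associations["module_id"] == module_id
        return sorted(self.associations.loc[mask, "regulator_id"].unique())

    @property
    def regulators_per_module(self) -> pd.Series:
        """Number of distinct regulators associated with each module."""
        return (self.associations.groupby("module_id")["regulator_id"]
                .nunique().sort_index())

    @property
    def max_pairs_per_regulator(self) -> pd.Series:
        """Maximum regulator-target pairs each regulator can generate
        (sum of its modules' target counts)."""
        sizes = self.module_sizes
        uniq = self.associations.drop_duplicates(["regulator_id", "module_id"])
        pairs = uniq["module_id"].map(sizes)
        return pairs.groupby(uniq["regulator_id"]).sum().sort_index()

    @property
    def total_pairs(self) -> int:
        return int(self.max_pairs_per_regulator.sum())

    # -- I/O --------------------------------------------------------------

    def save(self, targets_path: str | Path, regulators_path: str | Path) -> None:
        t = self.targets.rename("module_id")
        t.index.name = "gene_id"
        t.to_csv(targets_path, sep="\t", lineterminator="\n")
        self.associations.to_csv(regulators_path, sep="\t", index=False,
                                 lineterminator="\n")

    @classmethod
    def load(cls, targets_path: str | Path,
             regulators_path: str | Path) -> "RegulatoryModel":
        t = pd.read_csv(targets_path, sep="\t", index_col="gene_id")["module_id"]
        a = pd.read_csv(regulators_path, sep="\t")
        return cls(t, a)


# ---------------------------------------------------------------------------
# module-bin permutation enrichment


def _restrict_to_targets(genes: Iterable, model: RegulatoryModel) -> pd.Index:
    genes = pd.Index(pd.unique(pd.Index(genes)))
    hits = genes[genes.isin(model.targets.index)]
    if len(hits) == 0:
        raise ValidationError("no gene in the list is a model target")
    return hits


def module_null_counts(model: RegulatoryModel, x: int, n_perm: int,
                       rng: np.random.Generator) -> tuple[np.ndarray, list]:
    """Null per-module hit counts: n_perm draws of x distinct targets.

    Returns ``(counts, module_order)`` with counts of shape
    (n_perm, n_modules).  Vectorized by ranking a uniform matrix per row --
    equivalent to sampling without replacement.
    """
    module_order = list(model.module_sizes.index)
    code = {m: i for i, m in enumerate(module_order)}
    gene_modules = model.targets.map(code).to_numpy()
    n_targets = gene_modules.size
    counts = np.empty((n_perm, len(module_order)), dtype=np.int64)
    chunk = max(1, int(2e7) // max(n_targets, 1))
    for start in range(0, n_perm, chunk):
        stop = min(start + chunk, n_perm)
        u = rng.random((stop - start, n_targets))
        picks = np.argpartition(u, x - 1, axis=1)[:, :x]
        chosen = gene_modules[picks]
        block = np.zeros(((stop - start), len(module_order)), dtype=np.int64)
        rows = np.repeat(np.arange(stop - start), x)
        np.add.at(block, (rows, chosen.ravel()), 1)
        counts[start:stop] = block
    return counts, module_order


def module_bin_enrichment(genes: Iterable, model: RegulatoryModel,
                          n_perm: int = 10_000, seed: int = 0,
                          q_threshold: float = 0.05,
                          null_counts: np.ndarray | None = None,
                          ) -> pd.DataFrame:
    """Permutation test for over-populated coarse modules.

    X = number of distinct listed genes that are model targets.  Each of
    ``n_perm`` permutations distributes X genes (drawn without replacement
    from all targets) into the modules; the per-module p-value is the
    smoothed upper tail (1 + #{null count >= observed}) / (n_perm + 1),
    BH-adjusted across modules.  ``null_counts`` allows re-using a
    precomputed null for the same X and model.
    """
    hits = _restrict_to_targets(genes, model)
    x = len(hits)
    observed = (model.targets.loc[hits].value_counts()
                .reindex(model.module_sizes.index, fill_value=0))
    if null_counts is None:
        rng = np.random.default_rng(seed)
        null_counts, module_order = module_null_counts(model, x, n_perm, rng)
    else:
        module_order = list(model.module_sizes.index)
        n_perm = null_counts.shape[0]
    obs = observed.loc[module_order].to_numpy()
    exceed = (null_counts >= obs[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    sizes = model.module_sizes.loc[module_order].to_numpy()
    expected = x * sizes / sizes.sum()
    out = pd.DataFrame(
        {
            "size": sizes,
            "observed": obs,
            "expected": expected,
            "p": p,
            "q": bh_adjust(p),
        },
        index=pd.Index(module_order, name="module_id"),
    )
    out["enriched"] = out["q"] < q_threshold
    out.attrs["x"] = x
    out.attrs["n_dropped"] = len(pd.Index(pd.unique(pd.Index(genes)))) - x
    return out


# ---------------------------------------------------------------------------
# regulator-target-pair over-representation


def pair_enrichment(genes: Iterable, model: RegulatoryModel,
                    q_threshold: float = 0.01) -> pd.DataFrame:
    """Chi-square over-representation of regulator-target pairs in a list.

    A listed target gene contributes one pair to every regulator associated
    with its module.  For each regulator the 2x2 table contrasts its pairs
    vs all other regulators' pairs, in-list vs remaining-in-model; Pearson
    chi-square without continuity correction, Fisher fallback when an
    expected cell is below 5, BH across regulators.
    """
    hits = _restrict_to_targets(genes, model)
    module_counts = model.targets.loc[hits].value_counts()
    uniq = model.associations.drop_duplicates(["regulator_id", "module_id"])
    in_list = (uniq["module_id"].map(module_counts).fillna(0)
               .groupby(uniq["regulator_id"]).sum().sort_index())
    max_pairs = model.max_pairs_per_regulator
    total_in_list = int(in_list.sum())
    total_model = model.total_pairs

    rows = []
    for reg in max_pairs.index:
        a = int(in_list.get(reg, 0))
        b = total_in_list - a
        c = int(max_pairs[reg]) - a
        d = (total_model - int(max_pairs[reg])) - b
        if max_pairs[reg] == 0:
            raise ValidationError(f"regulator {reg!r} has zero model pairs")
        stat, p, method = enrichment_2x2(a, b, c, d)
        expected = total_in_list * max_pairs[reg] / total_model
        # one-sided call: only over-represented regulators are of interest
        enriched_direction = a > expected
        rows.append((reg, a, int(max_pairs[reg]), expected, stat, p, method,
                     enriched_direction))
    out = pd.DataFrame(
        rows,
        columns=["regulator_id", "observed", "max_pairs", "expected",
                 "statistic", "p", "method", "over"],
    ).set_index("regulator_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["selected"] = (out["q"] < q_threshold) & out["over"]
    out.attrs["total_pairs_in_list"] = total_in_list
    return out


def select_regulators(pool_pair_results: Mapping[str, pd.DataFrame],
                      pool_module_results: Mapping[str, pd.DataFrame],
                      model: RegulatoryModel,
                      q_pair: float = 0.01,
                      q_module: float = 0.05) -> list:
    """Dual-criterion regulator selection.

    A regulator is kept when (a) its pairs are over-represented (BH
    Q<``q_pair``) in at least one cluster pool, and (b) it is associated
    with a module enriched (BH Q<``q_module``) in at least one pool.
    """
    pair_hits: set = set()
    for res in pool_pair_results.values():
        mask = (res["q"] < q_pair) & res.get("over", True)
        pair_hits.update(res.index[mask])
    module_hits: set = set()
    for res in pool_module_results.values():
        for module_id in res.index[res["q"] < q_module]:
            module_hits.update(model.regulators_of_module(module_id))
    return sorted(pair_hits & module_hits)


def regulator_cluster_matrix(cluster_genes: Mapping, regulators: Sequence,
                             model: RegulatoryModel,
                             ) -> tuple[pd.DataFrame, list]:
    """Raw pair-enrichment p-value of every cluster for every regulator.

    Entries are raw p-values (significance calls belong to the pool-level
    selection, not this matrix).  Clusters without any model-target gene
    get p=1 for all regulators and are returned in the flagged list.
    """
    if not len(regulators) or not len(cluster_genes):
        raise ValidationError("need non-empty regulator and cluster sets")
    cols, flagged = {}, []
    for label, genes in cluster_genes.items():
        try:
            res = pair_enrichment(genes, model)
        except ValidationError:
            cols[label] = pd.Series(1.0, index=pd.Index(regulators))
            flagged.append(label)
            continue
        cols[label] = res["p"].reindex(pd.Index(regulators), fill_value=1.0)
    matrix = pd.DataFrame(cols)
    matrix.index.name = "regulator_id"
    return matrix, flagged


@dataclass
class HClusterResult:
    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    degenerate: bool


def hcluster_matrix(p_matrix: pd.DataFrame,
                    p_floor: float = 1e-300) -> HClusterResult:
    """Average-linkage hierarchical clustering of a p-value matrix.

    Rows (regulators) and columns (clusters) are clustered on their
    -log10(p) vectors with Euclidean distance.  Deterministic for a given
    matrix; an all-equal matrix is flagged degenerate (its order is the
    input order).
    """
    if p_matrix.shape[0] < 2 or p_matrix.shape[1] < 2:
        raise ValidationError("matrix must be at least 2x2")
    scores = -np.log10(np.clip(p_matrix.to_numpy(dtype=float), p_floor, 1.0))
    degenerate = bool(np.allclose(scores, scores.flat[0]))

    def _cluster(mat):
        link = hierarchy.linkage(pdist(mat, metric="euclidean"),
                                 method="average")
        return link, list(hierarchy.leaves_list(link))

    row_link, row_leaves = _cluster(scores)
    col_link, col_leaves = _cluster(scores.T)
    return HClusterResult(
        row_order=[p_matrix.index[i] for i in row_leaves],
        col_order=[p_matrix.columns[i] for i in col_leaves],
        row_linkage=row_link,
        col_linkage=col_link,
        degenerate=degenerate,
    )
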