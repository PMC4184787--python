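"""Lineage-specificity screens over population-mean expression profiles.

Two complementary criteria identify genes whose expression is specific to a
focal lineage (here neutrophils, abbreviated NF) against a large comparator
panel of other immune populations:

* **presence criterion** -- the gene is reliably expressed (population mean
  strictly above the presence threshold, default intensity 120) in *every*
  focal population and in *no* comparator population;
* **fold criterion** -- the minimum mean among the focal populations is at
  least ``min_fold`` (default 2) times the maximum mean among comparators.

The symmetric screen with the roles swapped finds genes specifically
*under*-expressed in the focal lineage; there the fold inequality is strict
(more than ``min_fold``-fold), mirroring the asymmetric phrasing of the two
screens.

All screens operate on a per-gene *specificity summary* (per-focal-population
means plus comparator median/min/max and comparator count-above-threshold),
which can be built from a full mean table with :func:`build_summary` or come
from an externally published marker panel such as the bundled ImmGen
neutrophil panel (:func:`load_neutrophil_marker_panel`).
"""

from __future__ import annotations

import math
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AnalysisConfig, ValidationError, summarize_populations

#: Columns a specificity summary must carry in addition to the per-focal
#: population mean columns.
SUMMARY_COLUMNS = ("nf_min", "nf_max", "nf_median",
                   "non_nf_min", "non_nf_max", "non_nf_median",
                   "non_nf_above")


def load_neutrophil_marker_panel() -> pd.DataFrame:
    """Bundled 31-gene neutrophil marker panel from the ImmGen compendium.

    Per-gene mean intensities in the five neutrophil populations (bone
    marrow BM, blood BL, and the activated SF/UA/TG populations), the
    published NF and non-NF median/range summaries over 5 neutrophil and
    198 non-neutrophil populations, and the number of non-neutrophil
    populations with mean expression greater than 120.
    """
    ref = resources.files("neutrokit.data") / "immgen_neutrophil_markers.tsv"
    with resources.as_file(ref) as path:
        panel = pd.read_csv(path, sep="\t", index_col="gene_id")
    panel = panel.rename(columns={"non_nf_above_120": "non_nf_above"})
    panel.attrs["nf_pops"] = ["BM", "BL", "SF", "UA", "TG"]
    return panel


def panel_to_summary(panel: pd.DataFrame,
                     nf_pops: Sequence[str] = ("BM", "BL", "SF", "UA", "TG"),
                     ) -> pd.DataFrame:
    """Normalize a published marker panel into a specificity summary frame."""
    cols = list(nf_pops) + list(SUMMARY_COLUMNS)
    missing = [c for c in cols if c not in panel.columns]
    if missing:
        raise ValidationError(f"panel missing columns: {missing}")
    out = panel[cols].copy()
    out.attrs["nf_pops"] = list(nf_pops)
    return out


def build_summary(means: pd.DataFrame,
                  nf_pops: Sequence[str],
                  non_nf_pops: Sequence[str],
                  threshold: float) -> pd.DataFrame:
    """Per-gene specificity summary from a full population-mean table."""
    nf_pops, non_nf_pops = list(nf_pops), list(non_nf_pops)
    _check_popsets(nf_pops, non_nf_pops)
    nf = summarize_populations(means, nf_pops, threshold)
    non = summarize_populations(means, non_nf_pops, threshold)
    out = means[nf_pops].copy()
    out["nf_min"] = nf["min"]
    out["nf_max"] = nf["max"]
    out["nf_median"] = nf["median"]
    out["non_nf_min"] = non["min"]
    out["non_nf_max"] = non["max"]
    out["non_nf_median"] = non["median"]
    out["non_nf_above"] = non["count_above"]
    out.attrs["nf_pops"] = nf_pops
    return out


def _check_popsets(nf_pops: Sequence[str], non_nf_pops: Sequence[str]) -> None:
    if not nf_pops or not non_nf_pops:
        raise ValidationError("both population sets must be non-empty")
    overlap = set(nf_pops) & set(non_nf_pops)
    if overlap:
        raise ValidationError(f"population sets overlap: {sorted(overlap)}")


def _nf_pop_columns(summary: pd.DataFrame) -> list[str]:
    pops = summary.attrs.get("nf_pops")
    if pops is None:
        pops = [c for c in summary.columns if c not in SUMMARY_COLUMNS]
    return list(pops)


# ---------------------------------------------------------------------------
# over-expression screen


def presence_criterion_summary(summary: pd.DataFrame,
                               threshold: float = 120.0) -> pd.Index:
    """Genes expressed above threshold in all focal, no comparator populations."""
    nf = summary[_nf_pop_columns(summary)].to_numpy(dtype=float)
    ok = (nf > threshold).all(axis=1) & (summary["non_nf_above"].to_numpy() == 0)
    return summary.index[ok]


def fold_criterion_summary(summary: pd.DataFrame,
                           min_fold: float = 2.0) -> pd.Index:
    """Genes whose focal minimum is >= min_fold x comparator maximum."""
    ok = (summary["nf_min"].to_numpy(dtype=float)
          >= min_fold * summary["non_nf_max"].to_numpy(dtype=float))
    return summary.index[ok]


def presence_criterion(means: pd.DataFrame,
                       nf_pops: Sequence[str],
                       non_nf_pops: Sequence[str],
                       threshold: float = 120.0) -> pd.Index:
    summary = build_summary(means, nf_pops, non_nf_pops, threshold)
    return presence_criterion_summary(summary, threshold)


def fold_criterion(means: pd.DataFrame,
                   nf_pops: Sequence[str],
                   non_nf_pops: Sequence[str],
                   min_fold: float = 2.0) -> pd.Index:
    summary = build_summary(means, nf_pops, non_nf_pops, threshold=120.0)
    return fold_criterion_summary(summary, min_fold)


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (so 11.5 -> 12, 2.5 -> 3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def specificity_report(summary: pd.DataFrame,
                       cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Marker-table report for the union of the two over-expression criteria.

    One row per gene passing either criterion: the per-focal-population
    means, NF and non-NF median/range, the comparator count-above-threshold,
    the two criterion flags, and the min(NF)/max(non-NF) fold ratio both raw
    and rounded half-away-from-zero to the nearest integer (the convention
    under which a ratio of 11.87 is reported as "12-fold").
    """
    cfg = cfg or AnalysisConfig()
    present = presence_criterion_summary(summary, cfg.presence_threshold)
    folded = fold_criterion_summary(summary, cfg.min_fold)
    union = summary.index[summary.index.isin(present) | summary.index.isin(folded)]
    rep = summary.loc[union].copy()
    rep["pass_presence"] = rep.index.isin(present)
    rep["pass_fold"] = rep.index.isin(folded)
    ratio = rep["nf_min"] / rep["non_nf_max"]
    rep["fold_ratio"] = ratio
    rep["fold_ratio_rounded"] = [round_half_away(r) for r in ratio]
    return rep


# ---------------------------------------------------------------------------
# under-expression screen


def under_expression_screen(means: pd.DataFrame,
                            nf_pops: Sequence[str],
                            non_nf_pops: Sequence[str],
                            cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Mirror screen for genes specifically *under*-expressed in the lineage.

    Presence flag: mean above threshold in every comparator population and
    in no focal population.  Fold flag: comparator minimum strictly more
    than ``min_fold`` times the focal maximum.  Returns the union of the two
    flag sets with per-criterion flags.
    """
    cfg = cfg or AnalysisConfig()
    _check_popsets(nf_pops, non_nf_pops)
    t = cfg.presence_threshold
    nf = means[list(nf_pops)].to_numpy(dtype=float)
    non = means[list(non_nf_pops)].to_numpy(dtype=float)
    presence = (non > t).all(axis=1) & ~(nf > t).any(axis=1)
    fold = non.min(axis=1) > cfg.min_fold * nf.max(axis=1)
    either = presence | fold
    return pd.DataFrame(
        {"pass_presence": presence[either], "pass_fold": fold[either]},
        index=means.index[either],
    )


def union_size(n_a: int, n_b: int, n_both: int) -> int:
    """Size of the union of two criterion sets by inclusion-exclusion."""
    if n_both > min(n_a, n_b):
        raise ValidationError("intersection larger than a criterion set")
    return n_a + n_b - n_both


def collapse_probes(flags: pd.DataFrame,
                    probe_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Collapse probe-level flags to gene level by OR over a gene's probes."""
    genes = pd.Series({p: probe_to_gene[p] for p in flags.index})
    return flags.groupby(genes).any()
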