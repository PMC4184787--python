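"""Gene filters and comparisons for cross-condition activation analyses.

The composite *variation filter* keeps the genes that are both reliably
expressed and reproducibly variable across neutrophil conditions:

1. mean intensity above the presence threshold (120) in at least one
   condition;
2. one-way ANOVA across conditions on log2 replicate values, P below 0.01;
3. a mean-ratio of at least 2 in some pairwise comparison of conditions;
4. within-group coefficient of variation (SD/mean of the linear replicate
   values) below 0.5 in every condition.

The remaining operations compare activated conditions to a reference
(circulating blood neutrophils): per-condition fold-change tables,
log-scale correlation and regression slope between conditions, strict and
relaxed three-way Venn region counts, condition-specific gene lists, and a
pairwise test comparing category counts between two gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AnalysisConfig, ExpressionMatrix, ValidationError
from .stats import bh_adjust, chi_square_2x2, fisher_2x2


@dataclass
class FilteredGeneSet:
    """Outcome of the composite variation filter.

    ``table`` holds per-gene diagnostics (max condition mean, ANOVA p,
    max pairwise fold, max within-group CV) and the four boolean flags;
    ``genes`` is the list passing all four.
    """

    table: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.table.index[self.table["pass_all"]]


def variation_filter(m: ExpressionMatrix,
                     conditions: Sequence[str],
                     cfg: AnalysisConfig | None = None,
                     cv_mode: Literal["all", "any"] = "all",
                     use_fdr: bool = False) -> FilteredGeneSet:
    """Apply the four-part presence/ANOVA/fold/CV filter.

    ``conditions`` are population ids (each with >=2 replicate samples).
    ``cv_mode="all"`` requires CV below the cut-off in every condition;
    ``"any"`` in at least one.  With ``use_fdr=True`` the ANOVA criterion
    is applied to BH-adjusted values at Q<0.05 instead of raw P<0.01 (the
    variant used for focused re-analyses of small gene sets).
    """
    cfg = cfg or AnalysisConfig()
    conditions = list(conditions)
    if len(conditions) < 2:
        raise ValidationError("need at least two conditions")
    groups = []
    for cond in conditions:
        samples = m.samples_of(cond)
        if len(samples) < 2:
            raise ValidationError(
                f"condition {cond!r} has {len(samples)} replicate(s); "
                "ANOVA and CV require at least 2"
            )
        groups.append(m.values[samples].to_numpy(dtype=float))

    cond_means = np.column_stack([g.mean(axis=1) for g in groups])
    cond_sds = np.column_stack([g.std(axis=1, ddof=1) for g in groups])

    # ANOVA on log2 replicates; a zero-intensity replicate would be a data
    # error upstream, guard anyway.
    if any((g <= 0).any() for g in groups):
        raise ValidationError("non-positive intensity among replicates")
    log_groups = [np.log2(g) for g in groups]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, anova_p = sps.f_oneway(*[g.T for g in log_groups], axis=0)
    anova_p = np.where(np.isnan(anova_p), 1.0, anova_p)

    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(cond_means > 0, cond_sds / cond_means, np.inf)
        max_fold = cond_means.max(axis=1) / cond_means.min(axis=1)
    max_fold = np.where(np.isfinite(max_fold), max_fold, np.inf)

    pass_presence = cond_means.max(axis=1) > cfg.presence_threshold
    if use_fdr:
        anova_q = bh_adjust(anova_p)
        pass_anova = anova_q < cfg.q_module
    else:
        pass_anova = anova_p < cfg.anova_p
    pass_fold = max_fold >= cfg.min_fold
    if cv_mode == "all":
        pass_cv = (cv < cfg.max_cv).all(axis=1)
    elif cv_mode == "any":
        pass_cv = (cv < cfg.max_cv).any(axis=1)
    else:
        raise ValidationError(f"unknown cv_mode {cv_mode!r}")

    table = pd.DataFrame(
        {
            "max_mean": cond_means.max(axis=1),
            "anova_p": anova_p,
            "max_fold": max_fold,
            "max_cv": cv.max(axis=1),
            "pass_presence": pass_presence,
            "pass_anova": pass_anova,
            "pass_fold": pass_fold,
            "pass_cv": pass_cv,
        },
        index=m.gene_ids,
    )
    table["pass_all"] = (pass_presence & pass_anova & pass_fold & pass_cv)
    return FilteredGeneSet(table)


def fold_vs_reference(means: pd.DataFrame,
                      conditions: Sequence[str],
                      reference: str) -> pd.DataFrame:
    """Per-gene fold change of each condition mean over the reference mean."""
    if reference not in means.columns:
        raise ValidationError(f"reference condition {reference!r} not present")
    ref = means[reference].to_numpy(dtype=float)
    if (ref == 0).any():
        bad = means.index[np.where(ref == 0)[0][0]]
        raise ValidationError(f"zero reference mean for gene {bad!r}")
    return means[list(conditions)].div(means[reference], axis=0)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    slope: float
    slope_ci: tuple[float, float]
    n: int


def condition_correlation(fc_a: Sequence[float],
                          fc_b: Sequence[float]) -> CorrelationResult:
    """Pearson r and OLS slope between two log2 fold-change vectors.

    Folds are log2-transformed; the slope regresses log2(b) on log2(a) and
    carries a 95% confidence interval from the regression standard error.
    """
    a = np.log2(np.asarray(fc_a, dtype=float))
    b = np.log2(np.asarray(fc_b, dtype=float))
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("fold vectors must be equal-length 1-D")
    if a.size < 3:
        raise ValidationError("need at least 3 genes")
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        raise ValidationError("zero variance in a fold vector")
    fit = sps.linregress(a, b)
    half = sps.t.ppf(0.975, a.size - 2) * fit.stderr
    return CorrelationResult(
        r=float(fit.rvalue),
        slope=float(fit.slope),
        slope_ci=(float(fit.slope - half), float(fit.slope + half)),
        n=int(a.size),
    )


def venn_counts(fc: pd.DataFrame,
                strict: float = 2.0,
                relaxed: float | None = None,
                direction: Literal["up", "down"] = "up") -> dict[frozenset, int]:
    """Three-way Venn region counts of regulated genes across conditions.

    Strict mode (``relaxed=None``): a gene belongs to a condition when its
    fold exceeds ``strict`` (or falls below 1/strict for ``direction="down"``),
    and regions are the usual exclusive Venn regions of those three sets.

    Relaxed mode: a gene is shared between two conditions when one exceeds
    the strict cut-off and the other at least the relaxed one; the triple
    region requires one strict and the remaining two relaxed.  Genes
    exceeding strict in one condition with no relaxed partner stay in that
    condition's exclusive region.

    In both modes the region counts sum to the number of genes exceeding
    the strict cut-off in at least one condition.
    """
    conds = list(fc.columns)
    if len(conds) != 3:
        raise ValidationError(f"need exactly 3 conditions, got {len(conds)}")
    folds = fc.to_numpy(dtype=float)
    if direction == "down":
        with np.errstate(divide="ignore"):
            folds = 1.0 / folds
    elif direction != "up":
        raise ValidationError(f"unknown direction {direction!r}")

    hit_strict = folds > strict
    regions: dict[frozenset, int] = {
        frozenset(s): 0
        for r in (1, 2, 3)
        for s in combinations(conds, r)
    }
    if relaxed is None:
        for row in hit_strict:
            members = frozenset(c for c, h in zip(conds, row) if h)
            if members:
                regions[members] += 1
        return regions

    hit_relaxed = folds > relaxed
    for s_row, r_row in zip(hit_strict, hit_relaxed):
        if not s_row.any():
            continue
        if r_row.all():  # one strict + other two at least relaxed
            regions[frozenset(conds)] += 1
            continue
        shared = frozenset(
            c for c, s, r in zip(conds, s_row, r_row) if s or r
        )
        # with exactly one relaxed partner this is a pair; with none, a single
        regions[shared] += 1
    return regions


def condition_specific_genes(means: pd.DataFrame,
                             condition: str,
                             other_conditions: Sequence[str],
                             reference: str,
                             min_fold: float = 2.0) -> pd.Index:
    """Genes at least ``min_fold`` higher in one condition than in each other
    condition and the reference."""
    if condition in other_conditions:
        raise ValidationError("condition may not appear in other_conditions")
    target = means[condition].to_numpy(dtype=float)
    ok = np.ones(len(means), dtype=bool)
    for other in list(other_conditions) + [reference]:
        ok &= target >= min_fold * means[other].to_numpy(dtype=float)
    return means.index[ok]


def category_count_compare(k1: int, n1: int, k2: int, n2: int,
                           method: Literal["auto", "fisher", "chisq"] = "auto",
                           ) -> float:
    """Two-sided p-value comparing k1/n1 vs k2/n2 category counts.

    Builds the 2x2 table [[k1, n1-k1], [k2, n2-k2]].  ``"fisher"`` uses the
    exact test, ``"chisq"`` the Pearson chi-square without continuity
    correction, and ``"auto"`` picks chi-square when every expected count is
    at least 5 and Fisher otherwise.
    """
    if k1 > n1 or k2 > n2 or min(k1, n1, k2, n2) < 0:
        raise ValidationError("counts must satisfy 0 <= k <= n")
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    if method == "fisher":
        return fisher_2x2(a, b, c, d)
    stat, p, expected = chi_square_2x2(a, b, c, d)
    if method == "chisq":
        return p
    if method == "auto":
        return p if expected >= 5 else fisher_2x2(a, b, c, d)
    raise ValidationError(f"unknown method {method!r}")
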