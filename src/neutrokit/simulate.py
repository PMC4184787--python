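"""Synthetic expression matrices and regulatory models with known truth.

The generator emulates the shape of an immune-population microarray
compendium: a handful of neutrophil populations profiled in triplicate
across source/activation conditions (BM, BL, SF, UA, TG), a scaled-down
panel of non-neutrophil comparator populations, multiplicative (log-normal)
replicate noise with a controlled linear-scale CV, and three kinds of
planted structure -- lineage-specific genes, activation-pattern archetypes
relative to blood, and a module/regulator model in which chosen regulators'
modules preferentially harbor one archetype's genes.

Truth tables accompany every output so downstream sensitivity/specificity
can be scored without re-deriving labels.  The same seed always reproduces
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (NEUTROPHIL, NON_NEUTROPHIL, ExpressionMatrix,
                   ValidationError)
from .regulatory import RegulatoryModel


@dataclass(frozen=True)
class Archetype:
    """A planted activation pattern: per-condition fold multipliers vs blood."""

    name: str
    pattern: Mapping[str, float]  # condition -> fold multiplier (BL-relative)
    n_genes: int


def default_archetypes(fold: float = 4.0, n_genes: int = 50) -> list[Archetype]:
    """Six canonical activation patterns over the SF/UA/TG conditions."""
    f = fold
    return [
        Archetype("up_all", {"SF": f, "UA": f, "TG": f}, n_genes),
        Archetype("down_all", {"SF": 1 / f, "UA": 1 / f, "TG": 1 / f}, n_genes),
        Archetype("sf_only", {"SF": f, "UA": 1.0, "TG": 1.0}, n_genes),
        Archetype("ua_only", {"SF": 1.0, "UA": f, "TG": 1.0}, n_genes),
        Archetype("tg_only", {"SF": 1.0, "UA": 1.0, "TG": f}, n_genes),
        Archetype("mixed", {"SF": f, "UA": 1 / f, "TG": 1.0}, n_genes),
    ]


@dataclass
class SimulationDesign:
    """Desk-scale study design mirroring the compendium's structure.

    Defaults: 2,000 genes; five neutrophil conditions x 3 replicates; 20
    non-neutrophil populations x 2 replicates; linear-scale within-group
    noise CV 0.1; 30 lineage-specific genes at 20-fold elevation; six
    50-gene activation archetypes at 4-fold effects; 40 coarse modules and
    30 regulators with 3 planted regulators at concentration 0.9.
    """

    n_genes: int = 2000
    nf_conditions: Sequence[str] = ("BM", "BL", "SF", "UA", "TG")
    nf_replicates: int = 3
    n_non_nf: int = 20
    non_nf_replicates: int = 2
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_cv: float = 0.1
    n_specific_genes: int = 30
    specific_fold: float = 20.0
    archetypes: list[Archetype] = field(default_factory=default_archetypes)
    n_modules: int = 40
    n_regulators: int = 30
    n_planted_regulators: int = 3
    concentration: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_modules < 2 or self.n_regulators < 1:
            raise ValidationError("counts must be positive (modules >= 2)")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.specific_fold <= 1:
            raise ValidationError("specific_fold must be > 1")
        if not 0 <= self.concentration <= 1:
            raise ValidationError("concentration must lie in [0, 1]")
        planted = self.n_specific_genes + sum(a.n_genes for a in self.archetypes)
        if planted > self.n_genes:
            raise ValidationError("planted genes exceed n_genes")


def _lognormal_noise(rng: np.random.Generator, means: np.ndarray,
                     cv: float) -> np.ndarray:
    """Multiplicative noise with exact mean preservation.

    For linear-scale CV c, a log-normal factor exp(N(-s^2/2, s)) with
    s^2 = ln(1 + c^2) has mean 1 and SD c.
    """
    if cv == 0:
        return means.copy()
    s = np.sqrt(np.log1p(cv ** 2))
    factors = rng.lognormal(mean=-s ** 2 / 2, sigma=s, size=means.shape)
    return means * factors


def simulate_expression(design: SimulationDesign,
                        ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a matrix with planted specific genes and archetype clusters.

    Returns the ExpressionMatrix and a per-gene truth table with columns
    ``role`` (baseline / specific / archetype) and ``archetype`` (pattern
    name or empty).  At ``noise_cv=0`` replicates equal their population
    means exactly.
    """
    rng = np.random.default_rng(design.seed)
    genes = [f"g{i:05d}" for i in range(design.n_genes)]
    nf_pops = list(design.nf_conditions)
    non_nf_pops = [f"NN{i:02d}" for i in range(design.n_non_nf)]

    # population-mean layer ------------------------------------------------
    baseline = 2.0 ** rng.normal(design.baseline_log2_mean,
                                 design.baseline_log2_sd, design.n_genes)
    pop_means = pd.DataFrame(
        np.tile(baseline[:, None], (1, len(nf_pops) + len(non_nf_pops))),
        index=pd.Index(genes, name="gene_id"),
        columns=nf_pops + non_nf_pops,
    )

    truth = pd.DataFrame({"role": "baseline", "archetype": ""},
                         index=pop_means.index)
    cursor = 0

    # lineage-specific genes: low everywhere, elevated specific_fold in all
    # neutrophil populations; the low level sits below the presence
    # threshold and the high level above it.
    specific = genes[cursor:cursor + design.n_specific_genes]
    cursor += design.n_specific_genes
    low = 2.0 ** rng.uniform(4.0, 6.5, len(specific))  # 16..90
    pop_means.loc[specific, :] = low[:, None]
    pop_means.loc[specific, nf_pops] = (low * design.specific_fold)[:, None]
    truth.loc[specific, "role"] = "specific"

    # activation archetypes: fold multipliers on the activated conditions
    # relative to blood, in neutrophil populations only.
    for arch in design.archetypes:
        members = genes[cursor:cursor + arch.n_genes]
        cursor += arch.n_genes
        for cond, fold in arch.pattern.items():
            if cond not in nf_pops:
                raise ValidationError(
                    f"archetype {arch.name!r}: unknown condition {cond!r}")
            pop_means.loc[members, cond] *= fold
        truth.loc[members, "role"] = "archetype"
        truth.loc[members, "archetype"] = arch.name

    # replicate layer ------------------------------------------------------
    columns, col_pop = [], []
    for pop in nf_pops:
        for r in range(design.nf_replicates):
            columns.append(f"{pop}_r{r + 1}")
            col_pop.append(pop)
    for pop in non_nf_pops:
        for r in range(design.non_nf_replicates):
            columns.append(f"{pop}_r{r + 1}")
            col_pop.append(pop)
    mean_matrix = pop_means[col_pop].to_numpy()
    values = _lognormal_noise(rng, mean_matrix, design.noise_cv)

    populations = pd.DataFrame(
        {
            "population_id": col_pop,
            "group_class": [NEUTROPHIL if p in nf_pops else NON_NEUTROPHIL
                            for p in col_pop],
            "condition": [p if p in nf_pops else "" for p in col_pop],
        },
        index=pd.Index(columns, name="sample_id"),
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pop_means.index, columns=columns),
        populations,
    )
    return matrix, truth


def simulate_model(design: SimulationDesign, truth: pd.DataFrame,
                   ) -> tuple[RegulatoryModel, pd.DataFrame]:
    """Generate a module/regulator model with planted enrichments.

    All genes are partitioned into ``n_modules`` bins of uneven size.  Each
    of the first ``n_planted_regulators`` archetypes gets a dedicated
    regulator: a fraction ``concentration`` of that archetype's genes is
    concentrated into two modules associated with that regulator (the rest
    are scattered), so the regulator's target pairs are over-represented in
    any list dominated by the archetype.  At concentration 0 no structure
    is planted.  Remaining regulators get random module associations;
    weights are association strengths drawn away from zero and are not used
    by the tests.

    Returns the model and a planted-truth table (regulator_id, archetype,
    planted flag for every regulator).
    """
    rng = np.random.default_rng(design.seed + 1)
    genes = list(truth.index)
    modules = [f"m{i:02d}" for i in range(design.n_modules)]
    regulators = [f"R{i:02d}" for i in range(design.n_regulators)]
    planted_archetypes = [a.name for a in design.archetypes][
        : design.n_planted_regulators]
    planted_regs = regulators[: len(planted_archetypes)]

    # uneven module sizes via a Dirichlet split
    weights = rng.dirichlet(np.full(design.n_modules, 2.0))
    assignment = pd.Series(
        rng.choice(design.n_modules, size=len(genes), p=weights),
        index=pd.Index(genes, name="gene_id"),
    )

    dedicated: dict[str, list[int]] = {}
    reserved: set[int] = set()
    for reg, arch in zip(planted_regs, planted_archetypes):
        free = [i for i in range(design.n_modules) if i not in reserved]
        own = list(rng.choice(free, size=2, replace=False))
        reserved.update(own)
        dedicated[reg] = own
        arch_genes = truth.index[truth["archetype"] == arch]
        n_conc = int(round(design.concentration * len(arch_genes)))
        conc = rng.choice(arch_genes, size=n_conc, replace=False)
        assignment.loc[conc] = rng.choice(own, size=n_conc)

    targets = assignment.map(lambda i: modules[i])

    rows = []
    for reg in regulators:
        if reg in dedicated:
            mods = list(dedicated[reg])
        else:
            n_assoc = int(rng.integers(1, 6))
            candidates = [i for i in range(design.n_modules)
                          if i not in reserved]
            mods = list(rng.choice(candidates,
                                   size=min(n_assoc, len(candidates)),
                                   replace=False))
        for m in mods:
            weight = float(rng.uniform(0.2, 1.0) * rng.choice([-1.0, 1.0]))
            rows.append((reg, modules[m], weight))
    associations = pd.DataFrame(rows, columns=["regulator_id", "module_id",
                                               "weight"])

    # guarantee model invariants: every populated module needs a regulator,
    # every module id used by a regulator needs a target gene
    populated = set(targets.unique())
    covered = set(associations["module_id"].unique())
    for module_id in sorted(populated - covered):
        reg = regulators[int(rng.integers(len(planted_regs),
                                          design.n_regulators))]
        associations.loc[len(associations)] = (reg, module_id,
                                               float(rng.uniform(0.2, 1.0)))
    empty = covered - populated
    if empty:
        associations = associations.loc[
            ~associations["module_id"].isin(empty)].reset_index(drop=True)

    model = RegulatoryModel(targets, associations)
    planted_truth = pd.DataFrame(
        {
            "archetype": [dict(zip(planted_regs, planted_archetypes)).get(r, "")
                          for r in regulators],
            "planted": [r in planted_regs for r in regulators],
        },
        index=pd.Index(regulators, name="regulator_id"),
    )
    if design.concentration == 0:
        planted_truth["planted"] = False
    return model, planted_truth
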