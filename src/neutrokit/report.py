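"""Pipeline driver, heatmap normalization, and run manifest.

``run_pipeline`` chains the stages -- simulate (or load) -> variation
filter -> K-means clustering and merging -> cluster pooling -> regulator
inference -- writing every intermediate table plus a JSON manifest with
parameters, seeds and output checksums so a run can be verified and
reproduced exactly.

``heatmap_normalize`` implements the display convention used for
cross-condition expression heatmaps: per gene, the mean of the log2 values
across the displayed populations sits at the center of the color gradient
(white) and the full gradient spans a fixed fold range (8-fold by default),
so a 2-fold difference is visible and color is comparable between genes;
larger spreads are clipped and flagged.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import sys
import time
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .clustering import ClusterSet, kmeans_cluster, merge_clusters
from .core import (AnalysisConfig, ExpressionMatrix, ValidationError,
                   load_expression, log2_mean_center, population_means)
from .filters import variation_filter
from .regulatory import (RegulatoryModel, hcluster_matrix,
                         module_bin_enrichment, pair_enrichment,
                         regulator_cluster_matrix, select_regulators)
from .simulate import SimulationDesign, simulate_expression, simulate_model


def heatmap_normalize(means: pd.DataFrame,
                      popset: Sequence[str] | None = None,
                      fold_span: float = 8.0,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale per-gene log2 mean-centered values into [-1, 1].

    Centered log2 values are divided by log2(fold_span)/2, so that ±1 spans
    exactly ``fold_span``-fold; entries beyond the span are clipped.
    Returns ``(display, clipped)`` where ``clipped`` flags the entries that
    hit the limit.  Invariant to scaling a gene's means by any positive
    constant.
    """
    if fold_span <= 1:
        raise ValidationError("fold_span must be > 1")
    centered = log2_mean_center(means, popset)
    half_span = np.log2(fold_span) / 2.0
    scaled = centered / half_span
    clipped = scaled.abs() > 1.0 + 1e-9  # tolerance: exact-span genes are not flagged
    return scaled.clip(-1.0, 1.0), clipped


def pool_clusters(cs: ClusterSet, profiles: pd.DataFrame,
                  sample_conditions: Mapping[str, str],
                  reference: str = "BL",
                  activated: Sequence[str] = ("SF", "UA", "TG"),
                  ) -> dict[str, list]:
    """Partition clusters into up / down / complex pools vs the reference.

    A cluster is *up* when its mean profile sits above the reference level
    in every activated condition, *down* when below in every one, and
    *complex* otherwise.  Levels are per-condition means of the cluster's
    centroid (already mean-centered across samples).
    """
    cond_of = pd.Series(sample_conditions)
    pools: dict[str, list] = {"up": [], "down": [], "complex": []}
    for label in cs.centroids.index:
        centroid = cs.centroids.loc[label]
        by_cond = centroid.groupby(cond_of[centroid.index]).mean()
        diffs = [by_cond[a] - by_cond[reference] for a in activated]
        if all(d > 0 for d in diffs):
            pools["up"].append(label)
        elif all(d < 0 for d in diffs):
            pools["down"].append(label)
        else:
            pools["complex"].append(label)
    return pools


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _log(msg: str, t0: float) -> None:
    print(f"[neutrokit +{time.perf_counter() - t0:7.2f}s] {msg}",
          file=sys.stderr)


def read_config(path: str | Path) -> dict:
    """Flat INI config: [inputs], [simulate], [analysis] sections."""
    parser = configparser.ConfigParser()
    with open(path) as fh:
        parser.read_file(fh)
    return {s: dict(parser[s]) for s in parser.sections()}


def run_pipeline(config: Mapping | str | Path, outdir: str | Path) -> dict:
    """Execute filter -> cluster -> pools -> regulator inference end to end.

    ``config`` is a mapping (or INI file path) with optional sections:
    ``inputs`` (matrix/popmap/model file paths), ``simulate`` (synthetic
    design overrides; used when no input files are given) and ``analysis``
    (AnalysisConfig overrides).  Writes all stage outputs under ``outdir``
    and returns the manifest (also written as ``manifest.json``).  Any
    stage failure aborts with the stage name and cause.
    """
    if not isinstance(config, Mapping):
        config = read_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    analysis_kwargs = {
        k: type(getattr(AnalysisConfig(), k))(v)
        for k, v in config.get("analysis", {}).items()
    }
    cfg = AnalysisConfig(**analysis_kwargs)
    stage = "inputs"
    written: dict[str, Path] = {}
    try:
        inputs = config.get("inputs", {})
        if "matrix" in inputs:
            for key in ("matrix", "popmap"):
                if key not in inputs:
                    raise ValidationError(f"missing input file: {key}")
            matrix = load_expression(inputs["matrix"], inputs["popmap"])
            truth = None
            if "model_targets" in inputs:
                model = RegulatoryModel.load(inputs["model_targets"],
                                             inputs["model_regulators"])
            else:
                model = None
            planted = None
        else:
            stage = "simulate"
            sim_kwargs = dict(config.get("simulate", {}))
            for key, val in sim_kwargs.items():
                default = getattr(SimulationDesign(), key)
                sim_kwargs[key] = type(default)(val)
            design = SimulationDesign(seed=cfg.seed, **sim_kwargs)
            matrix, truth = simulate_expression(design)
            model, planted = simulate_model(design, truth)
            matrix.save(outdir / "matrix.tsv", outdir / "popmap.csv")
            model.save(outdir / "model_targets.tsv",
                       outdir / "model_regulators.tsv")
            truth.to_csv(outdir / "truth_genes.tsv", sep="\t")
            planted.to_csv(outdir / "truth_regulators.tsv", sep="\t")
            written.update({p.name: p for p in [
                outdir / "matrix.tsv", outdir / "popmap.csv",
                outdir / "model_targets.tsv", outdir / "model_regulators.tsv",
                outdir / "truth_genes.tsv", outdir / "truth_regulators.tsv"]})
        _log("inputs ready", t0)

        stage = "filter"
        nf_conditions = [p for p in matrix.populations_of_class("neutrophil")]
        filtered = variation_filter(matrix, nf_conditions, cfg)
        filtered.table.to_csv(outdir / "filter.tsv", sep="\t")
        written["filter.tsv"] = outdir / "filter.tsv"
        genes = filtered.genes
        if len(genes) < 2:
            raise ValidationError("fewer than 2 genes passed the filter")
        _log(f"filter kept {len(genes)} genes", t0)

        stage = "cluster"
        cluster_conditions = [c for c in ("BL", "SF", "UA", "TG")
                              if c in nf_conditions] or nf_conditions
        samples = [s for c in cluster_conditions for s in matrix.samples_of(c)]
        profiles = np.log2(matrix.values.loc[genes, samples])
        k = min(cfg.k_clusters, len(genes))
        cs = kmeans_cluster(profiles, k=k, seed=cfg.seed)
        cs = merge_clusters(cs, profiles)
        assign = cs.assignments.to_frame()
        assign["coefficient"] = cs.assignments.map(cs.coefficients)
        assign.to_csv(outdir / "clusters.tsv", sep="\t")
        cs.centroids.to_csv(outdir / "cluster_centroids.tsv", sep="\t")
        written["clusters.tsv"] = outdir / "clusters.tsv"
        written["cluster_centroids.tsv"] = outdir / "cluster_centroids.tsv"
        _log(f"{cs.k} clusters after merging", t0)

        stage = "pools"
        cond_map = {s: matrix.condition_of(matrix.sample_to_population[s])
                    for s in samples}
        pools = pool_clusters(cs, profiles, cond_map)
        with open(outdir / "pools.json", "w") as fh:
            json.dump({k: [int(c) for c in v] for k, v in pools.items()}, fh,
                      indent=1)
        written["pools.json"] = outdir / "pools.json"

        if model is not None:
            stage = "regulators"
            pool_pair, pool_module = {}, {}
            rng = np.random.default_rng(cfg.seed)
            for pool, labels in pools.items():
                members = cs.assignments.index[cs.assignments.isin(labels)]
                if not len(members):
                    continue
                try:
                    pool_module[pool] = module_bin_enrichment(
                        members, model, n_perm=cfg.n_permutations,
                        seed=int(rng.integers(2 ** 31 - 1)),
                        q_threshold=cfg.q_module)
                    pool_pair[pool] = pair_enrichment(
                        members, model, q_threshold=cfg.q_pair)
                except ValidationError:
                    continue
                pool_module[pool].to_csv(outdir / f"modules_{pool}.tsv",
                                         sep="\t")
                pool_pair[pool].to_csv(outdir / f"pairs_{pool}.tsv", sep="\t")
                written[f"modules_{pool}.tsv"] = outdir / f"modules_{pool}.tsv"
                written[f"pairs_{pool}.tsv"] = outdir / f"pairs_{pool}.tsv"
            selected = select_regulators(pool_pair, pool_module, model,
                                         q_pair=cfg.q_pair,
                                         q_module=cfg.q_module)
            (outdir / "selected_regulators.txt").write_text(
                "\n".join(str(r) for r in selected) + "\n")
            written["selected_regulators.txt"] = (
                outdir / "selected_regulators.txt")
            _log(f"{len(selected)} regulators selected", t0)

            if selected and cs.k >= 2:
                cluster_genes = {c: list(cs.members(c))
                                 for c in cs.centroids.index}
                p_matrix, flagged = regulator_cluster_matrix(
                    cluster_genes, selected, model)
                p_matrix.to_csv(outdir / "p_matrix.tsv", sep="\t")
                written["p_matrix.tsv"] = outdir / "p_matrix.tsv"
                if p_matrix.shape[0] >= 2 and p_matrix.shape[1] >= 2:
                    hc = hcluster_matrix(p_matrix)
                    with open(outdir / "p_matrix_order.json", "w") as fh:
                        json.dump({"rows": [str(r) for r in hc.row_order],
                                   "cols": [str(c) for c in hc.col_order],
                                   "degenerate": hc.degenerate}, fh, indent=1)
                    written["p_matrix_order.json"] = (
                        outdir / "p_matrix_order.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "neutrokit_version": __version__,
        "seed": cfg.seed,
        "analysis_config": asdict(cfg),
        "outputs": {name: _sha256(path) for name, path in sorted(
            written.items())},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    _log("done", t0)
    return manifest
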