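"""K-means expression-pattern clustering with a randomization validity control.

Genes that pass the activation filter are clustered on their replicate-level
profiles: each profile is mean-centered across samples (no variance
scaling, so shape-identical profiles of different magnitude stay close) and
Lloyd's K-means with Euclidean distance partitions them.  Cluster coherence
is summarized by a *correlation coefficient* -- the mean Pearson correlation
between member profiles and the cluster's mean profile.  Two controls
support the clustering:

* clusters whose mean profiles share a pattern are merged greedily, with a
  merge rolled back if it drops a coefficient by more than a small guard
  (default 0.03);
* the whole procedure is repeated on data randomized within each sample
  (column-wise permutation), bounding the cluster coherence achievable by
  chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ValidationError


def mean_center_rows(profiles: pd.DataFrame) -> pd.DataFrame:
    arr = profiles.to_numpy(dtype=float)
    return pd.DataFrame(arr - arr.mean(axis=1, keepdims=True),
                        index=profiles.index, columns=profiles.columns)


@dataclass
class ClusterSet:
    """A K-means partition of gene profiles.

    assignments: gene -> cluster label (0..k-1).
    centroids: cluster x samples mean (already-centered) profiles.
    coefficients: per-cluster mean member-to-centroid Pearson correlation.
    min_coefficients: per-cluster minimum member correlation (diagnostic).
    degenerate_genes: genes with zero-variance centered profiles; they
        contribute correlation 0 and are flagged here.
    """

    assignments: pd.Series
    centroids: pd.DataFrame
    coefficients: pd.Series
    min_coefficients: pd.Series
    n_iter: int
    seed: int
    inertia: float
    degenerate_genes: list = field(default_factory=list)
    #: within-cluster squared distance after each assignment step of the
    #: winning restart; non-increasing by construction of Lloyd's algorithm
    objective_trace: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.centroids)

    def members(self, label) -> pd.Index:
        return self.assignments.index[self.assignments == label]


def _lloyd(x: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int
           ) -> tuple[np.ndarray, np.ndarray, int, float, list[float]]:
    """One Lloyd run: returns (labels, centroids, n_iter, inertia, trace).

    Initial centroids are k distinct profiles sampled without replacement;
    an emptied cluster is re-seeded at the point farthest from its current
    centroid.  Convergence = assignments unchanged.  ``trace`` records the
    within-cluster squared distance after each assignment step.
    """
    n = x.shape[0]
    centroids = x[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        trace.append(float(d2[np.arange(n), new_labels].sum()))
        for c in range(k):
            mask = new_labels == c
            if mask.any():
                centroids[c] = x[mask].mean(axis=0)
            else:
                farthest = d2[np.arange(n), new_labels].argmax()
                centroids[c] = x[farthest]
                new_labels[farthest] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    inertia = float(((x - centroids[labels]) ** 2).sum())
    return labels, centroids, it, inertia, trace


def kmeans_cluster(profiles: pd.DataFrame, k: int, seed: int,
                   n_init: int = 10, max_iter: int = 300) -> ClusterSet:
    """Cluster mean-centered gene profiles with Lloyd's K-means.

    ``profiles`` is genes x samples (replicate-level values; any monotone
    transform such as log2 should be applied by the caller).  The best of
    ``n_init`` seeded restarts by within-cluster squared distance is kept;
    identical seed and input give identical output.
    """
    if k > len(profiles):
        raise ValidationError(f"k={k} exceeds number of genes {len(profiles)}")
    if profiles.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    centered = mean_center_rows(profiles)
    x = centered.to_numpy(dtype=float)
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_init):
        rng = np.random.Generator(np.random.PCG64(child))
        labels, centroids, n_iter, inertia, trace = _lloyd(x, k, rng, max_iter)
        if best is None or inertia < best[3] - 1e-12:
            best = (labels, centroids, n_iter, inertia, trace)
    labels, centroids, n_iter, inertia, trace = best
    assignments = pd.Series(labels, index=profiles.index, name="cluster")
    centroid_df = pd.DataFrame(centroids, columns=profiles.columns)
    coeff, min_coeff, degenerate = _coefficients(x, labels, centroids,
                                                 profiles.index)
    return ClusterSet(assignments, centroid_df, coeff, min_coeff,
                      n_iter, seed, inertia, degenerate, trace)


def _pearson_to_centroid(x: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of x with the centroid; rows or a
    centroid with zero variance yield 0."""
    xm = x - x.mean(axis=1, keepdims=True)
    cm = centroid - centroid.mean()
    xs = np.sqrt((xm ** 2).sum(axis=1))
    cs = np.sqrt((cm ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xm @ cm) / (xs * cs)
    return np.where(np.isfinite(r), r, 0.0)


def _coefficients(x: np.ndarray, labels: np.ndarray, centroids: np.ndarray,
                  index: pd.Index):
    coeff, min_coeff, degenerate = {}, {}, []
    for c in sorted(set(labels)):
        mask = labels == c
        members = x[mask]
        if mask.sum() == 1:
            coeff[c], min_coeff[c] = 1.0, 1.0
            continue
        r = _pearson_to_centroid(members, centroids[c])
        zero_var = ~np.any(members != members.mean(axis=1, keepdims=True),
                           axis=1)
        degenerate.extend(index[mask][zero_var])
        coeff[c] = float(r.mean())
        min_coeff[c] = float(r.min())
    return (pd.Series(coeff, name="coefficient"),
            pd.Series(min_coeff, name="min_coefficient"), degenerate)


def cluster_correlations(cs: ClusterSet, profiles: pd.DataFrame) -> pd.Series:
    """Recompute per-cluster coefficients for a ClusterSet on given profiles."""
    centered = mean_center_rows(profiles).loc[cs.assignments.index]
    x = centered.to_numpy(dtype=float)
    labels = cs.assignments.to_numpy()
    centroids = np.vstack([
        x[labels == c].mean(axis=0) for c in sorted(set(labels))
    ])
    coeff, min_coeff, degenerate = _coefficients(x, labels, centroids,
                                                 centered.index)
    cs.coefficients, cs.min_coefficients = coeff, min_coeff
    cs.degenerate_genes = degenerate
    return coeff


def _standardized_centroid_corr(centroids: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation between centroid profiles."""
    z = centroids - centroids.mean(axis=1, keepdims=True)
    norm = np.sqrt((z ** 2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norm > 0, z / norm, 0.0)
    return z @ z.T


def merge_clusters(cs: ClusterSet, profiles: pd.DataFrame,
                   merge_threshold: float = 0.9,
                   max_drop: float = 0.03) -> ClusterSet:
    """Greedily merge clusters with near-identical patterns.

    Candidate pairs are those whose mean profiles correlate at least
    ``merge_threshold`` after standardization (so magnitude differences do
    not block a merge).  The highest-correlation pair is merged first; the
    merge is kept only if the merged cluster's coefficient is within
    ``max_drop`` of both originals', otherwise it is rolled back and the
    pair blacklisted.  Genes are never added or removed, so the result is a
    coarsening of the input partition.
    """
    centered = mean_center_rows(profiles).loc[cs.assignments.index]
    x = centered.to_numpy(dtype=float)
    labels = cs.assignments.to_numpy().copy()

    def centroid(mask):
        return x[mask].mean(axis=0)

    def cluster_coeff(mask):
        if mask.sum() == 1:
            return 1.0
        r = _pearson_to_centroid(x[mask], centroid(mask))
        return float(r.mean())

    active = sorted(set(labels))
    coeffs = {c: cluster_coeff(labels == c) for c in active}
    rejected: set[frozenset] = set()
    while True:
        cents = np.vstack([centroid(labels == c) for c in active])
        corr = _standardized_centroid_corr(cents)
        best_pair, best_r = None, merge_threshold
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                pair = frozenset((active[i], active[j]))
                if pair in rejected:
                    continue
                if corr[i, j] >= best_r:
                    # strict improvement or first hit; ties keep the earlier
                    # (lower-index) pair for determinism
                    if best_pair is None or corr[i, j] > best_r:
                        best_pair, best_r = (active[i], active[j]), corr[i, j]
        if best_pair is None:
            break
        a, b = best_pair
        merged_mask = (labels == a) | (labels == b)
        merged_coeff = cluster_coeff(merged_mask)
        if merged_coeff < min(coeffs[a], coeffs[b]) - max_drop:
            rejected.add(frozenset(best_pair))
            continue
        labels[labels == b] = a
        coeffs[a] = merged_coeff
        del coeffs[b]
        active = sorted(set(labels))
        rejected = {p for p in rejected if b not in p}

    relabel = {old: new for new, old in enumerate(active)}
    new_labels = np.array([relabel[c] for c in labels])
    assignments = pd.Series(new_labels, index=cs.assignments.index,
                            name="cluster")
    centroids = pd.DataFrame(
        np.vstack([centroid(new_labels == c) for c in range(len(active))]),
        columns=profiles.columns,
    )
    coeff, min_coeff, degenerate = _coefficients(
        x, new_labels, centroids.to_numpy(), centered.index)
    return ClusterSet(assignments, centroids, coeff, min_coeff,
                      cs.n_iter, cs.seed, float("nan"), degenerate)


@dataclass
class RandomizationResult:
    """Null coefficient distribution from column-permuted re-clustering."""

    coefficients: list[pd.Series]

    @property
    def all_values(self) -> np.ndarray:
        return np.concatenate([c.to_numpy() for c in self.coefficients])

    @property
    def max(self) -> float:
        return float(self.all_values.max())


def randomization_control(profiles: pd.DataFrame, k: int, n_reps: int,
                          seed: int, n_init: int = 10) -> RandomizationResult:
    """Cluster-coherence null: permute each sample's values across genes,
    re-cluster, and record the per-cluster coefficients.

    Permuting within columns preserves each sample's value distribution
    while destroying gene-level patterns, so the resulting coefficients
    bound what the clustering can achieve by chance.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1 for a null distribution")
    rng = np.random.default_rng(seed)
    arr = profiles.to_numpy(dtype=float)
    out = []
    for rep in range(n_reps):
        shuffled = np.column_stack(
            [rng.permutation(arr[:, j]) for j in range(arr.shape[1])]
        )
        df = pd.DataFrame(shuffled, index=profiles.index,
                          columns=profiles.columns)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cs = kmeans_cluster(df, k, seed=sub_seed, n_init=n_init)
        out.append(cs.coefficients)
    return RandomizationResult(out)
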