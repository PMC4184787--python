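# Methods

## Data model and conventions

The analysis currency is a genes × samples matrix of normalized,
linear-scale microarray intensities together with a sample → population
map. Populations carry a class (neutrophil / non-neutrophil) and, for
neutrophils, a condition label (BM, BL, SF, UA, TG). All screens operate
on *population means* over replicate samples; log2 is applied only where a
specific analysis needs it (ANOVA, clustering profiles, correlation of
fold-changes, heatmap display). No pseudocount is ever added: normalized
intensities on this platform are bounded well above zero (panel minima are
around 8), so a non-positive value is treated as a data error rather than
silently shifted.

Medians of even-sized sets are the mean of the central pair (the screens
themselves only exercise n = 5). "Expressed" means a population mean
*strictly* greater than the presence threshold of 120 intensity units —
the level associated with ~95% probability of detectable protein on this
array generation. Matrix files are UTF-8 tab-delimited text with a
`gene_id` header cell and are parsed with round-trip float precision, so a
save/load cycle is bit-identical.

## Specificity screens

Over-expression: criterion (i) requires mean > 120 in every focal
population and in no comparator population; criterion (ii) requires
min(focal means) ≥ `min_fold` × max(comparator means), with `min_fold` = 2.
The reported fold ratio min(NF)/max(non-NF) is rounded half-away-from-zero
to the nearest integer, the convention under which 11.87 prints as
"12-fold". The under-expression screen swaps the roles and uses a
*strict* inequality (more than 2-fold); the asymmetry is deliberate and
mirrors how the two screens are conventionally phrased. Probe-level flags
collapse to gene level by OR over a gene's probes.

## Activation filter

Four conjunctive criteria over the neutrophil conditions: presence
(mean > 120 in ≥ 1 condition), one-way fixed-effects ANOVA across
conditions on log2 replicate values at raw P < 0.01, a mean-ratio ≥ 2 in
some unordered condition pair (equivalently max/min of condition means),
and within-group CV (SD/mean of linear replicates) < 0.5 in *every*
condition (`cv_mode="any"` relaxes this). ANOVA is computed on log2 values
because the platform's replicate noise is multiplicative; the log makes it
approximately homoscedastic. A BH-adjusted variant (Q < 0.05) is exposed
for focused re-analyses of small gene sets. Conditions with a single
replicate are rejected rather than silently skipped, since both ANOVA and
CV are undefined there.

Venn counts across the three activated conditions are computed from
fold-changes versus blood. In strict mode membership is fold > cutoff
(fold < 1/cutoff for down-regulation). In relaxed mode two conditions
share a gene when one exceeds the strict cutoff and the other at least the
relaxed one (default 1.5), and the triple region requires one strict plus
two relaxed; in both modes the seven region counts sum to the number of
genes exceeding the strict cutoff somewhere, and relaxed shared regions
contain the strict shared regions.

Between-condition agreement is summarized by Pearson r of log2
fold-changes and the OLS slope of one log2 fold vector on the other with a
95% t-interval. Category-count comparisons between two gene lists use a
2×2 two-sided Fisher exact test, or Pearson chi-square without continuity
correction when all expected counts are ≥ 5.

## Pattern clustering

Profiles are per-gene mean-centered across samples with no variance
scaling, so shape-identical patterns of different magnitude remain close —
this is what makes the later merging step meaningful. Lloyd's K-means
(Euclidean distance) is implemented in-package because its contract is
pinned: initial centroids are k distinct profiles sampled without
replacement under the seed, an emptied cluster is re-seeded at the point
farthest from its centroid, convergence means unchanged assignments, and
the best of `n_init` = 10 seeded restarts by within-cluster squared
distance is kept. Identical seed and input give identical output; the
objective trace is recorded and is non-increasing.

The cluster *coefficient* is the mean Pearson correlation between member
profiles and the cluster mean profile (the minimum is kept as a
diagnostic; a singleton cluster scores 1 by convention, and a
zero-variance profile contributes 0 and is flagged). Merging is greedy:
the pair of clusters whose standardized mean profiles correlate highest
(≥ 0.9) merges first, and a merge is rolled back when the merged
coefficient falls more than 0.03 below either original — the guard that
certifies a merge changed magnitude grouping, not pattern. The
randomization control permutes values within each sample (column),
preserving every sample's value distribution while destroying gene-level
covariation, then re-clusters and records the coefficients; on structured
data the real coefficients should exceed the null maximum outright.

For pipeline runs the clustered profiles are log2 replicate values of the
blood and activated conditions (BL, SF, UA, TG); BM is used in the filter
but not in the activation-pattern profiles.

## Regulatory inference

The regulatory model maps each target gene to exactly one coarse module
(up to 81) and associates each module with several regulators via
regression weights. Weights define which associations exist; they are
comparable only within a module and are never entered into any test
statistic.

*Module-bin permutation*: X = number of distinct listed genes that are
model targets (non-targets are dropped with a logged count). Each of
10,000 permutations draws X genes without replacement from all targets —
a hypergeometric null, chosen because a fixed set of distinct genes is
being distributed, not independent balls — and per-module p is the
smoothed upper tail (1 + #{null ≥ observed}) / (n_perm + 1), which cannot
be zero. BH across modules, enriched at Q < 0.05. The permutation null
for given X and module sizes is exposed separately (`module_null_counts`)
so calibration studies can reuse one null across many lists.

*Pair over-representation*: a listed gene contributes one pair per
regulator of its module. For each regulator R the 2×2 table is
[[pairs_R in list, pairs_other in list], [pairs_R remaining in model,
pairs_other remaining]]; Pearson chi-square without continuity correction
(the exact contingency construction is a declared design choice), Fisher
fallback when an expected cell is below 5, BH across regulators,
selected at Q < 0.01 *and* observed above expected (over-representation
only).

Selection is the conjunction over the up/down/complex cluster pools: a
pair-test hit in some pool and association with an enriched module in
some pool. BH is applied within each pool separately. The regulator ×
cluster matrix holds *raw* pair p-values (significance lives in the
pool-level selection); clusters with no model targets get p = 1 and a
flag. Both axes are clustered with average linkage on Euclidean distances
between −log10(p) vectors (p floored at 1e−300), deterministically.

## Synthetic data

The generator emulates the compendium's design at desk scale: 2,000
genes; five neutrophil conditions × 3 replicates; 20 non-neutrophil
populations × 2 replicates; gene baselines log-normal around 2^8;
replicate noise log-normal with linear CV 0.1 (σ² = ln(1 + CV²), mean
preserved exactly). Planted structure: 30 lineage-specific genes whose
non-neutrophil level is drawn between 16 and 90 (below the presence
threshold) and elevated 20-fold in all neutrophil populations; six
50-gene activation archetypes (up/down in all activated conditions, one
per single condition, one mixed) at 4-fold effects versus blood; 40
coarse modules with Dirichlet-uneven sizes and 30 regulators, three of
which are planted by concentrating 90% of one archetype's genes into two
dedicated modules. These defaults were chosen once to resemble the study
design while keeping the full test battery in seconds, and all of them
are explicit `SimulationDesign` fields.

What the synthetic experiments demonstrate: the screens achieve exact
recall/precision on planted genes at the design noise level; clustering
recovers planted archetypes (adjusted Rand ≥ 0.9 at CV 0.1); real cluster
coefficients exceed the randomized maximum; planted regulators are
selected with sensitivity ≥ 0.9 and random lists select essentially none.
What they do not demonstrate: behavior under probe-level artifacts, batch
effects, heavy-tailed or correlated noise, or the exact gene counts of
any real dataset — those depend on the deposited data, not on the
algorithms.

## Numerical and calibration notes

* Permutation p-values are discrete: they can only be as fine as the null
  distribution of the count statistic. The uniformity check therefore
  uses a dedicated model with four 4,000-target modules and lists of
  8,000 genes, where the hypergeometric count SD (~27) makes the p-value
  staircase fine relative to the KS resolution at 1,000 lists; on small
  modules the same test would reject uniformity for discreteness alone.
* BH is the exact step-up: q_(i) = min_{j≥i} p_(j)·n/j, clipped to 1;
  it matches statsmodels' `fdr_bh` to 1e−12 in the tests.
* The heatmap display divides per-gene centered log2 values by
  log2(span)/2 (span 8 by default) and clips to [−1, 1], flagging clipped
  entries; the output is invariant to positive rescaling of a gene.
* Ties: K-means restarts keep the first-best objective; merging breaks
  correlation ties toward lower cluster indices; hierarchical leaf orders
  come from SciPy's deterministic linkage.

## Known limitations

* The ANOVA flavor, the chi-square contingency construction, and the
  exact clustering initialization of the original analysis tools are not
  fully specified anywhere; the choices above are explicit, documented
  substitutes rather than reconstructions.
* Merging is an automated greedy procedure with a coefficient guard; an
  analyst merging by inspection may accept or refuse different pairs.
* The permutation and pair tests treat genes as exchangeable; gene-length
  or expression-level biases present in real lists are not modeled.
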