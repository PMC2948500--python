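# Methods

`crcpathways` implements a multidirectional analysis of bulk microarray
expression data over the colorectal adenoma–carcinoma sequence: normal
mucosa (NC) → adenoma (AD) → carcinoma (CA). The design principle is that a
single normalization and a single feature-ranking method each impose
arbitrary analytic choices, so a pathway is reported only when it survives
*every* combination of two normalization arms and two probe-ranking
criteria, and only after pathways attributable to cell-type composition
(epithelium versus bulk mucosa) are subtracted. The package runs entirely on
synthetic experiments with recorded ground truth, so each stage's recovery
behavior is measurable.

## Pipeline model

**Normalization arms.** Two matrix-level normalization contracts are
compared, emulating the behavior of the two classical probe-level chains at
the level of the summarized matrix (probe-level background correction and
summarization are out of scope):

* *Global scaling* — each array is multiplied by `target / trimmed_mean`
  (two-sided trim, default `trim = 0.02`, `target = 500`; the scanner-era
  convention — the constants are configurable because published studies
  rarely print them). Removes per-array scale factors exactly and nothing
  else.
* *Least-variant set (LVS)* — probes are ranked by the variance of their
  within-array ranks (invariant to any monotone per-array transform); the
  lowest 60% (`lvs_proportion = 0.6`) anchor a robust Theil–Sen fit of each
  array's log2 intensities onto the across-array median profile of the LVS
  probes, and the fitted line is applied to all probes. Removes scale
  factors *and* log-linear intensity distortions. The published LVS method
  ranks probes by an RA-plot residual criterion; rank variance was chosen as
  a dependency-free deterministic emulation. The Theil–Sen fit uses a
  deterministic 400-probe quantile-spread subsample of the LVS set, since
  the full pairwise-slope estimator is quadratic in the set size.
* *Quantile normalization* is provided as the baseline LVS replaces; the
  consensus pipeline itself uses the scaling and LVS arms.

**Filtering.** Within each arm: (1) a detection threshold is set at the
98th percentile (nearest-rank) of Y-chromosome probe intensities pooled over
female samples — in females these probes measure pure background — and
probes must exceed it in at least 5% of samples (strictly greater,
`ceil`-rounded sample count); (2) whole-tissue data additionally lose probes
whose fold change versus their own median (two-sided, linear scale) exceeds
1.5 in fewer than 6 samples. After thresholding, Y-linked probes are removed
from the analysis universe (`filter.drop_y_probes`): at desk scale a few
dozen strongly bimodal male/female probes would dominate the leading SVD
mode, an artifact the full 54k-probe arrays this emulates do not show.

**Probe orderings.** Supervised: per-probe Welch t statistics with
two-sided permutation p-values — exhaustive over label splits when
`C(n, n1) ≤ n_perm` (p = fraction of splits reaching the observed |t|,
observed split included, so p > 0), Monte Carlo with the (1+x)/(1+N)
correction otherwise — BH-adjusted, probes sorted ascending (ties: raw p,
then |t| descending, then probe id). Unsupervised: probes sorted by absolute
loading on a chosen SVD mode (default mode 1) of the probe-centered log2
matrix; each mode is sign-fixed so its largest-|loading| probe loads
positively. Monte Carlo label subsets are drawn in canonical
sorted-sample-id order, which makes every statistic invariant to permuting
the input columns.

**Low-purity flagging.** Mode-1 sample scores are split at the midpoint of
the two group medians; tumor-labeled samples on the normal side are flagged
and (by default) excluded from the supervised comparison of that contrast —
the unsupervised ranking retains the full decomposition. Tumor samples
whose annotated malignant content falls below 35% are likewise excluded
from the whole-tissue progression contrasts. Flagging is advisory: the
flagged ids are reported, and exclusion is a config switch.

**Pathway enrichment.** For a pathway with member ranks
`r_1 < … < r_m` in a list of `N` probes,
`D⁺ = max_i ( i/m − (r_i − 1)/N )` measures concentration at the top. The
null tail `P(D⁺ ≥ d)` over all `C(N, m)` equally likely placements is
computed exactly by a lattice-path count (O(N·m), identical to enumeration:
member `i` avoids `d` iff its rank exceeds `N(i/m − d) + 1`, and sequences
satisfying all bounds are counted by a cumulative-sum recursion with
log-scale rescaling). The one-sided iid tail (Birnbaum–Tingey, effective
size m) is exposed as `method="asymptotic"` and used automatically only
when `N·m` exceeds 5·10⁶; at the sizes the pipeline reaches the exact path
always applies. Pathways with fewer than `min_size = 5` members in the
filtered universe are not tested; p-values are BH-adjusted across tested
pathways.

**Consensus rule.** Within one ordering, a pathway is significant when its
adjusted KS p is below 0.01 in at least one normalization arm, or below
0.05 in both. A contrast's consensus set is the intersection of the two
orderings' selections. The epithelium-versus-mucosa background is the set of
pathways significant (same rule, supervised ordering) in at least 3 of the
4 microdissected CEC-vs-MUC comparisons (NC, NT, AD, CA); the final report
per contrast is consensus minus background.

**Progression markers.** A probe is a progression marker when, in all three
sample arms (whole sections, microdissected epithelium, microdissected
mucosa) and under both normalizations, its group means are strictly ordered
along NC → AD → CA and both adjacent contrasts reach FDR-adjusted p < 0.01.
"Gradual change throughout progression" is operationalized as both adjacent
steps significant with consistently ordered means — the main interpretive
decision in this module; a trend test over the three groups jointly would
be an alternative. Negating the matrix exactly swaps the up and down sets.

## Synthetic data model

A probe's log2 value is
`base_p + effect_{p,g(s)}·purity_s + affinity_p·(epi_s − 0.5) + ε`, with

* `base_p ~ N(8, 1.5²)` (log2 scale) and per-probe noise
  `sd_p = sqrt(noise_sd² + b_p²)`, `noise_sd = 0.2`, `b_p ~ U(0, 0.4)`. The
  heterogeneous biological component matters: with uniform noise the
  1.5-fold-change filter degenerates into a lottery over noise tails instead
  of separating stable from variable transcripts. The resulting total
  within-group sd (0.2–0.45) is typical of expressed probe sets on
  short-oligo arrays.
* Planted pathway effects: members of a pathway planted on contrast
  `"X_vs_Y"` gain `δ` log2 units (default 1.0) in the elevated groups;
  members of an `"epithelium"` pathway instead get an affinity coefficient
  of `δ` (default 1.5), making them cell-composition confounds rather than
  disease signals. Background probes get `affinity ~ N(0, 0.3)`.
* `epi_s` is each sample's epithelium fraction, Beta-distributed per group
  (whole tissue: NC ~ Beta(14,6), AD ~ Beta(10,10), CA ~ Beta(9,11);
  microdissected epithelium ~ Beta(80,4), mucosa ~ Beta(16,48) — capture is
  tightly controlled, bulk sections are not). `purity_s = epi_s / E[epi |
  group]` scales the planted group effects *in whole-tissue designs only*,
  so low-content tumors drift toward the normal group (this is what the
  SVD flagging detects); microdissected samples carry the full effect.
* Monotone markers: 10 up and 10 down probes with a 1.0 log2 step per
  stage, drawn from probes free of planted pathway effects, identical probe
  ids across the whole-tissue and microdissected simulations.
* Technical artifacts applied on the linear scale: per-array factor
  `exp(N(0, 0.15²))` and a per-array power distortion `I ↦ I^(1+γ)`,
  `γ ~ N(0, 0.03²)` — a smooth monotone intensity-rank bias that scaling
  normalization only partially removes and LVS removes exactly, which is
  precisely the contrast between the two arms.
* Sex: samples are male with probability 0.5; the 30 trailing probes are
  Y-linked and sit at background (log2 ≈ 4) in females.

The default study is 5,000 probes; 20 whole-tissue samples per disease
group; 15 microdissected samples per tissue×stage cell; a 100-pathway
non-overlapping dictionary (sizes 10–40) with three pathways planted per
disease contrast and two epithelium confounds. Pathway counts and sizes are
scaled down from the ~200-category flat pathway databases this emulates, in
proportion to the reduced probe universe. The dictionary generator supports
partial overlap; the default study uses disjoint sets so every planted
effect stays attributable to exactly one pathway (overlapping planted sets
stack effects and can silently create extra monotone probes).

What the generator does **not** emulate: probe-level structure (GC content,
probe affinities, mismatch probes), correlated co-expression beyond the
planted axes, batch-by-date effects, RNA-quality gradients, and any
relationship between a pathway's identity and its biology. Passing
recovery tests therefore demonstrates that the pipeline's logic is sound
under its own assumptions, not that it would reproduce any particular
published pathway list from raw arrays.

## Numerical choices

* Permutation depth `n_perm = 20,000` in the pipeline: the permutation
  floor 1/(n_perm+1), multiplied by the BH factor at ~5,000 probes with
  ~10²  truly changed probes, must stay below the 0.01 marker threshold.
* Percentile convention: nearest rank (`ceil(p/100·n)`-th order statistic);
  "above threshold" and "fewer than 6 samples" are strict inequalities.
* BH adjustment delegates to `statsmodels.stats.multitest.multipletests`
  (`fdr_bh`); the test suite checks it against an independent brute-force
  step-up oracle.
* LVS set size is `round(proportion·n_probes)` (half away from zero); LVS
  selection ties break by probe id.
* Degenerate cases: zero variance in both groups with equal means gives
  t = 0, p = 1 (not an error); a probe with zero median fails the
  fold-change filter with an explicit error; a trimmed mean of zero fails
  scaling normalization.
* Seeds: every stochastic stage derives its seed as
  `(seed + crc32(stage_tag)) mod 2³¹`, so stages are decorrelated but the
  whole run is reproducible from one integer, independent of execution
  order.

## Known limitations

* The consensus intersection is deliberately conservative: a marker or
  pathway must clear twelve significance gates, so sensitivity is traded
  for specificity — under the default conditions a planted marker near the
  top of the biological-noise range can drop a single cell below FDR 0.01
  and be lost. This mirrors the method's own philosophy (consensus over
  analytic variants reduces false positives at the cost of misses).
* Matrix-level normalization emulations cannot capture probe-level effects;
  conclusions about MAS5-like versus LVS-like behavior apply to their
  normalization contracts only.
* The exact KS null assumes exchangeable member placement, i.e. it is a
  competitive test against the uniform rank distribution; correlated member
  statistics (co-expression) would make it anti-conservative on real data.
* `flag_low_separation_samples` assumes the chosen mode separates the two
  groups; if mode 1 tracks a different axis the flags are meaningless —
  flagging is therefore advisory and reported, never silent.
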