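# Methods

This note documents the statistical model behind each module, the default
parameters and why they were chosen, and the known limitations. All
empirical numbers quoted here were measured with the code in this
repository (most are re-checked by the test suite).

## Data model and ingestion (`mycohub.io`)

Samples are rows, ASVs are columns, counts are non-negative integers.
Sample metadata requires `species`, `tissue`, `replicate`. Validation
distinguishes errors (shape/type/ID mismatches between counts, metadata,
sequences) from warnings (missing taxonomy entries), since taxonomy is
annotation rather than structure. Merging two species' tables takes the
union of ASV columns, filling absent ASVs with zeros; the merge summary
reports `n_a + n_b − n_shared = n_union`.

## Synthetic generator (`mycohub.synthetic`)

The generator exists to provide planted ground truth for recovery and
calibration tests, not to be a faithful ecological simulator. Design:

- **Nested tissue pools.** Each tissue's species pool is a subset of the
  next older tissue's pool (youngest = smallest), so the tissue-level
  presence matrix is nested by construction. Pool sizes interpolate from
  `pool_min` to `n_asvs`.
- **Planted producers.** `n_producers` ASVs are drawn from the youngest
  pool (so they occur everywhere), given reference-derived marker
  sequences, and given mean abundances that track the metabolite gradient
  across tissues.
- **Planted modules.** `n_modules` disjoint sets of `module_size` ASVs
  share a lognormal latent factor per sample, which induces positive
  co-occurrence within each set.
- **Counts.** Per-sample expected compositions are drawn once per tissue
  with lognormal replicate noise, scaled by a lognormal sequencing depth
  (`depth_log_mean`), and realized as negative-binomial counts.
- **Sequences.** 250-bp marker sequences; producer ASVs are ≤2 mutations
  from a producing reference strain (> 99% identity), all other ASVs are
  random (expected identity far below any screening threshold).
- **Truth JSON** records producer IDs, module assignments and tissue pools.

Limits: no compositional bias, no chimeras or sequencing error model, no
negative interactions in modules, and the metabolite gradient is noise-free
at the tissue level. Recovery tests are therefore upper bounds on
real-data performance.

## Diversity (`mycohub.diversity`)

Rarefaction is subsampling without replacement at a fixed depth; samples
below depth are dropped with a logged warning. Bray–Curtis is computed on
relative abundances by default. NMDS uses scikit-learn's non-metric MDS
(two dimensions, normalized stress-1); the reported stress is cross-checked
in tests with an independent isotonic-regression computation. PERMANOVA
uses the pseudo-F from the Gower-centered partition of squared distances
with label permutations, `p = (1 + #{F_perm ≥ F_obs}) / (n_perm + 1)`, so p
is never zero. Measured type-I error at α = 0.05 over 2,000 null
simulations (12 samples, 199 permutations): 0.0475.

## PHP screen (`mycohub.php`)

An ASV is a potential producer (PHP) if **either** line of evidence holds:

1. **Identity**: best semi-global alignment against any producing reference
   strain has percent identity ≥ 97 (inclusive). Scoring: match +1,
   mismatch −1, gap of length L costs 2 + L, terminal gaps free and
   excluded from the identity denominator. A fast banded edit-distance
   prefilter (margin 5) discards hopeless candidates before exact affine
   alignment; tests assert the prefilter never changes results.
   **`min_coverage = 0.8`**: with free terminal gaps, two unrelated
   sequences almost always share a tiny perfect overlap that scores "100%
   identity" over a few columns, so a hit must additionally cover ≥ 80% of
   the shorter sequence (the conventional coverage floor of common
   clustering tools). This guard was added after property-based testing
   exposed the chance-overlap artifact.
2. **Correlation**: Kendall tau-b between the ASV's tissue-mean relative
   abundance and the tissue metabolite gradient is strictly > 0.4.
   Tau-b handles ties; constant vectors have undefined tau and never pass.

The final call set is the union with per-ASV evidence flags;
`n_union = n_clustering + n_correlation − n_both`.

## Nestedness (`mycohub.nestedness`)

- **NODF** over the tissue-level presence matrix: for every ordered pair of
  rows (and of columns) with strictly decreasing, nonzero totals, paired
  overlap = |shared| / |smaller|; pairs with equal totals contribute 0; the
  score is the mean over all row and column pairs × 100. Verified against
  an all-pairs brute-force oracle.
- **Temperature (variant).** Rows/columns are ranked by decreasing totals;
  the isocline is the diagonal band u + v = c with area equal to the fill;
  temperature is the mean squared relative distance of "unexpected" cells
  (presences below the isocline, absences above) normalized by the
  all-unexpected bound, × 100. Because marginal-total ties make any single
  packing order arbitrary (and for wide matrices ties are unavoidable),
  cell positions are averaged uniformly over each tie block, i.e. the
  statistic is the exact expectation over random tie orderings. This makes
  it invariant to input row/column order (property-tested) while leaving
  tie-free matrices unchanged. It is *not* numerically identical to the
  classic temperature; treat it as a comparable disorder index on [0, 100]
  (perfect staircase = 0; 4×4 checkerboard = 50).
- **Null model**: column (ASV) occurrence totals fixed, presences placed in
  uniformly random rows; one-sided `p = (1 + #{NODF_null ≥ NODF_obs}) /
  (n_sims + 1)`.

## Networks (`mycohub.network`)

Default backend `clr-spearman-perm`: counts + 0.5 pseudocount → CLR →
pairwise Spearman → per-pair null by permuting one column (default 1,000
permutations) → BH across pairs → keep edges with q ≤ 0.05. Note the
discrete permutation p-values have floor 1/(n_perm + 1); with many
candidate pairs the BH threshold can fall below that floor, so `n_perm`
must be large enough for the intended FDR (the pipeline defaults satisfy
this). Backends are pluggable via `register_backend`.

Modules: Clauset–Newman–Moore greedy modularity (unweighted). Node roles:
Zi (within-module degree z-score) and Pi (participation coefficient) with
the conventional strict cutoffs Zi > 2.5 and Pi > 0.62; boundary values are
peripheral. Baselines: Erdős–Rényi G(n, m) graphs matched on nodes/edges;
degree-distribution tail fit by OLS on log–log survival counts.

## Differential abundance (`mycohub.diffabund`)

Per-ASV negative-binomial Wald test of a two-group contrast:

- **Size factors**: median-of-ratios to the geometric-mean reference over
  ASVs present in all samples. When no ASV is present in every sample
  (typical for cross-species contrasts with disjoint ASV sets), a
  positive-counts pseudo-reference mode restricts the geometric mean and
  median to each sample's nonzero ASVs (`pseudo_reference=True`; the main
  entry point falls back to it automatically with a warning).
- **Dispersion**: per-ASV method-of-moments estimate, floored at 1e-8 and
  moderated from below by the **mean of the clipped per-ASV estimates**.
  The more obvious median moderation left small-sample dispersions
  under-estimated and pushed the realized FDR of the full pipeline to
  ~0.10 at a nominal 0.05; mean moderation (less downward-biased for the
  right-skewed MoM distribution) brought the measured null FDR to
  0.00–0.06 across the tested conditions without losing power on planted
  effects. `moderate=False` recovers the unmoderated estimator.
- **Test**: statsmodels NB GLM with fixed per-ASV alpha, Wald p on the
  group coefficient, BH adjustment, significance = `padj ≤ padj_max` and
  `|log2FC| ≥ lfc_min`.

## Pipeline (`mycohub.pipeline`)

A single master seed fans out to per-stage seeds via
`(seed XOR crc32(stage_name)) mod (2^31 − 1)`, so each stage's randomness
is independent of the others and all derived seeds are valid 31-bit ints.
Outputs include `results.json`, a Markdown report, and `manifest.json`
with the SHA-256 of every written file; identical config + seed produces a
byte-identical manifest.

## Open decisions / limitations

- The temperature statistic is a documented variant, not the classic
  algorithm (no isocline optimization); comparisons with published
  temperature values are qualitative only.
- The null model fixes occurrence totals but not sample (row) richness; a
  bipartite swap null would hold both and is a natural extension.
- NB dispersion moderation is a single global lower bound, not an
  empirical-Bayes shrinkage toward a mean–dispersion trend.
- The network permutation null permutes one member of each pair, which
  tests independence but not compositional artifacts beyond what CLR
  removes.
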