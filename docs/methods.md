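# Methods

This note documents the models, estimators and numerical choices behind
`spongenet`, and what the synthetic benchmarks do and do not demonstrate.

## Setting and model

The package analyses a two-group (normal vs placenta percreta) bulk
RNA-seq design with three jointly profiled RNA classes: protein-coding
mRNAs, lncRNAs and miRNAs. Its scientific core is the ceRNA ("sponge")
hypothesis: a lncRNA that shares many miRNA binding partners with an mRNA
competes for those miRNAs, so the pair's expression should co-vary
positively while the mediating miRNAs move in the opposite direction.
The inference chain screens each class for differential expression,
groups deregulated coding genes into co-expression modules, scores every
differential lncRNA–gene pair for shared-miRNA enrichment and expression
correlation, and assembles passing pairs with their top mediating miRNAs
into a triplet network.

## Differential screening

* **Normalization.** Median-of-ratios size factors: for features with
  strictly positive counts in every sample, factor_j = median_i of
  count_ij / geometric-mean_i. No rescaling is applied afterwards;
  factors of balanced libraries are ≈ 1 by construction. `baseMean` is
  the mean of normalized counts over all samples and doubles as the
  expression-level ranking key for hub-lncRNA selection.
* **Test.** A two-sided Welch t-test on log2(normalized + 1). This is a
  deliberate, documented simplification: it is deterministic,
  dependency-free, and calibrated on the synthetic data this package
  ships with (the null benchmark below runs at the design's own 4 + 4
  scale, where the test is mildly conservative). It does not shrink
  dispersions and will be underpowered relative to count-model tests on
  real data at n = 4; anyone analysing real data should treat the
  screening stage as replaceable.
* **Degenerate features.** Both groups constant and equal → p = 1; both
  constant but unequal → sentinel p = 1e-300 with a warning (avoids NaN
  propagation while keeping the feature visibly significant).
* **Calls.** up ⇔ log2FC ≥ +1 and p < 0.05; down symmetric. The
  fold-change boundary is inclusive and the p boundary strict, exactly as
  the thresholds are printed. BH-adjusted p-values are reported per class
  for reference, but screening uses raw p by design.
* **Orientation.** Positive log2FC = higher in PP. Pseudocount 1
  (configurable) stabilises fold changes of low-count features at the
  cost of shrinking them toward 0.
* **qPCR.** 2^−ΔΔCt with ΔΔCt = (Ct_target,case − Ct_ref,case) −
  (Ct_target,ctrl − Ct_ref,ctrl).

## Co-expression core

Unsigned adjacency a_ij = |r_ij|^β by default (signed option
((1+r)/2)^β). β is picked as the smallest power in 1..20 whose signed
scale-free fit — the squared correlation between log10(mean connectivity
per bin) and log10(bin frequency) over 10 bins, negated for increasing
slopes — reaches 0.8, falling back to the argmax (with a warning) and to
β = 6 when connectivity is degenerate. Topological overlap uses the
standard formula with unit diagonal; the implementation is vectorised
(l = A² − 2A for unit-diagonal A) and is held to the triple-loop
definition at 1e-12 in the tests.

Module detection is average-linkage hierarchical clustering of 1 − TOM
with a **static** branch cut (default height 0.995) and a minimum module
size of 30; smaller clusters become "grey". Dynamic hybrid tree cutting
is intentionally out of scope — the static cut keeps the algorithm small
and auditable, at the cost of merging adjacent branches when between-
module overlap creeps above 1 − cut_height (see the benchmark notes
below). Modules are colour-named in decreasing size order following the
conventional palette (turquoise = largest).

Eigengenes are the first right-singular vector of the gene-standardized
(ddof = 1) module submatrix, scaled to unit variance and oriented so the
mean correlation with the module's genes is positive;
variance_explained = σ₁²/Σσ². Module–trait association is the Pearson
(point-biserial) correlation of the eigengene with the 0/1 condition.
The pipeline applies the co-expression stage to the differential coding
genes (raw p < 0.05), mirroring the "deregulated genes" reading of the
workflow it re-implements; when fewer than 20 genes survive, β falls
back to 6 rather than fitting a scale-free curve to a handful of points.

## Sponge statistic

For a lncRNA–gene pair with miRNA sets M_l, M_g inside a universe U:

* **P1** = P(X ≥ |M_l ∩ M_g|), X hypergeometric with population |U|,
  successes |M_l|, draws |M_g| — the one-tailed Fisher exact test on the
  2×2 membership table. The upper tail is symmetric in the two sets, so
  which margin is "draws" is immaterial.
* **P2** = two-sided t-based p of the Pearson correlation of the pair's
  log2 expression across **all** samples (both groups).
* **Combined**: Fisher's sum of logs, X = −2(ln P1 + ln P2) ~ χ²₄; the
  survival function has the closed form exp(−X/2)(1 + X/2). Zero
  p-values are clamped to 1e-300 with a warning.
* **FDR**: Benjamini–Hochberg step-up across *all* enumerated candidate
  pairs — the most conservative family choice; restricting the family to
  k ≥ 10 pairs would only make passing easier.
* **Filters**: FDR ≤ 0.05 (inclusive), shared miRNAs k ≥ 10 (inclusive),
  pair correlation r > 0.25 (strict). Candidates and the miRNA universe
  are pre-filtered to differential features (raw p < 0.05); the universe
  choice ("de" vs all target-map miRNAs) is exposed as a flag.
* **Seed families**: by default each miRNA id is its own seed family; an
  optional id→family map collapses family members before counting shared
  miRNAs.
* **Mediators**: ranked by differential p-value (default) or by mean
  |correlation| to the two pair members — both orderings are reported
  because the two conventions coexist in practice; ties break
  lexicographically. The top 20 mediators per passing pair enter the SIF
  export (two edges per triplet: lncRNA→miRNA, miRNA→mRNA).

Output ordering (FDR ascending, then k descending, then ids) is fully
deterministic, so repeated runs are byte-identical.

## Hub selection and enrichment

Fig-4-style partner ranking uses |r| (strong negative regulators are as
interesting as positive ones); the hub-lncRNA filter uses **signed**
r > 0.5, since the selection targets positively coupled lncRNAs. The two
rankings for the Venn step are ascending differential p and descending
baseMean, truncated to k_top = 20; the intersection is the selection.
Over-representation is the same hypergeometric upper tail as P1, BH
adjusted across pathways, with the universe defaulting to annotated
features.

## Synthetic generator

Counts are NB(μ, φ) with variance μ + φμ², default φ = 0.1 (a typical
bulk RNA-seq dispersion; the emulated study reports none). Per-feature
baseline means are log-normal around `baseline_mean` = 100 with σ = 0.5
(natural log), giving a realistic dynamic range; per-sample depth
multipliers are log-normal(0, 0.1). All planted effects act on the log2
mean, so counts remain integers:

* **Differential plants**: ±`planted_lfc` (default 1.5) added to the
  case group, alternating sign.
* **Modules**: genes share a latent factor f = 0.5·x + √(1−0.25)·ε
  (x = ±1 the condition, ε per-sample noise), scaled by
  `module_strength`; the 0.5 trait loading makes eigengenes track the
  condition without making distinct modules collinear.
* **Triplets**: the lncRNA and mRNA share a pure-noise factor (loading
  `module_strength`) and are both shifted up in the case group; their
  shared miRNAs are shifted down with a −0.5·strength loading on the same
  factor, emulating anti-correlated mediators. Target-map edges for all
  shared miRNAs are planted; decoy edges are uniform at
  `decoy_target_density`, excluding planted edges so truth stays
  unambiguous.

One master seed is split into per-class substreams (SeedSequence spawn),
so partial re-runs reproduce exactly. The generator does **not** model
batch effects beyond depth, isoforms, length bias, or read-level noise;
passing benchmarks demonstrate the statistical machinery recovers planted
structure under its own assumptions, not performance on real libraries.

A constraint worth knowing: planted features must stay a minority of
their RNA class. Median-of-ratios normalization assumes most features are
unchanged; configurations where module genes or planted miRNAs dominate a
class silently absorb the signal into the size factors (and that is a
faithful reproduction of what would happen with real data).

## Benchmark conditions

* **Null specificity**: 200 replicates (100 in the acceptance script) at
  the study's own 4 + 4 scale with nothing planted
  (150/100/100 features, decoy density 0.1); the mean fraction of
  enumerated pairs passing must not exceed the nominal 5% FDR plus
  3 Monte-Carlo SEs. In practice the joint k ≥ 10 / r > 0.25 / FDR filter
  yields essentially zero null passes.
* **Module recovery**: 3 planted 50-gene modules, strength 0.9, 20
  samples per group, 500 coding genes, default β = 6; mean adjusted Rand
  index vs planted labels (computed over planted genes) ≥ 0.9 over 20
  seeds. At 10 samples per group the static cut begins to merge modules
  through chance-correlation bridges — the documented price of skipping
  dynamic tree cutting.
* **Triplet recovery**: 10 planted triplet groups (12 shared miRNAs)
  among ~1400 enumerated candidate pairs (300/100/500 features, decoy
  density 0.02), 15 samples per group so the Welch screen has adequate
  power for the 1.5 log2FC plants against their ~1.0 log2-sd factor
  variance; mean recall and precision ≥ 0.8 over 20 seeds.
* **Determinism**: the full pipeline on a 500-gene integration fixture
  (4 + 4 samples) run twice with one seed must produce identical SHA-256
  hashes for every output file.

Problem sizes were chosen so the full suite and the acceptance script
each complete in a few minutes on one CPU while keeping every Monte-Carlo
band meaningful.

## Known limitations

* The Welch-on-log DE test is a screening device, not a count model; no
  dispersion shrinkage, GLM designs, covariates or batch correction.
* Static tree cut; no module merging by eigengene correlation; no
  blockwise decomposition for very large gene sets.
* Sequence-level seed matching, binding-energy prediction and
  conditional-correlation ceRNA statistics are out of scope; the target
  map is consumed as given.
* Feature identifiers are opaque strings; no id mapping between
  annotation systems.
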