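# Methods

## Patient representations

**Code arm.** The design matrix is the raw count-weighted embedding sum
`X = P·E`. Rows are *not* scaled or standardized by default: the magnitude
of a patient's record (how often codes recur) is treated as signal. A
`normalize` flag offers per-row L2 normalization as a sensitivity analysis.
Codes present in the records but absent from the embedding table are dropped
with a warning rather than zero-imputed, since silent zero rows would bias
the sums. Patients left with no codes after removing the
condition-of-interest codes are excluded (and reported), mirroring a cohort
filter that requires at least one comorbidity code.

**Note arm.** Text chunking cuts at most 1024 characters per chunk,
preferring the last whitespace inside each window and hard-splitting only
when a window contains none; concatenating the chunks reproduces the input
exactly.

The per-row attention entropy is the Ebrahimi–Pflughoeft–Soofi spacing
estimator: for order statistics `x_(1..n)`, window `m = ⌊√n + 0.5⌋`,
boundary convention `x_(j)=x_(1)` for `j<1`, `x_(n)` for `j>n`, and
coefficients `c_i = 1+(i−1)/m` (head), `2` (interior), `1+(n−i)/m` (tail),

    H = (1/n) Σ log( n (x_(i+m) − x_(i−m)) / (c_i m) ).

Numerical choices: zero spacings (tied attention values) are clamped at
machine epsilon instead of producing −∞, which keeps the subsequent softmax
well-defined while deterministically driving degenerate rows' weights toward
zero; the softmax subtracts the max entropy for stability; no jitter is ever
added, so ties resolve by exact arithmetic. Rows shorter than 4 tokens
cannot feed the spacing estimator, so such chunks fall back to simple mean
pooling with a logged warning. The estimator is shift-invariant and adds
`log s` under scaling by `s`, which the tests verify to 1e-9.

The weighting direction follows the estimator-softmax composition as
defined: higher-entropy (diffuse-attention) rows receive *higher* weight.
No sign flip is exposed. Entropy-weighted pooling is the default mode, with
`simple_mean` available for comparison; the two agree exactly whenever all
attention rows are equal.

## Provider alignment

Alignment operates on the 2-D reduction of the pooled note vectors, not in
the full token-embedding space, and is fully unsupervised. The transport
problem uses uniform weights on both clouds and squared-Euclidean cost, and
is solved exactly (linear programming via HiGHS); entropic regularization is
deliberately out of scope. Each source point then moves to the barycenter
of its transported mass, which places every aligned point inside the convex
hull of the reference cloud. The reference provider defaults to the one
with the most patients (ties broken lexicographically): this is reproducible
and leaves the largest share of the cohort undistorted. Non-reference
providers are processed in sorted order, so runs are deterministic.

The 2-D reducer is pluggable: a UMAP backend (seeded, single-threaded) and a
PCA backend. PCA is exact, fast, and preserves additive offsets, which makes
it the right tool for tests and for the acceptance script; UMAP is the
default for exploratory use. Reducer settings and seed are recorded in the
output's `reducer_params`.

## Clustering

Ward linkage in Euclidean geometry throughout (Ward's minimum-variance
criterion presumes squared-Euclidean distances). The merge heights equal
`√(2·ΔESS)` and are checked in the tests against a brute-force
minimum-ESS-increase agglomerator on all small instances. k is selected in
2–10 by maximal mean silhouette on cuts of the *same* dendrogram, ties
breaking toward smaller k; within-cluster sum of squares per k is emitted as
an elbow diagnostic but never decides. Labels are canonicalized by
decreasing cluster size (ties by smallest member index) so outputs are
stable across runs. A labeling in which every cluster is a singleton scores
silhouette 0 by convention.

## Characterization statistics

* 2×2 enrichment tests use the Yates continuity correction. The choice is
  forced by arithmetic: recomputing the reference cohort's printed sex
  enrichment (e.g. 200/356 female in the smallest code cluster vs 1478/3098
  in the rest) gives the printed 8.8 only with the correction — uncorrected
  Pearson gives ≈ 9.2.
* r×c tests use uncorrected Pearson χ²; the reference 3×3 cross-tabulation
  statistic (89.43) matches only the uncorrected form.
* "Standardized residuals" are implemented as *adjusted* residuals,
  `(O−E)/√(E(1−p_row)(1−p_col))`. The convention is again pinned by
  consistency: inverting this formula on the published marginals and the six
  published cell residuals yields an integer table that satisfies all
  marginals exactly (Pearson residuals do not), and recomputing residuals
  from the reconstruction round-trips the published values.
* The prevalence ratio uses patient-level presence, not occurrence counts;
  a feature with zero prevalence outside the cluster is reported as
  `EXCLUSIVE` rather than an infinite ratio, and zero in-cluster prevalence
  gives PR = 0. Both-zero is an error.
* Multiplicity: Bonferroni for code-enrichment scans (family = all features
  tested within one cluster's analysis), Benjamini–Hochberg for the
  demographic characterizations and post hoc tests. The family definitions
  are configuration, not constants, since reasonable analysts draw them
  differently. α = 0.05 two-sided throughout.
* The top-code rule: if any feature survives correction, report the (≤10)
  significant features with the highest PR; otherwise fall back to the
  highest-PR nonsignificant ones (their nonsignificance remains visible in
  the output).
* Kruskal–Wallis uses midranks with the standard tie correction; the rank
  effect size is η² = (H−k+1)/(N−k). Dunn's z statistics use the pooled-rank
  variance with tie correction and BH adjustment over the k(k−1)/2 pairs.

## Topic terms

Class-based TF-IDF over per-cluster aggregated term counts:
`W(t,c) = (count(t,c)/tokens_in_c) · log(1 + A/f_t)` with `A` the mean token
count per cluster and `f_t` the term's total count — the canonical
class-based formulation. Unigrams only, lowercased, English stop words
removed, and terms in more than 80% of notes dropped (both configurable).
The score is invariant under duplicating every document. Embedding-based
keyword re-ranking and LLM theme naming are out of scope; outputs are raw
ranked term lists with term prevalence ratios.

## Synthetic cohort

The generator emulates the study conditions the pipeline expects:

* **Codes.** Each subtype has a Dirichlet code profile (concentration 1.0,
  with a contiguous marker block boosted ×10); a patient draws a
  Poisson(30)-sized multinomial from their subtype's profile, plus 1–2
  condition-of-interest codes so the exclusion path is always exercised.
  Empirical per-subtype code marginals converge to the planted profile
  (tested in L1 at ~10⁴ draws).
* **Code embeddings.** Isotropic Gaussian base (scale 1/√d) plus
  `subtype_separation` times a subtype-specific orthonormal direction on
  that subtype's marker codes, so count-weighted sums separate by subtype.
* **Notes.** Token columns are subtype mean + provider offset + unit
  isotropic noise; the provider offset is an additive vector in
  token-embedding space (magnitude `provider_shift_scale`), *before*
  reduction — so the batch effect must survive dimensionality reduction, as
  a real provider effect would. Attention rows are softmaxes of Gaussian
  logits at a per-row temperature drawn log-uniformly in [0.05, 5], giving
  the heterogeneous row-entropy spread the weighting scheme needs.
* **Demographics.** Sex is Bernoulli per subtype, age of onset Gaussian per
  subtype (defaults 73.6/69.8/75.5 ± 9.1/9.6/8.1 years — one early-onset and
  one late-onset subtype), diagnosis categories a tilted categorical.
* Truth labels are written only to a separate `truth.csv`, never into any
  pipeline input, so leakage into an analysis is structurally impossible.

Default sizes (300 patients, 3 subtypes, 120 codes, 1–2 chunks of 12–32
tokens, 4 providers) keep a full two-arm run in seconds while leaving every
statistic well-conditioned; the token dimension defaults to 768 to match
transformer output but tests and the acceptance script use 64, which changes
nothing structurally. What the generator does *not* emulate: realistic
clinical text, longitudinal visit dynamics, missing data, or correlated
code co-occurrence beyond the Dirichlet profiles — so passing tests
demonstrate the pipeline's mechanics and its ability to undo an additive
batch effect, not performance on real EHR data.

## Known limitations

* The entropy-weighting direction (up-weighting diffuse attention) is
  implemented as specified by the estimator-softmax composition; whether the
  opposite direction would pool better is an open empirical question the
  package does not answer.
* Barycentric projection contracts each provider cloud toward the reference
  cloud's interior; with very unequal cloud sizes this shrinks within-
  provider variance.
* The exact transport LP scales as an LP with n·m variables; it is intended
  for per-provider clouds of up to a few thousand points, not for
  million-point alignment.
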