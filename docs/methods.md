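# Methods

This note documents the model, its parameters and defaults, the synthetic
data the package is validated on, numerical choices, and the design decisions
taken where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Model and assumptions

The classifier operates entirely on **intrasample ranks**: within each sample
(column), genes are ranked ascending, ties receiving the mean of the spanned
positions so that every column sums to n(n+1)/2. The working assumption is
that subtype identity is encoded in the *relative ordering* of informative
gene pairs within a sample, and that cross-cohort technical variation acts
(to first order) as a strictly increasing per-sample transformation of
expression — which cannot change any rank. Gene-level batch effects that
re-order genes *within* samples are not removed by construction; robustness
to them comes from aggregating many pair indicators per subtype and from
screening pairs with large rank margins.

A fitted model is, per subtype, a list of **oriented gene pairs** (hi, lo)
meaning "rank(hi) > rank(lo) votes for this subtype". A sample's subtype
score is the mean of these binary votes, in [0, 1]; prediction is argmax with
deterministic tie-breaking by the model's fixed subtype order (tie flagged).
Scores are mean indicators, not calibrated probabilities.

At prediction time ranks are recomputed **within the model's gene universe**
(the union of genes appearing in retained pairs). This makes prediction
independent of the input platform's full gene complement; the alternative
(ranking within all supplied genes) is available as `rank_mode="full"` for
sensitivity analysis. Pairs touching genes absent from the input are skipped
when they are at most 5% of a subtype's features (configurable); beyond that
the input is rejected as incompatible rather than silently imputed.

## Training pipeline and parameters

| stage | parameter | default | meaning |
|---|---|---|---|
| differential ranking | `rank_frac` | 0.11 | rank-difference cutoff as a fraction of the gene count; the absolute cutoff is round(rank_frac·n) so the operating point transfers across platforms |
| | `diff_alpha` | 0.05 | two-sided t-test level (Welch by default; pooled variance by flag). No multiplicity correction is applied at this screen — it is a filter, not an inference |
| reversal screen | thresholds | 0.95 / 0.90 / 0.85 / 0.80 | minimum reversal ratio per ordered comparison (see README); ≥ comparison (inclusive) so the stated values are attainable exactly; strict mode by flag |
| | `screen_alpha` | 0.05 | Fisher exact level, two-sided by the point-probability rule; no FDR correction over the pair tests |
| elastic net | `alpha` | 0.1 | L1/L2 mixing; near-ridge keeps groups of correlated pairs together |
| | `n_folds` | 10 | stratified CV folds; degrades to the minority-class size with a warning when a class is smaller |
| | `lambda_rule` | `lambda_1se` | largest λ whose mean CV binomial deviance is within one SE of the minimum; `lambda_min` by flag; misclassification loss by flag |
| | path | 100 λ, 4 decades | log-spaced from the analytic λ_max (all-zero model) downward; binary features are not re-standardized |

Signature genes for subtype S are the union of (∩ up-genes over S's three
comparisons) and (∩ down-genes over the same three); candidate pairs are
drawn only from S's signature genes. A pair must pass **all three**
comparisons with a consistent orientation; pairs whose passing orientation
conflicts across comparisons are discarded. Both orientations are evaluated
because the subtype-characteristic direction of a pair is not known a priori.

Each of the 12 elastic-net runs (subtype × other subtype) restricts samples
to the two compared subtypes; a subtype's final features are the
intersection of its three selected sets. The stored coefficient is the mean
of a feature's nonzero coefficients across the runs that selected it —
reported for inspection only, since scoring uses unweighted mean indicators.

## Numerical choices

- **Fisher exact test**: vectorised over tables grouped by their margin
  triple; the two-sided mass sums hypergeometric point probabilities
  ≤ p_obs·(1+1e−7), the standard relative gate that absorbs floating-point
  noise in exact ties. Verified against exact-rational enumeration (max
  abs deviation is recomputed by the acceptance script) and against
  `scipy.stats.fisher_exact`.
- **Elastic-net path solver**: IRLS + cyclic coordinate descent with
  soft-thresholding (exact zeros), warm-started down the λ path, jitted with
  numba; convergence at max coefficient change < 1e−6 (weights floored at
  1e−5). Verified against `glmnet` in R at fixed λ values (agreement ~1e−8).
  The solver is fully deterministic; the only randomness in training is the
  seeded, stratified CV fold assignment, so a fixed seed makes `fit`
  byte-reproducible.
- **Per-run seeds** are derived from the user seed and the run tag (subtype
  pair, fold) by a CRC-based mix, kept below 2³¹.
- **Degenerate inputs**: zero-variance vectors in z-scoring become all-zeros
  with a warning (z-scoring per sample is rank-preserving and hence optional
  for this method); constant indicator columns are excluded from selection
  outright (their penalized optimum is exactly 0); zero-denominator metrics
  are reported as NaN ("undefined") with a warning, never silently as 0;
  ties in ranks fall in the ≤ branch of the pair indicator (a tied pair votes
  for neither orientation).
- **AUC** uses the midrank (Mann–Whitney) formulation on the subtype's
  continuous score; per-subtype "accuracy" is one-vs-rest (TP+TN)/total,
  the convention consistent with the other one-vs-rest metrics.
- **t-SNE** embedding is a thin seeded wrapper (PCA initialisation); its
  perplexity (default 30) is documented, not inferred from any reference.

## Synthetic cohorts: what they emulate and what they do not

The generator emulates a multi-cohort subtyping study:

- **Composition**: 4 subtypes at proportions 223:70:144:326 (a realistic,
  strongly unbalanced training composition with the rarest class ~9%);
  default 240 samples in 3 equal batches, class-stratified within batch.
- **Baseline**: per-gene lognormal expression; between-gene log-scale sd 2.0
  (typical spread of log microarray intensities / log-TPM), within-gene
  noise sd 0.3.
- **Markers**: 40 per subtype (half up, half down), disjoint across
  subtypes, drawn from the central rank band. Shifts are calibrated **on the
  rank scale**: an up-marker's baseline mean is raised to the value
  `marker_shift`·n positions higher in the sorted baseline (default 0.2), so
  the intended mean rank displacement is a fixed fraction of the gene count
  at any n.
- **Batch effects, two layers**: a per-batch strictly increasing warp of the
  positive expression scale (identity / affine gain+offset / power /
  log1p) — rank-preserving, so provably invisible to the method but ruinous
  for absolute-expression classifiers — plus per-(gene, batch) additive log-
  scale shifts (sd 0.4), which genuinely perturb ranks. The second layer is
  deliberate: without it, held-out evaluation of a rank-pair classifier
  would be trivially equivalent to in-batch evaluation.

Passing tests on these cohorts demonstrate: recovery of planted structure at
the stated screen operating points, exact rank-invariance to sample-level
distortions, and robustness of held-out assignment to moderate gene-level
batch noise. They do **not** demonstrate performance on real tumor cohorts:
the generator has no correlated gene modules, no platform-specific probe
behavior, no RNA-seq count noise, no mislabelled training samples, and its
subtype boundaries are cleaner than the molecular continuum between the two
numerically designated subgroups in real data.

Problem sizes in the test suite and acceptance script (2000 genes, 240
samples, 5 replicates) are the package's chosen desk-scale study; stage
counts scale with the signature sizes, and the pair-combinatorics checks use
the published signature sizes directly.

## Open design points, resolved

- The source normalisation recipe ("x − x̄ / s over columns") is ambiguous in
  orientation; per-sample z-scoring is the default reading (GEO series
  matrices are samples-in-columns) and is provably a no-op for ranks, so the
  ambiguity is immaterial to the method; per-gene is offered for parity
  experiments.
- Whether the 12 selection runs should use all samples with one-vs-one
  labels or only the two compared subtypes is unstated in the source
  description; the two-subtype restriction is implemented, mirroring the
  screening comparisons.
- Whether the reversal screen intersects comparisons before or after
  orientation bookkeeping is unstated; requiring a single consistent
  orientation across all three comparisons is the only self-consistent
  choice and is what is implemented.
- The printed formula for the pair-association p-value contains a repeated
  term that does not define a probability; the surrounding text describes
  Fisher's exact test, which is what is implemented. Likewise a stated
  retention rule of "p > 0.05" contradicts the stated 0.05 threshold two
  sentences earlier; significant association (p < α) is implemented.
- Sparse-selection sanity checks run the selector at a lasso-leaning mixing
  value (α = 0.9): at the near-ridge default α = 0.1 the 1-SE solution is
  intentionally non-sparse under separation — the reference R implementation
  behaves identically — so "noise features excluded" is a property of the
  sparse regime, not of α = 0.1.

## Known limitations

- Screening cost grows quadratically in signature-set size; pair iteration
  is chunked (identical output to full enumeration) but very large signature
  sets will dominate runtime, consistent with the method's known cost
  profile (~10⁵–10⁶ Fisher tests at full scale).
- With near-separable training data the 1-SE rule can retain every screened
  pair (CV deviance decreases monotonically along the path); refinement then
  prunes nothing. This is faithful reference behavior, not a defect, but
  users expecting aggressive pruning should consider `lambda_min` plus a
  larger α.
- Scores of subtypes with few retained pairs are coarse (multiples of 1/m);
  ties are possible and are flagged rather than hidden.
- An all-identical expression column yields all-tied ranks and zero
  indicators everywhere; such degenerate samples score 0 for every subtype
  and are assigned by tie-break with the flag set.
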