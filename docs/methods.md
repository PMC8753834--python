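# Methods

## Model and assumptions

`histosig` treats a bulk lung-adenocarcinoma expression profile as a
mixture of histologic growth-pattern components and estimates the relative
abundance of the lepidic and solid components with a rank-based,
single-sample enrichment statistic. The approach assumes:

- expression is on a roughly continuous log-like scale (log microarray
  intensity or log TPM); the statistic uses ranks plus |e| weighting, so
  monotone transformations of scale matter only mildly;
- a subtype-labeled training cohort (e.g. microdissected, pattern-pure
  samples) is available to derive the signatures;
- subtype identity expresses itself as many moderately shifted genes
  rather than a few switch-like markers — the signature is deliberately
  *weighted* and genome-wide rather than a thresholded gene list.

### Signature construction

One-vs-rest differential expression per subtype gives per-gene (t, p).
Weights are `w± = min(-log p, c)/c` gated by the sign of t, with trim cap
`c = 10`. Choices made where the construction was genuinely open:

- **Log base**: natural log (default). With c = 10 the weight saturates at
  p ≈ 4.5e-5, a plausible saturation point for a 48-sample design; a
  `log_base="10"` switch is provided (saturation at p = 1e-10).
- **Rescaling to [0, 1]**: division by the cap (default), which makes
  weights comparable across signatures and cohorts; per-vector min-max is
  available as `rescale="minmax"`.
- **t-test flavor**: pooled-variance Student's test by default, Welch as
  an option; with ~10 vs ~38 samples and planted unit variances the two
  are nearly identical on the synthetic cohorts.
- **Degenerate genes** (zero variance in both groups) get t = 0, p = 1 —
  weight 0 — instead of being dropped, keeping the signature aligned with
  the matrix. A gene constant within each group but differing between
  groups receives a saturated weight (t clipped to a large finite value,
  p to the smallest positive double).
- **"Most specific" ranking** for the merged top-k panel: ascending p,
  ties broken by descending |t| then lexicographic gene id —
  deterministic across platforms.

### Single-sample scoring

Genes present in both the sample and the signature are sorted by
decreasing expression (ties broken lexicographically by gene id). The
foreground/background cumulative curves

    f(i) = Σ_{k≤i} |e_k w_k| / Σ_k |e_k w_k|
    b(i) = Σ_{k≤i} |e_k (1−w_k)| / Σ_k |e_k (1−w_k)|

are compared; the raw score is the signed deviation f − b at the index of
maximum absolute deviation (smallest index on ties) — the weighted
Kolmogorov–Smirnov convention. Numerical notes:

- Negative expression values (two-channel log ratios) are permitted:
  ranking uses signed e, the curves use |e|.
- The raw score is normalized as `(ES − mean_null)/sd_null` against a null
  of uniformly random gene-to-weight permutations with e held fixed
  (default `n_perm = 1000`, minimum 100; sd with ddof = 1). What to
  permute and how to normalize are configuration-level decisions; gene-label
  permutation with a z-transform is the package's choice.
- A null spread at float-rounding scale (≤ 1e-12; e.g. constant weights,
  where f and b cancel identically) is reported as degenerate with score 0
  rather than divided through.
- S⁺ and S⁻ for one sample use the *same* permutation index sequence, so
  S = S⁺ − S⁻ is not inflated by independent Monte-Carlo noise and
  swapping w+ with w− negates S exactly (bit-level, not just in
  distribution).
- A one-sided profile (all w− = 0, as in marker-gene immune profiles)
  scores its silent component as 0 rather than erroring.
- Samples must contain ≥ 50 % of the signature's genes (warning below
  80 %); per-sample RNG seeds derive from the base seed and a CRC32 of the
  sample id, making cohort scoring reproducible and invariant to column
  order.
- Permutation ES values are computed in vectorized chunks capped at
  2.5 M matrix cells, bounding memory at a few hundred MB regardless of
  signature size.

### Downstream analyses

- **Dichotomization**: high = score strictly above the cutoff (median or
  0); ties go low — deterministic and conservative for "high-score"
  claims.
- **Wilcoxon rank-sum**: exact enumeration when the smaller group has
  ≤ 10 observations and there are no ties, otherwise the normal
  approximation with tie and continuity correction.
- **Genomic features**: filtered to ≥ 20 altered samples before testing;
  flagged at unadjusted p < 0.01 by default (BH-adjusted flagging is an
  option, off by default, mirroring common practice for this screen).
- **Cox regression** (lifelines): Wald CIs and p-values; a warning is
  issued below 10 events per covariate. Stage and sex enter the
  multivariate model as binary covariates.
- **AUC**: probability that a random responder outscores a random
  non-responder with ties counting ½, identical to U/(n₁n₂).

## Synthetic data: what it emulates, and what it does not

The pure-cohort generator emulates a microdissected training design: five
subtypes with 10/10/10/9/9 samples, 10,000 genes, 500 planted genes per
subtype (half up, half down) shifted by 1.5 within-group SD on unit
Gaussian noise. The admixed generator draws per-sample subtype fractions
from Dirichlet(1, …, 1) and emits the fraction-weighted mixture of subtype
mean profiles plus noise. Outcome generators condition on the latent
lepidic fraction: exponential survival with log-hazard linear in the
(standardized) fraction and independent uniform censoring; Bernoulli
genomic features with log-odds linear in (1 − fraction); Gaussian drug
sensitivity linear in fraction; Bernoulli response with logit linear in
the standardized fraction, with the slope for a target population AUC
solved by quadrature rather than empirical tuning.

Not emulated: probe-level artifacts, batch/platform effects, count noise
(a log-normal surrogate stands in for RNA-seq), correlated gene modules,
and admixture of more than the five canonical patterns. Passing the
recovery tests therefore demonstrates correctness of the statistics and
the pipeline's ability to recover planted structure — not clinical
performance on real cohorts, where effect sizes, gene–gene correlation and
annotation noise differ.

## Problem sizes in the test and acceptance runs

Signature-recovery checks run at the full reference design (48 samples ×
10,000 genes). End-to-end fraction recovery uses a 2,000-gene /
300-planted-per-subtype rendition of the same generator with n = 100
admixed samples at n_perm = 1000 — chosen as the package's standard
desk-scale configuration; at the full 10,000-gene design the recovered
correlations are indistinguishable (≈ 0.91–0.95 Spearman in both cases)
because admixture noise, not signature size, is limiting. Survival,
feature-calibration and AUC checks use n = 200–300 samples and 10,000
null features.

## Known limitations

- Planted-gene recall at the reference design is power-limited: with
  10 vs 38 samples and 1.5 SD effects, the noncentrality is ≈ 4.2 while
  the BH threshold at FDR < 0.01 over 10,000 genes sits near t ≈ 3.8
  (df 46), so per-gene power — hence recall — is ≈ 0.65 even though
  precision is ≈ 0.99. Larger effects or cohorts are required for ≥ 0.9
  recall; the acceptance run reports the honest value.
- Scores are relative (z-like against a per-sample permutation null), not
  calibrated fractions; comparing absolute score levels across platforms
  requires a common signature and comparable gene coverage.
- The permutation null treats genes as exchangeable; strong co-expression
  among signature genes makes the null anti-conservative.
- The scoring loop is per-sample vectorized but cohort-serial; very large
  cohorts (10⁴ samples at 10⁴ genes, n_perm 10³) are out of scope.
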