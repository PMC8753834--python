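# histosig

Weighted gene-signature scoring of histologic growth-pattern components in
lung adenocarcinoma expression profiles.

Early-stage lung adenocarcinomas are graded by their histological growth
patterns — lepidic (low grade), acinar, papillary, micropapillary and
solid (high grade) — but most tumors are mixtures of several patterns, and
pathologist percentage calls are semi-quantitative and slide-limited.
`histosig` quantifies the *lepidic* and *solid* components of a tumor
directly from its bulk (or pseudobulk) expression profile: an **L-score**
and an **S-score** per sample, usable for prognosis, genomic-feature
association, drug-sensitivity correlation and immunotherapy-response
analysis. The same scoring engine accepts any externally derived weight
profile, e.g. immune-cell marker profiles for infiltration estimates.

## Method

**Signature construction.** From a subtype-labeled training cohort, each
gene is tested one-vs-rest with a two-sample t-test (Student's by default),
giving per-gene vectors {t} and {p}. A pair of weight vectors encodes
up- and down-regulation specificity:

```
w+_k = min(-ln p_k, c) / c   if t_k > 0, else 0
w-_k = min(-ln p_k, c) / c   if t_k < 0, else 0
```

with trim cap c = 10 (weights saturate at p ≈ 4.5·10⁻⁵). The pair
(w+, w−) is the weighted signature for the subtype.

**Single-sample scoring.** For one sample, genes are sorted by decreasing
expression into e = (e₁, …, eₙ) and a foreground cumulative curve is
compared with a background curve:

```
f(i) = Σ_{k≤i} |e_k w_k| / Σ_k |e_k w_k|
b(i) = Σ_{k≤i} |e_k (1-w_k)| / Σ_k |e_k (1-w_k)|
```

The raw enrichment score is the signed value of f − b at the index of
maximum |f − b| (a weighted Kolmogorov–Smirnov statistic in the GSEA
family). It is z-normalized against a null distribution obtained by
permuting the gene-to-weight assignment (default 1000 permutations), giving
S⁺ from w+ and S⁻ from w−, and the final score **S = S⁺ − S⁻**. Both
components share one permutation sequence, so exchanging w+ and w− negates
S exactly. Higher L-/S-scores mean a larger lepidic/solid component.

**Downstream analyses.** Median (or zero) dichotomization with log-rank
tests, univariate/multivariate Cox proportional-hazards regression, binary
genomic-feature association (Wilcoxon rank-sum with a minimum-recurrence
filter, default ≥ 20 altered samples, p < 0.01), Spearman correlation with
drug sensitivity (−ln(IC50 + 1) scale), and responder classification
(ROC/AUC). A synthetic-data module generates subtype-labeled and latently
admixed cohorts with planted marker genes plus matched survival, genomic,
drug and response outcomes, so the whole pipeline is testable offline.

## Worked example

Fit signatures on a simulated subtype-pure cohort, then score five admixed
tumors:

```python
import histosig as hs
from histosig import simulate as sim

x, labels, truth = sim.generate_pure_cohort(n_genes=2000, n_planted_per_subtype=300, seed=42)
builder = hs.SubtypeSignatureBuilder(subtypes=["lepidic", "solid"]).fit(x.T, labels)

xa, at = sim.generate_admixed_cohort(n_samples=5, truth=truth, seed=43)
scorer = hs.EnrichmentScorer(builder.signatures_, n_perm=1000, random_state=7).fit(xa.T)
scores = scorer.transform(xa.T)
scores["true_lepidic_fraction"] = at.fractions["lepidic"]
print(scores.round(2))
```

prints

```
           lepidic  solid  true_lepidic_fraction
sample_id
T0000        -3.42  -2.55                   0.02
T0001        -2.44   6.45                   0.03
T0002        -1.72   7.80                   0.10
T0003         1.68  -2.51                   0.17
T0004         2.07  -2.53                   0.20
```

The `lepidic` column is the L-score (z-like units against the permutation
null): it increases with the latent lepidic fraction, and the two
near-pure solid tumors (T0001, T0002) stand out with S-scores above 6.
On a 100-sample admixed cohort the Spearman correlation between L-score
and the latent lepidic fraction exceeds 0.9.

The same workflow is available from the shell:

```
histosig simulate pure --out-dir sim --seed 2
histosig build-signature --expression sim/expression.tsv --annotation sim/annotation.tsv --out-dir sig
histosig score --expression sim/expression.tsv --signature sig/signature_lepidic.tsv \
    --n-perm 1000 --seed 17 --out scores.tsv
histosig report --config run.yaml        # score + survival/feature/drug/response report
```

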