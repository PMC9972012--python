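# Methods

This note documents the models and procedures implemented in
`sting_sclc`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Expression handling

Expression matrices are genes × samples with a value-scale tag:
`linear` (FPKM or normalized intensities, non-negative) or `log2p1`
(already log2(x+1)-transformed). Loading uppercases gene symbols and
collapses duplicate rows to the row with maximal mean expression — the
standard deterministic probeset-collapse rule. Missing values are
rejected at load time because every downstream rank and correlation
assumes complete vectors.

Gene filtering removes genes whose value is 0 in **strictly more than**
75% of samples (`zero_fraction = 0.75`; the boundary case, exactly 75%,
is kept). The same rule prunes a working signature after restriction.
The log transform is log2(x+1) and refuses to run twice.

Batch handling: an optional per-batch median-centering hook is provided
and off by default. It is a lightweight exploratory device, not a
fitted batch-effect model; co-clustering of separately normalized
cohorts should be interpreted cautiously.

## ssGSEA

Per sample, genes are ordered by decreasing expression (ties broken by
descending input position, for bit-reproducibility). Walking the
ordered list, the in-set cumulative distribution weighted by
rank^τ (rank N for the top gene, 1 for the bottom) is compared with the
uniform out-of-set cumulative distribution, and the score is the
**sum over all ranks** of the difference — the single-sample area
convention, not classic GSEA's maximum deviation. τ defaults to 0.25,
the conventional single-sample weighting; τ = 0 reduces to an
unweighted KS-type running sum. Because the statistic depends on ranks
only, it is invariant to any strictly monotone transform of a sample's
expression vector (property-tested).

With `normalize=True` (default) each set's scores are divided by their
(max − min) across exactly the samples scored in that call: scores are
cohort-relative and not comparable across separately scored cohorts. A
single sample cannot be range-normalized and must be scored with
`normalize=False`.

## NE score

`NE = (corr(sample, NE profile) − corr(sample, non-NE profile)) / 2`
with Pearson correlations over the shared signature genes, hence
bounded in [−1, +1]; positive predicts neuroendocrine differentiation.
The reference is an *averaged* profile per class (mean over reference
cell lines of each phenotype) supplied as data; the package's bundled
reference is synthetic. At least `min_overlap = 10` of the 50 signature
genes must be present (Pearson stability); constant subvectors are
errors. Swapping the two reference profiles negates the score exactly.

## Subtyping

Samples are clustered agglomeratively on the STING-signature
submatrix. Both supported distances act on **gene-wise z-scored**
profiles (population SD, divisor n, for determinism) — the row-scaling
convention of expression heatmaps:

- `euclidean_z` + Ward linkage (**default**),
- `correlation` (1 − Pearson between z-scored sample profiles) +
  average linkage.

The default was chosen for an identifiability reason: a pathway
signature whose member genes move *concordantly* between subtypes
produces, along the gene axis, a nearly constant offset between
samples. Pearson's per-profile centering removes exactly that
component, so sample-correlation distance is close to blind to overall
signature activity and clusters mostly noise in this regime; Euclidean
distance on z-scored genes sees the level shift directly. Correlation
distance remains appropriate, and is provided, for signatures with
genuinely bidirectional patterns.

The tree is cut at exactly k clusters (k = 3 default, configurable; no
automatic model selection). Clusters are named by mean gene-wise
z-scored signature expression, descending: STING-high, -intermediate,
-low (for k ≠ 3, `cluster-rank-i`). This naming rule is an explicit
convention of the package. Ties within 1e-12 break toward the smaller
cluster id with a warning. New samples are classified to the nearest
cluster centroid in the training cohort's z-space under the clustering
distance, requiring coverage of at least half the working signature.
Partition agreement is summarized by a contingency table and the
adjusted Rand index.

## Preranked GSEA

The ranked list orders genes by a differential-expression metric
(log2FC, or sign(log2FC)·−log10 p), descending, ties broken
lexicographically. The enrichment score is the classic weighted-KS
statistic (hit increment |metric|^weight normalized over in-set genes,
weight = 1 default; miss decrement 1/(N − N_set)); ES is the signed
maximum deviation. If every in-set metric is exactly zero the hit
weights fall back to equal, keeping the statistic defined.

The null is built by **gene-set permutation** — redrawing random sets
of equal size from the ranked list — which is the standard choice when
the input is a preranked list (phenotype permutation needs the
per-sample matrix). NES divides ES by the mean |null ES| of matching
sign; the nominal p is the one-sided Monte-Carlo rate with a +1
pseudo-count so p is never 0 and is valid at any permutation count
(minimum enforced: 100). Each set in a panel receives its own seed
derived from the panel seed and the set's position, making panel
results order-stable and reproducible. BH adjustment is applied across
the panel.

## Differential expression

Counts are first library-size normalized by median-of-ratios (the
reference is the geometric mean across samples of each all-positive
gene). Fold change is log2((mean_A + c)/(mean_B + c)) with pseudocount
c = 1 by default (avoids division by zero on counts).

The default test is a **moderated two-sample t** on log2(x+1) values:
per-gene pooled variances (df = n_A + n_B − 2) are shrunk toward a
prior variance with prior df fitted across genes by the standard
empirical-Bayes moment equations on log s²; the statistic is referred
to t with the summed df. The moderation matters at the study's sample
sizes — with 4 vs 4 samples an unmoderated Welch test has as few as ~3
effective df, which floors its attainable p-values above the BH cutoff
in a several-thousand-gene screen regardless of effect size. Plain
Welch (`welch_on_log`) and externally supplied per-gene p-values
(`external`, e.g. from an NB-GLM engine) plug into the same contract.

DEG calling applies the strict rule: up = {log2FC > 1 and BH q <
0.05}, down symmetric; both inequalities strict, boundary-tested.
Swapping the groups negates every fold change and swaps the up/down
sets exactly.

## Somatic variant cascade and frequencies

Filters run in a fixed order so per-step drop counts are well-defined:
(1) VAF strictly below 0.1 (VAF = 0.1 survives); (2) region class in
{intronic, UTR3, UTR5} — splicing and exonic pass; (3) present in the
1000 Genomes population database; (4) present in the matched normal
(germline). Conservation (input = survivors + Σ drops) and idempotence
are tested invariants.

A sample counts as mutated for a group (gene symbol or pathway tag
such as NOTCH/MMR/HRR/NER/BER/NHEJ/FA/TLS/CPF) if it carries ≥ 1
surviving matching variant; percentages are rounded half-up to one
decimal. Fisher tests are two-sided by hypergeometric
probability-mass ordering (the common exact convention; other
conventions — mid-p, SPSS variants — can differ in the third decimal).
A zero margin makes the test degenerate (p = 1, odds ratio undefined);
a zero cell triggers a 0.5 continuity shift for the odds ratio only,
with a warning.

## Synthetic-data generator

The generator defines the conditions every recovery test runs under.
All randomness flows from one seed through named substreams (cohort /
counts / variants), so outputs are bit-identical under a fixed seed.

**Cohort** (default 20 samples per subtype, 2,000 genes): background
genes are Gaussian on the log2 scale (mean 6, between-gene SD 1.5,
within-gene noise SD 1). The 62 STING-signature genes shift by
+Δ·SD in STING-high and −Δ·SD in STING-low (Δ = 2 by default),
modulated by per-gene effect weights ~ Gamma(4, 1/4) (mean 1, CV 0.5):
real pathway activation moves member genes by unequal amounts, and the
weights keep the *mean* shift at Δ while restoring that heterogeneity.
The 50 NE-signature genes are drawn to correlate with a synthetic NE
reference profile in STING-low samples and with the non-NE profile in
STING-high (coupling 0.9, via the exact Gaussian construction
x = c·z_ref + √(1−c²)·ε); intermediates couple to the average of the
two. The 29 ten-gene immune marker sets are elevated by 1 log2 unit in
STING-high; EMT is mildly elevated in STING-high and ferroptosis
mildly depressed in STING-low, matching the reported phenotype
directions. Values are clipped at 0 to stay on a log2(x+1) scale.

**Treatment counts** (4 vs 4, 2,000 genes): gamma-Poisson
(negative-binomial) counts with base means ~ LogNormal(log 100, 1),
sample-specific library factors ~ U(0.7, 1.3), and dispersion 0.05 —
the replicate-to-replicate variability regime of cell-line contrasts
(CV ≈ 22%), which is what this arm of the study emulates; patient
tumors would warrant ~0.1–0.3. A 50-gene ISG-like up-set and a 50-gene
adhesion-like down-set get a 4-fold planted change in the treated arm.

**Variants**: per sample and pathway tag, Bernoulli indicators with
subtype-specific rates. Defaults encode the reported pattern: NOTCH
0.304/0.294/0.143 (low/intermediate/high), MMR 0 in STING-low and 0.25
in STING-high, TP53/RB1 near-ubiquitous and subtype-independent. Real
events draw VAF ~ U(0.1, 0.6), exonic, database-negative. Ten decoy
records per filter step are spiked in, each violating exactly one step
and carrying its ground-truth drop step, so cascade tests can assert
per-step counts.

**What the generator does not emulate**: gene–gene correlation beyond
the planted modules, batch effects, outlier samples, heavy-tailed
expression, mixed or ambiguous subtypes, co-mutation structure, and
realistic gene identity (all simulated symbols carry a SIM marker; the
bundled signatures are size-matched stand-ins, not the published
lists). Passing recovery tests therefore demonstrates correctness of
the pipeline's computations under its stated model, not performance on
real cohorts.

## Numerical conventions

- Ranking ties: ssGSEA breaks expression ties by descending input
  position; preranked GSEA breaks metric ties lexicographically by
  symbol. Both are arbitrary but fixed, for reproducibility.
- z-scoring uses population SD (divisor n); zero-SD genes are left
  centered (SD treated as 1).
- Range normalization of ssGSEA scores errors on a single sample or a
  degenerate (zero-range) cohort rather than returning NaN.
- Monte-Carlo p-values carry a +1 pseudo-count; with no same-sign null
  scores the p is floored at 1/(1 + n_perm) with a warning.
- Percentages print half-up to one decimal (Decimal arithmetic, not
  banker's rounding).
- Analysis drivers use the default problem sizes above (60-sample
  cohort, 2,000-gene count matrices, 500–1,000 permutations), chosen
  so each driver completes in seconds while keeping every planted
  effect comfortably identifiable.

## Known limitations

- The ssGSEA normalization is cohort-relative; scores from different
  calls are not comparable.
- The moderated t assumes roughly exchangeable per-gene variances on
  the log scale; strongly heteroskedastic count data with many
  near-zero genes would warrant an NB-GLM engine supplied through the
  `external` contract.
- k is fixed by the caller; the package deliberately offers no
  consensus clustering or cluster-number selection.
- The Fisher odds-ratio continuity correction is reported, not
  inferential; confidence intervals are out of scope.
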