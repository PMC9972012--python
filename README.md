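# sting-sclc

Signature-based stratification of small-cell lung cancer (SCLC)
transcriptomes by STING-pathway activity, with the downstream scoring,
enrichment, differential-expression, and somatic-mutation analyses that
characterize the resulting subtypes.

SCLC is an aggressive neuroendocrine lung cancer that is mostly
immune-cold, yet a subset of tumors retains activity of the cGAS–STING
innate-immune axis and with it higher immune infiltration. This package
stratifies tumors on a STING-pathway gene signature into **STING-high /
STING-intermediate / STING-low** subtypes and quantifies what
distinguishes them: neuroendocrine differentiation, EMT, ferroptosis,
immune-infiltrate composition, pathway enrichment, treatment-induced
expression changes, and somatic mutation frequencies. Everything runs on
a bundled synthetic-cohort generator, so no controlled-access data are
needed; users with real cohorts supply their own expression TSV, GMT
gene sets, and variant tables through the same interfaces.

## What it computes

- **ssGSEA signature scores** — per sample, genes are ranked by
  decreasing expression and the score is the area between the
  rank\^τ-weighted in-set cumulative distribution and the uniform
  out-of-set one (τ = 0.25 by default):

      ES(sample, S) = Σ_i [ P_in(i) − P_out(i) ]

  Used for EMT (200 genes), ferroptosis (45 genes) and 29
  immune-infiltrate marker sets.
- **NE score** — the correlation contrast against paired
  neuroendocrine / non-neuroendocrine reference profiles,
  `NE = (corr_NE − corr_nonNE) / 2 ∈ [−1, +1]`; positive means
  neuroendocrine.
- **Subtyping** — agglomerative clustering of samples on the 62-gene
  STING signature (Ward on gene-wise z-scored profiles by default), cut
  at k = 3 and named by mean signature activity.
- **Preranked GSEA** — weighted-KS enrichment score, gene-set
  permutation NES (`NES = ES / mean |null ES| of matching sign`), and
  Benjamini–Hochberg q-values.
- **Differential expression** — median-of-ratios normalization,
  moderated t (empirical-Bayes variance shrinkage), and the strict DEG
  rule |log2FC| > 1 and BH q < 0.05.
- **Somatic filters** — the four-step cascade (VAF < 0.1; intronic/UTR;
  1000 Genomes; matched normal), per-subtype mutation frequencies, and
  2×2 Fisher exact tests.
- **IHC score** — staining intensity (0–3) × extent (0–4).

## Worked example

The numbered scripts under `analysis/` run the whole study on the
synthetic cohort (60 samples, three planted subtypes, signature shift
Δ = 2 SD, seed 0) and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_subtype_cohort.py
```

prints

```
           subtype  n  sting_signature_mean  mean_ne_score
        STING-high 20                 7.968         -0.401
STING-intermediate 20                 6.020         -0.008
         STING-low 20                 4.065          0.419

clustered 60 samples on 62 signature genes (k=3)
adjusted Rand index vs planted labels: 1.000
```

The signature mean falls by ~3.9 log2 units from STING-high to
STING-low (the planted 2·Δ·SD = 4), the NE score runs opposite to STING
activity (STING-low tumors are the most neuroendocrine), and clustering
recovers the planted subtypes exactly (ARI 1.0). Subsequent scripts
score the signature panels (`03`), run the subtype GSEA contrast (`04`),
call treatment DEGs — 100% of the planted 4-fold gene sets recovered at
n = 4 vs 4 (`05`) — and tabulate per-subtype mutation frequencies after
the filter cascade (`06`).

The same workflow is available as a CLI for file-based inputs:

```bash
sting-sclc simulate --seed 0 --out-dir fixtures/
sting-sclc pipeline --in-dir fixtures/ --out-dir out/
```

## Layout

- `src/sting_sclc/` — the library: `io` (matrices, GMT, filters),
  `scoring` (ssGSEA, NE, IHC), `subtyping`, `enrichment`, `diffexp`,
  `variants`, `simulate` (synthetic cohorts), `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property, and end-to-end suites with independent
  brute-force oracles for every rank/statistics primitive.
- `docs/methods.md` — models, parameter choices, and limitations.

The bundled gene signatures are clearly-marked synthetic stand-ins with
the published sizes (62/50/200/45 and 29 marker sets); supply real
published lists as GMT to analyze real cohorts.
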