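"""Single-sample signature scores.

Two scoring families coexist here:

* ssGSEA — a rank-based per-sample enrichment score. For each sample the
  genes are ordered by decreasing expression; walking down that order, an
  in-set cumulative distribution weighted by rank^tau is compared with the
  uniform out-of-set cumulative distribution and the score is the *area*
  (sum over all ranks) between the two, not the maximum deviation. This is
  the single-sample convention, as opposed to classic two-group GSEA.
  Scores are cohort-relative when range normalization is on: each set's
  scores are divided by (max - min) over exactly the samples scored in
  that call.

* NE score — a correlation contrast against paired neuroendocrine /
  non-neuroendocrine reference profiles:

      NE = (corr(sample, NE profile) - corr(sample, non-NE profile)) / 2

  with Pearson correlations, hence bounded in [-1, +1]; positive values
  indicate neuroendocrine differentiation.

The IHC score (staining intensity grade 0-3 times staining extent grade
0-4) also lives here as the tissue-level readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSetCollection

SSGSEA = "ssgsea"
NE_CORRELATION = "ne_correlation"


class ScoringError(ValueError):
    pass


@dataclass
class ScoreTable:
    """Samples x scores matrix with a method tag per score column."""

    values: pd.DataFrame                      # index: sample ids, columns: score names
    method_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ScoringError("ScoreTable must not contain missing entries")
        for col in self.values.columns:
            self.method_tags.setdefault(col, SSGSEA)

    def join(self, other: "ScoreTable") -> "ScoreTable":
        if not self.values.index.equals(other.values.index):
            raise ScoringError("sample sets differ between score tables")
        merged = pd.concat([self.values, other.values], axis=1)
        tags = {**self.method_tags, **other.method_tags}
        return ScoreTable(merged, tags)


@dataclass
class NEReference:
    """Mean expression of the NE signature genes in reference NE and non-NE lines."""

    gene_ids: list[str]
    ne_profile: np.ndarray
    nonne_profile: np.ndarray

    def __post_init__(self) -> None:
        self.ne_profile = np.asarray(self.ne_profile, dtype=float)
        self.nonne_profile = np.asarray(self.nonne_profile, dtype=float)
        n = len(self.gene_ids)
        if self.ne_profile.shape != (n,) or self.nonne_profile.shape != (n,):
            raise ScoringError("reference profiles must match gene_ids length")
        if np.std(self.ne_profile) == 0 or np.std(self.nonne_profile) == 0:
            raise ScoringError("reference profiles must have nonzero variance")

    def swapped(self) -> "NEReference":
        return NEReference(list(self.gene_ids), self.nonne_profile.copy(), self.ne_profile.copy())


def read_ne_reference(path) -> NEReference:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    genes = df["gene"].astype(str).str.upper().tolist()
    return NEReference(genes, df["ne"].to_numpy(float), df["non_ne"].to_numpy(float))


def write_ne_reference(ref: NEReference, path) -> None:
    pd.DataFrame(
        {"gene": ref.gene_ids, "ne": ref.ne_profile, "non_ne": ref.nonne_profile}
    ).to_csv(path, sep="\t", index=False)


def _rank_order(expr: np.ndarray) -> np.ndarray:
    """Indices of genes in decreasing expression; ties broken by decreasing input position."""
    idx = np.arange(len(expr))
    return np.lexsort((-idx, -expr))


def _ssgsea_sample(expr: np.ndarray, in_set: np.ndarray, tau: float) -> float:
    n = len(expr)
    n_in = int(in_set.sum())
    n_out = n - n_in
    order = _rank_order(expr)
    hits = in_set[order]
    # rank values N..1 down the ordered list; weight = rank^tau for in-set genes
    ranks = np.arange(n, 0, -1, dtype=float)
    w = np.where(hits, ranks**tau, 0.0)
    denom = w.sum()
    p_in = np.cumsum(w) / denom
    p_out = np.cumsum(np.where(hits, 0.0, 1.0)) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea_score(
    m: ExpressionMatrix,
    set_name: str,
    gs: GeneSetCollection,
    tau: float = 0.25,
    normalize: bool = True,
) -> ScoreTable:
    """ssGSEA score of one gene set for every sample of ``m``.

    With ``normalize`` the per-set scores are divided by their (max - min)
    across the scored samples, so values are comparable only within the
    cohort passed in this call; a single sample cannot be range-normalized.
    """
    if set_name not in gs:
        raise KeyError(f"gene set {set_name!r} not in collection")
    genes = m.values.index
    in_set = np.asarray(genes.isin(gs[set_name]))
    if not in_set.any():
        raise ScoringError(f"gene set {set_name!r} has no overlap with the matrix")
    if in_set.all():
        raise ScoringError(f"gene set {set_name!r} covers every matrix gene; score undefined")
    arr = m.values.to_numpy(float)
    raw = np.array([_ssgsea_sample(arr[:, j], in_set, tau) for j in range(arr.shape[1])])
    if normalize:
        if arr.shape[1] < 2:
            raise ScoringError("range normalization needs >=2 samples; use normalize=False")
        rng = raw.max() - raw.min()
        if rng == 0:
            raise ScoringError("all samples scored identically; range normalization undefined")
        raw = raw / rng
    return ScoreTable(
        pd.DataFrame({set_name: raw}, index=m.values.columns),
        {set_name: SSGSEA},
    )


def ne_score(sample: pd.Series, ref: NEReference, min_overlap: int = 10) -> float:
    """Correlation-contrast neuroendocrine score, bounded in [-1, +1]."""
    ref_genes = pd.Index([g.upper() for g in ref.gene_ids])
    sample = sample.copy()
    sample.index = sample.index.astype(str).str.upper()
    shared = ref_genes.intersection(sample.index)
    if len(shared) < min_overlap:
        raise ScoringError(
            f"only {len(shared)} genes shared with the NE reference; need >= {min_overlap}"
        )
    pos = {g: i for i, g in enumerate(ref_genes)}
    idx = [pos[g] for g in shared]
    x = sample.loc[shared].to_numpy(float)
    ne = ref.ne_profile[idx]
    nonne = ref.nonne_profile[idx]
    if np.std(x) == 0:
        raise ScoringError("sample subvector has zero variance; correlation undefined")
    if np.std(ne) == 0 or np.std(nonne) == 0:
        raise ScoringError("reference subvector has zero variance on the shared genes")
    r_ne = float(np.corrcoef(x, ne)[0, 1])
    r_nonne = float(np.corrcoef(x, nonne)[0, 1])
    return (r_ne - r_nonne) / 2.0


def score_panel(
    m: ExpressionMatrix,
    gs: GeneSetCollection,
    panel: list[str],
    ref: NEReference | None = None,
    tau: float = 0.25,
    normalize: bool = True,
    min_overlap: int = 10,
) -> ScoreTable:
    """ssGSEA-score every set in ``panel`` and append an NE column if a reference is given."""
    missing_report: dict[str, list[str]] = {}
    tables: list[ScoreTable] = []
    for name in panel:
        if name not in gs:
            raise KeyError(f"gene set {name!r} not in collection")
        missing_report[name] = [g for g in gs[name] if g not in set(m.values.index)]
        tables.append(ssgsea_score(m, name, gs, tau=tau, normalize=normalize))
    out = tables[0]
    for t in tables[1:]:
        out = out.join(t)
    if ref is not None:
        ne = pd.Series(
            [ne_score(m.values[s], ref, min_overlap=min_overlap) for s in m.values.columns],
            index=m.values.columns,
            name="NE",
        )
        out = out.join(ScoreTable(ne.to_frame(), {"NE": NE_CORRELATION}))
    out.missing_report = missing_report  # type: ignore[attr-defined]
    return out


def correlate_scores(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ScoringError("need two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ScoringError("constant vector; correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def ihc_score(intensity: int, extent: int) -> int:
    """Immunohistochemistry score: staining intensity (0-3) x staining extent (0-4)."""
    if intensity not in (0, 1, 2, 3):
        raise ValueError(f"intensity grade must be 0..3, got {intensity}")
    if extent not in (0, 1, 2, 3, 4):
        raise ValueError(f"extent grade must be 0..4, got {extent}")
    return intensity * extent


def write_score_table(t: ScoreTable, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        t.values.to_csv(fh, sep="\t", index_label="sample")
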