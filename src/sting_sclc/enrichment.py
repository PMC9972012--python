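"""Preranked gene-set enrichment: ES, permutation NES, and BH-adjusted significance.

The enrichment score is the classic weighted Kolmogorov-Smirnov running
sum: walking a list of genes ranked by a differential-expression metric,
the sum rises by |metric|^weight (normalized over in-set genes) at each
set member and falls by 1/(N - N_set) otherwise; ES is the signed maximum
deviation. Because the input is a preranked list, the null is built by
gene-set permutation — redrawing random sets of the same size from the
list — and

    NES = ES / mean(|null ES| of the same sign)
    p   = (1 + #{same-sign null |ES'| >= |ES|}) / (1 + #same-sign null)

The +1 pseudo-count makes the Monte-Carlo p valid (never exactly 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection


class EnrichmentError(ValueError):
    pass


@dataclass
class RankedList:
    """Genes ordered by a ranking metric, descending; ties by gene symbol."""

    gene_ids: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.gene_ids) != len(self.metric):
            raise EnrichmentError("one metric value per gene required")
        if not np.isfinite(self.metric).all():
            raise EnrichmentError("ranking metric must be finite")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise EnrichmentError("duplicate genes in ranked list")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p: float
    q: float | None
    n_perm: int
    seed: int
    n_hits: int


def rank_genes(de: pd.DataFrame, metric: str = "log2fc") -> RankedList:
    """Build a ranked list from a differential-expression table.

    ``metric`` is ``log2fc`` or ``signed_logp`` (sign(log2fc) * -log10(p)).
    Descending order; ties break lexicographically by gene symbol.
    """
    if len(de) == 0:
        raise EnrichmentError("empty differential-expression table")
    if de["gene"].duplicated().any():
        raise EnrichmentError("duplicate genes in DE table")
    if metric == "log2fc":
        vals = de["log2fc"].to_numpy(float)
    elif metric == "signed_logp":
        p = np.clip(de["p"].to_numpy(float), 1e-300, 1.0)
        vals = np.sign(de["log2fc"].to_numpy(float)) * (-np.log10(p))
    else:
        raise EnrichmentError(f"unknown ranking metric {metric!r}")
    if not np.isfinite(vals).all():
        raise EnrichmentError("non-finite ranking metric")
    df = pd.DataFrame({"gene": de["gene"].astype(str), "m": vals})
    df = df.sort_values(["m", "gene"], ascending=[False, True], kind="mergesort")
    return RankedList(df["gene"].tolist(), df["m"].to_numpy())


def enrichment_score(
    r: RankedList, set_genes, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted-KS enrichment score and the full running sum."""
    members = {str(g).upper() for g in set_genes}
    hits = np.array([g.upper() in members for g in r.gene_ids])
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise EnrichmentError("gene set has no overlap with the ranked list")
    if n_hits == len(r):
        raise EnrichmentError("gene set covers the whole ranked list; ES undefined")
    w = np.abs(r.metric) ** weight
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all in-set metrics are exactly 0: fall back to equal hit weights
        hit_w = hits.astype(float)
        denom = hit_w.sum()
    miss_step = 1.0 / (len(r) - n_hits)
    running = np.cumsum(hit_w / denom - np.where(hits, 0.0, miss_step))
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


def _null_es(r: RankedList, n_hits: int, n_perm: int, weight: float, rng) -> np.ndarray:
    """ES of ``n_perm`` random same-size gene sets, vectorized over permutations.

    Uses the fact that the running sum attains its extrema only adjacent
    to hit positions, so each permutation needs O(n_hits) work.
    """
    n = len(r)
    w = np.abs(r.metric) ** weight
    miss_step = 1.0 / (n - n_hits)
    # positions of each null set: rows of sorted draws without replacement
    pos = np.empty((n_perm, n_hits), dtype=np.int64)
    for i in range(n_perm):
        pos[i] = np.sort(rng.choice(n, size=n_hits, replace=False))
    hw = w[pos]                                     # (n_perm, n_hits)
    denom = hw.sum(axis=1, keepdims=True)
    zero = denom[:, 0] == 0
    if zero.any():
        hw[zero] = 1.0
        denom[zero] = n_hits
    H = np.cumsum(hw, axis=1) / denom               # cumulative hit mass after hit i
    i1 = np.arange(1, n_hits + 1)
    misses_before = pos + 1 - i1                    # misses up to and incl. position of hit i
    after = H - misses_before * miss_step           # running sum just after hit i
    before = after - hw / denom                     # running sum just before hit i
    cand = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(n_perm), idx]


def nes(
    r: RankedList,
    set_genes,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    set_name: str = "",
) -> EnrichmentResult:
    """Normalized enrichment score with a gene-set-permutation null."""
    if n_perm < 100:
        raise EnrichmentError("need n_perm >= 100 for a usable null")
    es, _ = enrichment_score(r, set_genes, weight=weight)
    members = {str(g).upper() for g in set_genes}
    n_hits = sum(g.upper() in members for g in r.gene_ids)
    rng = np.random.default_rng(seed)
    null = _null_es(r, n_hits, n_perm, weight, rng)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if len(same_sign) == 0:
        warnings.warn("no null scores share the observed sign; p floored at 1/(1+n_perm)")
        p = 1.0 / (1.0 + n_perm)
        nes_val = 0.0 if es == 0 else np.sign(es) * np.inf
    else:
        p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + len(same_sign))
        nes_val = es / np.mean(np.abs(same_sign))
    return EnrichmentResult(
        set_name=set_name, es=es, nes=float(nes_val), p=float(p), q=None,
        n_perm=n_perm, seed=seed, n_hits=n_hits,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (capped at 1, order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise EnrichmentError("p-values must be a non-empty 1-d vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise EnrichmentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gsea_panel(
    r: RankedList,
    gs: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Run preranked GSEA over every set of a collection; BH-adjust across sets.

    Each set gets its own deterministic seed derived from ``seed`` and the
    set's position, so results do not depend on dict iteration effects.
    """
    rows = []
    for i, name in enumerate(gs.names()):
        res = nes(r, gs[name], n_perm=n_perm, seed=seed + i, weight=weight, set_name=name)
        rows.append(res)
    df = pd.DataFrame(
        {
            "set": [x.set_name for x in rows],
            "es": [x.es for x in rows],
            "nes": [x.nes for x in rows],
            "p": [x.p for x in rows],
            "n_hits": [x.n_hits for x in rows],
        }
    )
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df
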