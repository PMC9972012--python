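"""Two-group differential expression and the study's DEG-calling rule.

The module's job is the thresholding rule — a gene is differentially
expressed when |log2 fold change| > 1 (strict) and its BH-adjusted
p-value is < 0.05 (strict) — plus a pluggable per-gene test on
log2(x+1) values. The default test is a moderated two-sample t: per-gene
pooled variances are shrunk toward a common prior fitted across genes by
the usual empirical-Bayes moment equations, which buys back the power a
plain per-gene test throws away at small n (the same idea the standard
NB/limma engines rely on). Welch's unmoderated t and externally supplied
per-gene p-values are available through the same contract.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats

from .enrichment import bh_adjust
from .io import LINEAR, ExpressionMatrix


class DiffExpError(ValueError):
    pass


def _check_groups(m: ExpressionMatrix, group_a: list[str], group_b: list[str]) -> None:
    if not group_a or not group_b:
        raise DiffExpError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise DiffExpError("groups overlap")
    missing = (set(group_a) | set(group_b)) - set(m.sample_ids)
    if missing:
        raise DiffExpError(f"unknown samples: {sorted(missing)[:5]}")


def size_factors(m: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios library-size factors (reference = geometric mean gene).

    Genes with a zero count in any sample are excluded from the reference,
    the usual convention for count data.
    """
    if m.scale != LINEAR:
        raise DiffExpError("size factors are defined on linear counts")
    vals = m.values
    pos = vals[(vals > 0).all(axis=1)]
    if len(pos) < 10:
        raise DiffExpError("too few all-positive genes to estimate size factors")
    log_gm = np.log(pos).mean(axis=1)
    sf = np.exp(np.log(pos).sub(log_gm, axis=0).median(axis=0))
    return sf.rename("size_factor")


def normalize_library(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample's counts by its median-of-ratios size factor."""
    sf = size_factors(m)
    return ExpressionMatrix(m.values.div(sf, axis=1), LINEAR, m.sample_meta)


def log2_fold_change(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2((mean_A + c) / (mean_B + c)) on linear-scale values."""
    _check_groups(m, group_a, group_b)
    if m.scale != LINEAR:
        raise DiffExpError("fold change is computed on linear counts/FPKM")
    mean_a = m.values[group_a].mean(axis=1)
    mean_b = m.values[group_b].mean(axis=1)
    if pseudocount == 0 and ((mean_a == 0) | (mean_b == 0)).any():
        raise DiffExpError("zero group mean with pseudocount 0")
    return np.log2((mean_a + pseudocount) / (mean_b + pseudocount)).rename("log2fc")


def _trigamma_inverse(y: float) -> float:
    # Newton iteration for trigamma^{-1}; y > 0
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _moderated_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided p-values from a pooled-variance t with EB variance shrinkage.

    Per-gene pooled variances s^2 (df d) are shrunk toward a prior s0^2
    with df d0, both fitted by the moment equations on log s^2 across
    genes; the moderated statistic is referenced to t with d + d0 df.
    """
    na, nb = a.shape[1], b.shape[1]
    d = na + nb - 2
    ss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / d
    ok = s2 > 0
    if ok.sum() < 10:
        raise DiffExpError("too few genes with positive variance to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    var_e = float(np.var(e, ddof=1)) - float(special.polygamma(1, d / 2.0))
    if var_e > 1e-8:
        d0 = 2.0 * _trigamma_inverse(var_e)
        s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_post = d + d0
    else:
        # variances are essentially exchangeable: use the common value
        s2_post = np.full_like(s2, float(np.exp(np.mean(e))))
        df_post = np.inf
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    t = (a.mean(axis=1) - b.mean(axis=1)) / se
    if np.isinf(df_post):
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df_post)


def two_group_test(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    method: str = "moderated",
    external_p: dict[str, float] | pd.Series | None = None,
) -> pd.Series:
    """Per-gene two-sided p-values on log2(x+1) values.

    ``method`` is ``moderated`` (EB-shrunk pooled-variance t, default),
    ``welch_on_log`` (plain Welch), or ``external`` (caller-supplied
    p-values keyed by gene).
    """
    _check_groups(m, group_a, group_b)
    if method == "external":
        if external_p is None:
            raise DiffExpError("method='external' requires external_p")
        p = pd.Series(external_p, dtype=float).reindex(m.gene_ids)
        if p.isna().any():
            missing = p.index[p.isna()].tolist()
            raise DiffExpError(f"external p-values missing for genes: {missing[:5]}")
        return p.rename("p")
    if method not in ("welch_on_log", "moderated"):
        raise DiffExpError(f"unknown method {method!r}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise DiffExpError("the t-tests need >=2 samples per group")
    vals = np.log2(m.values + 1.0) if m.scale == LINEAR else m.values
    a = vals[group_a].to_numpy(float)
    b = vals[group_b].to_numpy(float)
    if method == "moderated":
        p = _moderated_t(a, b)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = res.pvalue
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance genes: no evidence
    return pd.Series(p, index=m.gene_ids, name="p")


def differential_expression(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = 1.0,
    method: str = "moderated",
    external_p: dict[str, float] | pd.Series | None = None,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    normalize: bool = True,
) -> pd.DataFrame:
    """Full DE table: gene, log2fc, p, q (BH), significant flag.

    By default the counts are library-size normalized (median of ratios)
    first, so fold changes and tests compare composition, not depth.
    """
    if normalize and m.scale == LINEAR:
        m = normalize_library(m)
    lfc = log2_fold_change(m, group_a, group_b, pseudocount=pseudocount)
    p = two_group_test(m, group_a, group_b, method=method, external_p=external_p)
    q = bh_adjust(p.to_numpy())
    df = pd.DataFrame({"gene": m.gene_ids, "log2fc": lfc.to_numpy(), "p": p.to_numpy(), "q": q})
    df["significant"] = (df["log2fc"].abs() > lfc_threshold) & (df["q"] < q_threshold)
    return df


def call_degs(
    results: pd.DataFrame,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Up- and down-regulated gene sets under the strict |log2FC| and BH-q rule."""
    if len(results) == 0:
        return set(), set()
    if "q" not in results.columns:
        raise DiffExpError("results must carry BH-adjusted q-values")
    sig = results["q"] < q_threshold
    up = set(results.loc[sig & (results["log2fc"] > lfc_threshold), "gene"])
    down = set(results.loc[sig & (results["log2fc"] < -lfc_threshold), "gene"])
    return up, down
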