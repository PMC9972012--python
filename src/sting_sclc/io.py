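"""Expression-matrix and gene-set containers with the study's loading rules.

Expression values arrive either on a linear scale (FPKM, normalized
intensities) or already log2(x+1)-transformed; the container carries that
tag so downstream code can refuse double transforms. Loading uppercases
gene symbols, collapses duplicate gene rows to the row with maximal mean
expression (the usual probeset-collapse convention), and rejects missing
values outright, because every downstream rank and correlation assumes
complete vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LINEAR = "linear"
LOG2P1 = "log2p1"
_SCALES = (LINEAR, LOG2P1)


class ExpressionError(ValueError):
    """Raised for malformed or inconsistent expression data."""


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a value-scale tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol (uppercase, unique) with one
        column per sample.
    scale
        ``"linear"`` (non-negative FPKM/intensities) or ``"log2p1"``.
    sample_meta
        Optional per-sample annotations (cohort, batch, group label),
        indexed by sample id.
    """

    values: pd.DataFrame
    scale: str = LINEAR
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ExpressionError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ExpressionError("empty expression matrix")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicated gene ids after loading: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise ExpressionError("duplicated sample ids")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ExpressionError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise ExpressionError("expression values must be finite (no NA/inf)")
        if self.scale == LINEAR and (arr < 0).any():
            raise ExpressionError("linear-scale expression must be non-negative")
        if self.sample_meta is not None and not self.sample_meta.index.equals(self.values.columns):
            self.sample_meta = self.sample_meta.reindex(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        meta = None if self.sample_meta is None else self.sample_meta.loc[sample_ids]
        return ExpressionMatrix(self.values[sample_ids].copy(), self.scale, meta)


@dataclass
class GeneSetCollection:
    """Named gene-symbol sets (order-preserving, deduplicated)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            seen: list[str] = []
            for g in genes:
                g = str(g).upper()
                if g and g not in seen:
                    seen.append(g)
            if not seen:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = seen
        self.sets = clean

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


def read_expression_matrix(path, scale_hint: str = LINEAR) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene symbol, header of sample ids).

    Duplicate gene rows (e.g. multiple probesets mapping to one symbol) are
    collapsed to the row with maximal mean expression. Non-numeric or
    missing cells are an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ExpressionError(f"{path}: empty expression matrix")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ExpressionError(f"{path}: non-numeric cell at gene {row!r}, sample {col!r}")
    if df.isna().any().any():
        n = int(df.isna().sum().sum())
        raise ExpressionError(f"{path}: {n} missing values after load; complete matrices required")
    df.index = df.index.astype(str).str.upper()
    if df.index.duplicated().any():
        df = _collapse_duplicates(df)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, scale=scale_hint)


def _collapse_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    # keep, per symbol, the row with the largest mean expression; stable on ties
    means = df.mean(axis=1).to_numpy()
    order = np.arange(len(df))
    pick: dict[str, int] = {}
    for i, (sym, mu) in enumerate(zip(df.index, means)):
        j = pick.get(sym)
        if j is None or mu > means[j]:
            pick[sym] = i
    rows = sorted(pick.values(), key=lambda i: order[i])
    return df.iloc[rows]


def write_expression_matrix(m: ExpressionMatrix, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        m.values.to_csv(fh, sep="\t", index_label="gene")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB gene1 TAB gene2 ..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name, desc, *genes = fields
            sets[name] = genes
            descriptions[name] = desc
    if n_lines == 0:
        raise ValueError(f"{path}: empty GMT file")
    return GeneSetCollection(sets, descriptions)


def write_gmt(gs: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in gs.sets.items():
            desc = gs.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def filter_low_expressed(m: ExpressionMatrix, zero_fraction: float = 0.75) -> ExpressionMatrix:
    """Drop genes whose value is 0 in strictly more than ``zero_fraction`` of samples."""
    if not 0.0 <= zero_fraction <= 1.0:
        raise ValueError(f"zero_fraction must be in [0,1], got {zero_fraction}")
    if m.scale != LINEAR:
        raise ExpressionError("filter_low_expressed expects linear-scale values")
    frac_zero = (m.values == 0).mean(axis=1)
    keep = frac_zero <= zero_fraction  # "more than" is strict
    return ExpressionMatrix(m.values.loc[keep].copy(), m.scale, m.sample_meta)


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every value x by log2(x + 1); tags the matrix as log2p1."""
    if m.scale == LOG2P1:
        raise ExpressionError("matrix is already log2(x+1)-transformed")
    return ExpressionMatrix(np.log2(m.values + 1.0), LOG2P1, m.sample_meta)


@dataclass
class SignatureRestriction:
    """Result of restricting a matrix to a working signature."""

    matrix: ExpressionMatrix
    missing: list[str]          # signature symbols absent from the matrix
    dropped_low: list[str]      # present but zero in >75% of samples


def restrict_to_signature(
    m: ExpressionMatrix,
    set_name: str,
    gs: GeneSetCollection,
    zero_fraction: float = 0.75,
) -> SignatureRestriction:
    """Restrict ``m`` to the genes of one signature, in signature order.

    Signature genes absent from the matrix are reported as missing;
    present genes whose expression is 0 in strictly more than
    ``zero_fraction`` of the samples are dropped from the working
    signature (the same rule used to build the signature itself).
    """
    if set_name not in gs:
        raise KeyError(f"gene set {set_name!r} not in collection")
    signature = gs[set_name]
    have = set(m.values.index)
    present = [g for g in signature if g in have]
    missing = [g for g in signature if g not in have]
    sub = m.values.loc[present]
    frac_zero = (sub == 0).mean(axis=1)
    keep = [g for g in present if frac_zero[g] <= zero_fraction]
    dropped = [g for g in present if g not in set(keep)]
    if len(keep) < 2:
        raise ExpressionError(
            f"signature {set_name!r}: only {len(keep)} usable genes in matrix; need >=2"
        )
    return SignatureRestriction(
        ExpressionMatrix(m.values.loc[keep].copy(), m.scale, m.sample_meta),
        missing=missing,
        dropped_low=dropped,
    )


def median_center_batches(m: ExpressionMatrix, batch: pd.Series) -> ExpressionMatrix:
    """Optional per-batch median centering hook (off by default in the pipeline).

    Subtracts, per gene, the within-batch median. A lightweight alternative
    for exploratory co-clustering of cohorts; not a substitute for a fitted
    batch model, and only defined on log-scale values.
    """
    if m.scale != LOG2P1:
        raise ExpressionError("median centering is defined on log2p1 values")
    out = m.values.copy()
    batch = batch.reindex(m.values.columns)
    for b in batch.dropna().unique():
        cols = batch.index[batch == b]
        med = out[cols].median(axis=1)
        out[cols] = out[cols].sub(med, axis=0)
    return ExpressionMatrix(out, m.scale, m.sample_meta)
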