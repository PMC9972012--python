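"""Somatic-variant filter cascade, subtype mutation frequencies, and Fisher tests.

The cascade removes, in this fixed order: (1) variants with VAF strictly
below 0.1, (2) intronic and UTR variants, (3) variants present in the
1000 Genomes population database, (4) variants also seen in the matched
normal (germline). The order is part of the contract so per-step drop
counts are well-defined. Splicing and exonic variants pass step 2.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .subtyping import SubtypeAssignment

REGION_CLASSES = ("exonic", "splicing", "intronic", "UTR3", "UTR5", "intergenic", "other")
UTR_CLASSES = ("intronic", "UTR3", "UTR5")

VARIANT_COLUMNS = [
    "sample_id", "gene", "chrom", "position", "ref", "alt",
    "vaf", "region_class", "in_1000g", "in_matched_normal", "pathway_tags",
]

FILTER_STEPS = ("low_vaf", "intronic_utr", "thousand_genomes", "matched_normal")


class VariantError(ValueError):
    pass


def validate_variants(v: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in v.columns]
    if missing:
        raise VariantError(f"variant table missing columns: {missing}")
    if len(v):
        if ((v["vaf"] < 0) | (v["vaf"] > 1)).any():
            raise VariantError("VAF must lie in [0, 1]")
        if (v["position"] < 1).any():
            raise VariantError("positions are 1-based; must be >= 1")
        bad = set(v["region_class"]) - set(REGION_CLASSES)
        if bad:
            raise VariantError(f"unknown region classes: {sorted(bad)}")
    return v


def read_variant_table(path) -> pd.DataFrame:
    v = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"sample_id": str, "gene": str, "chrom": str, "pathway_tags": str},
    )
    v["pathway_tags"] = v.get("pathway_tags", pd.Series(dtype=str)).fillna("")
    v["in_1000g"] = v["in_1000g"].astype(bool)
    v["in_matched_normal"] = v["in_matched_normal"].astype(bool)
    return validate_variants(v)


def write_variant_table(v: pd.DataFrame, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        v.to_csv(fh, sep="\t", index=False)


def filter_variants(
    v: pd.DataFrame, vaf_min: float = 0.1
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the four-step somatic filter cascade; report drops per step.

    A variant with VAF exactly ``vaf_min`` survives step 1 (the threshold
    is "lower than"). Conservation holds: len(input) = len(output) + sum
    of the per-step drops.
    """
    validate_variants(v)
    drops: dict[str, int] = {}
    cur = v
    keep = cur["vaf"] >= vaf_min
    drops["low_vaf"] = int((~keep).sum())
    cur = cur[keep]

    keep = ~cur["region_class"].isin(UTR_CLASSES)
    drops["intronic_utr"] = int((~keep).sum())
    cur = cur[keep]

    keep = ~cur["in_1000g"].astype(bool)
    drops["thousand_genomes"] = int((~keep).sum())
    cur = cur[keep]

    keep = ~cur["in_matched_normal"].astype(bool)
    drops["matched_normal"] = int((~keep).sum())
    cur = cur[keep]

    return cur.reset_index(drop=True), drops


def _round_half_up_1dp(x: float) -> float:
    return float(Decimal(str(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _matches_group(v: pd.DataFrame, group: str) -> pd.Series:
    by_gene = v["gene"].astype(str).str.upper() == group.upper()
    tags = v["pathway_tags"].fillna("").astype(str).str.upper()
    by_tag = tags.str.split(";").apply(lambda ts: group.upper() in [t.strip() for t in ts])
    return by_gene | by_tag


def mutation_frequency(
    v: pd.DataFrame,
    assign: SubtypeAssignment,
    group: str,
) -> pd.DataFrame:
    """Per-subtype mutation frequency for one gene symbol or pathway tag.

    A sample counts as mutated when it carries at least one surviving
    variant in the group; percentages are rounded half-up to one decimal
    (30.4% style). Every variant's sample must be in the assignment.
    """
    validate_variants(v)
    if assign.labels is None:
        raise VariantError("assignment has no subtype labels")
    label_of = dict(zip(assign.sample_ids, assign.labels))
    unknown = set(v["sample_id"].astype(str)) - set(assign.sample_ids)
    if unknown:
        raise VariantError(f"variants carry samples absent from assignment: {sorted(unknown)[:5]}")
    hit_samples = set(v.loc[_matches_group(v, group), "sample_id"].astype(str))
    rows = []
    for label in dict.fromkeys(assign.labels):  # preserve label order
        members = [s for s in assign.sample_ids if label_of[s] == label]
        mutated = sum(s in hit_samples for s in members)
        pct = _round_half_up_1dp(100.0 * mutated / len(members)) if members else 0.0
        rows.append({"subtype": label, "mutated": mutated, "total": len(members), "percent": pct})
    return pd.DataFrame(rows)


def fisher_exact_2x2(table) -> tuple[float | None, float]:
    """Two-sided Fisher exact test by hypergeometric probability-mass ordering.

    Returns (odds ratio, p). With a zero cell the odds ratio gets a 0.5
    continuity shift (flagged by a warning); with a zero margin the test
    is degenerate: p = 1 and the odds ratio is undefined (None).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise VariantError("need a 2x2 table of non-negative integer counts")
    a, b, c, d = t.ravel()
    if min(a + b, c + d, a + c, b + d) == 0:
        warnings.warn("zero margin: Fisher p degenerate (1.0), odds ratio undefined")
        return None, 1.0
    _, p = stats.fisher_exact(t, alternative="two-sided")
    if 0 in (a, b, c, d):
        warnings.warn("zero cell: odds ratio uses a 0.5 continuity shift")
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    oddsratio = (a * d) / (b * c)
    return float(oddsratio), float(p)
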