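"""Hierarchical subtyping of tumors on the STING-pathway signature.

Samples are clustered bottom-up on their gene-wise z-scored signature
profiles (default: Euclidean distance with Ward linkage; 1 - Pearson
correlation with average linkage as the alternative), the tree is cut at
k clusters (k=3 by default), and clusters
are named by mean gene-wise z-scored signature expression, descending:
STING-high, STING-intermediate, STING-low. The naming rule is an explicit
convention of this package — the subtype names come from the biology, the
rule that assigns them to clusters is ours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from .io import ExpressionMatrix

SUBTYPE_LABELS = ("STING-high", "STING-intermediate", "STING-low")
CORRELATION = "correlation"
EUCLIDEAN_Z = "euclidean_z"


class SubtypingError(ValueError):
    pass


@dataclass
class SubtypeAssignment:
    sample_ids: list[str]
    cluster_id: np.ndarray                      # 1..k per sample
    linkage_record: np.ndarray                  # scipy linkage matrix
    params: dict = field(default_factory=dict)
    labels: list[str] | None = None             # filled by label_clusters

    def __post_init__(self) -> None:
        self.cluster_id = np.asarray(self.cluster_id, dtype=int)
        if len(self.cluster_id) != len(self.sample_ids):
            raise SubtypingError("one cluster id per sample required")

    @property
    def k(self) -> int:
        return len(np.unique(self.cluster_id))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample": self.sample_ids, "cluster": self.cluster_id})
        if self.labels is not None:
            df["label"] = self.labels
        return df


def _zscore_genes(values: pd.DataFrame) -> pd.DataFrame:
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=0)  # population SD for determinism
    sd = sd.replace(0, 1.0)
    return values.sub(mu, axis=0).div(sd, axis=0)


def _sample_distance(values: pd.DataFrame, distance: str) -> np.ndarray:
    # both distances act on gene-wise z-scored profiles (heatmap "scale rows"
    # convention); without it a uniform signature shift cancels out of the
    # per-sample centering inside Pearson and is invisible to the clustering
    Z = _zscore_genes(values).to_numpy(float).T  # samples x genes
    if distance == CORRELATION:
        if (Z.std(axis=1) == 0).any():
            raise SubtypingError("constant sample profile; correlation distance undefined")
        return pdist(Z, metric="correlation")
    if distance == EUCLIDEAN_Z:
        return pdist(Z, metric="euclidean")
    raise SubtypingError(f"unknown distance {distance!r}")


def cluster_samples(
    m_sig: ExpressionMatrix,
    k: int = 3,
    distance: str = EUCLIDEAN_Z,
    linkage_method: str = "ward",
) -> SubtypeAssignment:
    """Agglomerative clustering of samples on signature genes, cut to k clusters."""
    n = m_sig.shape[1]
    if k > n:
        raise SubtypingError(f"k={k} exceeds the {n} available samples")
    if m_sig.shape[0] < 2:
        raise SubtypingError("need >=2 signature genes to cluster")
    d = _sample_distance(m_sig.values, distance)
    if linkage_method == "ward" and distance != EUCLIDEAN_Z:
        raise SubtypingError("ward linkage requires euclidean_z distance")
    Z = linkage(d, method=linkage_method)
    clusters = fcluster(Z, t=k, criterion="maxclust")
    return SubtypeAssignment(
        sample_ids=m_sig.sample_ids,
        cluster_id=clusters,
        linkage_record=Z,
        params={"distance": distance, "linkage": linkage_method, "k": k},
    )


def label_clusters(assign: SubtypeAssignment, m_sig: ExpressionMatrix) -> SubtypeAssignment:
    """Name clusters by mean gene-wise z-scored signature expression, descending.

    For k=3 the names are STING-high / STING-intermediate / STING-low;
    for any other k the labels are ``cluster-rank-i`` in the same order.
    Ties between cluster means (within 1e-12) break toward the smaller
    cluster id, with a warning.
    """
    if list(m_sig.sample_ids) != list(assign.sample_ids):
        raise SubtypingError("assignment and matrix refer to different samples")
    z = _zscore_genes(m_sig.values)
    ids = np.unique(assign.cluster_id)
    means = {}
    for cid in ids:
        cols = [s for s, c in zip(assign.sample_ids, assign.cluster_id) if c == cid]
        means[cid] = float(z[cols].to_numpy().mean())
    vals = np.array([means[c] for c in ids])
    if len(ids) > 1:
        gaps = np.abs(vals[:, None] - vals[None, :])
        np.fill_diagonal(gaps, np.inf)
        if gaps.min() < 1e-12:
            warnings.warn("tie in cluster mean signature expression; breaking by cluster id")
    # descending mean; ties by smaller cluster id (stable after primary sort)
    order = sorted(ids, key=lambda c: (-means[c], c))
    if len(ids) == 3:
        name_of = {cid: SUBTYPE_LABELS[r] for r, cid in enumerate(order)}
    else:
        name_of = {cid: f"cluster-rank-{r + 1}" for r, cid in enumerate(order)}
    labels = [name_of[c] for c in assign.cluster_id]
    return SubtypeAssignment(
        sample_ids=list(assign.sample_ids),
        cluster_id=assign.cluster_id.copy(),
        linkage_record=assign.linkage_record,
        params=dict(assign.params),
        labels=labels,
    )


def compare_assignments(
    assign: SubtypeAssignment, other: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Contingency table and adjusted Rand index against an external labeling."""
    other = other.reindex(assign.sample_ids)
    if other.isna().any():
        raise SubtypingError("external labeling does not cover every sample")
    ours = pd.Series(
        assign.labels if assign.labels is not None else assign.cluster_id,
        index=assign.sample_ids,
    )
    table = pd.crosstab(ours, other)
    ari = float(adjusted_rand_score(ours.to_numpy(), other.to_numpy()))
    return table, ari


def classify_new_sample(
    profile: pd.Series,
    assign: SubtypeAssignment,
    m_sig: ExpressionMatrix,
    min_coverage: float = 0.5,
) -> str:
    """Assign a new profile to the nearest cluster centroid under the clustering distance."""
    if assign.labels is None:
        raise SubtypingError("assignment has no labels; run label_clusters first")
    profile = profile.copy()
    profile.index = profile.index.astype(str).str.upper()
    sig_genes = m_sig.values.index
    shared = sig_genes.intersection(profile.index)
    if len(shared) < min_coverage * len(sig_genes):
        raise SubtypingError(
            f"profile covers {len(shared)}/{len(sig_genes)} signature genes; "
            f"need >= {min_coverage:.0%}"
        )
    distance = assign.params.get("distance", CORRELATION)
    # express both the profile and the centroids in the training cohort's
    # gene-wise z-space, matching the clustering distance
    mu = m_sig.values.loc[shared].mean(axis=1)
    sd = m_sig.values.loc[shared].std(axis=1, ddof=0).replace(0, 1.0)
    z_sig = m_sig.values.loc[shared].sub(mu, axis=0).div(sd, axis=0)
    x = ((profile.loc[shared] - mu) / sd).to_numpy(float)
    best: tuple[float, int] | None = None
    label_of: dict[int, str] = {}
    for cid in np.unique(assign.cluster_id):
        cols = [s for s, c in zip(assign.sample_ids, assign.cluster_id) if c == cid]
        centroid = z_sig[cols].mean(axis=1).to_numpy(float)
        if distance == CORRELATION:
            if np.std(x) == 0 or np.std(centroid) == 0:
                raise SubtypingError("constant vector; correlation distance undefined")
            d = 1.0 - float(np.corrcoef(x, centroid)[0, 1])
        else:
            d = float(np.linalg.norm(x - centroid))
        label_of[cid] = [
            lab for s, c, lab in zip(assign.sample_ids, assign.cluster_id, assign.labels)
            if c == cid
        ][0]
        if best is None or d < best[0] - 1e-15:
            best = (d, cid)
        elif abs(d - best[0]) <= 1e-15:
            warnings.warn("profile equidistant to two centroids; keeping smaller cluster id")
    assert best is not None
    return label_of[best[1]]
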