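"""Hierarchical clustering on Spearman-correlation distances with Ward
linkage, plus cluster/attribute purity reporting and heatmap export.

Ward linkage is applied to the correlation distances as-is via the
Lance-Williams update (scipy's implementation); Ward formally assumes
Euclidean distances, so this mirrors the described method rather than a
geometrically clean embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from cd8mir.io_core import Cd8mirError, ExpressionMatrix, SampleTable, ValidationError


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray  # scipy linkage format, n-1 merges
    leaf_labels: list[str]

    def cut(self, k: int) -> dict[str, int]:
        """Cluster assignments (1..k) for the k-cluster cut."""
        n = len(self.leaf_labels)
        if not 2 <= k <= n:
            raise ValidationError(f"k={k} out of range [2, {n}]")
        labels = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.leaf_labels, (int(v) for v in labels)))

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick string with branch lengths."""
        n = len(self.leaf_labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.leaf_labels[i] for i in range(n)}
        for idx, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            new = n + idx
            node[new] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[new] = h
        return node[n + len(self.linkage_matrix) - 1] + ";"


def spearman_distance_matrix(
    mat: ExpressionMatrix, axis: str = "samples", min_obs: int = 3, center_rows: bool = False
) -> pd.DataFrame:
    """Pairwise-complete Spearman distance d = 1 - rho between samples or features.

    ``center_rows`` subtracts each feature's mean first; for sample-axis
    clustering of a group-contrast panel this removes the shared baseline
    profile that otherwise dominates the rank correlations.
    """
    if center_rows:
        mat = mat.copy_with(mat.data.sub(mat.data.mean(axis=1), axis=0), mat.value_kind)
    if axis == "samples":
        df = mat.data
        labels = mat.sample_ids
        vectors = [df[s].to_numpy() for s in labels]
    elif axis == "features":
        labels = mat.feature_ids
        vectors = [mat.data.loc[f].to_numpy() for f in labels]
    else:
        raise ValidationError("axis must be 'samples' or 'features'")
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vi, vj = vectors[i], vectors[j]
            ok = np.isfinite(vi) & np.isfinite(vj)
            if ok.sum() < min_obs:
                raise Cd8mirError(
                    f"pair ({labels[i]}, {labels[j]}): only {int(ok.sum())} complete observations"
                )
            if np.unique(vi[ok]).size == 1 or np.unique(vj[ok]).size == 1:
                offender = labels[i] if np.unique(vi[ok]).size == 1 else labels[j]
                raise Cd8mirError(f"constant vector for '{offender}': Spearman rho undefined")
            rho = spearmanr(vi[ok], vj[ok]).statistic
            dist[i, j] = dist[j, i] = 1.0 - rho
    return pd.DataFrame(dist, index=labels, columns=labels)


def ward_cluster(dist: pd.DataFrame, k: int = 2) -> tuple[Dendrogram, dict[str, int]]:
    """Ward linkage (Lance-Williams) on a precomputed distance matrix."""
    labels = list(dist.index)
    n = len(labels)
    if not 2 <= k <= n:
        raise ValidationError(f"k={k} out of range [2, {n}]")
    condensed = squareform(dist.to_numpy(), checks=True)
    Z = linkage(condensed, method="ward")
    dend = Dendrogram(linkage_matrix=Z, leaf_labels=labels)
    return dend, dend.cut(k)


@dataclass
class PurityReport:
    contingency: pd.DataFrame  # cluster x attribute value counts
    purity: float
    pure: bool


def cluster_separation_check(
    dend: Dendrogram, meta: SampleTable, attribute: str = "smoker", k: int = 2
) -> PurityReport:
    """Contingency of the k-cut clusters against a sample attribute.

    Purity = (sum over clusters of the majority count) / n; ``pure`` means
    every cluster is homogeneous in the attribute.
    """
    if attribute not in meta.data.columns:
        raise ValidationError(f"attribute '{attribute}' absent from metadata")
    assignments = dend.cut(k)
    missing = [s for s in assignments if s not in meta.data.index]
    if missing:
        raise ValidationError(f"leaves without metadata: {missing}")
    rows = pd.DataFrame(
        {
            "cluster": [assignments[s] for s in assignments],
            attribute: [meta.data.loc[s, attribute] for s in assignments],
        }
    )
    tab = pd.crosstab(rows["cluster"], rows[attribute])
    majority = tab.max(axis=1).sum()
    purity = float(majority / tab.to_numpy().sum())
    pure = bool((tab.gt(0).sum(axis=1) == 1).all())
    return PurityReport(contingency=tab, purity=purity, pure=pure)


def heatmap_frame(mat: ExpressionMatrix, zscore_rows: bool = True) -> pd.DataFrame:
    """Display matrix: per-feature z-scores (display only; clustering uses raw values)."""
    df = mat.data
    if not zscore_rows:
        return df.copy()
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0).replace(0, np.nan)
    return df.sub(mu, axis=0).div(sd, axis=0)
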