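"""Expression filtering, per-gene scaling and hierarchical clustering.

The expressed-gene filter reproduces the VST > 3 rule used to select genes
for network analysis: a gene is kept when it exceeds the threshold in at
least ``min_samples`` sections of at least ``min_trees`` distinct trees.
Gene clustering uses correlation distance (1 - Pearson r) on per-gene
standardized profiles; section clustering uses Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .containers import SectionSeries


@dataclass
class ClusterAssignment:
    """Result of cutting an agglomerative linkage tree into k clusters."""

    items: list[str]
    labels: np.ndarray  # cluster labels 1..k, aligned with items
    linkage: np.ndarray  # scipy linkage matrix (merge order + heights)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster": self.labels}, index=pd.Index(self.items, name="item")
        )


def filter_expressed(
    series: SectionSeries,
    vst_threshold: float = 3.0,
    min_samples: int = 2,
    min_trees: int = 3,
) -> SectionSeries:
    """Keep genes expressed above ``vst_threshold`` in >= ``min_samples``
    sections of >= ``min_trees`` distinct trees.  Gene order is preserved;
    the operation is idempotent."""
    trees = series.trees
    if min_trees > len(trees):
        raise ValueError(
            f"min_trees={min_trees} exceeds the {len(trees)} trees present"
        )
    tree_of = series.section_meta["tree"]
    above = series.values.gt(vst_threshold)
    trees_passing = (
        above.T.groupby(tree_of, sort=False).sum().ge(min_samples).sum(axis=0)
    )
    keep = trees_passing.ge(min_trees)
    return SectionSeries(series.values.loc[keep], series.section_meta)


def scale_per_gene(series: SectionSeries) -> SectionSeries:
    """Standardize each gene row to mean 0, sd 1 across all sections.

    Zero-variance rows become all zeros rather than NaN.
    """
    x = series.values.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    out = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return SectionSeries(
        pd.DataFrame(out, index=series.values.index, columns=series.values.columns),
        series.section_meta,
    )


def cluster_genes(
    series: SectionSeries,
    k: int,
    distance: str = "pearson",
    method: str = "average",
) -> ClusterAssignment:
    """Cluster genes on 1 - Pearson r of their scaled profiles.

    Average linkage by default; the tree is cut into ``k`` groups.
    """
    items = series.genes
    if len(items) < 2:
        raise ValueError("need at least 2 genes to cluster")
    if k > len(items) or k < 1:
        raise ValueError("k must lie in 1..n_genes")
    scaled = scale_per_gene(series).values.to_numpy(dtype=float)
    if distance == "pearson":
        if (scaled.std(axis=1) == 0).any():
            raise ValueError("zero-variance gene under Pearson distance")
        dist = pdist(scaled, metric="correlation")
    elif distance == "euclidean":
        dist = pdist(scaled, metric="euclidean")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    z = linkage(dist, method=method)
    labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterAssignment(items, labels.astype(int), z)


def cluster_sections(
    series: SectionSeries,
    k: int = 4,
    distance: str = "euclidean",
    method: str = "ward",
) -> ClusterAssignment:
    """Cluster sections (columns) on Euclidean distance, Ward linkage."""
    items = series.sections
    if len(items) < 2:
        raise ValueError("need at least 2 sections to cluster")
    if k > len(items) or k < 1:
        raise ValueError("k must lie in 1..n_sections")
    x = series.values.to_numpy(dtype=float).T
    if distance != "euclidean":
        raise ValueError(f"unknown distance {distance!r}")
    z = linkage(pdist(x, metric="euclidean"), method=method)
    labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterAssignment(items, labels.astype(int), z)
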