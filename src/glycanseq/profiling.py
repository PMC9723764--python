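"""Percentage lectin profiles, positivity calls, and sample clustering.

A sample's lectin *intensity* is its barcode count divided by the total
number of assigned lectin barcodes in that sample, expressed as a percentage;
profile rows therefore sum to 100. Unassigned, ambiguous and too-short reads
never enter the denominator. Hierarchical clustering of profile rows is the
standard first look at such data (two bacterial species, or the pups and
adult microbiotas, splitting into two clusters).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .counting import CountMatrix

DEFAULT_POSITIVE_THRESHOLD = 15.0

_LINKAGES = ("average", "single", "complete", "ward", "weighted", "centroid", "median")
_METRICS = ("euclidean", "cityblock", "correlation", "cosine", "braycurtis", "canberra", "chebyshev")


class ProfilingError(ValueError):
    pass


@dataclass
class ProfileMatrix:
    """Samples x lectins percentage matrix with optional group labels."""

    values: pd.DataFrame  # percentages, rows sum to 100
    groups: pd.Series | None = None  # index = sample ids

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ProfilingError("profile entries must be non-negative")
        row_sums = self.values.sum(axis=1)
        if not np.allclose(row_sums, 100.0, atol=1e-6):
            bad = row_sums[~np.isclose(row_sums, 100.0, atol=1e-6)]
            raise ProfilingError(f"profile rows must sum to 100; offenders: {dict(bad)}")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.values.index)
            if self.groups.isna().any():
                raise ProfilingError("groups missing for some samples")

    def write(self, path: str | Path) -> None:
        df = self.values.round(4).copy()
        if self.groups is not None:
            df.insert(0, "group", self.groups)
        df.insert(0, "sample_id", df.index)
        df.to_csv(path, sep="\t", index=False, float_format="%.4f")

    @classmethod
    def read(cls, path: str | Path) -> "ProfileMatrix":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("sample_id")
        groups = None
        if "group" in df.columns:
            groups = df.pop("group")
        return cls(values=df.astype(float), groups=groups)


def normalize(counts: CountMatrix, groups: pd.Series | dict | None = None) -> ProfileMatrix:
    """Counts -> percentage profile: 100 * count / n_assigned per sample."""
    denom = counts.tallies["n_assigned"].astype(float)
    zero = denom.index[denom == 0].tolist()
    if zero:
        raise ProfilingError(f"samples with zero assigned reads cannot be normalized: {zero}")
    values = counts.counts.div(denom, axis=0) * 100.0
    if groups is not None and not isinstance(groups, pd.Series):
        groups = pd.Series(groups)
    return ProfileMatrix(values=values, groups=groups)


def profile_from_raw_counts(
    counts: pd.DataFrame, groups: pd.Series | dict | None = None
) -> ProfileMatrix:
    """Percentage profile straight from a samples x lectins count frame.

    Convenience path for count tables produced without read-status tallies
    (e.g. simulated count matrices); the denominator is the row sum.
    """
    totals = counts.sum(axis=1).astype(float)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ProfilingError(f"samples with zero counts cannot be normalized: {zero}")
    if groups is not None and not isinstance(groups, pd.Series):
        groups = pd.Series(groups)
    return ProfileMatrix(values=counts.div(totals, axis=0) * 100.0, groups=groups)


def flag_positive(
    profile: ProfileMatrix,
    group: str,
    threshold: float = DEFAULT_POSITIVE_THRESHOLD,
) -> set[str]:
    """Lectins whose mean percentage within ``group`` strictly exceeds the
    positivity threshold (default >15, the screening cut used to pick lectins
    for orthogonal validation)."""
    if threshold < 0:
        raise ProfilingError("threshold must be >= 0")
    if profile.groups is None:
        raise ProfilingError("profile has no group labels")
    mask = profile.groups == group
    if not mask.any():
        raise ProfilingError(f"unknown group label {group!r}")
    means = profile.values.loc[mask].mean(axis=0)
    return set(means.index[means > threshold])


@dataclass
class ClusterResult:
    """Agglomerative clustering of profile rows.

    Holds the scipy linkage matrix, dendrogram leaf order, cophenetic
    distance matrix, and the metric/linkage names used.
    """

    linkage_matrix: np.ndarray
    sample_ids: list[str]
    leaf_order: list[str]
    cophenetic: pd.DataFrame
    metric: str
    method: str
    profile: ProfileMatrix

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels (1..k) from cutting the tree into k clusters."""
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids)

    def reordered_values(self) -> pd.DataFrame:
        """Heatmap-ready profile matrix with rows in dendrogram leaf order."""
        return self.profile.values.loc[self.leaf_order]

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge-height branch lengths."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def render(node, parent_dist: float) -> str:
            length = parent_dist - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def cluster_samples(
    profile: ProfileMatrix, metric: str = "euclidean", method: str = "average"
) -> ClusterResult:
    """Hierarchically cluster sample rows of a percentage profile.

    Defaults (Euclidean distance, average linkage) are the usual choice for
    lectin-profile heatmaps; both are configurable.
    """
    if len(profile.values) < 2:
        raise ProfilingError("clustering requires at least 2 samples")
    if metric not in _METRICS:
        raise ProfilingError(f"unknown metric {metric!r}; options: {list(_METRICS)}")
    if method not in _LINKAGES:
        raise ProfilingError(f"unknown linkage {method!r}; options: {list(_LINKAGES)}")
    X = profile.values.to_numpy(dtype=float)
    dists = pdist(X, metric=metric)
    Z = hierarchy.linkage(dists, method=method)
    coph = squareform(hierarchy.cophenet(Z, dists)[1])
    ids = list(profile.values.index)
    leaves = hierarchy.leaves_list(Z)
    return ClusterResult(
        linkage_matrix=Z,
        sample_ids=ids,
        leaf_order=[ids[i] for i in leaves],
        cophenetic=pd.DataFrame(coph, index=ids, columns=ids),
        metric=metric,
        method=method,
        profile=profile,
    )


def plot_heatmap(result: ClusterResult, path: str | Path) -> None:
    """Optional PNG heatmap of the leaf-ordered profile matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = result.reordered_values()
    fig, ax = plt.subplots(figsize=(max(6, 0.25 * data.shape[1]), 0.4 * data.shape[0] + 2))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(data.index)), data.index)
    ax.set_xticks(range(len(data.columns)), data.columns, rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="% of lectin barcodes")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
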