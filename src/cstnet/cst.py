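"""Community state type discovery.

Samples are clustered hierarchically on ``1 - Pearson`` distances computed
between their species-abundance vectors (average linkage by default).  The
number of community state types (CSTs) is chosen by cutting the single
fitted dendrogram at each candidate k and taking the k that maximizes the
mean silhouette width on the same distances; ties go to the smaller k.
CSTs holding at least a stated fraction of all samples (default 15%) are
flagged as high prevalence clusters (HPCs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage, to_tree
from scipy.spatial.distance import squareform
from skbio.stats.distance import DistanceMatrix

from .diversity import distance_matrix
from .io import AbundanceTable, align_metadata

__all__ = [
    "CstResult",
    "fit_dendrogram",
    "hcl_cluster",
    "mean_silhouette",
    "select_k",
    "identify_hpcs",
    "group_composition",
    "dendrogram_to_newick",
]

HPC_MIN_PREVALENCE = 0.15


@dataclass
class CstResult:
    """Clustering outcome: labels, model-selection trace and HPC flags.

    ``labels`` maps each sample to a cluster id; ids are contiguous integers
    starting at 1, ordered by decreasing cluster size.  ``prevalence`` is the
    fraction of samples per cluster (sums to 1) and ``hpc_ids`` the clusters
    at or above the HPC prevalence threshold.  ``group_composition`` rows
    (one per cluster) each sum to 1 over metadata groups.
    """

    labels: pd.Series
    k: int
    silhouette_by_k: pd.Series
    linkage_matrix: np.ndarray | None = None
    hpc_ids: list[int] = field(default_factory=list)
    hpc_min_prevalence: float | None = None
    collective_coverage: float | None = None
    group_composition: pd.DataFrame | None = None

    @property
    def prevalence(self) -> pd.Series:
        counts = self.labels.value_counts().sort_index()
        return counts / counts.sum()


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary cluster codes to 1..k ordered by decreasing size.

    Ties on size are broken by order of first appearance, which is stable
    across runs.
    """
    codes, counts = np.unique(raw, return_counts=True)
    first_seen = {c: int(np.argmax(raw == c)) for c in codes}
    order = sorted(codes, key=lambda c: (-counts[list(codes).index(c)], first_seen[c]))
    mapping = {c: i + 1 for i, c in enumerate(order)}
    return np.asarray([mapping[c] for c in raw])


def fit_dendrogram(table: AbundanceTable, linkage_method: str = "average"):
    """Fit one hierarchical tree on 1-Pearson sample distances.

    Returns ``(linkage_matrix, distance_matrix)``; all cuts for candidate k
    come from this single tree, so partitions at successive k are nested.
    """
    dm = distance_matrix(table, metric="pearson")
    condensed = squareform(np.asarray(dm.data), checks=False)
    z = linkage(condensed, method=linkage_method)
    return z, dm


def hcl_cluster(table: AbundanceTable, k: int, linkage_method: str = "average") -> pd.Series:
    """Cut the average-linkage 1-Pearson dendrogram into exactly k clusters."""
    n = table.n_samples
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    z, _ = fit_dendrogram(table, linkage_method)
    raw = cut_tree(z, n_clusters=k).ravel()
    return pd.Series(_relabel_by_size(raw), index=table.sample_ids, name="cst")


def mean_silhouette(dm: DistanceMatrix, labels) -> float:
    """Mean silhouette width of a partition under a precomputed distance.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean distance to
    the sample's own cluster (excluding itself) and b(i) the smallest mean
    distance to another cluster.  Singleton clusters score 0, as does the
    degenerate a = b = 0 case (all points identical).
    """
    d = np.asarray(dm.data, dtype=float)
    labels = np.asarray(labels)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length does not match distance matrix")
    codes, inv = np.unique(labels, return_inverse=True)
    k = codes.size
    if k < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    onehot = np.zeros((n, k))
    onehot[np.arange(n), inv] = 1.0
    sizes = onehot.sum(axis=0)
    # mean distance from each sample to each cluster (own cluster excludes self)
    sums = d @ onehot
    denom = np.where(sizes[None, :] - onehot > 0, sizes[None, :] - onehot, 1.0)
    mean_to = sums / denom
    a = mean_to[np.arange(n), inv]
    b_candidates = np.where(onehot.astype(bool), np.inf, mean_to)
    b = b_candidates.min(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (b - a) / np.maximum(a, b)
    s = np.nan_to_num(s, nan=0.0, posinf=0.0, neginf=0.0)
    s[sizes[inv] == 1] = 0.0
    return float(s.mean())


def select_k(
    table: AbundanceTable,
    k_range=range(2, 16),
    linkage_method: str = "average",
) -> CstResult:
    """Pick the number of CSTs by the silhouette criterion.

    One dendrogram is fitted; it is cut at every k in ``k_range`` and the
    mean silhouette on the same 1-Pearson distances is recorded.  The
    selected k maximizes the trace, ties broken toward smaller k.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k_range")
    n = table.n_samples
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    z, dm = fit_dendrogram(table, linkage_method)
    cuts = cut_tree(z, n_clusters=ks)
    sil = {}
    labels_by_k = {}
    for j, k in enumerate(ks):
        raw = cuts[:, j].ravel()
        labels_by_k[k] = _relabel_by_size(raw)
        sil[k] = mean_silhouette(dm, raw)
    trace = pd.Series(sil, name="mean_silhouette").sort_index()
    best_k = int(trace.idxmax())  # idxmax returns the first (smallest) maximizer
    labels = pd.Series(labels_by_k[best_k], index=table.sample_ids, name="cst")
    return CstResult(labels=labels, k=best_k, silhouette_by_k=trace, linkage_matrix=z)


def identify_hpcs(result: CstResult, min_prevalence: float = HPC_MIN_PREVALENCE) -> CstResult:
    """Flag clusters covering at least ``min_prevalence`` of all samples.

    The threshold is inclusive.  Also records the collective coverage (sum
    of HPC prevalences); an empty HPC set is legitimate.
    """
    prevalence = result.prevalence
    hpc = prevalence[prevalence >= min_prevalence]
    result.hpc_ids = [int(c) for c in hpc.index]
    result.hpc_min_prevalence = min_prevalence
    result.collective_coverage = float(hpc.sum())
    return result


def group_composition(result: CstResult, metadata: pd.DataFrame) -> CstResult:
    """Per-cluster fraction of member samples from each metadata group."""
    missing = [s for s in result.labels.index if s not in metadata.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    groups = metadata.loc[result.labels.index, "group"]
    table = pd.crosstab(result.labels, groups.astype(str))
    comp = table.div(table.sum(axis=1), axis=0)
    comp.index.name = "cst"
    result.group_composition = comp
    return result


def dendrogram_to_newick(z: np.ndarray, leaf_names) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(z)
    names = list(leaf_names)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"
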