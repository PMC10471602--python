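"""Clustering of gene variability profiles and heatmap ordering.

Genes are clustered on their raw LCV profiles (rows = genes, columns = group
scores) with k-means: LCV is already a bounded, comparable 0–100 scale, so no
row standardization is applied.  Cluster count defaults to 10 but a silhouette
scan over candidate k is provided as the verification step.  For heatmap
export, columns (groups) are ordered by average-linkage hierarchical
clustering and the dendrogram is serialized as Newick.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from skbio import TreeNode
from sklearn.cluster import kmeans_plusplus
from sklearn.metrics import silhouette_samples

from .datamodel import ValidationError
from .lcv import LCVMatrix

logger = logging.getLogger("canalex")


@dataclass
class ClusterAssignment:
    gene_ids: list[str]
    labels: np.ndarray  # 1..k, renumbered by descending cluster mean LCV
    k: int
    sizes: dict[int, int]
    wcss: float
    objective_trace: list[float]
    seed: int
    n_restarts: int

    def members(self, label: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == label]


@dataclass
class SilhouetteScan:
    k_values: list[int]
    mean_widths: list[float]  # NaN where silhouette undefined
    selected_k: int | None  # None when silhouette is undefined at every k


def _complete_profiles(lcv: LCVMatrix) -> tuple[list[str], np.ndarray]:
    X = lcv.scores
    keep = X.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("excluding %d genes with undefined LCV in some group", dropped)
    sub = X[keep]
    return list(sub.index), sub.to_numpy(dtype=float)


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int = 300,
           tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Plain Lloyd iterations; the objective is checked to be non-increasing."""
    trace: list[float] = []
    labels = np.zeros(len(X), dtype=int)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        obj = float(d2[np.arange(len(X)), labels].sum())
        if trace and obj > trace[-1] + 1e-9 * max(1.0, trace[-1]):
            raise AssertionError("k-means objective increased across an iteration")
        converged = bool(trace) and trace[-1] - obj <= tol * max(1.0, trace[-1])
        trace.append(obj)
        new_centers = centers.copy()
        for j in range(len(centers)):
            pts = X[labels == j]
            if len(pts):
                new_centers[j] = pts.mean(axis=0)
        if converged or np.allclose(new_centers, centers):
            centers = new_centers
            break
        centers = new_centers
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    wcss = float(d2[np.arange(len(X)), labels].sum())
    return labels, centers, wcss, trace


def kmeans_cluster(lcv: LCVMatrix, k: int, seed: int = 0, n_restarts: int = 10
                   ) -> ClusterAssignment:
    """k-means (Lloyd's algorithm, k-means++ seeding, best of restarts).

    Labels are renumbered 1..k by descending cluster mean LCV so repeated runs
    on the same data yield identical numbering.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    gene_ids, X = _complete_profiles(lcv)
    if k > len(gene_ids):
        raise ValidationError(f"k={k} exceeds {len(gene_ids)} usable genes")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        centers, _ = kmeans_plusplus(
            X, n_clusters=k, random_state=int(rng.integers(2**31 - 1))
        )
        labels, centers, wcss, trace = _lloyd(X, centers)
        if best is None or wcss < best[2]:
            best = (labels, centers, wcss, trace)
    labels, centers, wcss, trace = best
    # renumber by descending cluster mean LCV (mean over profile entries)
    means = [X[labels == j].mean() if (labels == j).any() else -np.inf for j in range(k)]
    order = np.argsort(means)[::-1]
    remap = {int(old): rank + 1 for rank, old in enumerate(order)}
    new_labels = np.array([remap[int(l)] for l in labels])
    sizes = {j: int((new_labels == j).sum()) for j in range(1, k + 1)}
    return ClusterAssignment(
        gene_ids=gene_ids,
        labels=new_labels,
        k=k,
        sizes=sizes,
        wcss=wcss,
        objective_trace=trace,
        seed=seed,
        n_restarts=n_restarts,
    )


def silhouette_scan(lcv: LCVMatrix, k_range: tuple[int, int], seed: int = 0,
                    n_restarts: int = 10) -> SilhouetteScan:
    """Mean silhouette width for each candidate k; selected k maximizes it.

    Silhouette of point i is (b − a)/max(a, b) with a = mean intra-cluster
    distance and b = smallest mean distance to another cluster (Euclidean).
    A k whose fit degenerates to fewer than 2 non-empty clusters is NaN.
    Ties select the smallest k.
    """
    gene_ids, X = _complete_profiles(lcv)
    lo, hi = k_range
    if lo < 2 or hi > len(gene_ids) - 1 or lo > hi:
        raise ValidationError(f"k range {k_range} outside [2, {len(gene_ids) - 1}]")
    ks, widths = [], []
    for k in range(lo, hi + 1):
        assignment = kmeans_cluster(lcv, k, seed=seed, n_restarts=n_restarts)
        labels = assignment.labels
        ks.append(k)
        if len(np.unique(labels)) < 2:
            widths.append(float("nan"))
            continue
        widths.append(float(silhouette_samples(X, labels).mean()))
    arr = np.array(widths)
    if np.isnan(arr).all():
        logger.warning("silhouette undefined for every candidate k (degenerate data)")
        selected = None
    else:
        selected = ks[int(np.nanargmax(arr))]
    return SilhouetteScan(k_values=ks, mean_widths=widths, selected_k=selected)


@dataclass
class HeatmapOrder:
    row_order: list[str]
    column_order: list[str]
    column_newick: str
    column_linkage: np.ndarray
    column_names: list[str]  # original (pre-ordering) column order of the linkage


def _linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    tree = TreeNode.from_linkage_matrix(Z, leaf_names)
    buf = _io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def order_for_heatmap(lcv: LCVMatrix, clusters: ClusterAssignment) -> HeatmapOrder:
    """Row/column ordering for heatmap export.

    Rows are grouped by cluster label and, within each cluster, ordered by the
    leaf order of an average-linkage tree on the gene profiles.  Columns
    (groups) are ordered by average-linkage hierarchical clustering on
    Euclidean distances between group LCV profiles, serialized as Newick.
    """
    gene_ids, X = _complete_profiles(lcv)
    pos = {g: i for i, g in enumerate(gene_ids)}
    row_order: list[str] = []
    for label in range(1, clusters.k + 1):
        members = clusters.members(label)
        if not members:
            continue
        sub = X[[pos[g] for g in members], :]
        if len(members) > 2:
            Z = linkage(sub, method="average")
            members = [members[i] for i in leaves_list(Z)]
        row_order.extend(members)

    cols = lcv.group_names
    col_profiles = X.T
    Zc = linkage(col_profiles, method="average")
    column_order = [cols[i] for i in leaves_list(Zc)]
    newick = _linkage_to_newick(Zc, cols)
    return HeatmapOrder(
        row_order=row_order,
        column_order=column_order,
        column_newick=newick,
        column_linkage=Zc,
        column_names=list(cols),
    )


def column_split(order: HeatmapOrder, n_groups: int = 2) -> dict[str, int]:
    """Cut the column dendrogram into ``n_groups`` flat clusters.

    Used to check the qualitative maternal-morph pairing of the heatmap
    columns: cutting at two clusters should split the groups by maternal
    morph when maternal patterns dominate.
    """
    labels = fcluster(order.column_linkage, t=n_groups, criterion="maxclust")
    return {c: int(l) for c, l in zip(order.column_names, labels)}
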