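"""Sample similarity: euclidean distances, Ward clustering, beta densities.

Distances are plain euclidean over all probes per sample pair.  Clustering
uses Ward linkage in its "D2" sense: the Lance–Williams update operates on
squared distances and merge heights are reported back on the distance
scale (the behaviour of the classical ``ward.D2`` agglomeration).  The
dendrogram can be exported as a merge table or a Newick string.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import gaussian_kde

from .matrix import MethlineageError, MethylationMatrix


def pairwise_distances(beta_matrix: MethylationMatrix) -> pd.DataFrame:
    """Symmetric euclidean distance matrix over samples (zero diagonal)."""
    if beta_matrix.n_samples < 2:
        raise MethlineageError("need >= 2 samples")
    X = beta_matrix.values.to_numpy().T
    if not np.isfinite(X).all():
        raise MethlineageError("missing or non-finite values; impute before computing distances")
    D = squareform(pdist(X, metric="euclidean"))
    return pd.DataFrame(D, index=beta_matrix.sample_ids, columns=beta_matrix.sample_ids)


def check_distance_matrix(dist: pd.DataFrame) -> None:
    arr = dist.to_numpy()
    if arr.shape[0] != arr.shape[1]:
        raise MethlineageError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise MethlineageError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
        raise MethlineageError("distance matrix must have a zero diagonal")
    if (arr < -1e-12).any():
        raise MethlineageError("distances must be non-negative")


def hierarchical_cluster(dist: pd.DataFrame, method: str = "ward_d2") -> pd.DataFrame:
    """Agglomerative clustering of a distance matrix.

    Returns the merge table: one row per merge with the two merged node ids
    (leaves are 0..n-1, internal nodes n, n+1, ... in merge order), the
    merge height on the distance scale, and the cluster size.  Heights are
    non-decreasing for Ward linkage.
    """
    check_distance_matrix(dist)
    scipy_method = {"ward_d2": "ward", "average": "average", "complete": "complete", "single": "single"}.get(
        method
    )
    if scipy_method is None:
        raise MethlineageError(f"unknown linkage {method!r}")
    y = squareform(dist.to_numpy(), checks=False)
    Z = hierarchy.linkage(y, method=scipy_method)
    out = pd.DataFrame(Z, columns=["node_a", "node_b", "height", "size"])
    out["node_a"] = out["node_a"].astype(int)
    out["node_b"] = out["node_b"].astype(int)
    out["size"] = out["size"].astype(int)
    out.attrs["labels"] = list(dist.index)
    return out


def cut_tree(merges: pd.DataFrame, k: int) -> pd.Series:
    """Flat cluster labels (1..k) from a merge table."""
    Z = merges[["node_a", "node_b", "height", "size"]].to_numpy(dtype=float)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=merges.attrs.get("labels", range(len(labels))))


def to_newick(merges: pd.DataFrame) -> str:
    """Newick export of the merge table, branch lengths from merge heights."""
    labels = merges.attrs.get("labels")
    Z = merges[["node_a", "node_b", "height", "size"]].to_numpy(dtype=float)
    tree = hierarchy.to_tree(Z)
    return _newick_root(tree, labels)


def _newick_root(tree, labels) -> str:
    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            name = labels[node.id] if labels else f"leaf{node.id}"
            return f"{name}:{length:.10g}"
        return f"({walk(node.left, node.dist)},{walk(node.right, node.dist)}):{length:.10g}"

    if tree.is_leaf():
        return f"{labels[tree.id] if labels else 'leaf0'};"
    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def beta_density_profiles(
    beta_matrix: MethylationMatrix, probe_ids, grid_size: int = 512
) -> pd.DataFrame:
    """Per-sample kernel density of beta values over [0, 1].

    Gaussian KDE with Silverman bandwidth and boundary reflection at 0 and
    1 so each curve integrates to ~1 on the unit interval.  Returns a
    DataFrame (grid x samples) with the grid as index.
    """
    probe_ids = list(probe_ids)
    if not probe_ids:
        raise MethlineageError("empty probe set")
    grid = np.linspace(0.0, 1.0, grid_size)
    out = {}
    for s in beta_matrix.sample_ids:
        x = beta_matrix.values.loc[probe_ids, s].to_numpy()
        if np.ptp(x) < 1e-12:
            # degenerate: all mass at one value; narrow gaussian bump
            dens = np.exp(-0.5 * ((grid - x[0]) / 0.01) ** 2)
            dens /= np.trapezoid(dens, grid)
        else:
            kde = gaussian_kde(x, bw_method="silverman")
            dens = kde(grid) + kde(-grid) + kde(2.0 - grid)
            dens /= np.trapezoid(dens, grid)
        out[s] = dens
    return pd.DataFrame(out, index=grid)
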