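"""Grouping indicators by similarity of environmental responsiveness.

Two indicators respond to the environment alike when their mutual-prediction
matrices look alike.  Similarity is the plain Euclidean distance between the
flattened matrices (sRMSE is already dimensionless, so no rescaling), the
dendrogram comes from Ward's method (the Ward.D2 convention: Ward's objective
on squared Euclidean distances with square-root merge heights), and cluster
significance is decided by the SIMPROF permutation routine: descend the tree
from the root, test each node's objects for multivariate structure, and stop
at the first homogeneous nodes — those are the significant clusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


def _matrix_values(obj) -> np.ndarray:
    if hasattr(obj, "srmse"):
        return np.asarray(obj.srmse, dtype=float)
    return np.asarray(obj, dtype=float)


def matrix_distance(a, b) -> float:
    """Euclidean norm of the entrywise difference between two matrices.

    Undefined (NaN) entries must sit at identical positions in both matrices
    and are excluded from the sum; mismatched masks or shapes raise.
    """
    A, B = _matrix_values(a), _matrix_values(b)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    mask_a, mask_b = np.isnan(A), np.isnan(B)
    if not np.array_equal(mask_a, mask_b):
        raise ValueError("undefined entries are not at identical positions")
    diff = A[~mask_a] - B[~mask_b]
    return float(np.sqrt(np.sum(diff**2)))


def ward_clustering(distances) -> np.ndarray:
    """Ward (D2) agglomeration from pairwise distances.

    Accepts a condensed distance vector or a square symmetric matrix and
    returns a scipy linkage array.  Deterministic for a given input order.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim == 2:
        d = squareform(d, checks=True)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite pairwise distance")
    if d.size < 1:
        raise ValueError("need at least 2 objects")
    return linkage(d, method="ward")


@dataclass
class ClassificationResult:
    """Dendrogram plus SIMPROF-gated significant clusters."""

    names: list[str]
    linkage: np.ndarray
    distances: np.ndarray  # condensed
    labels: pd.Series  # object -> cluster id (1-based)
    node_pvalues: pd.DataFrame  # per tested internal node: size, pi, p, significant
    alpha: float
    n_perm: int
    seed: int | None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())


def _sorted_profile(sub: np.ndarray) -> np.ndarray:
    return np.sort(pdist(sub))


def _permuted_profiles(sub: np.ndarray, n_perm: int, rng) -> np.ndarray:
    """Ordered distance profiles of tables with each variable independently
    permuted across objects (the SIMPROF exchangeability null)."""
    k, v = sub.shape
    out = np.empty((n_perm, k * (k - 1) // 2))
    for p in range(n_perm):
        idx = np.argsort(rng.random((k, v)), axis=0)
        permuted = np.take_along_axis(sub, idx, axis=0)
        out[p] = _sorted_profile(permuted)
    return out


def simprof(
    data,
    names=None,
    alpha: float = 0.01,
    n_perm: int = 999,
    seed: int | None = None,
    Z: np.ndarray | None = None,
) -> ClassificationResult:
    """Similarity-profile permutation test gating a Ward dendrogram.

    ``data`` is an objects x variables table.  At each internal node (taken
    top-down from the root) the test statistic pi is the summed absolute
    deviation of the node's ordered pairwise-distance profile from the mean
    ordered profile of permuted tables; its null distribution comes from a
    second, independent batch of permutations, and p uses the add-one
    estimator (1 + #{pi_perm >= pi_obs}) / (1 + n_perm).  Descent continues
    only through significant nodes; the leaves of the stopped traversal are
    the significant clusters.  Nodes with fewer than 3 objects are
    untestable and treated as homogeneous.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be an objects x variables table")
    n = X.shape[0]
    if names is None:
        names = [f"obj{i}" for i in range(n)]
    names = [str(nm) for nm in names]
    if len(names) != n:
        raise ValueError("names must match the number of objects")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = np.random.default_rng(seed)

    condensed = pdist(X)
    if Z is None:
        Z = ward_clustering(condensed)

    root = to_tree(Z)
    tested: list[dict] = []
    clusters: list[list[int]] = []

    def visit(node) -> None:
        members = node.pre_order(lambda leaf: leaf.id)
        if node.is_leaf() or len(members) < 3:
            if not node.is_leaf():
                logger.info("node with %d objects untestable; treated as homogeneous", len(members))
            clusters.append(members)
            return
        sub = X[np.sort(members)]
        obs = _sorted_profile(sub)
        mean_profile = _permuted_profiles(sub, n_perm, rng).mean(axis=0)
        pi_obs = float(np.abs(obs - mean_profile).sum())
        null = np.abs(_permuted_profiles(sub, n_perm, rng) - mean_profile).sum(axis=1)
        p = float((1 + np.sum(null >= pi_obs)) / (1 + n_perm))
        significant = p <= alpha
        tested.append(
            {"size": len(members), "pi": pi_obs, "p": p, "significant": significant}
        )
        if significant:
            visit(node.get_left())
            visit(node.get_right())
        else:
            clusters.append(members)

    if n == 1:
        clusters.append([0])
    else:
        if n < 3:
            warnings.warn("fewer than 3 objects: SIMPROF untestable, one cluster reported")
        visit(root)

    lab = np.zeros(n, dtype=int)
    for cid, members in enumerate(sorted(clusters, key=min), start=1):
        lab[members] = cid
    labels = pd.Series(lab, index=pd.Index(names, name="object"))
    node_pvalues = pd.DataFrame(tested, columns=["size", "pi", "p", "significant"])
    return ClassificationResult(
        names, Z, condensed, labels, node_pvalues, alpha, n_perm, seed
    )


def classify_indicators(
    matrices: dict,
    alpha: float = 0.01,
    n_perm: int = 999,
    seed: int | None = None,
) -> ClassificationResult:
    """Full pipeline: matrix distances -> Ward dendrogram -> SIMPROF clusters.

    ``matrices`` maps indicator name to its mutual-prediction matrix (array
    or :class:`~divdyn.mutual.MutualPredictionMatrix`).  Indicators are
    processed in lexicographic name order, so the result is invariant to the
    order of the mapping.  Entries undefined in *any* matrix are dropped
    from every matrix before computing distances (logged).
    """
    names = sorted(str(k) for k in matrices)
    if len(names) < 2:
        raise ValueError("need at least 2 indicators")
    mats = [_matrix_values(matrices[k]) for k in names]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("all mutual-prediction matrices must share a shape")
    flat = np.stack([m.ravel() for m in mats])
    defined = np.all(np.isfinite(flat), axis=0)
    if not defined.all():
        logger.warning(
            "dropping %d matrix entries undefined in at least one indicator",
            int(np.sum(~defined)),
        )
    flat = flat[:, defined]
    return simprof(flat, names, alpha=alpha, n_perm=n_perm, seed=seed)


def to_newick(Z: np.ndarray, names: list[str]) -> str:
    """Dendrogram as a Newick string; branch lengths are merge-height gaps."""
    root = to_tree(Z)

    def fmt(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.10g}"
        left = fmt(node.get_left(), node.dist)
        right = fmt(node.get_right(), node.dist)
        return f"({left},{right}):{length:.10g}"

    return fmt(root, root.dist) + ";"
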